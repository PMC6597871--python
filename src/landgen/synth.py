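"""Synthetic landscapes, clustered sampling designs and genotypes.

The generator instantiates the statistical structure the rest of the
pipeline assumes: Gaussian-random-field rasters for elevation and climate;
habitat maps by thresholding a field; a clustered sampling design (several
colonies per location, within-location geographic distance zero); and
genotypes whose between-location allele-frequency covariance decays with
circuit-theory resistance distance on a chosen surface (the
isolation-by-resistance hypothesis made generative).  A minority of loci
can be "spiked" with allele-frequency clines along an environmental
gradient to exercise the association scans.  Every dataset is fully
reproducible from its seed, and the generating parameters are recorded in
a :class:`TruthRecord`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .genotypes import GenotypeTable
from .rasters import RasterGrid, write_ascii_grid
from .resistance import ResistanceSurface, pairwise_circuit_resistance

__all__ = [
    "TruthRecord",
    "SyntheticDataset",
    "simulate_landscape",
    "simulate_sampling_design",
    "simulate_genotypes_ibr",
    "spike_adaptive_loci",
    "write_dataset",
]


@dataclass
class TruthRecord:
    """Generating parameters of a synthetic dataset (ground truth)."""

    surface: str = ""
    sigma_logit: float = 0.0
    decay_range: float = 0.0
    location_noise_sd: float = 0.0
    adaptive_loci: list = field(default_factory=list)
    adaptive_slope: float = 0.0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


@dataclass
class SyntheticDataset:
    rasters: dict
    samples: pd.DataFrame
    genotypes: GenotypeTable
    env: pd.DataFrame | None
    truth: TruthRecord


def _gaussian_field(shape, corr_cells, rng) -> np.ndarray:
    """Stationary Gaussian random field via smoothed white noise,
    standardized to zero mean and unit variance."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=corr_cells, mode="wrap")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def simulate_landscape(
    nrows: int = 40,
    ncols: int = 40,
    autocorr_range: float = 5.0,
    habitat_prob: float = 0.5,
    cellsize: float = 0.05,
    xllcorner: float = -42.0,
    yllcorner: float = -8.0,
    seed: int = 0,
) -> dict:
    """Generate a coherent set of raster layers.

    Returns a dict of :class:`RasterGrid`: ``elevation`` and ``climate``
    (independent unit-variance Gaussian fields with correlation length
    ``autocorr_range`` cells), ``habitat`` (a third field thresholded so a
    fraction ``habitat_prob`` of cells is habitat, coded 1/0) and
    ``roughness`` (local standard deviation of elevation in a 3x3 window).
    """
    if nrows < 10 or ncols < 10:
        raise ValueError("landscape must be at least 10x10")
    rng = np.random.default_rng(seed)
    elev = _gaussian_field((nrows, ncols), autocorr_range, rng)
    climate = _gaussian_field((nrows, ncols), autocorr_range, rng)
    habitat_field = _gaussian_field((nrows, ncols), autocorr_range, rng)
    if habitat_prob >= 1.0:
        habitat = np.ones((nrows, ncols))
    elif habitat_prob <= 0.0:
        habitat = np.zeros((nrows, ncols))
    else:
        thr = np.quantile(habitat_field, 1.0 - habitat_prob)
        habitat = (habitat_field >= thr).astype(float)
    mean = ndimage.uniform_filter(elev, size=3, mode="nearest")
    sq_mean = ndimage.uniform_filter(elev ** 2, size=3, mode="nearest")
    roughness = np.sqrt(np.maximum(sq_mean - mean ** 2, 0.0))

    def _grid(v):
        return RasterGrid(v, cellsize, xllcorner, yllcorner)

    return {
        "elevation": _grid(elev - elev.min() + 0.1),
        "climate": _grid(climate - climate.min() + 0.1),
        "habitat": _grid(habitat),
        "roughness": _grid(roughness + 0.01),
    }


def simulate_sampling_design(
    n_locations: int,
    colonies_per_location_mean: float,
    raster: RasterGrid,
    seed: int = 0,
) -> pd.DataFrame:
    """Place sampling locations on valid cells and draw colony counts.

    Locations occupy distinct valid cells chosen uniformly; colony counts
    are 1 + Poisson(mean - 1) (truncated at one colony).  Colonies share
    their location's coordinates, so within-location distance is zero.
    """
    if n_locations < 2:
        raise ValueError("need at least 2 locations")
    rng = np.random.default_rng(seed)
    valid = np.argwhere(~np.isnan(raster.values))
    if valid.shape[0] < n_locations:
        raise ValueError("raster too small for the requested number of locations")
    pick = rng.choice(valid.shape[0], size=n_locations, replace=False)
    xs = raster.x_centers()
    ys = raster.y_centers()
    rows = []
    for loc_idx, cell in enumerate(valid[pick]):
        r, c = cell
        n_col = 1 + rng.poisson(max(colonies_per_location_mean - 1.0, 0.0))
        for k in range(n_col):
            rows.append({
                "id": f"L{loc_idx:03d}C{k:02d}",
                "lon": float(xs[c]), "lat": float(ys[r]),
                "location_id": f"L{loc_idx:03d}",
            })
    return pd.DataFrame(rows)


def habitat_mask(habitat: RasterGrid) -> RasterGrid:
    """Raster whose valid cells are the habitat cells only.

    Used to constrain sampling designs to habitat (colonies nest in
    habitat; sampling follows beekeepers), which also keeps the node-local
    resistance of every sampling location comparable.
    """
    vals = np.where(habitat.values == 1.0, 1.0, np.nan)
    return RasterGrid(vals, habitat.cellsize, habitat.xllcorner,
                      habitat.yllcorner, habitat.crs, habitat.nodata)


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_genotypes_ibr(
    design: pd.DataFrame,
    surface: ResistanceSurface,
    n_loci: int = 1000,
    fst_scale: float = 0.3,
    decay_range: float | None = None,
    location_noise_sd: float = 0.0,
    seed: int = 0,
    neighborhood: int = 8,
) -> tuple[GenotypeTable, TruthRecord]:
    """Genotypes whose spatial covariance decays with circuit resistance.

    Per locus, an ancestral frequency p0 ~ U(0.1, 0.9) is drawn and the
    location logit-frequencies follow a multivariate normal with mean
    logit(p0) and covariance sigma^2 exp(-R_ab / phi), where R_ab is the
    effective resistance between locations a and b on ``surface``,
    sigma = ``fst_scale`` and phi = ``decay_range`` (default: the median
    off-diagonal resistance, putting the decay in the middle of the
    realized resistance scale).  ``location_noise_sd`` adds independent
    location-level logit noise per locus — shared drift within a location
    that creates the location-pair dependence the nested MLPE absorbs.
    Individual dosages are Binomial(2, p_location).
    """
    if n_loci < 100:
        raise ValueError("simulate at least 100 loci")
    rng = np.random.default_rng(seed)
    locs = design.drop_duplicates("location_id").reset_index(drop=True)
    rd = pairwise_circuit_resistance(surface, locs, neighborhood=neighborhood)
    R = rd.values
    if not np.isfinite(R).all():
        raise ValueError("disconnected sampling locations on the surface")
    if decay_range is None:
        off = R[np.triu_indices(R.shape[0], k=1)]
        decay_range = float(np.median(off)) if off.size else 1.0
        decay_range = max(decay_range, 1e-6)
    cov = fst_scale ** 2 * np.exp(-R / decay_range)
    if location_noise_sd > 0:
        cov = cov + location_noise_sd ** 2 * np.eye(R.shape[0])
    # numerical jitter for the Cholesky factor
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(R.shape[0]))

    n_loc = len(locs)
    p0 = rng.uniform(0.1, 0.9, n_loci)
    z = rng.standard_normal((n_loc, n_loci))
    logits = _logit(p0)[None, :] + L @ z
    p_loc = np.clip(_expit(logits), 0.001, 0.999)

    loc_index = {lid: k for k, lid in enumerate(locs["location_id"])}
    sample_loc = design["location_id"].map(loc_index).to_numpy()
    dosages = rng.binomial(2, p_loc[sample_loc, :]).astype(float)

    loci = pd.DataFrame({
        "id": [f"snp{j:05d}" for j in range(n_loci)],
        "chrom": ["chr1"] * n_loci,
        "pos": np.arange(1, n_loci + 1) * 100,
        "phred_quality": rng.uniform(35.0, 75.0, n_loci),
        "mean_depth": rng.uniform(22.0, 48.0, n_loci),
    })
    samples = design.copy().reset_index(drop=True)
    gt = GenotypeTable(dosages, loci, samples)
    truth = TruthRecord(
        surface=surface.provenance, sigma_logit=fst_scale,
        decay_range=float(decay_range), location_noise_sd=location_noise_sd,
        seed=seed, extra={"n_loci": n_loci, "n_locations": n_loc},
    )
    return gt, truth


def spike_adaptive_loci(
    gt: GenotypeTable,
    env_values: np.ndarray,
    fraction: float = 0.05,
    slope: float = 1.0,
    seed: int = 0,
) -> tuple[GenotypeTable, TruthRecord]:
    """Replace a fraction of loci with environmental allele-frequency clines.

    Selected loci get per-sample frequencies logistic(a + slope * env)
    with a ~ U(logit 0.2, logit 0.8) and env standardized; dosages are
    redrawn Binomial(2, p).  The modified locus indices are recorded.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    env = np.asarray(env_values, dtype=float)
    if env.size != gt.n_samples:
        raise ValueError("environment vector length must match samples")
    rng = np.random.default_rng(seed)
    env_std = (env - env.mean()) / env.std(ddof=0)
    n_spike = max(int(round(fraction * gt.n_loci)), 1)
    idx = np.sort(rng.choice(gt.n_loci, size=n_spike, replace=False))
    dosages = gt.dosages.copy()
    for j in idx:
        a = rng.uniform(_logit(0.2), _logit(0.8))
        p = np.clip(_expit(a + slope * env_std), 0.001, 0.999)
        dosages[:, j] = rng.binomial(2, p)
    out = GenotypeTable(dosages, gt.loci.copy(), gt.samples.copy())
    truth = TruthRecord(adaptive_loci=idx.tolist(), adaptive_slope=slope, seed=seed)
    return out, truth


def sample_env_matrix(design: pd.DataFrame, rasters: dict) -> pd.DataFrame:
    """Environmental values at each sample's cell, one column per raster."""
    out = {"sample_id": design["id"].tolist()}
    for name, grid in rasters.items():
        vals = []
        for lon, lat in zip(design["lon"], design["lat"]):
            r, c = grid.index_of(float(lon), float(lat))
            vals.append(float(grid.values[r, c]))
        out[name] = vals
    return pd.DataFrame(out)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write VCF, metadata CSV, ASCII rasters and the truth record."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(ds.genotypes, outdir / "genotypes.vcf")
    meta = ds.samples.rename(columns={"id": "sample_id"})
    meta.to_csv(outdir / "samples.csv", index=False)
    for name, grid in ds.rasters.items():
        write_ascii_grid(grid, outdir / f"{name}.asc")
    if ds.env is not None:
        ds.env.to_csv(outdir / "environment.csv", index=False)
    (outdir / "truth.json").write_text(ds.truth.to_json())


def write_vcf(gt: GenotypeTable, path) -> None:
    """Write the genotype table as a minimal VCF 4.2 text file."""
    gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gt.samples["id"].astype(str)) + "\n")
        for j in range(gt.n_loci):
            rec = gt.loci.iloc[j]
            depth = int(round(rec["mean_depth"])) if np.isfinite(rec["mean_depth"]) else "."
            cells = []
            for val in gt.dosages[:, j]:
                g = "./." if np.isnan(val) else gt_strings[val]
                cells.append(f"{g}:{depth}")
            fh.write(
                f"{rec['chrom']}\t{int(rec['pos'])}\t{rec['id']}\tA\tT\t"
                f"{rec['phred_quality']:.2f}\t.\t.\tGT:DP\t" + "\t".join(cells) + "\n"
            )
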