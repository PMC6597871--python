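"""Genotype tables: VCF input, locus quality filters, LD pruning, clusters.

The central container is :class:`GenotypeTable`, a samples x loci matrix of
allele dosages (0/1/2 copies of the alternate allele, NaN for missing calls)
together with per-locus records (position, site quality, mean depth) and
per-sample records (coordinates, sampling location, optional genetic
cluster).  The filter chain mirrors a typical RADseq quality-control
protocol: site quality (Phred) bounds, mean-depth bounds, per-locus
missingness, minor-allele frequency, a Hardy-Weinberg exact test, and greedy
LD pruning on the dosage correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeTable",
    "FilterSpec",
    "FilterReport",
    "read_vcf",
    "apply_locus_filters",
    "hwe_exact_test",
    "ld_prune",
    "assign_clusters",
]

#: maximum tolerated fraction of missing genotype calls at a locus
MAX_MISSING_FRACTION = 0.25


@dataclass
class GenotypeTable:
    """Allele-dosage matrix with locus and sample metadata.

    ``dosages[i, j]`` counts alternate-allele copies for sample *i* at locus
    *j* (0, 1 or 2; NaN = missing).  ``loci`` has columns ``id, chrom, pos,
    phred_quality, mean_depth``; ``samples`` has ``id, lon, lat, location_id``
    and optionally ``cluster``.
    """

    dosages: np.ndarray
    loci: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x loci)")
        n, m = self.dosages.shape
        if m < 1:
            raise ValueError("a genotype table needs at least one locus")
        if len(self.loci) != m or len(self.samples) != n:
            raise ValueError("metadata lengths do not match the dosage matrix")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.loci["id"].duplicated().any():
            raise ValueError("locus ids must be unique")
        if self.samples["id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        if not np.isfinite(self.samples[["lon", "lat"]].to_numpy(float)).all():
            raise ValueError("every sample needs finite coordinates")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus from non-missing genotypes."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_loci(self, keep: np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        return GenotypeTable(
            dosages=self.dosages[:, keep],
            loci=self.loci.iloc[keep].reset_index(drop=True),
            samples=self.samples.copy(),
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        return GenotypeTable(
            dosages=self.dosages[keep, :],
            loci=self.loci.copy(),
            samples=self.samples.iloc[keep].reset_index(drop=True),
        )


@dataclass
class FilterSpec:
    """Thresholds of the locus filter chain.

    Defaults follow a stringent RADseq protocol: Phred site quality in
    [30, 80], mean depth in [20, 50], LD pruning at r^2 < 0.4 and a
    Hardy-Weinberg exact-test cutoff of p < 1e-4.
    """

    phred_min: float = 30.0
    phred_max: float = 80.0
    depth_min: float = 20.0
    depth_max: float = 50.0
    ld_r2_max: float = 0.4
    hwe_alpha: float = 1e-4
    maf_min: float | None = None
    max_missing: float = MAX_MISSING_FRACTION

    def __post_init__(self) -> None:
        for name in ("phred_min", "phred_max", "depth_min", "depth_max"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.ld_r2_max <= 1.0:
            raise ValueError("ld_r2_max must lie in [0, 1]")
        if not 0.0 < self.hwe_alpha < 1.0:
            raise ValueError("hwe_alpha must lie in (0, 1)")


@dataclass
class FilterReport:
    """Per-criterion removal counts of one filter-chain application."""

    steps: list = field(default_factory=list)  # (step name, n removed)
    n_input: int = 0
    n_retained: int = 0

    @property
    def removed(self) -> dict:
        return dict(self.steps)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "steps": [{"step": s, "removed": int(r)} for s, r in self.steps],
        }


def read_vcf(path, metadata) -> GenotypeTable:
    """Load biallelic SNPs from a VCF plus a sample-metadata CSV.

    The metadata CSV must have columns ``sample_id, lon, lat, location_id``
    covering every sample in the VCF.  Multiallelic and non-SNP records are
    dropped (counted in the log); missing genotypes become NaN dosages.
    """
    from cyvcf2 import VCF

    meta = pd.read_csv(metadata)
    required = {"sample_id", "lon", "lat", "location_id"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata CSV lacks columns: {sorted(missing_cols)}")

    vcf = VCF(str(path), gts012=True)
    vcf_samples = list(vcf.samples)
    known = set(meta["sample_id"].astype(str))
    unmatched = [s for s in vcf_samples if s not in known]
    if unmatched:
        raise ValueError(f"samples present in VCF but absent from metadata: {unmatched}")

    dosage_cols, records = [], []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3 = missing
        gt[gt == 3] = np.nan
        depth = np.nan
        try:
            dp = var.format("DP")
            if dp is not None:
                dp = np.asarray(dp, dtype=float).ravel()
                dp[dp < 0] = np.nan
                depth = float(np.nanmean(dp)) if np.isfinite(dp).any() else np.nan
        except Exception:
            pass
        if not np.isfinite(depth):
            info_dp = var.INFO.get("DP")
            if info_dp is not None:
                depth = float(info_dp) / max(len(vcf_samples), 1)
        records.append({
            "id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}",
            "chrom": var.CHROM,
            "pos": int(var.POS),
            "phred_quality": float(var.QUAL) if var.QUAL is not None else np.nan,
            "mean_depth": depth,
        })
        dosage_cols.append(gt)
    if n_dropped:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)
    if not dosage_cols:
        raise ValueError("VCF contains no biallelic SNP records")

    loci = pd.DataFrame(records)
    meta = meta.set_index(meta["sample_id"].astype(str)).loc[vcf_samples]
    samples = pd.DataFrame({
        "id": vcf_samples,
        "lon": meta["lon"].to_numpy(float),
        "lat": meta["lat"].to_numpy(float),
        "location_id": meta["location_id"].to_numpy(),
    })
    if "cluster" in meta.columns:
        samples["cluster"] = meta["cluster"].to_numpy()
    return GenotypeTable(np.column_stack(dosage_cols), loci, samples)


def hwe_exact_test(dosages: np.ndarray) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and enumerates the probability
    of every possible heterozygote count, summing configurations whose
    probability does not exceed that of the observed one.  A monomorphic
    locus returns p = 1 (no evidence of deviation).
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    n = d.size
    if n < 5:
        raise ValueError("HWE exact test needs at least 5 non-missing genotypes")
    n_het = int((d == 1).sum())
    n_alt = int(d.sum())
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0

    # log P(het = h | allele counts) up to a shared constant
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    from scipy.special import gammaln

    n_common = 2 * n - n_rare
    logp = (
        gammaln(n + 1)
        - gammaln((n_rare - hs) / 2 + 1)
        - gammaln(hs + 1)
        - gammaln((n_common - hs) / 2 + 1)
        + hs * np.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[hs == n_het]
    if observed.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = probs[probs <= observed[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _pairwise_complete_r2(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of vector x with each column of Y,
    using pairwise-complete observations."""
    out = np.empty(Y.shape[1])
    for j in range(Y.shape[1]):
        ok = ~np.isnan(x) & ~np.isnan(Y[:, j])
        if ok.sum() < 3:
            out[j] = 0.0
            continue
        xv, yv = x[ok], Y[ok, j]
        xv = xv - xv.mean()
        yv = yv - yv.mean()
        denom = np.sqrt((xv ** 2).sum() * (yv ** 2).sum())
        out[j] = 0.0 if denom == 0 else ((xv * yv).sum() / denom) ** 2
    return out


def ld_prune(gt: GenotypeTable, r2_max: float = 0.4) -> GenotypeTable:
    """Greedy LD pruning on squared dosage correlation.

    Loci are visited in (chrom, pos) order; a locus is kept only if its r^2
    with every previously kept locus is <= ``r2_max``.  Deterministic.
    """
    if gt.n_loci < 2:
        return gt
    order = np.lexsort((gt.loci["pos"].to_numpy(), gt.loci["chrom"].astype(str).to_numpy()))
    kept: list[int] = []
    for j in order:
        x = gt.dosages[:, j]
        if np.nanstd(x) == 0:
            kept.append(j)  # monomorphic loci carry no LD information
            continue
        if kept:
            r2 = _pairwise_complete_r2(x, gt.dosages[:, kept])
            if (r2 > r2_max).any():
                continue
        kept.append(j)
    kept_sorted = np.sort(np.asarray(kept))
    return gt.subset_loci(kept_sorted)


def apply_locus_filters(gt: GenotypeTable, spec: FilterSpec) -> tuple[GenotypeTable, FilterReport]:
    """Apply the scalar locus filters in order: quality, depth, missingness,
    MAF, HWE.  LD pruning and outlier removal are separate steps.

    Returns the filtered table and a report itemizing removals per step.
    """
    if gt.n_loci < 1:
        raise ValueError("empty genotype table")
    report = FilterReport(n_input=gt.n_loci)
    current = gt

    def _step(name: str, keep_mask: np.ndarray, table: GenotypeTable) -> GenotypeTable:
        removed = int((~keep_mask).sum())
        report.steps.append((name, removed))
        if removed == table.n_loci:
            raise ValueError("all loci removed; relax the filter thresholds")
        return table.subset_loci(np.flatnonzero(keep_mask)) if removed else table

    qual = current.loci["phred_quality"].to_numpy(float)
    keep = np.isfinite(qual) & (qual >= spec.phred_min) & (qual <= spec.phred_max)
    current = (_step("quality", keep, current))

    depth = current.loci["mean_depth"].to_numpy(float)
    keep = np.isfinite(depth) & (depth >= spec.depth_min) & (depth <= spec.depth_max)
    current = (_step("depth", keep, current))

    miss = np.isnan(current.dosages).mean(axis=0)
    current = (_step("missingness", miss <= spec.max_missing, current))

    if spec.maf_min is not None and spec.maf_min > 0:
        p = current.allele_freq()
        maf = np.minimum(p, 1 - p)
        current = (_step("maf", maf >= spec.maf_min, current))

    if spec.hwe_alpha > 0:
        keep = np.ones(current.n_loci, dtype=bool)
        for j in range(current.n_loci):
            d = current.dosages[:, j]
            d = d[~np.isnan(d)]
            if d.size < 5 or np.all(d == d[0]):
                continue
            keep[j] = hwe_exact_test(current.dosages[:, j]) >= spec.hwe_alpha
        current = (_step("hwe", keep, current))

    report.n_retained = current.n_loci
    return current, report


def assign_clusters(gt: GenotypeTable, qmatrix: pd.DataFrame) -> GenotypeTable:
    """Assign each sample to its highest-ancestry cluster from a Q-matrix.

    ``qmatrix`` must have a ``sample_id`` column plus one column per
    cluster; rows must sum to 1 (tolerance 1e-6).  Ties go to the lowest
    cluster index (1-based), with a log note.
    """
    q = qmatrix.set_index(qmatrix["sample_id"].astype(str)).drop(columns=["sample_id"])
    missing = [s for s in gt.samples["id"].astype(str) if s not in q.index]
    if missing:
        raise ValueError(f"Q-matrix lacks samples: {missing}")
    q = q.loc[gt.samples["id"].astype(str)]
    mat = q.to_numpy(float)
    if mat.shape[1] < 1:
        raise ValueError("Q-matrix needs at least one ancestry column")
    sums = mat.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = gt.samples["id"].iloc[np.flatnonzero(np.abs(sums - 1.0) > 1e-6)].tolist()
        raise ValueError(f"ancestry rows do not sum to 1 for samples: {bad}")
    cluster = mat.argmax(axis=1) + 1  # 1-based
    ties = np.isclose(mat, mat.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info("assign_clusters: %d tie(s) broken toward the lowest cluster index",
                    int(ties.sum()))
    samples = gt.samples.copy()
    samples["cluster"] = cluster
    return GenotypeTable(gt.dosages, gt.loci.copy(), samples)
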