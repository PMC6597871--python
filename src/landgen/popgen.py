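"""Per-cluster diversity statistics, Tajima's D and the LD method for Ne.

Diploid genotypes are reduced to allele counts wherever a haplotype-level
statistic (pi, S, Tajima's D) is needed; under the infinite-sites model the
allele counts are sufficient.  Tajima's D carries a Monte-Carlo bias
correction for minor-allele-frequency filtering: the same filter applied to
neutral constant-size coalescent replicates yields the expected shift of D,
which is subtracted from the observed value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

__all__ = [
    "DiversitySummary",
    "NeutralSimSpec",
    "diversity_metrics",
    "tajimas_d",
    "tajimas_d_from_counts",
    "simulate_neutral_sample",
    "debias_tajimas_d",
    "ld_ne",
]


# ---------------------------------------------------------------------------
# Tajima's D

def _tajima_constants(n: int) -> dict:
    """The classical coefficients for n sequences (n >= 4)."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def tajimas_d_from_counts(derived_counts: np.ndarray, n_haplotypes: int) -> float:
    """Tajima's D from per-site derived-allele counts among n haplotypes.

    D = (pi_hat - S/a1) / sqrt(e1*S + e2*S*(S-1)).  Returns NaN when there
    are no segregating sites.
    """
    k = np.asarray(derived_counts, dtype=float)
    n = int(n_haplotypes)
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 haplotypes")
    seg = (k > 0) & (k < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    k = k[seg]
    pi_hat = float(np.sum(2.0 * k * (n - k) / (n * (n - 1.0))))
    c = _tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1.0)
    return float((pi_hat - S / c["a1"]) / np.sqrt(var))


def tajimas_d(gt: GenotypeTable) -> float:
    """Genome-wide Tajima's D treating 2N diploid genotypes as 2N haplotypes.

    Uses only loci with complete data so that a single haplotype count
    applies; loci with missing calls are dropped with their alleles.
    """
    if gt.n_samples < 2:
        raise ValueError("need at least 2 diploid samples")
    complete = ~np.isnan(gt.dosages).any(axis=0)
    d = gt.dosages[:, complete]
    if d.shape[1] == 0:
        raise ValueError("no loci with complete genotype data")
    counts = d.sum(axis=0)
    return tajimas_d_from_counts(counts, 2 * gt.n_samples)


# ---------------------------------------------------------------------------
# Neutral coalescent simulation

@dataclass
class NeutralSimSpec:
    """Conditions of a constant-size neutral coalescent simulation.

    Either ``s_fixed`` (number of segregating sites, placed multinomially by
    branch length) or ``theta`` (population mutation rate; Poisson mutation
    count) must be set.
    """

    n_haplotypes: int
    s_fixed: int | None = None
    theta: float | None = None
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes < 4:
            raise ValueError("need at least 4 haplotypes")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")
        if (self.s_fixed is None) == (self.theta is None):
            raise ValueError("set exactly one of s_fixed or theta")


def _coalescent_branches(n: int, rng: np.random.Generator):
    """One standard coalescent genealogy for n tips.

    Returns (lengths, sizes): per-branch-segment total length (in coalescent
    units) and the number of descendant tips of each segment, plus the list
    of per-segment descendant index arrays.
    """
    lineages = [np.array([i]) for i in range(n)]
    seg_len: list[float] = []
    seg_tips: list[np.ndarray] = []
    k = n
    while k > 1:
        t = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        for lin in lineages:
            seg_len.append(t)
            seg_tips.append(lin)
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (i, j) if i < j else (j, i)
        merged = np.concatenate([lineages[i], lineages[j]])
        lineages[i] = merged
        lineages.pop(j)
        k -= 1
    return np.asarray(seg_len), seg_tips


def simulate_neutral_sample(spec: NeutralSimSpec) -> list[np.ndarray]:
    """Simulate neutral samples; returns one 0/1 haplotype matrix
    (n_haplotypes x S) per replicate.

    Coalescence times are exponential with rate k(k-1)/2 while k lineages
    remain; mutations fall on branch segments with probability proportional
    to segment length (infinite sites, one column per mutation).
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.replicates):
        lengths, tips = _coalescent_branches(spec.n_haplotypes, rng)
        total = lengths.sum()
        if spec.s_fixed is not None:
            n_mut = spec.s_fixed
        else:
            n_mut = rng.poisson(spec.theta / 2.0 * total)
        if n_mut == 0:
            out.append(np.zeros((spec.n_haplotypes, 0), dtype=np.int8))
            continue
        hits = rng.choice(lengths.size, size=n_mut, p=lengths / total)
        mat = np.zeros((spec.n_haplotypes, n_mut), dtype=np.int8)
        for col, h in enumerate(hits):
            mat[tips[h], col] = 1
        out.append(mat)
    return out


def _filter_counts_maf(counts: np.ndarray, n: int, maf_min: float) -> np.ndarray:
    maf = np.minimum(counts, n - counts) / n
    return counts[maf >= maf_min]


def debias_tajimas_d(d_obs: float, maf_min: float, spec: NeutralSimSpec) -> dict:
    """Correct an observed Tajima's D for the bias of a MAF filter.

    Simulates neutral replicates matching the observed sample size and site
    count, applies the same MAF filter to each, and subtracts the mean of
    the filtered replicate D values (the expected shift under neutrality)
    from the observation.

    Returns a dict with ``corrected``, ``bias`` (mean filtered null D),
    ``mc_se`` and the replicate count.
    """
    reps = simulate_neutral_sample(spec)
    n = spec.n_haplotypes
    ds = []
    for mat in reps:
        counts = mat.sum(axis=0)
        counts = _filter_counts_maf(counts, n, maf_min)
        if counts.size == 0:
            continue
        d = tajimas_d_from_counts(counts, n)
        if np.isfinite(d):
            ds.append(d)
    if not ds:
        raise ValueError("the MAF filter removed every site in every replicate")
    ds = np.asarray(ds)
    bias = float(ds.mean())
    return {
        "corrected": float(d_obs) - bias,
        "bias": bias,
        "mc_se": float(ds.std(ddof=1) / np.sqrt(ds.size)),
        "replicates_used": int(ds.size),
    }


# ---------------------------------------------------------------------------
# Diversity summaries

@dataclass
class DiversitySummary:
    """Per-cluster diversity estimates with bootstrap confidence intervals."""

    cluster: object
    n: int
    ho: float
    ho_ci: tuple[float, float]
    he: float
    he_ci: tuple[float, float]
    f: float
    f_ci: tuple[float, float]
    pi: float
    pi_ci: tuple[float, float]
    tajima_d: float = float("nan")
    tajima_d_corrected: float = float("nan")
    ne: float = float("nan")
    ne_ci: tuple[float, float] = (float("nan"), float("nan"))

    def to_row(self) -> dict:
        return {
            "cluster": self.cluster, "N": self.n,
            "Ne": self.ne, "Ne_lo": self.ne_ci[0], "Ne_hi": self.ne_ci[1],
            "Ho": self.ho, "Ho_lo": self.ho_ci[0], "Ho_hi": self.ho_ci[1],
            "He": self.he, "He_lo": self.he_ci[0], "He_hi": self.he_ci[1],
            "F": self.f, "F_lo": self.f_ci[0], "F_hi": self.f_ci[1],
            "pi": self.pi, "pi_lo": self.pi_ci[0], "pi_hi": self.pi_ci[1],
            "tajima_d": self.tajima_d,
            "tajima_d_corrected": self.tajima_d_corrected,
        }


def _per_locus_stats(d: np.ndarray):
    """Per-locus Ho, unbiased He and per-site pi for one cluster block."""
    miss = np.isnan(d)
    n_obs = (~miss).sum(axis=0).astype(float)
    het = np.nansum(d == 1, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = het / n_obs
        p = np.nansum(d, axis=0) / (2.0 * n_obs)
        two_n = 2.0 * n_obs
        he = 2.0 * p * (1 - p) * two_n / (two_n - 1.0)
        k = np.nansum(d, axis=0)
        pi = 2.0 * k * (two_n - k) / (two_n * (two_n - 1.0))
    return ho, he, pi, p, n_obs


def _per_sample_f(d: np.ndarray, p: np.ndarray, n_obs: np.ndarray) -> np.ndarray:
    """Method-of-moments inbreeding coefficient per sample:
    (observed hom - expected hom) / (loci - expected hom)."""
    obs = ~np.isnan(d)
    hom = (d == 0) | (d == 2)
    with np.errstate(invalid="ignore"):
        e_hom_locus = 1.0 - 2.0 * p * (1 - p) * (2.0 * n_obs) / (2.0 * n_obs - 1.0)
    fs = np.empty(d.shape[0])
    for i in range(d.shape[0]):
        use = obs[i] & np.isfinite(e_hom_locus)
        o = float(hom[i, use].sum())
        e = float(e_hom_locus[use].sum())
        m = float(use.sum())
        fs[i] = (o - e) / (m - e) if m - e > 0 else np.nan
    return fs


def diversity_metrics(
    gt: GenotypeTable,
    by_cluster: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
    include_ne: bool = False,
) -> list[DiversitySummary]:
    """Cluster-level Ho, He, F, pi and Tajima's D with 95% bootstrap CIs.

    CIs come from ``n_boot`` nonparametric bootstrap draws over loci
    (percentile method).  ``include_ne`` additionally runs the LD method
    for effective population size (monogamy model) per cluster.
    """
    if by_cluster and "cluster" in gt.samples.columns:
        groups = [(c, np.flatnonzero((gt.samples["cluster"] == c).to_numpy()))
                  for c in sorted(gt.samples["cluster"].unique())]
    else:
        groups = [("all", np.arange(gt.n_samples))]

    rng = np.random.default_rng(seed)
    out = []
    for label, idx in groups:
        if idx.size < 2:
            raise ValueError(f"cluster {label!r} has fewer than 2 samples")
        d = gt.dosages[idx, :]
        ho, he, pi, p, n_obs = _per_locus_stats(d)
        usable = np.isfinite(ho) & np.isfinite(he) & (n_obs >= 2)
        ho, he, pi, p, n_obs = (a[usable] for a in (ho, he, pi, p, n_obs))
        db = d[:, usable]
        fs = _per_sample_f(db, p, n_obs)
        m = ho.size

        def _cluster_values(loci_idx):
            h_o = float(np.mean(ho[loci_idx]))
            h_e = float(np.mean(he[loci_idx]))
            p_i = float(np.mean(pi[loci_idx]))
            f_mean = float(np.nanmean(_per_sample_f(db[:, loci_idx], p[loci_idx], n_obs[loci_idx])))
            return h_o, h_e, f_mean, p_i

        est = (float(ho.mean()), float(he.mean()), float(np.nanmean(fs)), float(pi.mean()))
        boots = np.empty((n_boot, 4))
        for b in range(n_boot):
            draw = rng.integers(0, m, size=m)
            boots[b] = _cluster_values(draw)
        lo = np.percentile(boots, 2.5, axis=0)
        hi = np.percentile(boots, 97.5, axis=0)

        complete = ~np.isnan(db).any(axis=0)
        td = (tajimas_d_from_counts(db[:, complete].sum(axis=0), 2 * idx.size)
              if complete.any() else float("nan"))

        summary = DiversitySummary(
            cluster=label, n=int(idx.size),
            ho=est[0], ho_ci=(float(lo[0]), float(hi[0])),
            he=est[1], he_ci=(float(lo[1]), float(hi[1])),
            f=est[2], f_ci=(float(lo[2]), float(hi[2])),
            pi=est[3], pi_ci=(float(lo[3]), float(hi[3])),
            tajima_d=td,
        )
        if include_ne and idx.size >= 8 and m >= 2:
            sub = gt.subset_samples(idx)
            try:
                ne, ci = ld_ne(sub)
                summary.ne, summary.ne_ci = ne, ci
            except ValueError:
                pass
        out.append(summary)
    return out


def summaries_to_frame(summaries: list[DiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])


# ---------------------------------------------------------------------------
# LD method for effective population size

def _mean_pairwise_r2(d: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared dosage correlation over all locus pairs (complete-case
    per pair) and the per-pair values for jackknifing."""
    m = d.shape[1]
    vals = []
    for a in range(m - 1):
        for b in range(a + 1, m):
            ok = ~np.isnan(d[:, a]) & ~np.isnan(d[:, b])
            if ok.sum() < 4:
                continue
            x, y = d[ok, a], d[ok, b]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            vals.append((a, b, r * r, ok.sum()))
    if not vals:
        raise ValueError("no usable locus pairs for the LD method")
    arr = np.asarray([(v[2]) for v in vals])
    return float(arr.mean()), np.asarray(vals, dtype=float)


def _ne_from_r2prime(r2p: float, mating: str) -> float:
    # Bias-corrected LD-method inversion (Waples 2006 quadratic, S >= 30
    # form); the monogamy model doubles the random-mating estimate.
    if r2p <= 0:
        return float("inf")
    disc = 1.0 / 9.0 - 2.76 * r2p
    if disc < 0:
        disc = 0.0
    ne = (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2p)
    if ne <= 0:
        return float("inf")
    if mating == "monogamy":
        ne *= 2.0
    return float(ne)


def ld_ne(
    gt: GenotypeTable,
    allele_freq_min: float = 0.05,
    mating: str = "monogamy",
) -> tuple[float, tuple[float, float]]:
    """Effective population size by the bias-corrected LD method.

    Squared dosage correlations across all locus pairs are averaged,
    corrected for the sampling contribution (expected r^2 of 1/S + 3.19/S^2
    for sample size S), and inverted to Ne; the monogamy mating model
    doubles the random-mating estimate.  The CI is a delete-one-locus
    jackknife.  A non-positive corrected r^2 yields Ne = inf.
    """
    if mating not in ("monogamy", "random"):
        raise ValueError("mating must be 'monogamy' or 'random'")
    if gt.n_samples < 8:
        raise ValueError("the LD method needs at least 8 samples")
    p = gt.allele_freq()
    maf = np.minimum(p, 1 - p)
    use = np.flatnonzero(np.isfinite(maf) & (maf >= allele_freq_min))
    if use.size < 2:
        raise ValueError("fewer than 2 loci pass the allele-frequency threshold")
    d = gt.dosages[:, use]
    _, pair_vals = _mean_pairwise_r2(d)
    s_mean = float(pair_vals[:, 3].mean())
    expected_sampling = 1.0 / s_mean + 3.19 / s_mean ** 2
    r2p = float(pair_vals[:, 2].mean()) - expected_sampling
    ne = _ne_from_r2prime(r2p, mating)

    # delete-one-locus jackknife on the corrected mean r^2
    m = d.shape[1]
    jack = []
    for drop in range(m):
        mask = (pair_vals[:, 0] != drop) & (pair_vals[:, 1] != drop)
        if mask.sum() == 0:
            continue
        r2p_j = float(pair_vals[mask, 2].mean()) - expected_sampling
        jack.append(_ne_from_r2prime(r2p_j, mating))
    jack = np.asarray([j for j in jack if np.isfinite(j)])
    if jack.size >= 3 and np.isfinite(ne):
        theta = jack.mean()
        se = np.sqrt((jack.size - 1) / jack.size * np.sum((jack - theta) ** 2))
        ci = (max(ne - 1.96 * se, 0.0), ne + 1.96 * se)
    else:
        ci = (float("nan"), float("inf"))
    return ne, ci
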