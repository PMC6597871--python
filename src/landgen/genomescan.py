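"""Outlier and environmental-association genome scans.

Environmental association follows the latent-factor logic: per-locus
regression of allele dosage on an environmental variable conditional on the
top-k principal components of the genotype matrix (which absorb population
structure), with test statistics recalibrated by the genomic inflation
factor (lambda = median chi-square / 0.4549) and declared significant by
Benjamini-Hochberg FDR at q.  Robustness to the choice of k is handled by
intersecting candidate sets across k-1, k, k+1.  Differentiation outliers
use a per-locus Fst converted to a chi-square score and pass through the
same lambda/BH calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "ScanResult",
    "env_variable_select",
    "latent_factor_scan",
    "fst_outlier_scan",
    "genomic_inflation_adjust",
    "bh_fdr",
    "intersect_candidates",
]

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = 0.45493642311957174


@dataclass
class ScanResult:
    """Per-locus statistics of one genome scan."""

    table: pd.DataFrame  # locus_id, stat, p_raw, p_adj, flagged
    lam: float
    mode: str
    k: int | None = None
    q: float = 0.05
    meta: dict = field(default_factory=dict)

    @property
    def flagged_loci(self) -> set:
        return set(self.table.loc[self.table["flagged"], "locus_id"])


def genomic_inflation_adjust(pvals: np.ndarray) -> tuple[float, np.ndarray]:
    """Recalibrate p-values by the genomic inflation factor.

    p-values are mapped to 1-df chi-square scores, lambda is the ratio of
    their median to the null median (0.4549), and adjusted p-values are the
    upper tail of chi2(1) at score/lambda.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 p-values to estimate lambda")
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    z2 = stats.chi2.isf(p, 1)
    lam = float(np.median(z2) / CHI2_1_MEDIAN)
    adjusted = stats.chi2.sf(z2 / lam, 1)
    return lam, np.minimum(adjusted, 1.0)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at rate q."""
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(np.asarray(pvals, dtype=float), alpha=q,
                               method="fdr_bh")
    return reject


def env_variable_select(env: pd.DataFrame, n_axes: int = 4) -> dict:
    """Pick one representative variable per leading principal component.

    The environmental matrix is scaled, PCA'd, and for each of the first
    ``n_axes`` components the variable most correlated (absolutely) with
    the component scores is selected; a variable already taken is replaced
    by the next best, with a log note.
    """
    num = env.select_dtypes(include=[np.number])
    if num.shape[1] < n_axes:
        raise ValueError("fewer variables than requested axes")
    if num.shape[0] <= n_axes:
        raise ValueError("need more observations than axes")
    X = num.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError(f"constant columns: {list(num.columns[sd == 0])}")
    Xs = (X - X.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    var_explained = s ** 2 / np.sum(s ** 2)
    scores = u * s

    selected = []
    for axis in range(n_axes):
        corr = np.array([
            abs(np.corrcoef(Xs[:, j], scores[:, axis])[0, 1])
            for j in range(Xs.shape[1])
        ])
        for j in np.argsort(-corr):
            name = num.columns[j]
            if name not in selected:
                if j != int(np.argmax(corr)):
                    logger.info(
                        "axis %d: top variable already taken; substituting %r",
                        axis + 1, name)
                selected.append(name)
                break
    return {
        "selected": selected,
        "variance_explained": var_explained[:n_axes].tolist(),
        "cumulative_variance": float(var_explained[:n_axes].sum()),
    }


def _imputed_centered_dosages(gt: GenotypeTable) -> np.ndarray:
    d = gt.dosages.copy()
    mean = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = mean[idx[1]]
    return d - d.mean(axis=0)


def latent_factor_scan(
    gt: GenotypeTable,
    env_values: np.ndarray,
    k: int = 0,
    q: float = 0.05,
    lambda_adjust: bool = True,
) -> ScanResult:
    """Environmental-association scan conditional on k latent factors.

    The latent factors are the top-k principal components of the centered
    (mean-imputed) dosage matrix.  Per locus, the dosage is regressed on
    the environmental variable plus the factors; the z-statistic of the
    environmental coefficient gives a two-sided p-value, which is then
    lambda-recalibrated and BH-flagged at rate ``q``.
    """
    env = np.asarray(env_values, dtype=float)
    if env.size != gt.n_samples:
        raise ValueError("environmental vector length does not match samples")
    if np.std(env) == 0:
        raise ValueError("environmental variable is constant")
    if k >= gt.n_samples - 2:
        raise ValueError("k must be smaller than n_samples - 2")
    D = _imputed_centered_dosages(gt)
    env = (env - env.mean()) / env.std(ddof=0)

    if k > 0:
        u, s, _ = np.linalg.svd(D, full_matrices=False)
        factors = u[:, :k]
        # residualize both sides on the factors (and the intercept, already
        # removed by centering)
        proj = factors @ (factors.T @ env)
        env_r = env - proj
        D_r = D - factors @ (factors.T @ D)
        dof = gt.n_samples - 2 - k
    else:
        env_r, D_r = env, D
        dof = gt.n_samples - 2
    if dof < 1:
        raise ValueError("not enough residual degrees of freedom")
    sxx = float(env_r @ env_r)
    if sxx <= 0:
        raise ValueError("environmental variable fully explained by the factors")
    slope = (env_r @ D_r) / sxx
    rss = np.sum(D_r ** 2, axis=0) - slope ** 2 * sxx
    rss = np.maximum(rss, 1e-300)
    se = np.sqrt(rss / dof / sxx)
    tstat = slope / se
    p_raw = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p_raw = np.clip(p_raw, np.finfo(float).tiny, 1.0)

    lam, adjusted = genomic_inflation_adjust(p_raw)
    p_adj = adjusted if lambda_adjust else p_raw
    flagged = bh_fdr(p_adj, q)
    table = pd.DataFrame({
        "locus_id": gt.loci["id"].to_numpy(),
        "stat": tstat, "p_raw": p_raw, "p_adj": p_adj, "flagged": flagged,
    })
    return ScanResult(table, lam, mode="env_association", k=k, q=q)


def _per_locus_fst(d: np.ndarray, cluster_codes: np.ndarray) -> np.ndarray:
    """Ratio-of-variance-components Fst per locus across clusters."""
    clusters = np.unique(cluster_codes)
    r = clusters.size
    p_c = np.empty((r, d.shape[1]))
    n_c = np.empty((r, d.shape[1]))
    for a, c in enumerate(clusters):
        block = d[cluster_codes == c]
        n_c[a] = (~np.isnan(block)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_c[a] = np.nansum(block, axis=0) / (2.0 * n_c[a])
    n_tot = np.sum(n_c, axis=0)
    p_bar = np.sum(n_c * p_c, axis=0) / n_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        # Nei-style moment estimator with small-sample-corrected
        # within-cluster heterozygosity; lambda recalibration downstream
        # absorbs any residual scale misfit.
        hs_c = 2.0 * p_c * (1 - p_c) * (2.0 * n_c) / np.maximum(2.0 * n_c - 1.0, 1.0)
        hs = np.sum(n_c * hs_c, axis=0) / n_tot
        ht = 2.0 * p_bar * (1 - p_bar)
        fst = np.where(ht > 0, (ht - hs) / np.maximum(ht, 1e-12), 0.0)
    return np.clip(fst, -1.0, 1.0)


def fst_outlier_scan(
    gt: GenotypeTable,
    clusters: np.ndarray | None = None,
    q: float = 0.05,
) -> ScanResult:
    """Differentiation-outlier scan across genetic clusters.

    Per-locus Fst is scaled to a chi-square score with df = n_clusters - 1
    (score = df * Fst / mean Fst, a Lewontin-Krakauer-style statistic),
    lambda-recalibrated and BH-flagged.  Monomorphic loci are excluded with
    a warning; the flagged loci are candidates for removal before neutral
    analyses.
    """
    if clusters is None:
        if "cluster" not in gt.samples.columns:
            raise ValueError("no cluster assignments available")
        clusters = gt.samples["cluster"].to_numpy()
    codes, uniq = pd.factorize(pd.Series(clusters))
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every cluster needs at least 2 samples")

    p = gt.allele_freq()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.all():
        logger.warning("fst_outlier_scan: excluding %d monomorphic loci",
                       int((~poly).sum()))
    d = gt.dosages[:, poly]
    fst = _per_locus_fst(d, codes)
    fst = np.maximum(fst, 0.0)
    df = len(uniq) - 1
    mean_fst = max(float(np.nanmean(fst)), 1e-12)
    score = df * fst / mean_fst
    p_raw = np.clip(stats.chi2.sf(score, df), np.finfo(float).tiny, 1.0)
    lam, p_adj = genomic_inflation_adjust(p_raw)
    flagged = bh_fdr(p_adj, q)
    table = pd.DataFrame({
        "locus_id": gt.loci["id"].to_numpy()[poly],
        "stat": score, "p_raw": p_raw, "p_adj": p_adj, "flagged": flagged,
    })
    return ScanResult(table, lam, mode="fst_outlier", q=q)


def intersect_candidates(scans: list[ScanResult]) -> set:
    """Loci flagged in every scan (e.g. across k-1, k, k+1 runs)."""
    if len(scans) < 2:
        raise ValueError("need at least 2 scans to intersect")
    universes = [set(s.table["locus_id"]) for s in scans]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("scans cover different locus sets")
    out = scans[0].flagged_loci
    for s in scans[1:]:
        out &= s.flagged_loci
    return out
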