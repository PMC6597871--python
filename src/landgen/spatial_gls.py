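"""Habitat amount vs genetic diversity: spatial generalized least squares.

Location-level mean diversity (observed/expected heterozygosity, inbreeding)
is regressed on the fraction of habitat within a buffer around each
location.  Residuals of nearby locations are allowed to covary through a
parametric correlation kernel of great-circle distance (none, linear,
exponential, Gaussian, spherical, rational quadratic); kernels are compared
by small-sample AICc on REML fits, and the winning structure is refitted by
ML for a likelihood-ratio test of the habitat effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .genotypes import GenotypeTable
from .rasters import RasterGrid, haversine_km

__all__ = [
    "correlation_kernel",
    "habitat_fraction",
    "location_table",
    "GLSFit",
    "fit_gls",
    "compare_gls_structures",
]

STRUCTURES = ("none", "linear", "exponential", "gaussian", "spherical",
              "rational_quadratic")


def correlation_kernel(structure: str, d, range_: float = 1.0):
    """Spatial correlation at distance ``d`` for a named kernel.

    All kernels return 1 at d = 0; compact-support kernels (linear,
    spherical) are clipped at zero beyond their range.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if structure != "none" and not range_ > 0:
        raise ValueError("range must be positive")
    h = d / range_ if structure != "none" else d
    if structure == "none":
        return np.where(d == 0, 1.0, 0.0)
    if structure == "linear":
        return np.where(h < 1.0, 1.0 - h, 0.0)
    if structure == "exponential":
        return np.exp(-h)
    if structure == "gaussian":
        return np.exp(-h ** 2)
    if structure == "spherical":
        return np.where(h < 1.0, 1.0 - 1.5 * h + 0.5 * h ** 3, 0.0)
    if structure == "rational_quadratic":
        return 1.0 / (1.0 + h ** 2)
    raise ValueError(f"unknown correlation structure {structure!r}")


def habitat_fraction(
    landcover: RasterGrid,
    lon: float,
    lat: float,
    radius_km: float = 2.0,
    habitat_classes: tuple = (1,),
) -> float:
    """Fraction of habitat cells whose centers lie within ``radius_km``.

    Nodata cells are excluded from the denominator.  The default 2-km
    radius reflects a typical small-bee foraging range.
    """
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    xs = landcover.x_centers()
    ys = landcover.y_centers()
    dist = haversine_km(xs[None, :], ys[:, None], lon, lat)
    inside = dist <= radius_km
    vals = landcover.values[inside]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("buffer contains no valid land-cover cells")
    return float(np.isin(vals, np.asarray(habitat_classes, dtype=float)).mean())


def location_table(
    gt: GenotypeTable,
    landcover: RasterGrid | None = None,
    radius_km: float = 2.0,
    habitat_classes: tuple = (1,),
) -> pd.DataFrame:
    """Aggregate per-sample diversity to one row per sampling location.

    Columns: location_id, lon, lat, n, Ho, He, F and (when a land-cover
    raster is supplied) habitat fraction within the buffer.  Ho and F are
    means over the colonies sampled at the location; He uses location-level
    allele frequencies with the small-sample correction.
    """
    from .popgen import _per_locus_stats, _per_sample_f

    rows = []
    for loc_id, idx in gt.samples.groupby("location_id").groups.items():
        idx = np.asarray(idx)
        d = gt.dosages[idx, :]
        ho_l, he_l, _, p, n_obs = _per_locus_stats(d)
        usable = np.isfinite(ho_l) & (n_obs >= 1)
        ho = float(np.nanmean(ho_l[usable]))
        he_ok = np.isfinite(he_l)
        he = float(np.nanmean(he_l[he_ok])) if he_ok.any() else np.nan
        f = float(np.nanmean(_per_sample_f(d, p, n_obs)))
        lon = float(gt.samples["lon"].iloc[idx].mean())
        lat = float(gt.samples["lat"].iloc[idx].mean())
        row = {"location_id": loc_id, "lon": lon, "lat": lat,
               "n": int(idx.size), "Ho": ho, "He": he, "F": f}
        if landcover is not None:
            row["habitat"] = habitat_fraction(landcover, lon, lat, radius_km,
                                              habitat_classes)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GLSFit:
    """A generalized least squares fit with one spatial correlation kernel."""

    coef: np.ndarray
    se: np.ndarray
    names: list
    structure: str
    range_km: float
    sigma2: float
    loglik: float
    aic: float
    aicc: float
    n: int
    k: int
    method: str
    response: str
    transform: str


def _logit(y: np.ndarray, eps: float) -> np.ndarray:
    if np.any((y <= 0) | (y >= 1)):
        bad = y[(y <= 0) | (y >= 1)]
        if eps is None:
            raise ValueError(
                f"logit undefined for values {bad}; set an epsilon adjustment")
        warnings.warn("clipping responses at the logit epsilon")
        y = np.clip(y, eps, 1 - eps)
    return np.log(y / (1 - y))


def _gls_profile(X, y, C):
    """beta, sigma2 (ML), rss and log-likelihood pieces for correlation C."""
    cC = cho_factor(C, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cC[0]))))
    Ci_X = cho_solve(cC, X)
    Ci_y = cho_solve(cC, y)
    XtCiX = X.T @ Ci_X
    beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
    resid = y - X @ beta
    rss = float(resid @ cho_solve(cC, resid))
    return beta, rss, logdet, XtCiX


def _neg_loglik(X, y, C, method):
    n, p = X.shape
    try:
        beta, rss, logdet, XtCiX = _gls_profile(X, y, C)
    except np.linalg.LinAlgError:
        return 1e12, None
    if method == "ml":
        sigma2 = rss / n
        nll = 0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    else:
        sigma2 = rss / (n - p)
        sign, ld_x = np.linalg.slogdet(XtCiX)
        if sign <= 0:
            return 1e12, None
        nll = 0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + logdet + ld_x + (n - p))
    return nll, (beta, sigma2, XtCiX)


def fit_gls(
    table: pd.DataFrame,
    response: str,
    predictor: str | None,
    structure: str = "none",
    transform: str = "identity",
    method: str = "reml",
    logit_eps: float = 1e-3,
    nugget: float = 1e-8,
) -> GLSFit:
    """Fit y = b0 + b1*predictor with spatially correlated errors.

    ``predictor=None`` fits the intercept-only model.  The kernel range is
    estimated by bounded 1-D optimization of the profiled (RE)ML
    likelihood; ``transform="logit"`` maps proportion responses to the real
    line first (exact 0/1 clipped at ``logit_eps`` with a warning).  A tiny
    nugget keeps the correlation matrix positive definite.
    """
    if len(table) < 5:
        raise ValueError("need at least 5 locations")
    if method not in ("ml", "reml"):
        raise ValueError("method must be 'ml' or 'reml'")
    y = table[response].to_numpy(float)
    if transform == "logit":
        y = _logit(y, logit_eps)
    elif transform != "identity":
        raise ValueError("transform must be 'identity' or 'logit'")
    if not np.isfinite(y).all():
        raise ValueError("response not finite after transform")
    n = len(y)
    X = (np.column_stack([np.ones(n), table[predictor].to_numpy(float)])
         if predictor else np.ones((n, 1)))
    names = ["(intercept)"] + ([predictor] if predictor else [])

    lon = table["lon"].to_numpy(float)
    lat = table["lat"].to_numpy(float)
    D = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    dmax = float(D[D > 0].max()) if (D > 0).any() else 1.0

    def corr_at(rng_):
        C = correlation_kernel(structure, D, rng_)
        np.fill_diagonal(C, 1.0)
        return C + nugget * np.eye(n)

    if structure == "none":
        range_hat = np.nan
        C = np.eye(n)
        nll, parts = _neg_loglik(X, y, C, method)
    else:
        def obj(log_r):
            return _neg_loglik(X, y, corr_at(np.exp(log_r)), method)[0]

        res = optimize.minimize_scalar(
            obj, bounds=(np.log(dmax * 1e-3), np.log(dmax * 3.0)),
            method="bounded", options={"xatol": 1e-6})
        range_hat = float(np.exp(res.x))
        C = corr_at(range_hat)
        nll, parts = _neg_loglik(X, y, C, method)
    if parts is None:
        raise RuntimeError("correlation matrix not positive definite")
    beta, sigma2, XtCiX = parts
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtCiX)))
    loglik = -nll
    k = X.shape[1] + 1 + (0 if structure == "none" else 1)  # beta, sigma2, range
    aic = 2.0 * k - 2.0 * loglik
    aicc = aic + 2.0 * k * (k + 1) / max(n - k - 1, 1)
    return GLSFit(beta, se, names, structure, range_hat, float(sigma2),
                  float(loglik), float(aic), float(aicc), n, k, method,
                  response, transform)


def compare_gls_structures(
    table: pd.DataFrame,
    response: str,
    predictor: str,
    structures=STRUCTURES,
    transform: str = "identity",
    method: str = "reml",
) -> dict:
    """Rank correlation structures by AICc and test the predictor by LRT.

    REML fits of every structure are ranked by AICc; the best structure is
    refitted by ML with and without the predictor, and the habitat effect
    is assessed by a 1-df likelihood-ratio test.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures to compare")
    fits = [fit_gls(table, response, predictor, s, transform, method)
            for s in structures]
    order = np.argsort([f.aicc for f in fits], kind="mergesort")
    ranked = [fits[i] for i in order]
    best = ranked[0]
    full_ml = fit_gls(table, response, predictor, best.structure, transform, "ml")
    null_ml = fit_gls(table, response, None, best.structure, transform, "ml")
    chi2 = max(2.0 * (full_ml.loglik - null_ml.loglik), 0.0)
    p = float(stats.chi2.sf(chi2, 1))
    ranking = pd.DataFrame({
        "structure": [f.structure for f in ranked],
        "aicc": [f.aicc for f in ranked],
        "delta_aicc": [f.aicc - best.aicc for f in ranked],
        "range_km": [f.range_km for f in ranked],
        "loglik": [f.loglik for f in ranked],
    })
    return {"ranking": ranking, "best": best, "best_ml": full_ml,
            "lrt_chi2": chi2, "lrt_p": p}
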