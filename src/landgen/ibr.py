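"""Isolation-by-resistance regression with MLPE and nested-MLPE models.

Pairwise relatedness between individuals is regressed on pairwise
resistance distances.  Rows of the pair table are not independent: two
pairs sharing an individual are correlated.  The maximum-likelihood
population effects (MLPE) model captures this with an iid random effect
per individual,

    y_ij = x_ij' beta + u_i + u_j + eps_ij,        u ~ N(0, sigma_u^2),

inducing correlation rho = sigma_u^2 / (2 sigma_u^2 + sigma_e^2) <= 0.5
between pairs that overlap in one individual.  When several individuals
are sampled per location (clustered designs), pairs that compare the same
two *locations* are additionally correlated; ignoring this makes
fixed-effect inference anticonservative.  The nested MLPE (NMLPE) adds an
iid random effect per unordered location pair,

    y_ij = x_ij' beta + u_i + u_j + v_{L(i)L(j)} + eps_ij,

which absorbs that dependence.  Both models are fitted by (restricted)
maximum likelihood with the fixed effects and total variance profiled out
and the variance ratios optimized numerically; the Woodbury identity keeps
every likelihood evaluation at the cost of a small (n_individuals +
n_location_pairs) Cholesky factorization.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .relatedness import RelatednessMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PairTable",
    "MLPEFit",
    "build_pair_table",
    "fit_mlpe",
    "all_subsets_selection",
    "likelihood_ratio_test",
    "residual_serial_autocorrelation",
    "subset_sensitivity",
    "simulate_mlpe_dataset",
]

_LOG_GAMMA_MIN = np.log(1e-8)
_LOG_GAMMA_MAX = np.log(1e8)


@dataclass
class PairTable:
    """One row per unordered individual pair with response and predictors.

    ``data`` columns: ``i, j`` (integer sample indices), ``id_i, id_j``,
    ``loc_i, loc_j``, ``loc_pair`` (unordered location-pair key),
    ``response`` and one standardized column per predictor.
    """

    data: pd.DataFrame
    predictors: list
    n_individuals: int
    standardization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        needed = {"i", "j", "loc_pair", "response"}
        if not needed <= set(self.data.columns):
            raise ValueError(f"pair table lacks columns {sorted(needed - set(self.data.columns))}")
        if (self.data["i"] == self.data["j"]).any():
            raise ValueError("self-pairs are not allowed")

    @property
    def n_pairs(self) -> int:
        return len(self.data)

    def drop_individuals(self, drop: set) -> "PairTable":
        """Remove every pair involving any individual in ``drop``."""
        keep = ~(self.data["i"].isin(drop) | self.data["j"].isin(drop))
        return PairTable(self.data.loc[keep].reset_index(drop=True),
                         list(self.predictors), self.n_individuals,
                         dict(self.standardization))


def build_pair_table(
    rel: RelatednessMatrix,
    distances: dict,
    samples: pd.DataFrame,
) -> PairTable:
    """Assemble the pairwise regression table.

    ``distances`` maps predictor names to square matrices (or objects with a
    ``values`` attribute) aligned with ``samples``.  Each predictor is
    z-standardized; rows with non-finite predictor values (disconnected
    pairs) are dropped with a warning.
    """
    n = rel.n
    if len(samples) != n:
        raise ValueError("sample table does not match the relatedness matrix")
    ids = samples["id"].tolist()
    if list(rel.sample_ids) != ids:
        raise ValueError("sample ids misaligned between relatedness matrix and metadata")
    locs = samples["location_id"].tolist()
    iu, ju = np.triu_indices(n, k=1)
    rows = {
        "i": iu, "j": ju,
        "id_i": [ids[a] for a in iu], "id_j": [ids[b] for b in ju],
        "loc_i": [locs[a] for a in iu], "loc_j": [locs[b] for b in ju],
        "response": rel.values[iu, ju],
    }
    df = pd.DataFrame(rows)
    df["loc_pair"] = [tuple(sorted((a, b), key=str)) for a, b in zip(df["loc_i"], df["loc_j"])]

    standardization = {}
    keep = np.ones(len(df), dtype=bool)
    for name, mat in distances.items():
        vals = getattr(mat, "values", mat)
        vals = np.asarray(vals, dtype=float)
        if vals.shape != (n, n):
            raise ValueError(f"distance matrix {name!r} misaligned with samples")
        col = vals[iu, ju]
        keep &= np.isfinite(col)
        df[name] = col
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} pair(s) with infinite resistance")
        df = df.loc[keep].reset_index(drop=True)
    for name in distances:
        mu, sd = float(df[name].mean()), float(df[name].std(ddof=0))
        if sd == 0:
            raise ValueError(f"predictor {name!r} is constant")
        df[name] = (df[name] - mu) / sd
        standardization[name] = (mu, sd)
    return PairTable(df, list(distances.keys()), n, standardization)


@dataclass
class MLPEFit:
    """A fitted MLPE or NMLPE model."""

    beta: np.ndarray
    se: np.ndarray
    ci: np.ndarray  # (p, 2)
    names: list
    rho: float
    sigma2_u: float
    sigma2_v: float
    sigma2_e: float
    loglik: float
    n_params: int
    aic: float
    converged: bool
    method: str
    nested: bool
    formula: str
    n_obs: int
    identifiable: bool = True

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.names, "estimate": self.beta, "se": self.se,
            "ci_lo": self.ci[:, 0], "ci_hi": self.ci[:, 1],
        })


def _pair_design(pairs: PairTable, predictors):
    df = pairs.data
    m = len(df)
    X = np.column_stack([np.ones(m)] + [df[p].to_numpy(float) for p in predictors])
    names = ["(intercept)"] + list(predictors)
    y = df["response"].to_numpy(float)

    ind_codes, _ = pd.factorize(pd.concat([df["i"], df["j"]]).to_numpy())
    ci = ind_codes[:m]
    cj = ind_codes[m:]
    n_ind = int(ind_codes.max()) + 1
    Zu = np.zeros((m, n_ind))
    Zu[np.arange(m), ci] = 1.0
    Zu[np.arange(m), cj] += 1.0  # self-comparisons impossible, but robust

    lp_codes, lp_uniques = pd.factorize(df["loc_pair"])
    n_lp = len(lp_uniques)
    Zv = np.zeros((m, n_lp))
    Zv[np.arange(m), lp_codes] = 1.0
    return X, y, names, Zu, Zv, lp_codes


class _ProfiledLikelihood:
    """Profiled (RE)ML deviance of the MLPE family on a fixed design.

    Sigma(gamma) = I + gamma_u Zu Zu' + gamma_v Zv Zv'; beta and the
    residual variance are profiled analytically, leaving a 1- or 2-D
    optimization over log variance ratios.
    """

    def __init__(self, X, y, Zu, Zv, nested: bool, method: str):
        self.X, self.y = X, y
        self.m, self.p = X.shape
        self.nested = nested
        self.method = method
        Z = np.hstack([Zu, Zv]) if nested else Zu
        self.block_sizes = (Zu.shape[1], Zv.shape[1] if nested else 0)
        self.W = Z.T @ Z
        self.ZX = Z.T @ X
        self.Zy = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _gamma_vector(self, t):
        gam = np.exp(np.asarray(t, dtype=float))
        gam[np.asarray(t) <= _LOG_GAMMA_MIN + 1e-9] = 0.0
        return gam

    def components(self, t):
        gam = self._gamma_vector(t)
        n_u, n_v = self.block_sizes
        s = np.concatenate([
            np.full(n_u, np.sqrt(gam[0])),
            np.full(n_v, np.sqrt(gam[1])) if self.nested else np.empty(0),
        ])
        B = np.eye(s.size) + (s[:, None] * self.W) * s[None, :]
        cB = cho_factor(B, lower=True)
        logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(cB[0]))))
        SZX = s[:, None] * self.ZX
        SZy = s * self.Zy
        XtSiX = self.XtX - SZX.T @ cho_solve(cB, SZX)
        XtSiy = self.Xty - SZX.T @ cho_solve(cB, SZy)
        ytSiy = self.yty - float(SZy @ cho_solve(cB, SZy))
        beta = np.linalg.solve(XtSiX, XtSiy)
        rss = max(ytSiy - float(XtSiy @ beta), 1e-300)
        return gam, beta, rss, logdet_sigma, XtSiX

    def negloglik(self, t) -> float:
        try:
            _, _, rss, logdet, XtSiX = self.components(t)
        except np.linalg.LinAlgError:
            return 1e12
        m, p = self.m, self.p
        if self.method == "ml":
            sigma2 = rss / m
            return 0.5 * (m * np.log(2.0 * np.pi * sigma2) + logdet + m)
        sigma2 = rss / (m - p)
        sign, logdet_x = np.linalg.slogdet(XtSiX)
        if sign <= 0:
            return 1e12
        return 0.5 * ((m - p) * np.log(2.0 * np.pi * sigma2) + logdet
                      + logdet_x + (m - p))


def fit_mlpe(
    pairs: PairTable,
    predictors=None,
    nested: bool = False,
    method: str = "ml",
    n_starts: int = 3,
) -> MLPEFit:
    """Fit an MLPE (``nested=False``) or NMLPE (``nested=True``) model.

    ``method`` is ``"ml"`` (required for AIC comparison and LRTs across
    fixed-effect sets) or ``"reml"``.  Optimization runs bounded
    quasi-Newton on log variance ratios from ``n_starts`` starting points.
    """
    if method not in ("ml", "reml"):
        raise ValueError("method must be 'ml' or 'reml'")
    predictors = list(predictors) if predictors is not None else list(pairs.predictors)
    for p_ in predictors:
        if p_ not in pairs.data.columns:
            raise ValueError(f"predictor {p_!r} not in pair table")
    X, y, names, Zu, Zv, lp_codes = _pair_design(pairs, predictors)
    if Zu.shape[1] < 3:
        raise ValueError("need at least 3 individuals")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X[:, 1:], rowvar=False) if X.shape[1] > 2 else None
        raise ValueError(f"singular design among predictors {predictors}"
                         + ("" if corr is None else f"; correlations:\n{corr}"))

    identifiable = True
    if nested:
        counts = np.bincount(lp_codes)
        if counts.max() == 1:
            identifiable = False
            warnings.warn(
                "every location pair appears once: sigma_v and sigma_e are "
                "not separately identifiable; interpret their split with care"
            )

    lik = _ProfiledLikelihood(X, y, Zu, Zv, nested, method)
    dim = 2 if nested else 1
    bounds = [(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX)] * dim
    best = None
    for start in (-2.0, 0.0, 2.0)[:max(n_starts, 1)]:
        res = optimize.minimize(
            lik.negloglik, np.full(dim, start), method="L-BFGS-B",
            bounds=bounds, options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    t_hat = best.x.copy()
    # snap near-boundary ratios to exactly zero when that does not hurt
    for k in range(dim):
        if t_hat[k] < _LOG_GAMMA_MIN + 2.0:
            t_try = t_hat.copy()
            t_try[k] = _LOG_GAMMA_MIN
            if lik.negloglik(t_try) <= best.fun + 1e-7:
                t_hat = t_try

    gam, beta, rss, logdet, XtSiX = lik.components(t_hat)
    m, p = lik.m, lik.p
    denom = m if method == "ml" else m - p
    sigma2_e = rss / denom
    nll = lik.negloglik(t_hat)
    loglik = -nll
    gamma_u = float(gam[0])
    gamma_v = float(gam[1]) if nested else 0.0
    sigma2_u = gamma_u * sigma2_e
    sigma2_v = gamma_v * sigma2_e
    rho = gamma_u / (2.0 * gamma_u + gamma_v + 1.0)

    cov_beta = sigma2_e * np.linalg.inv(XtSiX)
    se = np.sqrt(np.diag(cov_beta))
    z = stats.norm.ppf(0.975)
    ci = np.column_stack([beta - z * se, beta + z * se])

    n_varcomp = 3 if nested else 2
    n_params = p + n_varcomp
    aic = 2.0 * n_params - 2.0 * loglik
    formula = "response ~ " + " + ".join(predictors) if predictors else "response ~ 1"
    return MLPEFit(
        beta=beta, se=se, ci=ci, names=names, rho=float(rho),
        sigma2_u=float(sigma2_u), sigma2_v=float(sigma2_v),
        sigma2_e=float(sigma2_e), loglik=float(loglik), n_params=n_params,
        aic=float(aic), converged=bool(best.success), method=method,
        nested=nested, formula=formula, n_obs=m, identifiable=identifiable,
    )


def all_subsets_selection(
    pairs: PairTable,
    predictors=None,
    collinearity_rmax: float = 0.6,
    nested: bool = False,
) -> pd.DataFrame:
    """AIC ranking of every subset of mutually noncollinear predictors.

    A subset is a candidate when every pair of its predictors has
    |Pearson r| < ``collinearity_rmax`` across the pair table.  All models
    (including intercept-only) are fitted by ML and ranked by AIC;
    Akaike weights are computed over the candidate set.
    """
    predictors = list(predictors) if predictors is not None else list(pairs.predictors)
    cols = {p: pairs.data[p].to_numpy(float) for p in predictors}
    ok_pair = {}
    for a, b in itertools.combinations(predictors, 2):
        r = float(np.corrcoef(cols[a], cols[b])[0, 1])
        ok_pair[(a, b)] = abs(r) < collinearity_rmax

    rows = []
    for size in range(len(predictors) + 1):
        for subset in itertools.combinations(predictors, size):
            if all(ok_pair[(a, b)] for a, b in itertools.combinations(subset, 2)):
                fit = fit_mlpe(pairs, list(subset), nested=nested, method="ml")
                rows.append({
                    "predictors": " + ".join(subset) if subset else "(intercept)",
                    "k": fit.n_params, "loglik": fit.loglik, "aic": fit.aic,
                    "rho": fit.rho, "_fit": fit,
                })
    table = pd.DataFrame(rows).sort_values(
        ["aic", "predictors"], kind="mergesort").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    w = np.exp(-0.5 * table["delta_aic"].to_numpy())
    table["weight"] = w / w.sum()
    return table


def likelihood_ratio_test(full: MLPEFit, reduced: MLPEFit):
    """Chi-square LRT of nested fixed-effect structures (ML fits only)."""
    if full.method != "ml" or reduced.method != "ml":
        raise ValueError("LRT on fixed effects requires ML fits")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("the reduced model has more parameters than the full model")
    chi2 = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def residual_serial_autocorrelation(fit: MLPEFit, pairs: PairTable, predictors=None) -> float:
    """Lag-1 autocorrelation of whitened residuals sorted by location pair.

    Residuals are decorrelated with the Cholesky factor of the fitted
    covariance (in location-pair sort order); a clearly positive value
    flags spatial dependence the correlation structure did not absorb.
    """
    predictors = predictors if predictors is not None else [
        n for n in fit.names if n != "(intercept)"]
    X, y, _, Zu, Zv, _ = _pair_design(pairs, predictors)
    order = pairs.data["loc_pair"].astype(str).argsort(kind="mergesort").to_numpy()
    X, y, Zu, Zv = X[order], y[order], Zu[order], Zv[order]
    m = len(y)
    if m < 3:
        raise ValueError("need at least 3 residuals")
    gam_u = fit.sigma2_u / fit.sigma2_e if fit.sigma2_e > 0 else 0.0
    gam_v = fit.sigma2_v / fit.sigma2_e if fit.sigma2_e > 0 else 0.0
    sigma = np.eye(m) + gam_u * (Zu @ Zu.T) + gam_v * (Zv @ Zv.T)
    L = cholesky(sigma, lower=True)
    resid = y - X @ fit.beta
    white = solve_triangular(L, resid, lower=True)
    return float(np.corrcoef(white[:-1], white[1:])[0, 1])


def subset_sensitivity(
    pairs: PairTable,
    predictors=None,
    n_subsets: int = 100,
    exclusion_sizes=(2, 4, 8),
    seed: int = 0,
    collinearity_rmax: float = 0.6,
    nested: bool = False,
    delta_aic_max: float = 2.0,
) -> pd.DataFrame:
    """Predictor inclusion frequency under random sample exclusion.

    For each exclusion size, ``n_subsets`` random individual subsets are
    dropped, model selection is rerun, and a predictor counts as included
    when it appears in any model with delta AIC <= ``delta_aic_max``.
    """
    predictors = list(predictors) if predictors is not None else list(pairs.predictors)
    individuals = np.unique(np.concatenate([
        pairs.data["i"].to_numpy(), pairs.data["j"].to_numpy()]))
    rng = np.random.default_rng(seed)
    rows = []
    for size in exclusion_sizes:
        if size >= individuals.size - 3:
            raise ValueError(f"exclusion size {size} leaves too few individuals")
        counts = {p: 0 for p in predictors}
        for _ in range(n_subsets):
            drop = set(rng.choice(individuals, size=size, replace=False).tolist()) if size else set()
            sub = pairs.drop_individuals(drop)
            table = all_subsets_selection(sub, predictors, collinearity_rmax, nested)
            best = table[table["delta_aic"] <= delta_aic_max]
            included = set()
            for terms in best["predictors"]:
                included.update(t.strip() for t in terms.split("+"))
            for p_ in predictors:
                if p_ in included:
                    counts[p_] += 1
        for p_, c in counts.items():
            rows.append({"exclusion_size": size, "predictor": p_,
                         "inclusion_freq": c / n_subsets})
    return pd.DataFrame(rows)


def simulate_mlpe_dataset(
    n_locations: int = 20,
    colonies_per_location: int = 3,
    beta: float = -0.5,
    sigma_u: float = 0.5,
    sigma_v: float = 0.0,
    sigma_e: float = 1.0,
    predictor_level: str = "location_pair",
    seed: int = 0,
) -> PairTable:
    """Draw a pair table from the (N)MLPE generative model.

    Individuals live at ``n_locations`` locations with
    ``colonies_per_location`` each; the predictor is standard normal at the
    chosen level (``"pair"`` or ``"location_pair"`` — resistance distances
    are functions of locations only, so ``location_pair`` is the realistic
    setting).  The response is beta*x + u_i + u_j + v_{AB} + eps.
    """
    rng = np.random.default_rng(seed)
    n = n_locations * colonies_per_location
    loc = np.repeat(np.arange(n_locations), colonies_per_location)
    iu, ju = np.triu_indices(n, k=1)
    m = iu.size
    lp = [tuple(sorted((int(loc[a]), int(loc[b])))) for a, b in zip(iu, ju)]
    lp_codes, lp_uniq = pd.factorize(pd.Series(lp))
    if predictor_level == "pair":
        x = rng.standard_normal(m)
    elif predictor_level == "location_pair":
        x_lp = rng.standard_normal(len(lp_uniq))
        x = x_lp[lp_codes]
    else:
        raise ValueError("predictor_level must be 'pair' or 'location_pair'")
    x = (x - x.mean()) / x.std(ddof=0)
    u = rng.normal(0.0, sigma_u, n)
    v = rng.normal(0.0, sigma_v, len(lp_uniq))
    y = beta * x + u[iu] + u[ju] + v[lp_codes] + rng.normal(0.0, sigma_e, m)
    df = pd.DataFrame({
        "i": iu, "j": ju,
        "id_i": iu, "id_j": ju,
        "loc_i": loc[iu], "loc_j": loc[ju],
        "loc_pair": lp, "response": y, "x": x,
    })
    return PairTable(df, ["x"], n, {"x": (0.0, 1.0)})
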