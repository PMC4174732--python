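"""Random-effects ANOVA with factor-specific residual variances.

The response (per-interval timing error, in seconds) is modelled as

    y_ijk = b0 + b_speed * fast_ij + b_ktt * ktt_ij + u_i + v_ij + e_ijk

with subject random intercepts ``u_i ~ N(0, sd_u^2)`` (within-individual
variability), set-within-subject random intercepts ``v_ij ~ N(0, sd_v^2)``
(within-performance variability), and residuals whose variance is
``sigma^2`` for untaped observations and ``sigma^2 * ratio`` for taped
ones.  The taping-specific residual variance ratio is the quantity of
interest: a ratio below one means the tape reduced the unexplained
trial-to-trial variability.

Estimation is by restricted maximum likelihood.  Because the fixed
covariates are constant within a set, the REML criterion depends on the
data only through per-set sufficient statistics (count, mean, within-set
sum of squares), which keeps each evaluation cheap regardless of how many
intervals a set contains.  Variance parameters are optimized on the log
scale (log SDs and log ratio), which is unconstrained and numerically
stable; Wald intervals are formed on that scale and back-transformed.

The likelihood-ratio test for heteroscedasticity compares two REML fits
with identical fixed effects (where REML likelihood ratios are valid)
against a chi-square with one degree of freedom.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sstats

from .errors import FitError, ValidationError
from .tempo import round_half_up

logger = logging.getLogger(__name__)

#: Required columns of an observation table.
OBSERVATION_COLUMNS = ("subject", "set", "ktt", "speed", "response_s")

_LOG_SD_BOUNDS = (np.log(1e-10), np.log(1e3))
_LOG_RATIO_BOUNDS = (np.log(1e-4), np.log(1e4))


def variance_ratio(sigma2_ktt: float, sigma2_nktt: float) -> float:
    """Taped-over-untaped residual variance ratio, 4-decimal rounding."""
    if sigma2_ktt <= 0 or sigma2_nktt <= 0:
        raise ValidationError("variances must be positive")
    return round_half_up(sigma2_ktt / sigma2_nktt, 4)


def validate_observations(data: pd.DataFrame) -> pd.DataFrame:
    """Check the observation-table schema and basic invariants."""
    missing = [c for c in OBSERVATION_COLUMNS if c not in data.columns]
    if missing:
        raise ValidationError(f"observation table is missing columns: {missing}")
    if not np.all(np.isfinite(data["response_s"].to_numpy(dtype=float))):
        raise ValidationError("response_s contains non-finite values")
    ktt = data["ktt"].astype(int)
    if not ktt.isin((0, 1)).all():
        raise ValidationError("ktt must be a 0/1 indicator")
    speed = data["speed"].astype(str)
    if not speed.isin(("fast", "slow")).all():
        raise ValidationError("speed must be 'fast' or 'slow'")
    return data


@dataclass
class _SetStats:
    """Per-set sufficient statistics grouped by subject.

    When every subject has the same number of sets the per-subject pieces
    are also stored stacked, enabling batched linear algebra.
    """

    subject_slices: list  # per subject: (n_j, sse_sum, sse_j, ybar_j, X_j, ktt_j)
    X_cols: list
    n_obs: int
    n_sets: int
    n_subjects: int
    contrast_df: int  # sum over sets of (n_j - 1)
    log_n_sum: float
    stacked: Optional[dict] = None


def _aggregate(data: pd.DataFrame) -> _SetStats:
    data = validate_observations(data)
    grp = data.groupby(["subject", "set"], sort=True)
    agg = grp["response_s"].agg(["count", "mean"]).rename(columns={"count": "n"})
    sse = grp["response_s"].apply(lambda y: float(np.sum((y - y.mean()) ** 2)))
    agg["sse"] = sse
    for col in ("ktt", "speed"):
        vals = grp[col].nunique()
        if (vals > 1).any():
            raise ValidationError(f"column {col!r} is not constant within a set")
        agg[col] = grp[col].first()
    agg = agg.reset_index()

    X_cols = ["intercept"]
    design = [np.ones(len(agg))]
    fast = (agg["speed"].astype(str) == "fast").to_numpy(dtype=float)
    if fast.std() > 0:
        X_cols.append("speed_fast")
        design.append(fast)
    ktt = agg["ktt"].to_numpy(dtype=float)
    if ktt.std() > 0:
        X_cols.append("ktt")
        design.append(ktt)
    X = np.column_stack(design)

    slices = []
    for _, sub in agg.groupby("subject", sort=True):
        i = sub.index.to_numpy()
        slices.append(
            (
                sub["n"].to_numpy(dtype=float),
                float(sub["sse"].sum()),
                sub["sse"].to_numpy(dtype=float),
                sub["mean"].to_numpy(dtype=float),
                X[i, :],
                sub["ktt"].to_numpy(dtype=float),
            )
        )
    n_obs = int(agg["n"].sum())
    stacked = None
    sizes = {len(sl[0]) for sl in slices}
    if len(sizes) == 1:
        stacked = {
            "n": np.stack([sl[0] for sl in slices]),
            "sse": np.stack([sl[2] for sl in slices]),
            "ybar": np.stack([sl[3] for sl in slices]),
            "X": np.stack([sl[4] for sl in slices]),
            "ktt": np.stack([sl[5] for sl in slices]),
        }
    return _SetStats(
        subject_slices=slices,
        X_cols=X_cols,
        n_obs=n_obs,
        n_sets=len(agg),
        n_subjects=agg["subject"].nunique(),
        contrast_df=int(n_obs - len(agg)),
        log_n_sum=float(np.sum(np.log(agg["n"].to_numpy(dtype=float)))),
        stacked=stacked,
    )


def _neg2_reml(theta: np.ndarray, ss: _SetStats, heteroscedastic: bool):
    """-2 x restricted log-likelihood (with constants) and GLS by-products.

    Uses the per-set sufficient-statistic decomposition: within-set
    contrasts contribute ``(n_j - 1) log d_j + SSE_j / d_j`` with residual
    variance ``d_j``; set means carry the random-effect structure through a
    small per-subject covariance matrix.
    """
    sd_u, sd_v, sd_e = np.exp(theta[:3])
    ratio = np.exp(theta[3]) if heteroscedastic else 1.0
    var_u, var_v, var_e = sd_u**2, sd_v**2, sd_e**2

    p = len(ss.X_cols)
    if ss.stacked is not None:
        st = ss.stacked
        n = st["n"]  # (S, m)
        d = var_e * np.where(st["ktt"] > 0, ratio, 1.0)
        logdet = float(np.sum((n - 1) * np.log(d)))
        c = float(np.sum(st["sse"] / d))
        S, m = n.shape
        Vbar = np.broadcast_to(var_u, (S, m, m)).copy()
        idx = np.arange(m)
        Vbar[:, idx, idx] += var_v + d / n
        try:
            L = np.linalg.cholesky(Vbar)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        logdet += 2.0 * float(np.sum(np.log(L[:, idx, idx])))
        rhs = np.concatenate([st["ybar"][:, :, None], st["X"]], axis=2)
        sol = np.linalg.solve(Vbar, rhs)  # (S, m, 1+p)
        sol_y, sol_X = sol[:, :, 0], sol[:, :, 1:]
        A = np.einsum("smp,smq->pq", st["X"], sol_X)
        b = np.einsum("smp,sm->p", st["X"], sol_y)
        c += float(np.einsum("sm,sm->", st["ybar"], sol_y))
    else:
        A = np.zeros((p, p))
        b = np.zeros(p)
        c = 0.0
        logdet = 0.0
        for n_j, _, sse_j, ybar, X, ktt in ss.subject_slices:
            d_j = var_e * np.where(ktt > 0, ratio, 1.0)
            logdet += float(np.sum((n_j - 1) * np.log(d_j)))
            c += float(np.sum(sse_j / d_j))
            Vbar = np.full((len(n_j), len(n_j)), var_u) + np.diag(var_v + d_j / n_j)
            try:
                L = np.linalg.cholesky(Vbar)
            except np.linalg.LinAlgError:
                return np.inf, None, None
            logdet += 2.0 * float(np.sum(np.log(np.diag(L))))
            sol_y = np.linalg.solve(L.T, np.linalg.solve(L, ybar))
            sol_X = np.linalg.solve(L.T, np.linalg.solve(L, X))
            A += X.T @ sol_X
            b += X.T @ sol_y
            c += float(ybar @ sol_y)
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    quad = c - float(b @ beta)
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf, None, None
    const = (ss.n_obs - p) * np.log(2 * np.pi) + ss.log_n_sum
    neg2 = logdet + quad + logdet_A + const
    if not np.isfinite(neg2):
        return np.inf, None, None
    return neg2, beta, A


@dataclass
class HeteroLMMFit:
    """Results of the (possibly heteroscedastic) random-effects fit.

    SD estimates and the variance ratio carry log-scale Wald 95% CIs;
    fixed effects carry t-based CIs and p-values.  ``loglik`` is the
    restricted log-likelihood at the optimum.
    """

    fixed_effects: pd.DataFrame
    within_individual_sd: float
    within_individual_sd_ci: Tuple[float, float]
    within_set_sd: float
    within_set_sd_ci: Tuple[float, float]
    residual_sd_nktt: float
    residual_sd_nktt_ci: Tuple[float, float]
    variance_ratio: float
    variance_ratio_ci: Optional[Tuple[float, float]]
    loglik: float
    heteroscedastic: bool
    converged: bool
    n_obs: int
    n_sets: int
    n_subjects: int
    message: str = ""

    def to_dict(self) -> Dict:
        return {
            "fixed_effects": self.fixed_effects.to_dict(orient="index"),
            "within_individual_sd": self.within_individual_sd,
            "within_individual_sd_ci": list(self.within_individual_sd_ci),
            "within_set_sd": self.within_set_sd,
            "within_set_sd_ci": list(self.within_set_sd_ci),
            "residual_sd_nktt": self.residual_sd_nktt,
            "residual_sd_nktt_ci": list(self.residual_sd_nktt_ci),
            "variance_ratio": self.variance_ratio,
            "variance_ratio_ci": list(self.variance_ratio_ci)
            if self.variance_ratio_ci
            else None,
            "loglik": self.loglik,
            "heteroscedastic": self.heteroscedastic,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_sets": self.n_sets,
            "n_subjects": self.n_subjects,
        }


def _start_values(ss: _SetStats, heteroscedastic: bool) -> np.ndarray:
    """Moment-based starting point on the log scale."""
    n_all, sse_all, ybars, subj_means = [], [], [], []
    for n_j, sse_sum, _, ybar, _, _ in ss.subject_slices:
        n_all.append(n_j)
        sse_all.append(sse_sum)
        ybars.append(ybar)
        subj_means.append(float(np.mean(ybar)))
    n_cat = np.concatenate(n_all)
    var_e = max(float(np.sum(sse_all)) / max(ss.contrast_df, 1), 1e-12)
    nbar = float(np.mean(n_cat))
    var_v = max(
        float(np.mean([np.var(y, ddof=1) if len(y) > 1 else 0.0 for y in ybars]))
        - var_e / nbar,
        1e-10,
    )
    var_u = max(
        (float(np.var(subj_means, ddof=1)) if len(subj_means) > 1 else 1e-8)
        - var_v / max(float(np.mean([len(y) for y in ybars])), 1.0),
        1e-10,
    )
    theta = [0.5 * np.log(var_u), 0.5 * np.log(var_v), 0.5 * np.log(var_e)]
    if heteroscedastic:
        theta.append(0.0)
    return np.asarray(theta)


def _hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_hetero_lmm(
    data: pd.DataFrame,
    heteroscedastic: bool = True,
    compute_ci: bool = True,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> HeteroLMMFit:
    """REML fit of the two-level random-effects model.

    Parameters
    ----------
    data
        Observation table with columns ``subject, set, ktt, speed,
        response_s`` (one row per produced interval).
    heteroscedastic
        If true, estimate a taped-specific residual variance ratio;
        otherwise the ratio is fixed at 1.
    compute_ci
        Skip the (finite-difference Hessian) Wald intervals when false —
        useful inside large simulation loops that only need estimates and
        likelihoods.
    """
    ss = _aggregate(data)
    if ss.n_subjects < 2:
        raise FitError("need at least 2 subjects")
    if ss.n_sets < 2 * ss.n_subjects:
        logger.warning("fewer than 2 sets per subject on average; fit may be fragile")
    if heteroscedastic:
        ktt_vals = {float(k) for sl in ss.subject_slices for k in sl[5]}
        if len(ktt_vals) < 2:
            raise FitError("heteroscedastic fit requires both taping levels")

    theta0 = _start_values(ss, heteroscedastic)
    bounds = [_LOG_SD_BOUNDS] * 3 + ([_LOG_RATIO_BOUNDS] if heteroscedastic else [])

    # scale per observation: keeps the criterion O(1) so relative stopping
    # rules behave the same regardless of dataset size
    scale = 1.0 / ss.n_obs

    def objective(theta: np.ndarray) -> float:
        return scale * _neg2_reml(theta, ss, heteroscedastic)[0]

    res = optimize.minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    # simplex polish guards against premature quasi-Newton stops with
    # finite-difference gradients; keep whichever point is better
    polish = optimize.minimize(
        objective,
        res.x if np.isfinite(res.fun) else theta0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": tol, "maxfev": 400},
    )
    best = min((r for r in (res, polish) if np.isfinite(r.fun)), key=lambda r: r.fun, default=None)
    if best is None:
        raise FitError(f"REML optimization failed: {res.message}")
    theta = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
    neg2, beta, A = _neg2_reml(theta, ss, heteroscedastic)
    loglik = -0.5 * neg2

    sd_u, sd_v, sd_e = np.exp(theta[:3])
    ratio = float(np.exp(theta[3])) if heteroscedastic else 1.0
    at_lower = theta[:3] <= _LOG_SD_BOUNDS[0] + 1e-6
    if at_lower.any():
        logger.warning("variance component(s) at zero boundary: %s", at_lower)

    z975 = sstats.norm.ppf(0.975)
    cis = [(np.nan, np.nan)] * len(theta)
    if compute_ci:
        try:
            H = 0.5 * ss.n_obs * _hessian(objective, theta)  # Hessian of -loglik
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            cis = [
                (float(np.exp(t - z975 * s)), float(np.exp(t + z975 * s)))
                for t, s in zip(theta, se)
            ]
        except np.linalg.LinAlgError:
            logger.warning("Hessian not invertible; Wald CIs unavailable")

    cov_beta = np.linalg.inv(A)
    se_beta = np.sqrt(np.diag(cov_beta))
    rows = []
    p_fix = len(ss.X_cols)
    for name, est, se_b in zip(ss.X_cols, beta, se_beta):
        if name == "intercept":
            ddf = max(ss.n_subjects - 1, 1)
        else:
            ddf = max(ss.n_sets - ss.n_subjects - (p_fix - 1), 1)
        tcrit = sstats.t.ppf(0.975, ddf)
        tval = est / se_b if se_b > 0 else np.inf
        rows.append(
            {
                "term": name,
                "estimate": float(est),
                "se": float(se_b),
                "ci_low": float(est - tcrit * se_b),
                "ci_high": float(est + tcrit * se_b),
                "df": int(ddf),
                "p_value": float(2 * sstats.t.sf(abs(tval), ddf)),
            }
        )
    fixed = pd.DataFrame(rows).set_index("term")

    at_zero = [bool(x) for x in at_lower]
    return HeteroLMMFit(
        fixed_effects=fixed,
        within_individual_sd=0.0 if at_zero[0] else float(sd_u),
        within_individual_sd_ci=cis[0],
        within_set_sd=0.0 if at_zero[1] else float(sd_v),
        within_set_sd_ci=cis[1],
        residual_sd_nktt=float(sd_e),
        residual_sd_nktt_ci=cis[2],
        variance_ratio=ratio,
        variance_ratio_ci=cis[3] if heteroscedastic else None,
        loglik=float(loglik),
        heteroscedastic=heteroscedastic,
        converged=bool(best.success or polish.success),
        n_obs=ss.n_obs,
        n_sets=ss.n_sets,
        n_subjects=ss.n_subjects,
        message=str(best.message),
    )


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def lrt_heteroscedasticity(fit_restricted: HeteroLMMFit, fit_full: HeteroLMMFit) -> LRTResult:
    """Likelihood-ratio test of the residual variance ratio (H0: ratio = 1).

    Both fits must be REML fits of the same data with the same fixed
    effects; the restricted fit is the homoscedastic one.
    """
    if fit_restricted.heteroscedastic or not fit_full.heteroscedastic:
        raise ValidationError("pass (homoscedastic restricted, heteroscedastic full)")
    same = (
        fit_restricted.n_obs == fit_full.n_obs
        and fit_restricted.n_sets == fit_full.n_sets
        and list(fit_restricted.fixed_effects.index) == list(fit_full.fixed_effects.index)
    )
    if not same:
        raise ValidationError("fits are not based on the same data and fixed effects")
    stat = max(2.0 * (fit_full.loglik - fit_restricted.loglik), 0.0)
    return LRTResult(statistic=float(stat), df=1, p_value=float(sstats.chi2.sf(stat, 1)))


@dataclass
class AnovaFTable:
    """Mixed-model F-tests for taping, tempo, and their interaction."""

    table: pd.DataFrame
    n_obs: int
    n_subjects: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def fit_wgamma_anova(data: pd.DataFrame, response: str = "z") -> AnovaFTable:
    """Repeated-measures ANOVA of per-set Fisher-Z mean wg1 values.

    Fits a linear mixed model with a subject random intercept (REML via
    statsmodels) on effect-coded taping and speed factors, and reports Wald
    F-tests for taping, speed, and their interaction with containment-style
    denominator degrees of freedom (observations minus subjects minus
    set-level fixed-effect parameters).
    """
    import statsmodels.api as sm

    for col in ("subject", "ktt", "speed", response):
        if col not in data.columns:
            raise ValidationError(f"missing column {col!r}")
    by_subject = data.groupby("subject")["ktt"].nunique()
    if (by_subject < 2).any():
        logger.warning("some subjects lack one taping level; unbalanced fit")
    if data["subject"].nunique() < 2:
        raise FitError("need at least 2 subjects")

    y = data[response].to_numpy(dtype=float)
    xk = data["ktt"].astype(int).to_numpy(dtype=float) - 0.5
    xs = (data["speed"].astype(str) == "fast").to_numpy(dtype=float) - 0.5
    X = np.column_stack([np.ones_like(y), xk, xs, xk * xs])
    terms = ["intercept", "ktt", "speed", "ktt_x_speed"]

    model = sm.MixedLM(y, X, groups=data["subject"].to_numpy())
    import warnings

    with warnings.catch_warnings():
        # boundary estimates (subject variance ~ 0) are legitimate here
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)

    n = len(y)
    n_subj = data["subject"].nunique()
    ddf = max(n - n_subj - 3, 1)
    rows = []
    for i, term in enumerate(terms):
        if term == "intercept":
            continue
        fstat = float((fit.fe_params[i] / fit.bse_fe[i]) ** 2)
        rows.append(
            {
                "term": term,
                "F": fstat,
                "df_num": 1,
                "df_den": int(ddf),
                "p_value": float(sstats.f.sf(fstat, 1, ddf)),
            }
        )
    return AnovaFTable(
        table=pd.DataFrame(rows).set_index("term"), n_obs=n, n_subjects=n_subj
    )
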