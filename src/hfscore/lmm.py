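"""Two-level nested random-intercept linear mixed model.

The weekly observations are modelled as

    y_{pai} = b0 + b1 * t + b2 * g + b3 * t * g + u_p + v_{a(p)} + e_{pai}

with ``t = week + 12`` (so the intercept is the Week -12 prediction),
``g`` the group indicator, ``u_p`` a patient-level random intercept,
``v_{a(p)}`` an anchor-within-patient random intercept (one cluster per
hospitalization, a singleton for controls), and independent Gaussian
residuals.  Variance components are estimated by REML (ML optional)
over log-parameterized variance ratios with the residual variance and
the fixed effects profiled out in closed form; the marginal covariance
is block diagonal by patient, and blocks sharing the same design and
anchor partition are factorized once and batched.

A deliberately naive dense multivariate-normal evaluation of the same
criterion (:func:`dense_loglik`) is provided as an independent oracle
for validation on small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import ndtr

__all__ = [
    "ModelSpec",
    "LMMFit",
    "WaldContrasts",
    "fit_nested_lmm",
    "fit_variance_components",
    "profile_loglik",
    "dense_loglik",
    "wald_contrasts",
    "predict_group_mean",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """What to fit and how.

    ``response`` is ``"score"`` or one of the seven component names;
    ``group_col`` names the column holding the two-level grouping
    factor and ``reference`` its baseline level (indicator 0).
    """

    response: str = "score"
    reml: bool = True
    n_starts: int = 3
    group_col: str = "group"
    reference: str | None = None


@dataclass
class LMMFit:
    """Fixed effects, variance components and metadata of one fit."""

    beta: np.ndarray
    beta_names: tuple[str, ...]
    se: np.ndarray
    vcov: np.ndarray
    var_patient: float
    var_anchor: float
    var_resid: float
    loglik: float
    converged: bool
    n_obs: int
    n_patients: int
    n_anchors: int
    method: str
    response: str = ""
    group_levels: tuple[str, str] | None = None

    def summary(self) -> pd.DataFrame:
        z = np.divide(
            self.beta, self.se, out=np.full_like(self.beta, np.nan),
            where=self.se > 0,
        )
        p = 2.0 * (1.0 - ndtr(np.abs(z)))
        return pd.DataFrame(
            {"coef": self.beta, "se": self.se, "z": z, "p": p},
            index=list(self.beta_names),
        )


@dataclass(frozen=True)
class WaldContrasts:
    """Between-group Week -12 (intercept) and weekly-slope contrasts."""

    intercept_diff: float
    intercept_se: float
    intercept_z: float
    intercept_p: float
    slope_diff: float
    slope_se: float
    slope_z: float
    slope_p: float


# ---------------------------------------------------------------------------
# Block machinery


class _Pattern:
    """Patient blocks sharing one design matrix and anchor partition."""

    __slots__ = ("X", "Y", "sizes", "n", "m", "J_full", "J_anchor")

    def __init__(self, X: np.ndarray, sizes: tuple[int, ...]):
        self.X = X
        self.sizes = sizes
        self.n = X.shape[0]
        self.Y: list[np.ndarray] = []
        self.m = 0
        self.J_full = np.ones((self.n, self.n))
        J = np.zeros((self.n, self.n))
        pos = 0
        for s in sizes:
            J[pos : pos + s, pos : pos + s] = 1.0
            pos += s
        self.J_anchor = J

    def finalize(self) -> None:
        self.Y = np.column_stack(self.Y)  # type: ignore[assignment]
        self.m = self.Y.shape[1]


def _build_patterns(
    y: np.ndarray,
    X: np.ndarray,
    patient_ids: np.ndarray,
    anchor_ids: np.ndarray,
) -> list[_Pattern]:
    order = np.lexsort((anchor_ids, patient_ids))
    y, X = y[order], X[order]
    patient_ids, anchor_ids = patient_ids[order], anchor_ids[order]
    patterns: dict[tuple, _Pattern] = {}
    boundaries = np.flatnonzero(patient_ids[1:] != patient_ids[:-1]) + 1
    for lo, hi in zip(
        np.concatenate(([0], boundaries)),
        np.concatenate((boundaries, [len(y)])),
    ):
        Xb = np.ascontiguousarray(X[lo:hi])
        ab = anchor_ids[lo:hi]
        sizes = tuple(
            np.diff(
                np.concatenate(
                    ([0], np.flatnonzero(ab[1:] != ab[:-1]) + 1, [len(ab)])
                )
            )
        )
        key = (Xb.tobytes(), sizes)
        pat = patterns.get(key)
        if pat is None:
            pat = patterns[key] = _Pattern(Xb, sizes)
        pat.Y.append(y[lo:hi])
    out = list(patterns.values())
    for pat in out:
        pat.finalize()
    return out


def _criterion(
    patterns: Sequence[_Pattern],
    gamma_patient: float,
    gamma_anchor: float,
    reml: bool,
    p: int,
    n: int,
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Profiled -2 log-likelihood plus GLS beta, sigma2 and X'W^-1X."""
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    ytWy = 0.0
    logdet = 0.0
    for pat in patterns:
        W = (
            np.eye(pat.n)
            + gamma_patient * pat.J_full
            + gamma_anchor * pat.J_anchor
        )
        c, low = cho_factor(W, lower=True, check_finite=False)
        logdet += 2.0 * pat.m * float(np.sum(np.log(np.diag(c))))
        WinvX = cho_solve((c, low), pat.X, check_finite=False)
        WinvY = cho_solve((c, low), pat.Y, check_finite=False)
        XtWX += pat.m * (pat.X.T @ WinvX)
        XtWy += pat.X.T @ WinvY.sum(axis=1)
        ytWy += float(np.sum(pat.Y * WinvY))
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(ytWy - float(beta @ XtWy), 0.0)
    dof = n - p if reml else n
    if rss <= 1e-12 * max(n, 1):
        # perfect fit: variance degenerates, likelihood unbounded
        return -math.inf, beta, 0.0, XtWX
    sigma2 = rss / dof
    neg2ll = dof * math.log(sigma2) + logdet + rss / sigma2 + dof * _LOG2PI
    if reml:
        sign, ld = np.linalg.slogdet(XtWX)
        neg2ll += ld
    return neg2ll, beta, sigma2, XtWX


def profile_loglik(
    y: np.ndarray,
    X: np.ndarray,
    patient_ids: Sequence,
    anchor_ids: Sequence,
    gamma_patient: float,
    gamma_anchor: float,
    reml: bool = True,
) -> tuple[float, np.ndarray, float]:
    """Profiled log-likelihood at given variance ratios.

    ``gamma_* = var_component / var_resid``.  Returns
    ``(loglik, beta_gls, sigma2_resid)``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    pid = np.asarray(pd.factorize(np.asarray(patient_ids))[0])
    aid = pd.factorize(
        np.asarray([f"{a}|{b}" for a, b in zip(patient_ids, anchor_ids)])
    )[0]
    patterns = _build_patterns(y, X, pid, aid)
    neg2ll, beta, sigma2, _ = _criterion(
        patterns, gamma_patient, gamma_anchor, reml, X.shape[1], len(y)
    )
    return -0.5 * neg2ll, beta, sigma2


def dense_loglik(
    y: np.ndarray,
    X: np.ndarray,
    patient_ids: Sequence,
    anchor_ids: Sequence,
    var_patient: float,
    var_anchor: float,
    var_resid: float,
    reml: bool = True,
) -> float:
    """Brute-force dense evaluation of the (restricted) log-likelihood.

    Builds the full marginal covariance ``V = var_resid * I +
    var_patient * Zp Zp' + var_anchor * Za Za'`` and evaluates the
    Gaussian (REML) likelihood at the GLS fixed effects, with no
    exploitation of block structure.  Intended as an independent oracle
    on small instances.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    pid = pd.factorize(np.asarray(patient_ids))[0]
    aid = pd.factorize(
        np.asarray([f"{a}|{b}" for a, b in zip(patient_ids, anchor_ids)])
    )[0]
    Zp = (pid[:, None] == np.arange(pid.max() + 1)[None, :]).astype(float)
    Za = (aid[:, None] == np.arange(aid.max() + 1)[None, :]).astype(float)
    V = (
        var_resid * np.eye(n)
        + var_patient * Zp @ Zp.T
        + var_anchor * Za @ Za.T
    )
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    r = y - X @ beta
    _, logdetV = np.linalg.slogdet(V)
    neg2ll = logdetV + float(r @ Vinv @ r)
    if reml:
        _, logdetX = np.linalg.slogdet(XtVX)
        neg2ll += logdetX + (n - p) * _LOG2PI
    else:
        neg2ll += n * _LOG2PI
    return -0.5 * neg2ll


def _moment_start(
    y: np.ndarray, X: np.ndarray, pid: np.ndarray
) -> tuple[float, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    var_r = float(np.var(r))
    if var_r <= 0:
        return 0.1, 0.05
    means = pd.Series(r).groupby(pid).mean()
    var_pm = float(means.var()) if len(means) > 1 else 0.0
    icc = min(max(var_pm / var_r, 0.02), 0.9)
    gamma_p = icc / (1.0 - icc)
    return gamma_p, 0.5 * gamma_p


def fit_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    patient_ids: Sequence,
    anchor_ids: Sequence,
    *,
    reml: bool = True,
    n_starts: int = 3,
    fixed_gamma: tuple[float, float] | None = None,
    beta_names: tuple[str, ...] | None = None,
) -> LMMFit:
    """REML/ML fit of the nested random-intercept model (low level).

    Optimizes the profiled criterion over log variance ratios with
    Nelder-Mead from ``n_starts`` scaled moment-based starts; ties are
    broken by likelihood, then by the smaller component norm.  Passing
    ``fixed_gamma`` skips optimization (``(0, 0)`` yields the OLS
    limit).  A perfect fit (zero residual) returns the OLS coefficients
    with all variance components zero; a constant response is an error.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than observations")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; the model is degenerate")
    pid = pd.factorize(np.asarray(patient_ids))[0]
    aid = pd.factorize(
        np.asarray([f"{a}|{b}" for a, b in zip(patient_ids, anchor_ids)])
    )[0]
    patterns = _build_patterns(y, X, pid, aid)
    names = beta_names or tuple(f"beta{i}" for i in range(p))

    def crit(gamma_p: float, gamma_a: float):
        return _criterion(patterns, gamma_p, gamma_a, reml, p, n)

    if fixed_gamma is not None:
        g_best = (max(fixed_gamma[0], 0.0), max(fixed_gamma[1], 0.0))
        converged = True
    else:
        g0p, g0a = _moment_start(y, X, pid)
        results: list[tuple[float, tuple[float, float], bool]] = []
        for scale in (1.0, 0.1, 10.0)[: max(n_starts, 1)]:
            theta0 = np.log(np.maximum([g0p * scale, g0a * scale], 1e-8))

            def objective(theta: np.ndarray) -> float:
                g = np.exp(np.clip(theta, -30.0, 12.0))
                val = crit(float(g[0]), float(g[1]))[0]
                return val if math.isfinite(val) else -1e30

            res = optimize.minimize(
                objective,
                theta0,
                method="Nelder-Mead",
                options={
                    "xatol": 1e-9, "fatol": 1e-10,
                    "maxiter": 600, "maxfev": 1200,
                },
            )
            g = np.exp(np.clip(res.x, -30.0, 12.0))
            results.append(
                (float(res.fun), (float(g[0]), float(g[1])), bool(res.success))
            )
        results.sort(key=lambda t: (t[0], t[1][0] ** 2 + t[1][1] ** 2))
        _, g_best, converged = results[0]
        # treat essentially-zero ratios as exactly zero
        g_best = tuple(0.0 if g < 1e-10 else g for g in g_best)

    neg2ll, beta, sigma2, XtWX = crit(*g_best)
    if not math.isfinite(neg2ll):  # perfect fit
        vcov = np.zeros((p, p))
        return LMMFit(
            beta=beta, beta_names=names, se=np.zeros(p), vcov=vcov,
            var_patient=0.0, var_anchor=0.0, var_resid=0.0,
            loglik=math.inf, converged=True, n_obs=n,
            n_patients=int(pid.max()) + 1, n_anchors=int(aid.max()) + 1,
            method="REML" if reml else "ML",
        )
    vcov = sigma2 * np.linalg.inv(XtWX)
    return LMMFit(
        beta=beta,
        beta_names=names,
        se=np.sqrt(np.diag(vcov)),
        vcov=vcov,
        var_patient=g_best[0] * sigma2,
        var_anchor=g_best[1] * sigma2,
        var_resid=sigma2,
        loglik=-0.5 * neg2ll,
        converged=converged,
        n_obs=n,
        n_patients=int(pid.max()) + 1,
        n_anchors=int(aid.max()) + 1,
        method="REML" if reml else "ML",
    )


_RESPONSE_COLS = {"score": "mean_score"}


def _response_column(response: str, columns: Sequence[str]) -> str:
    col = _RESPONSE_COLS.get(response, f"mean_{response}")
    if col in columns:
        return col
    if response in columns:
        return response
    raise KeyError(f"response column for {response!r} not found")


def fit_nested_lmm(
    observations: pd.DataFrame, spec: ModelSpec | None = None
) -> LMMFit:
    """Fit the weekly-trend model to a weekly-observations table.

    ``observations`` needs columns ``patient_id``, ``anchor_id``,
    ``week`` (in [-12, 0]), the response column (``mean_score`` or a
    ``mean_<component>``), and the grouping column.  Time is coded as
    ``week + 12`` so the intercept is the Week -12 prediction.
    """
    spec = spec or ModelSpec()
    obs = observations
    weeks = obs["week"].to_numpy(dtype=float)
    if weeks.min() < -12 or weeks.max() > 0:
        raise ValueError("weeks must lie in [-12, 0]")
    col = _response_column(spec.response, obs.columns)
    groups = obs[spec.group_col].astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 levels in {spec.group_col!r}")
    ref = spec.reference
    if ref is None:
        ref = "control" if "control" in levels else levels[0]
    other = next(l for l in levels if l != ref)
    for level in levels:
        n_pat = obs.loc[groups == level, "patient_id"].nunique()
        if n_pat < 2:
            raise ValueError(f"group level {level!r} has fewer than 2 patients")
    g = (groups != ref).to_numpy(dtype=float)
    t = weeks + 12.0
    X = np.column_stack([np.ones(len(obs)), t, g, t * g])
    fit = fit_variance_components(
        obs[col].to_numpy(dtype=float),
        X,
        obs["patient_id"].to_numpy(),
        obs["anchor_id"].to_numpy(),
        reml=spec.reml,
        n_starts=spec.n_starts,
        beta_names=("intercept", "week", "group", "week_x_group"),
    )
    fit.response = spec.response
    fit.group_levels = (ref, other)
    return fit


def wald_contrasts(fit: LMMFit) -> WaldContrasts:
    """Normal-approximation Wald tests of the group contrasts.

    The Week -12 contrast is the group main effect; the slope contrast
    is the week-by-group interaction.
    """
    if not fit.converged:
        raise ValueError("cannot test contrasts of a non-converged fit")
    if len(fit.beta) != 4:
        raise ValueError("contrasts require the 4-term trend model")

    def one(i: int) -> tuple[float, float, float, float]:
        est, se = float(fit.beta[i]), float(fit.se[i])
        z = est / se if se > 0 else math.inf * np.sign(est)
        pv = 2.0 * (1.0 - ndtr(abs(z))) if math.isfinite(z) else 0.0
        return est, se, z, pv

    i_est, i_se, i_z, i_p = one(2)
    s_est, s_se, s_z, s_p = one(3)
    return WaldContrasts(
        intercept_diff=i_est, intercept_se=i_se, intercept_z=i_z, intercept_p=i_p,
        slope_diff=s_est, slope_se=s_se, slope_z=s_z, slope_p=s_p,
    )


def predict_group_mean(fit: LMMFit, week: float, group: str) -> float:
    """Fixed-effect prediction ``b0 + b1*t + b2*g + b3*t*g``, t = week + 12."""
    if not -12 <= week <= 0:
        raise ValueError("week must lie in [-12, 0]")
    if fit.group_levels is None:
        raise ValueError("fit carries no group coding")
    ref, other = fit.group_levels
    if group == ref:
        g = 0.0
    elif group == other:
        g = 1.0
    else:
        raise ValueError(f"unknown group {group!r}; levels are {fit.group_levels}")
    t = week + 12.0
    b = fit.beta
    return float(b[0] + b[1] * t + b[2] * g + b[3] * t * g)
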