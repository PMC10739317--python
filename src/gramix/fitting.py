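"""Nonlinear least-squares estimation of Hill parameters and assay QC.

Fitting minimises unweighted squared residuals with a damped least-squares
(trust-region) solver; potency is estimated on the log10 scale for
conditioning. Standard errors come from the Jacobian-based covariance at
the optimum; Wald intervals use the t quantile with n_obs - p degrees of
freedom. By default the fit operates on replicate means of each
concentration (``aggregate="mean"``), the usual convention for plate
dose-response work; pass ``aggregate="none"`` to fit every well.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .types import LigandParams, ReferenceScale, ResponseCurve

__all__ = [
    "ActivityClass",
    "FitResult",
    "QCReport",
    "fit_hill",
    "fit_e2_reference",
    "goodness_of_fit",
    "classify_activity",
    "qc_recovery",
    "wald_interval",
    "wald_covers",
]

A_BOUNDS = (0.0, 3.0)
N_BOUNDS = (0.1, 10.0)
# LoD / LoQ conventions: activity below 10% is not detectable, below 20%
# is not quantifiable; the thresholds themselves fall on the upper class.
LOD_PCT = 10.0
LOQ_PCT = 20.0
E2_RECOVERY_RANGE = (89.0, 120.0)


class ActivityClass(str, Enum):
    NOT_DETECTED = "not_detected"
    BELOW_LOQ = "below_LoQ"
    QUANTIFIABLE = "quantifiable"


def classify_activity(max_observed: float) -> ActivityClass:
    """Classify a sample by its maximal observed % activity."""
    if not np.isfinite(max_observed):
        raise ValueError(f"activity must be finite, got {max_observed!r}")
    if max_observed < LOD_PCT:
        return ActivityClass.NOT_DETECTED
    if max_observed < LOQ_PCT:
        return ActivityClass.BELOW_LOQ
    return ActivityClass.QUANTIFIABLE


def goodness_of_fit(observed, predicted) -> tuple[float, float]:
    """RMSE and R² of predictions against observations.

    RMSE uses the plain mean of squared residuals (denominator n_obs).
    R² = 1 - SSres/SStot about the observed mean; undefined (NaN) when the
    observations have zero variance.
    """
    obs = np.asarray(
        observed.responses if isinstance(observed, ResponseCurve) else observed,
        dtype=float,
    ).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    mask = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[mask], pred[mask]
    if obs.size != pred.size or obs.size == 0:
        raise ValueError("observed and predicted must have equal, nonzero length")
    res = obs - pred
    rmse = float(np.sqrt(np.mean(res ** 2)))
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    rsq = float("nan") if sstot == 0.0 else float(1.0 - np.sum(res ** 2) / sstot)
    return rmse, rsq


@dataclass
class FitResult:
    params: Optional[LigandParams]
    scale: ReferenceScale
    se: dict[str, float]
    rmse: float
    rsq: float
    n_obs: int
    converged: bool
    residuals: np.ndarray
    n_params: int = 3
    message: str = ""
    # extra carries model-specific estimates, e.g. fitted (y0, m) for the
    # reference curve, and the log10-scale SE of c used for Wald intervals
    extra: dict = field(default_factory=dict)


def _failed(scale: ReferenceScale, n_obs: int, msg: str, n_params: int = 3) -> FitResult:
    return FitResult(
        params=None,
        scale=scale,
        se={},
        rmse=float("nan"),
        rsq=float("nan"),
        n_obs=n_obs,
        converged=False,
        residuals=np.array([]),
        n_params=n_params,
        message=msg,
    )


def _flatten(curve: ResponseCurve, aggregate: str) -> tuple[np.ndarray, np.ndarray]:
    if aggregate == "mean":
        x = curve.concentrations
        y = curve.mean_responses
    elif aggregate == "none":
        reps = curve.responses.shape[1]
        x = np.repeat(curve.concentrations, reps)
        y = curve.responses.ravel()
    else:
        raise ValueError(f"aggregate must be 'mean' or 'none', got {aggregate!r}")
    mask = np.isfinite(y)
    return x[mask], y[mask]


def _covariance(jac: np.ndarray, resid: np.ndarray, n_params: int) -> np.ndarray:
    """HC3-type sandwich covariance at the least-squares optimum.

    Luminescence-derived responses carry CV-style (signal-proportional)
    noise, so the homoscedastic J'J covariance understates the uncertainty
    of plateau-driven parameters; the leverage-corrected sandwich estimator
    stays calibrated without weighting the fit itself.
    """
    n_obs = resid.size
    if n_obs <= n_params:
        return np.full((n_params, n_params), np.nan)
    try:
        jtj_inv = np.linalg.pinv(jac.T @ jac)
        lev = np.clip(np.einsum("ij,jk,ik->i", jac, jtj_inv, jac), 0.0, 1.0 - 1e-6)
        w = resid ** 2 / (1.0 - lev) ** 2
        meat = (jac * w[:, None]).T @ jac
        cov = jtj_inv @ meat @ jtj_inv
    except np.linalg.LinAlgError:
        return np.full((n_params, n_params), np.nan)
    return cov


def _c_bounds(x: np.ndarray) -> tuple[float, float]:
    return np.log10(x.min() / 100.0), np.log10(x.max() * 100.0)


def fit_hill(
    curve: ResponseCurve,
    scale: ReferenceScale,
    init: Optional[LigandParams] = None,
    aggregate: str = "mean",
) -> FitResult:
    """Estimate (a, c, n) of a single ligand by least squares.

    The reference scale (y0, m) is held fixed from the E2 fit. Multi-start:
    the data-driven initial guess plus log-spaced perturbations of the
    initial potency; the best SSres wins, ties broken by the lower slope.
    """
    if np.unique(curve.concentrations).size < 4:
        raise ValueError("fitting requires at least 4 distinct concentrations")
    x, y = _flatten(curve, aggregate)
    n_obs = y.size
    if n_obs < 4:
        raise ValueError("fitting requires at least 4 finite observations")
    if np.ptp(y) < 1e-9 * max(1.0, abs(np.mean(y))):
        return _failed(scale, n_obs, "constant response: parameters unidentifiable")

    lx = np.log(x)

    def resid(theta: np.ndarray) -> np.ndarray:
        a, lc, n = theta
        with np.errstate(over="ignore"):
            t = np.exp(np.clip(n * (lx - lc * np.log(10.0)), -700, 700))
        return scale.y0 + scale.span * a * t / (1.0 + t) - y

    lc_lo, lc_hi = _c_bounds(x)
    if init is not None:
        a0, lc0, n0 = init.a, np.log10(init.c), init.n
    else:
        a0 = np.clip((y.max() - scale.y0) / scale.span, 0.05, A_BOUNDS[1])
        target = scale.y0 + (y.max() - scale.y0) / 2.0
        means = ResponseCurve(curve.concentrations, curve.responses).mean_responses
        c0 = curve.concentrations[int(np.argmin(np.abs(means - target)))]
        lc0, n0 = np.log10(c0), 1.0
    a0 = float(np.clip(a0, *A_BOUNDS))
    n0 = float(np.clip(n0, *N_BOUNDS))

    lo = np.array([A_BOUNDS[0], lc_lo, N_BOUNDS[0]])
    hi = np.array([A_BOUNDS[1], lc_hi, N_BOUNDS[1]])
    starts = [np.clip(np.array([a0, lc0 + d, n0]), lo, hi)
              for d in (0.0, -2.0, -1.0, 0.5, 1.0, 2.0)]

    best = None
    for x0 in starts:
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:  # pragma: no cover - solver failure is diagnostic only
            continue
        ssres = float(2.0 * res.cost)
        if best is None or ssres < best[0] * (1 - 1e-9) or (
            abs(ssres - best[0]) <= 1e-9 * max(best[0], 1e-300)
            and res.x[2] < best[1].x[2]
        ):
            best = (ssres, res)
    if best is None:
        return _failed(scale, n_obs, "all optimizer starts failed")
    ssres, res = best
    a, lc, n = res.x
    cov = _covariance(res.jac, res.fun, 3)
    se_diag = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    c = 10.0 ** lc
    se = {"a": float(se_diag[0]), "c": float(c * np.log(10.0) * se_diag[1]),
          "n": float(se_diag[2])}
    rmse, rsq = goodness_of_fit(y, y + res.fun)
    return FitResult(
        params=LigandParams(a=float(a), c=float(c), n=float(n)),
        scale=scale,
        se=se,
        rmse=rmse,
        rsq=rsq,
        n_obs=n_obs,
        converged=bool(res.success),
        residuals=res.fun.copy(),
        n_params=3,
        message=res.message,
        extra={"se_log10c": float(se_diag[1]), "ssres": ssres},
    )


def fit_e2_reference(
    curve: ResponseCurve,
    fix_m: Optional[float] = None,
    aggregate: str = "mean",
) -> tuple[ReferenceScale, FitResult]:
    """Fit the reference-agonist (E2) standard curve.

    Four-parameter logistic with efficacy fixed at 1: estimates
    (y0, m, c, n), returning the plate's reference scale and the E2 EC50
    used for QC dosing. ``fix_m`` pins the upper asymptote (e.g. at 100
    when upstream normalisation already scaled the plate).
    """
    if np.unique(curve.concentrations).size < 4:
        raise ValueError("fitting requires at least 4 distinct concentrations")
    x, y = _flatten(curve, aggregate)
    n_obs = y.size
    if np.ptp(y) < 1e-9 * max(1.0, abs(np.mean(y))):
        return ReferenceScale(), _failed(
            ReferenceScale(), n_obs, "constant response: parameters unidentifiable", 4)

    lx = np.log(x)
    free_m = fix_m is None
    n_params = 4 if free_m else 3

    def unpack(theta):
        if free_m:
            y0, m, lc, n = theta
        else:
            y0, lc, n = theta
            m = fix_m
        return y0, m, lc, n

    def resid(theta: np.ndarray) -> np.ndarray:
        y0, m, lc, n = unpack(theta)
        with np.errstate(over="ignore"):
            t = np.exp(np.clip(n * (lx - lc * np.log(10.0)), -700, 700))
        return y0 + (m - y0) * t / (1.0 + t) - y

    lc_lo, lc_hi = _c_bounds(x)
    y0_0 = max(float(y.min()), 0.0)
    m0 = float(y.max())
    target = y0_0 + (m0 - y0_0) / 2.0
    means = ResponseCurve(curve.concentrations, curve.responses).mean_responses
    lc0 = np.log10(curve.concentrations[int(np.argmin(np.abs(means - target)))])

    if free_m:
        lo = np.array([0.0, max(10.0, 0.2 * m0), lc_lo, N_BOUNDS[0]])
        hi = np.array([max(1.0, 0.5 * m0), 4.0 * m0, lc_hi, N_BOUNDS[1]])
        base = np.array([y0_0, m0, lc0, 1.0])
    else:
        lo = np.array([0.0, lc_lo, N_BOUNDS[0]])
        hi = np.array([max(1.0, 0.5 * fix_m), lc_hi, N_BOUNDS[1]])
        base = np.array([y0_0, lc0, 1.0])

    best = None
    idx_lc = 2 if free_m else 1
    for d in (0.0, -2.0, -1.0, 0.5, 1.0, 2.0):
        x0 = base.copy()
        x0[idx_lc] += d
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:  # pragma: no cover
            continue
        ssres = float(2.0 * res.cost)
        if best is None or ssres < best[0] * (1 - 1e-9):
            best = (ssres, res)
    if best is None:
        return ReferenceScale(), _failed(ReferenceScale(), n_obs,
                                         "all optimizer starts failed", n_params)
    ssres, res = best
    y0, m, lc, n = unpack(res.x)
    c = 10.0 ** lc
    cov = _covariance(res.jac, res.fun, n_params)
    se_diag = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    if free_m:
        se = {"y0": float(se_diag[0]), "m": float(se_diag[1]),
              "c": float(c * np.log(10.0) * se_diag[2]), "n": float(se_diag[3])}
        se_lc = float(se_diag[2])
    else:
        se = {"y0": float(se_diag[0]), "m": 0.0,
              "c": float(c * np.log(10.0) * se_diag[1]), "n": float(se_diag[2])}
        se_lc = float(se_diag[1])
    scale = ReferenceScale(y0=float(max(y0, 0.0)), m=float(m))
    rmse, rsq = goodness_of_fit(y, y + res.fun)
    fit = FitResult(
        params=LigandParams(a=1.0, c=float(c), n=float(n)),
        scale=scale,
        se={"a": 0.0, "c": se["c"], "n": se["n"]},
        rmse=rmse,
        rsq=rsq,
        n_obs=n_obs,
        converged=bool(res.success),
        residuals=res.fun.copy(),
        n_params=n_params,
        message=res.message,
        extra={"y0": float(y0), "m": float(m), "se_y0": se["y0"], "se_m": se["m"],
               "se_log10c": se_lc, "ssres": ssres},
    )
    return scale, fit


def wald_interval(fit: FitResult, param: str, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for one fitted parameter.

    For ``c`` the interval is formed on log10 c (the fitting scale) and
    exponentiated, yielding an asymmetric positive interval.
    """
    if fit.params is None or not fit.converged:
        raise ValueError("fit did not converge; no intervals available")
    dof = max(fit.n_obs - fit.n_params, 1)
    tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
    if param == "c":
        lc = np.log10(fit.params.c)
        half = tcrit * fit.extra["se_log10c"]
        return 10.0 ** (lc - half), 10.0 ** (lc + half)
    est = getattr(fit.params, param)
    half = tcrit * fit.se[param]
    return est - half, est + half


def wald_covers(fit: FitResult, truth: LigandParams, level: float = 0.95) -> dict[str, bool]:
    """Whether each parameter's Wald interval covers the generating truth."""
    out = {}
    for name, true_val in (("a", truth.a), ("c", truth.c), ("n", truth.n)):
        lo, hi = wald_interval(fit, name, level)
        out[name] = bool(lo <= true_val <= hi)
    return out


@dataclass
class QCReport:
    """Plate-level quality control summary."""

    e2_recovery: float
    passed: bool
    activity_classes: dict[str, ActivityClass] = field(default_factory=dict)


def qc_recovery(
    qc_responses,
    expected: float = 50.0,
    recovery_range: tuple[float, float] = E2_RECOVERY_RANGE,
    activities: Optional[dict[str, float]] = None,
) -> QCReport:
    """Recovery of QC wells dosed at the reference EC50.

    QC wells are dosed at the E2 EC50 so their expected response is 50% of
    the reference maximum; recovery is observed/expected in percent, passing
    within the accepted range (89%-120% by default).
    """
    qc = np.asarray(qc_responses, dtype=float)
    if qc.size < 3:
        raise ValueError("QC wells are run at least in triplicate")
    recovery = float(100.0 * np.nanmean(qc) / expected)
    passed = recovery_range[0] <= recovery <= recovery_range[1]
    classes = {k: classify_activity(v) for k, v in (activities or {}).items()}
    return QCReport(e2_recovery=recovery, passed=passed, activity_classes=classes)
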