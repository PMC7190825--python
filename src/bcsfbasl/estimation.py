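"""Nonlinear least-squares fitting of the forward models to TI/b-value series.

All fitters use bounded trust-region least squares
(:func:`scipy.optimize.least_squares`, method ``'trf'``), unweighted
residuals, and — for the kinetic models, whose delta/tau trade-off produces
a shallow RSS valley — a small multi-start over the transit time with the
best-RSS start winning (ties broken towards the smaller transit time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .signal_models import (
    IrParams,
    KineticParams,
    RelaxationSet,
    bcsfb_delta_m,
    buxton_params,
    inversion_recovery_signal,
)

__all__ = ["FitResult", "fit_inversion_recovery", "fit_bcsfb",
           "fit_buxton", "fit_dapp"]

#: transit-time initialisations for the kinetic-model multi-start, seconds
DELTA_STARTS = (0.2, 0.5, 1.0)

#: conversion from s^-1 to ml/100 ml/min (x100 for "per 100 ml", x60 for min)
PER_SECOND_TO_ML100ML_MIN = 6000.0


@dataclass
class FitResult:
    """Outcome of one model fit.

    estimates   parameter name -> value, model-native units
    stderr      parameter name -> standard error from the local Jacobian
                covariance (NaN where the covariance is singular)
    rss         residual sum of squares
    converged   optimizer success and finite, in-bounds estimates
    n_points    number of data points used
    """

    estimates: dict[str, float]
    stderr: dict[str, float]
    rss: float
    converged: bool
    n_points: int
    extras: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


def _stderr(res, names) -> dict[str, float]:
    """Per-parameter standard errors from the Gauss-Newton covariance
    s^2 (J^T J)^-1 with s^2 = RSS / (n - p); NaN if not estimable."""
    n, p = res.fun.size, len(names)
    out = {k: float("nan") for k in names}
    if n <= p:
        return out
    rss = float(res.fun @ res.fun)
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.inv(jtj) * rss / (n - p)
        diag = np.diag(cov)
        for k, v in zip(names, diag):
            out[k] = float(np.sqrt(v)) if v >= 0 else float("nan")
    except np.linalg.LinAlgError:
        pass
    return out


def _run(residual, x0, bounds, names) -> FitResult:
    x0 = np.clip(np.asarray(x0, float), bounds[0], bounds[1])
    res = least_squares(residual, x0, bounds=bounds, method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    est = {k: float(v) for k, v in zip(names, res.x)}
    ok = bool(res.success) and all(np.isfinite(v) for v in est.values())
    return FitResult(estimates=est, stderr=_stderr(res, names),
                     rss=float(res.fun @ res.fun), converged=ok,
                     n_points=res.fun.size)


def _check_series(x, y, n_free: int, what: str):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"{what}: x and y must be matching 1-D series")
    if x.size < n_free:
        raise ValueError(
            f"{what}: need at least {n_free} points, got {x.size}")
    return x, y


def fit_inversion_recovery(ti_list, signals, magnitude: bool = False,
                           fix_beta: float | None = None) -> FitResult:
    """Estimate (m0, t1, beta) from multi-TI control data.

    Fits the standard inversion-recovery model m0 (1 - 2 beta exp(-TI/T1)).
    ``magnitude=True`` restores signal polarity before fitting by flipping
    points below the best-candidate null point; ``fix_beta`` pins the
    inversion efficiency (e.g. 1.0 for ideal inversion).
    """
    free = 2 if fix_beta is not None else 3
    ti, sig = _check_series(ti_list, signals, free, "fit_inversion_recovery")

    if magnitude:
        sig = _restore_polarity(ti, np.abs(sig))

    m0_guess = max(float(np.max(np.abs(sig))), 1e-12)
    t1_guess = max(float(np.median(ti)), 0.2)
    names = ["m0", "t1"] if fix_beta is not None else ["m0", "t1", "beta"]
    lb = [1e-12, 0.1] + ([] if fix_beta is not None else [0.2])
    ub = [np.inf, 10.0] + ([] if fix_beta is not None else [1.0])

    def residual(x):
        beta = fix_beta if fix_beta is not None else x[2]
        p = IrParams(m0=x[0], t1=x[1], beta=min(max(beta, 1e-9), 1.0))
        return inversion_recovery_signal(ti, p) - sig

    best = None
    for t1_init in (t1_guess, 1.0, 4.0):
        x0 = [m0_guess, t1_init] + ([] if fix_beta is not None else [1.0])
        fit = _run(residual, x0, (lb, ub), names)
        if best is None or fit.rss < best.rss:
            best = fit
    if fix_beta is not None:
        best.estimates["beta"] = float(fix_beta)
        best.stderr["beta"] = 0.0
    if np.ptp(sig) == 0:
        # a constant series carries no T1 information
        best.converged = False
    if not best.converged:
        warnings.warn("inversion-recovery fit did not converge; "
                      "estimates are reported anyway", RuntimeWarning)
    return best


def _restore_polarity(ti, mag):
    """Pick the null-point split that best explains magnitude IR data and
    return the signed series (early TIs negative)."""
    best_sig, best_rss = mag, np.inf
    for k in range(mag.size + 1):
        trial = mag.copy()
        trial[:k] *= -1.0
        # quick linear-free check: fit via the full model at coarse tol
        m0 = max(float(np.max(mag)), 1e-12)

        def residual(x, trial=trial):
            p = IrParams(m0=x[0], t1=x[1], beta=min(max(x[2], 1e-9), 1.0))
            return inversion_recovery_signal(ti, p) - trial

        res = least_squares(residual, [m0, 2.0, 1.0],
                            bounds=([1e-12, 0.1, 0.2], [np.inf, 10.0, 1.0]),
                            method="trf")
        rss = float(res.fun @ res.fun)
        if rss < best_rss:
            best_rss, best_sig = rss, trial
    return best_sig


def fit_bcsfb(ti_list, dm_over_m0corr, fixed: dict,
              fix_tau: float | None = None) -> FitResult:
    """Estimate (f, delta, tau) of blood-water delivery to ventricular CSF.

    ``dm_over_m0corr`` is the ROI-summed difference signal divided by the
    ventricle-volume-corrected M0, so the model amplitude uses m0 = 1.
    ``fixed`` must supply alpha, phi, r1a and r1app (the latter from the
    long-TE control-signal inversion-recovery fit). The estimate ``f`` is in
    s^-1; ``f_ml100ml_min`` (x6000) is included in ``extras``.
    """
    n_free = 2 if fix_tau is not None else 3
    ti, dm = _check_series(ti_list, dm_over_m0corr, n_free + 1, "fit_bcsfb")
    alpha, phi = fixed["alpha"], fixed["phi"]
    r1a, r1app = fixed["r1a"], fixed["r1app"]

    if not np.any(dm):
        # no signal: zero delivery, exactly
        est = {"f": 0.0, "delta": 0.0,
               "tau": float(fix_tau) if fix_tau is not None else 0.1}
        return FitResult(estimates=est,
                         stderr={k: float("nan") for k in est}, rss=0.0,
                         converged=True, n_points=ti.size,
                         extras={"f_ml100ml_min": 0.0})

    names = ["f", "delta"] + ([] if fix_tau is not None else ["tau"])
    lb = [0.0, 0.0] + ([] if fix_tau is not None else [0.1])
    ub = [0.1, float(np.max(ti))] + ([] if fix_tau is not None else [10.0])

    def residual(x):
        f, delta = x[0], x[1]
        tau = fix_tau if fix_tau is not None else x[2]
        p = KineticParams(f=max(f, 0.0), delta=delta, tau=max(tau, 1e-6),
                          alpha=alpha, phi=phi, r1app=r1app, r1a=r1a, m0=1.0)
        return bcsfb_delta_m(ti, p) - dm

    f0 = 0.002
    best = None
    for d0 in DELTA_STARTS:
        x0 = [f0, d0] + ([] if fix_tau is not None else [3.0])
        fit = _run(residual, x0, (lb, ub), names)
        if (best is None or fit.rss < best.rss - 1e-15
                or (abs(fit.rss - best.rss) <= 1e-15
                    and fit["delta"] < best["delta"])):
            best = fit
    if fix_tau is not None:
        best.estimates["tau"] = float(fix_tau)
        best.stderr["tau"] = 0.0
    best.extras["f_ml100ml_min"] = best["f"] * PER_SECOND_TO_ML100ML_MIN
    return best


def fit_buxton(ti_list, dm_over_m0, fixed: dict,
               fix_tau: float | None = None) -> FitResult:
    """Estimate (f, delta) of cortical perfusion with the pulsed-ASL
    general kinetic model.

    The fitted ``f`` is the delivery rate per unit tissue magnetisation
    (k = f_blood/lambda, s^-1); CBF in ml/100 g/min is k * lambda * 6000
    at unit tissue density and is included in ``extras['cbf_ml100g_min']``.
    ``fixed`` must supply alpha, lambda_tissue, t1_tissue and r1a.
    """
    n_free = 2 if fix_tau is not None else 3
    ti, dm = _check_series(ti_list, dm_over_m0, max(n_free, 3), "fit_buxton")

    if not np.any(dm):
        est = {"f": 0.0, "delta": 0.0,
               "tau": float(fix_tau) if fix_tau is not None else 0.1}
        return FitResult(estimates=est,
                         stderr={k: float("nan") for k in est}, rss=0.0,
                         converged=True, n_points=ti.size,
                         extras={"cbf_ml100g_min": 0.0})

    alpha = fixed["alpha"]
    lam = fixed["lambda_tissue"]
    rel = RelaxationSet(t1_tissue=fixed["t1_tissue"],
                        t1_blood=1.0 / fixed["r1a"], lambda_tissue=lam)

    names = ["f", "delta"] + ([] if fix_tau is not None else ["tau"])
    lb = [0.0, 0.0] + ([] if fix_tau is not None else [0.1])
    ub = [0.1, float(np.max(ti))] + ([] if fix_tau is not None else [10.0])

    def residual(x):
        k, delta = x[0], x[1]
        tau = fix_tau if fix_tau is not None else x[2]
        p = buxton_params(max(k, 0.0), delta, max(tau, 1e-6), alpha, rel)
        return bcsfb_delta_m(ti, p) - dm

    best = None
    for d0 in DELTA_STARTS:
        x0 = [0.02, d0] + ([] if fix_tau is not None else [3.0])
        fit = _run(residual, x0, (lb, ub), names)
        if (best is None or fit.rss < best.rss - 1e-15
                or (abs(fit.rss - best.rss) <= 1e-15
                    and fit["delta"] < best["delta"])):
            best = fit
    if fix_tau is not None:
        best.estimates["tau"] = float(fix_tau)
        best.stderr["tau"] = 0.0
    best.extras["cbf_ml100g_min"] = (best["f"] * lam
                                     * PER_SECOND_TO_ML100ML_MIN)
    return best


def fit_dapp(b_values, signals) -> FitResult:
    """Apparent (pseudo-)diffusion coefficient from a mono-exponential decay.

    For exactly two b-values the closed form
    d_app = ln(S(b1)/S(b2)) / (b2 - b1) is used; for more, a log-linear
    least-squares fit. Returns (s0, d_app) with d_app in mm^2/s.
    """
    b, sig = _check_series(b_values, signals, 2, "fit_dapp")
    if np.unique(b).size < 2:
        raise ValueError("fit_dapp: need at least 2 distinct b-values")
    if np.any(sig <= 0):
        raise ValueError("fit_dapp: signals must be positive "
                         "(log-linear model)")
    log_s = np.log(sig)
    if b.size == 2:
        d = float((log_s[0] - log_s[1]) / (b[1] - b[0]))
        s0 = float(np.exp(log_s[0] + d * b[0]))
        resid = 0.0
        stderr = {"s0": float("nan"), "d_app": float("nan")}
    else:
        slope, intercept = np.polyfit(b, log_s, 1)
        d, s0 = float(-slope), float(np.exp(intercept))
        pred = intercept + slope * b
        resid = float(np.sum((log_s - pred) ** 2))
        n = b.size
        sxx = float(np.sum((b - b.mean()) ** 2))
        s2 = resid / (n - 2) if n > 2 else float("nan")
        stderr = {"s0": float("nan"),
                  "d_app": float(np.sqrt(s2 / sxx)) if n > 2 else float("nan")}
    return FitResult(estimates={"s0": s0, "d_app": d}, stderr=stderr,
                     rss=resid, converged=bool(np.isfinite(d)),
                     n_points=b.size)
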