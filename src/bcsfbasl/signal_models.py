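"""Closed-form forward models for FAIR-ASL signals.

All models here describe a single destination compartment (ventricular CSF
for the blood-CSF barrier measurement, cortical tissue for conventional
perfusion) receiving a rectangular bolus of inverted arterial blood water.
The labelled magnetisation decays at the blood rate ``r1a`` until delivery
and at the apparent rate of the destination compartment afterwards, which
yields the Alsop-Detre single-compartment solution

    dM(TI) = (2 m0 f a / phi) exp(-TI R1app)
             [exp(min(TI, d+tau) dR) - exp(d dR)] / dR,   dR = R1app - R1a

for TI > delta and zero before arrival. The same expression serves the
pulsed (FAIR) Buxton general kinetic model once the delivery rate is
expressed per unit of tissue magnetisation (k = f / lambda) and the
apparent relaxation includes venous clearance (1/T1' = 1/T1_tissue + k).

Times are seconds throughout; rates are s^-1. Unit conversion to the
conventional reporting units (ml/100 ml/min, ml/100 g/min) lives in
:mod:`bcsfbasl.quantification`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad

__all__ = [
    "RelaxationSet",
    "KineticParams",
    "IrParams",
    "MOUSE_9T4",
    "t2_attenuation",
    "inversion_recovery_signal",
    "bcsfb_delta_m",
    "buxton_delta_m",
    "buxton_params",
    "delivery_convolution_oracle",
    "diffusion_attenuation",
]

# Tolerance below which the exchange-rate difference dR = R1app - R1a is
# treated as zero and the analytic limit used (double-precision cancellation
# dominates below this scale).
DELTA_R_TOL = 1e-6


@dataclass(frozen=True)
class RelaxationSet:
    """Longitudinal/transverse relaxation constants and partition coefficients.

    Defaults are typical mouse-brain values at 9.4 T: T2 of 38, 30 and
    200 ms for parenchyma, blood and CSF; blood T1 of 2.4 s; blood-CSF
    partition coefficient of 1 and blood-tissue partition coefficient 0.9.
    """

    t1_blood: float = 2.4
    t1_tissue: float = 1.7
    t1_csf: float = 4.0
    t2_tissue: float = 0.038
    t2_blood: float = 0.030
    t2_csf: float = 0.200
    phi_csf: float = 1.0
    lambda_tissue: float = 0.9

    def __post_init__(self) -> None:
        for name in ("t1_blood", "t1_tissue", "t1_csf",
                     "t2_tissue", "t2_blood", "t2_csf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("phi_csf", "lambda_tissue"):
            v = getattr(self, name)
            if not 0 < v <= 1.2:
                raise ValueError(f"{name} must lie in (0, 1.2]")

    @property
    def r1a(self) -> float:
        """Longitudinal relaxation rate of arterial blood, s^-1."""
        return 1.0 / self.t1_blood


#: Mouse 9.4 T constants used throughout as the default acquisition context.
MOUSE_9T4 = RelaxationSet()


@dataclass(frozen=True)
class KineticParams:
    """Parameter set of the single-compartment delivery model.

    f       fractional delivery rate of labelled blood water, s^-1
    delta   transit (arrival) time, s
    tau     temporal width of the labelled bolus, s
    alpha   labelling (inversion) efficiency, in [0, 1]
    phi     blood-destination partition coefficient
    r1app   apparent longitudinal relaxation rate of the destination, s^-1
    r1a     longitudinal relaxation rate of blood, s^-1
    m0      equilibrium magnetisation of the destination, signal units
    """

    f: float
    delta: float
    tau: float
    alpha: float
    phi: float
    r1app: float
    r1a: float
    m0: float

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("f must be non-negative")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")
        if self.r1app <= 0 or self.r1a <= 0:
            raise ValueError("relaxation rates must be positive")


@dataclass(frozen=True)
class IrParams:
    """Inversion-recovery parameters: equilibrium signal, T1, inversion
    efficiency beta (1 = perfect inversion)."""

    m0: float
    t1: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")
        if self.t1 <= 0:
            raise ValueError("t1 must be positive")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")


def t2_attenuation(te, t2):
    """Fraction of transverse signal surviving an echo time.

    At TE = 220 ms with mouse T2s of 38/30/200 ms, parenchyma, blood and
    CSF retain ~0.3%, ~0.07% and ~33% of their TE = 0 signal -- the
    arithmetic behind the ultra-long-TE isolation of CSF.
    """
    te = np.asarray(te, dtype=float)
    if np.any(te < 0):
        raise ValueError("te must be non-negative")
    if np.any(np.asarray(t2) <= 0):
        raise ValueError("t2 must be positive")
    out = np.exp(-te / t2)
    return out if out.ndim else float(out)


def inversion_recovery_signal(ti, p: IrParams, magnitude: bool = False):
    """Standard inversion-recovery signal m0 (1 - 2 beta exp(-TI/T1)).

    With ``magnitude=True`` returns the absolute value, matching
    magnitude-reconstructed data.
    """
    ti = np.asarray(ti, dtype=float)
    out = p.m0 * (1.0 - 2.0 * p.beta * np.exp(-ti / p.t1))
    if magnitude:
        out = np.abs(out)
    return out if out.ndim else float(out)


def _delivery_kernel(ti, delta, tau, r1app, r1a):
    """Integral of the decayed bolus, exp(ti*r1app) * int_d^min(ti,d+tau)
    exp(-s r1a) exp(-(ti-s) r1app) ds, vectorised over ti with the
    degenerate r1app == r1a limit handled analytically."""
    ti = np.asarray(ti, dtype=float)
    upper = np.minimum(ti, delta + tau)
    width = np.clip(upper - delta, 0.0, None)
    dr = r1app - r1a
    if abs(dr) < DELTA_R_TOL:
        kern = width
    else:
        kern = (np.exp(upper * dr) - np.exp(delta * dr)) / dr
        kern = np.where(width > 0, kern, 0.0)
    return kern


def bcsfb_delta_m(ti, p: KineticParams):
    """Labelled-water signal delivered across the blood-CSF barrier.

    Extra-vascular single-compartment model of blood water delivery into
    ventricular CSF: zero before the transit time, then the Alsop-Detre
    solution with apparent CSF relaxation ``r1app``. The intravascular term
    is omitted -- at TE = 220 ms blood signal is nulled.
    """
    ti = np.asarray(ti, dtype=float)
    if np.any(ti < 0):
        raise ValueError("ti must be non-negative")
    amp = 2.0 * p.m0 * p.f * p.alpha / p.phi
    out = amp * np.exp(-ti * p.r1app) * _delivery_kernel(
        ti, p.delta, p.tau, p.r1app, p.r1a)
    return out if out.ndim else float(out)


def buxton_params(k: float, delta: float, tau: float, alpha: float,
                  rel: RelaxationSet, m0: float = 1.0) -> KineticParams:
    """Kinetic parameters for the pulsed-ASL general kinetic model.

    ``k`` is the delivery rate per unit of tissue magnetisation, k = f/lambda
    (so CBF in ml/100 g/min = k * lambda * 6000 at unit tissue density). The
    apparent tissue relaxation includes venous clearance:
    1/T1' = 1/T1_tissue + k.
    """
    if k < 0:
        raise ValueError("delivery rate must be non-negative")
    r1app = 1.0 / rel.t1_tissue + k
    return KineticParams(f=k, delta=delta, tau=tau, alpha=alpha, phi=1.0,
                         r1app=r1app, r1a=rel.r1a, m0=m0)


def buxton_delta_m(ti, p: KineticParams, rel: RelaxationSet | None = None):
    """Pulsed-ASL general kinetic model for cortical perfusion.

    Identical integral solution to :func:`bcsfb_delta_m`; the tissue-specific
    physics enters through the apparent relaxation rate, which must include
    venous clearance of labelled water (1/T1' = 1/T1_tissue + f/lambda). If a
    :class:`RelaxationSet` is supplied, ``r1app`` is recomputed from it and
    ``p.f`` (interpreted as k = f/lambda); otherwise ``p.r1app`` is trusted.
    """
    if rel is not None:
        p = replace(p, r1app=1.0 / rel.t1_tissue + p.f, r1a=rel.r1a, phi=1.0)
    return bcsfb_delta_m(ti, p)


def delivery_convolution_oracle(ti: float, p: KineticParams,
                                clearance_rate: float | None = None) -> float:
    """Numerical-quadrature reference for the closed-form delta-M models.

    Integrates 2 m0 f alpha / phi * int c(s) exp(-(ti-s) R) ds directly,
    with c(s) a rectangular bolus on [delta, delta+tau] decaying at r1a and
    R the destination's apparent rate (``clearance_rate`` overrides
    ``p.r1app``). Quadrature tolerance 1e-12; intended for verification only.
    """
    if ti < 0:
        raise ValueError("ti must be non-negative")
    rate = p.r1app if clearance_rate is None else clearance_rate
    lo, hi = p.delta, min(ti, p.delta + p.tau)
    if hi <= lo or p.f == 0:
        return 0.0

    def integrand(s: float) -> float:
        return math.exp(-s * p.r1a) * math.exp(-(ti - s) * rate)

    val, _ = quad(integrand, lo, hi, epsabs=1e-12, epsrel=1e-12)
    return 2.0 * p.m0 * p.f * p.alpha / p.phi * val


def diffusion_attenuation(b, d):
    """Mono-exponential diffusion attenuation exp(-b d).

    ``b`` in s/mm^2, ``d`` in mm^2/s. The apparent (pseudo-)diffusion
    coefficient of an ASL signal is elevated by intravascular flowing spins
    (the IVIM effect), which is why a CSF-like D_app of the ventricular ASL
    signal indicates the label has left the vasculature.
    """
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(b < 0) or np.any(d < 0):
        raise ValueError("b and d must be non-negative")
    out = np.exp(-b * d)
    return out if out.ndim else float(out)
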