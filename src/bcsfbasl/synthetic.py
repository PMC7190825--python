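"""Digital phantoms and simulated acquisitions.

Emulates the single-slice 32x32 mouse protocol (FOV 20x20 mm, 2.4 mm slice):
a cortical band of tissue and two caudal ventricle blobs whose CSF content is
expressed as per-voxel partial-volume fractions, so the low-resolution
functional ROI genuinely contains far more volume than CSF — the situation
the ventricle-volume M0 correction exists for.

Truth convention: ``f_bcsfb_true`` is stated in the reporting unit
(ml/100 ml/min) tied to the fixed functional-ROI volume (12 voxels,
11.25 mm^3). The simulator converts it to the native per-unit-CSF delivery
rate f_csf = (f_true/100 * V_roi) / (60 * V_vent) s^-1, which is what the
kinetic model sees; the analysis pipeline's M0 correction folds the
V_roi/V_vent ratio back out, so the recovered value equals ``f_bcsfb_true``
regardless of ventricle size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .quantification import AslSeries, RoiSpec
from .signal_models import (
    IrParams,
    KineticParams,
    RelaxationSet,
    bcsfb_delta_m,
    buxton_params,
    diffusion_attenuation,
    inversion_recovery_signal,
    t2_attenuation,
)

__all__ = ["PhantomSpec", "Protocol", "Phantom", "CohortSpec",
           "make_phantom", "simulate_acquisition", "simulate_subject",
           "simulate_cohort", "apply_intervention"]

GRID = (32, 32)
VOXEL_DIMS = (0.625, 0.625, 2.4)        # mm; FOV 20x20 mm / 32, 2.4 mm slice
TI_LIST = (0.2, 0.75, 1.5, 2.75, 4.0, 6.5)   # s


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of one synthetic subject.

    Flow truths use the reporting conventions (ml/100 ml/min for delivery to
    CSF relative to the functional-ROI volume; ml/100 g/min for cortical
    perfusion). Diffusion coefficients (mm^2/s) are free water for CSF, a
    parenchymal ADC for tissue, and an IVIM-elevated pseudo-diffusion
    coefficient for the vascular fraction of the short-TE ASL signal.
    """

    f_bcsfb_true: float = 24.0          # ml/100 ml/min
    cbf_true: float = 251.0             # ml/100 g/min
    ventricle_volume: float = 3.75      # mm^3
    relaxation: RelaxationSet = field(default_factory=RelaxationSet)
    delta_csf: float = 1.0              # s, CSF transit time
    tau_csf: float = 4.0                # s, labelled bolus width
    delta_cortex: float = 0.3           # s
    tau_cortex: float = 4.0             # s
    m0_csf_density: float = 100.0       # signal units per mm^3
    m0_tissue_density: float = 80.0
    ventricle_tissue_fraction: float = 0.0   # tissue fraction in ROI voxels
    d_csf: float = 3.0e-3               # mm^2/s
    d_tissue: float = 0.8e-3
    d_pseudo: float = 1.0e-2
    grid: tuple[int, int] = GRID
    voxel_dims: tuple[float, float, float] = VOXEL_DIMS

    def __post_init__(self) -> None:
        if self.f_bcsfb_true < 0 or self.cbf_true < 0:
            raise ValueError("flow truths must be non-negative")
        if self.ventricle_volume < 0:
            raise ValueError("ventricle_volume must be non-negative")
        if not 0 <= self.ventricle_tissue_fraction <= 1:
            raise ValueError("ventricle_tissue_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class Protocol:
    """Acquisition protocol for one series."""

    ti_list: tuple = TI_LIST
    te: float = 0.020                   # s
    repetitions: int = 5
    alpha: float = 1.0                  # labelling efficiency
    noise_sd: float = 0.2               # signal units per voxel per rep
    b_value: float = 0.0                # s/mm^2 motion-probing gradient
    labelling_width_mm: float = 19.2    # FAIR slice-selective width
    noise_model: str = "gaussian"       # or "rician"

    @classmethod
    def standard_asl(cls, **kw) -> "Protocol":
        """Short-TE conventional perfusion protocol (TE 20 ms, 5 reps)."""
        return cls(**{"te": 0.020, "repetitions": 5, **kw})

    @classmethod
    def bcsfb_asl(cls, **kw) -> "Protocol":
        """Ultra-long-TE CSF-isolating protocol (TE 220 ms, 20 reps)."""
        return cls(**{"te": 0.220, "repetitions": 20, **kw})


@dataclass
class Phantom:
    """Realised phantom: fraction maps, ROI masks and native-rate truths."""

    spec: PhantomSpec
    csf_frac: np.ndarray
    cortex_frac: np.ndarray
    roi_ventricles: np.ndarray          # boolean mask, the functional ROI
    roi_cortex: np.ndarray

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spec.voxel_dims))

    @property
    def functional_roi_volume(self) -> float:
        """mm^3 of the fixed 12-voxel functional ROI."""
        return float(self.roi_ventricles.sum()) * self.voxel_volume

    @property
    def f_csf_native(self) -> float:
        """Per-unit-CSF-volume delivery rate, s^-1."""
        if self.spec.ventricle_volume == 0:
            return 0.0
        total_ul_min = (self.spec.f_bcsfb_true / 100.0
                        * self.functional_roi_volume)
        return total_ul_min / (60.0 * self.spec.ventricle_volume)

    @property
    def k_cortex(self) -> float:
        """Tissue-normalised cortical delivery rate k = f/lambda, s^-1."""
        return self.spec.cbf_true / (
            self.spec.relaxation.lambda_tissue * 6000.0)

    def roi_spec_ventricles(self) -> RoiSpec:
        return RoiSpec(mask=self.roi_ventricles,
                       voxel_volume=self.voxel_volume,
                       ventricle_volume=self.spec.ventricle_volume)

    def roi_spec_cortex(self) -> RoiSpec:
        return RoiSpec(mask=self.roi_cortex, voxel_volume=self.voxel_volume)


def make_phantom(spec: PhantomSpec, seed: int = 0) -> Phantom:
    """Build the slice geometry: cortical band + two caudal ventricle blobs.

    The two 3x2 ventricle blobs (12 voxels) define the functional ROI; their
    CSF fractions are uniform and integrate to ``ventricle_volume`` exactly
    (to well within half a voxel). Deterministic given (spec, seed).
    """
    nx, ny = spec.grid
    voxel_volume = float(np.prod(spec.voxel_dims))
    csf = np.zeros((nx, ny))
    cortex = np.zeros((nx, ny))
    roi_vent = np.zeros((nx, ny), dtype=bool)

    # cortical band, rostral part of the slice
    cortex[5:11, 6:26] = 1.0
    roi_ctx = np.zeros((nx, ny), dtype=bool)
    roi_ctx[6:9, 10:22] = True

    # two 3x2 ventricle blobs, caudal
    roi_vent[18:21, 12:14] = True
    roi_vent[18:21, 18:20] = True
    n_roi = int(roi_vent.sum())
    frac = spec.ventricle_volume / (n_roi * voxel_volume)
    if frac > 1.0 - spec.ventricle_tissue_fraction + 1e-12:
        raise ValueError(
            f"ventricle_volume {spec.ventricle_volume} mm^3 exceeds the "
            f"capacity of the {n_roi}-voxel functional ROI "
            f"({n_roi * voxel_volume:.2f} mm^3)")
    csf[roi_vent] = frac
    cortex[roi_vent] = spec.ventricle_tissue_fraction

    return Phantom(spec=spec, csf_frac=csf, cortex_frac=cortex,
                   roi_ventricles=roi_vent, roi_cortex=roi_ctx)


def _compartment_signals(phantom: Phantom, ti: np.ndarray, te: float,
                         alpha: float, b_value: float):
    """Noiseless (control, delta-M) maps per TI, shape (n_ti, nx, ny)."""
    spec = phantom.spec
    rel = spec.relaxation
    vv = phantom.voxel_volume

    m0_csf = phantom.csf_frac * vv * spec.m0_csf_density
    m0_tis = phantom.cortex_frac * vv * spec.m0_tissue_density

    e2_csf = t2_attenuation(te, rel.t2_csf)
    e2_tis = t2_attenuation(te, rel.t2_tissue)

    ir_csf = inversion_recovery_signal(ti, IrParams(m0=1.0, t1=rel.t1_csf))
    ir_tis = inversion_recovery_signal(ti, IrParams(m0=1.0, t1=rel.t1_tissue))

    # delta-M per unit equilibrium magnetisation of each compartment
    if phantom.f_csf_native > 0 and alpha > 0:
        p_csf = KineticParams(f=phantom.f_csf_native, delta=spec.delta_csf,
                              tau=spec.tau_csf, alpha=alpha, phi=rel.phi_csf,
                              r1app=1.0 / rel.t1_csf, r1a=rel.r1a, m0=1.0)
        dm_csf = bcsfb_delta_m(ti, p_csf)
    else:
        dm_csf = np.zeros_like(ti)
    if phantom.k_cortex > 0 and alpha > 0:
        p_tis = buxton_params(phantom.k_cortex, spec.delta_cortex,
                              spec.tau_cortex, alpha, rel)
        dm_tis = bcsfb_delta_m(ti, p_tis)
    else:
        dm_tis = np.zeros_like(ti)

    # diffusion weighting: CSF control and CSF-borne label share the free-
    # water coefficient; the tissue label keeps a vascular (IVIM) component
    # at short TE, hence the elevated pseudo-diffusion coefficient
    a_csf = diffusion_attenuation(b_value, spec.d_csf)
    a_tis = diffusion_attenuation(b_value, spec.d_tissue)
    a_dm_tis = diffusion_attenuation(b_value, spec.d_pseudo)

    ctrl = (ir_csf[:, None, None] * m0_csf[None] * e2_csf * a_csf
            + ir_tis[:, None, None] * m0_tis[None] * e2_tis * a_tis)
    dm = (dm_csf[:, None, None] * m0_csf[None] * e2_csf * a_csf
          + dm_tis[:, None, None] * m0_tis[None] * e2_tis * a_dm_tis)
    return ctrl, dm


def simulate_acquisition(phantom: Phantom, protocol: Protocol,
                         seed: int = 0) -> AslSeries:
    """Forward-simulate one multi-TI control/label series.

    Per voxel: control = inversion recovery of the compartment
    magnetisations x T2 attenuation at the protocol TE; label = control -
    compartment-weighted delta-M. Independent noise is added to every
    control and label repetition (Gaussian by default; Rician on request).
    """
    rng = np.random.default_rng(seed)
    ti = np.asarray(protocol.ti_list, dtype=float)
    ctrl0, dm0 = _compartment_signals(phantom, ti, protocol.te,
                                      protocol.alpha, protocol.b_value)
    lab0 = ctrl0 - dm0
    shape = (ti.size, protocol.repetitions) + ctrl0.shape[1:]
    controls = np.broadcast_to(ctrl0[:, None], shape).copy()
    labels = np.broadcast_to(lab0[:, None], shape).copy()
    if protocol.noise_sd > 0:
        if protocol.noise_model == "gaussian":
            controls += rng.normal(0.0, protocol.noise_sd, shape)
            labels += rng.normal(0.0, protocol.noise_sd, shape)
        elif protocol.noise_model == "rician":
            for arr in (controls, labels):
                re = arr + rng.normal(0.0, protocol.noise_sd, shape)
                im = rng.normal(0.0, protocol.noise_sd, shape)
                arr[...] = np.hypot(re, im)
        else:
            raise ValueError(f"unknown noise model {protocol.noise_model!r}")
    return AslSeries(ti_list=ti, controls=controls, labels=labels,
                     te=protocol.te, voxel_dims=phantom.spec.voxel_dims,
                     scheme={"labelling": "FAIR",
                             "labelling_width_mm": protocol.labelling_width_mm,
                             "alpha": protocol.alpha,
                             "b_value": protocol.b_value})


def simulate_subject(phantom: Phantom, seed: int = 0,
                     noise_sd: float = 0.2, alpha: float = 1.0
                     ) -> tuple[AslSeries, AslSeries]:
    """Convenience: the paper protocol's (short-TE, long-TE) series pair."""
    ss = np.random.SeedSequence(seed).spawn(2)
    s_std = simulate_acquisition(
        phantom, Protocol.standard_asl(noise_sd=noise_sd, alpha=alpha),
        seed=ss[0].generate_state(1)[0] % (2**31))
    s_csf = simulate_acquisition(
        phantom, Protocol.bcsfb_asl(noise_sd=noise_sd, alpha=alpha),
        seed=ss[1].generate_state(1)[0] % (2**31))
    return s_std, s_csf


def apply_intervention(phantom: Phantom, cp_factor: float,
                       cortex_factor: float) -> Phantom:
    """Scale the true CP delivery and cortical perfusion (e.g. vasopressin:
    cp_factor ~ 0.37, cortex_factor ~ 1)."""
    if cp_factor < 0 or cortex_factor < 0:
        raise ValueError("factors must be non-negative")
    spec = replace(phantom.spec,
                   f_bcsfb_true=phantom.spec.f_bcsfb_true * cp_factor,
                   cbf_true=phantom.spec.cbf_true * cortex_factor)
    return replace(phantom, spec=spec)


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a group of subjects.

    Between-subject SDs default to printed-SEM x sqrt(n) scale for n = 12;
    the flow-volume slope induces the delivery/ventricle-volume correlation,
    with the residual SD chosen so the marginal f SD equals ``f_sd``.
    """

    n: int = 12
    f_mean: float = 20.0                # ml/100 ml/min
    f_sd: float = 3.5
    cbf_mean: float = 251.0             # ml/100 g/min
    cbf_sd: float = 24.0
    vent_mean: float = 3.5              # mm^3
    vent_sd: float = 0.75
    flow_volume_slope: float = 0.0      # (ml/100 ml/min) per mm^3
    within_sd: float = 1.15             # scan-rescan SD, ml/100 ml/min
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        for name in ("f_sd", "cbf_sd", "vent_sd", "within_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def adult(cls, **kw) -> "CohortSpec":
        return cls(**{"f_mean": 20.0, "cbf_mean": 251.0, **kw})

    @classmethod
    def aged(cls, **kw) -> "CohortSpec":
        return cls(**{"f_mean": 13.0, "cbf_mean": 218.0, **kw})


def draw_cohort_truths(cohort: CohortSpec) -> pd.DataFrame:
    """Subject-level true parameters for one cohort (no images)."""
    rng = np.random.default_rng(cohort.seed)
    vol = rng.normal(cohort.vent_mean, cohort.vent_sd, cohort.n)
    vol = np.clip(vol, 1.0, 10.0)
    resid_var = cohort.f_sd**2 - (cohort.flow_volume_slope
                                  * cohort.vent_sd)**2
    resid_sd = np.sqrt(max(resid_var, 0.0))
    f = (cohort.f_mean
         + cohort.flow_volume_slope * (vol - cohort.vent_mean)
         + rng.normal(0.0, resid_sd, cohort.n))
    f = np.clip(f, 0.1, None)
    cbf = np.clip(rng.normal(cohort.cbf_mean, cohort.cbf_sd, cohort.n),
                  10.0, None)
    return pd.DataFrame({"subject": np.arange(cohort.n),
                         "f_bcsfb_true": f, "cbf_true": cbf,
                         "ventricle_volume": vol})


def simulate_cohort(cohort: CohortSpec, base_spec: PhantomSpec | None = None,
                    generate_images: bool = True):
    """Draw a cohort and (optionally) forward-simulate every subject.

    Returns ``(subjects, truths)`` where ``truths`` is a DataFrame of the
    drawn per-subject parameters and ``subjects`` is a list of
    ``(phantom, series_standard, series_bcsfb)`` triples (empty when
    ``generate_images`` is False). Deterministic given the spec.
    """
    base_spec = base_spec or PhantomSpec()
    truths = draw_cohort_truths(cohort)
    subjects = []
    if generate_images:
        child_seeds = np.random.SeedSequence(cohort.seed).spawn(cohort.n)
        for i, row in truths.iterrows():
            spec = replace(base_spec,
                           f_bcsfb_true=float(row.f_bcsfb_true),
                           cbf_true=float(row.cbf_true),
                           ventricle_volume=float(row.ventricle_volume))
            phantom = make_phantom(spec)
            seed_i = int(child_seeds[i].generate_state(1)[0] % (2**31))
            s_std, s_csf = simulate_subject(phantom, seed=seed_i,
                                            noise_sd=cohort.noise_sd)
            subjects.append((phantom, s_std, s_csf))
    return subjects, truths
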