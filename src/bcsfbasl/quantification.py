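"""ROI-level quantification pipeline and cohort statistics.

The pipeline turns paired control/label image series at two echo times into
physiological quantities:

* TE = 20 ms series, cortical ROI  -> inversion-recovery fit of the control
  signal (M0, T1 of tissue), then the pulsed-ASL general kinetic model on
  dM/M0 -> cortical blood flow (ml/100 g/min).
* TE = 220 ms series, ventricular ROI -> inversion-recovery fit of the
  long-TE control signal (M0 of CSF, T1 of CSF), partial-volume correction
  of M0 by (functional ROI volume / ventricle volume), then the
  extra-vascular delivery model on dM/M0corr -> rate of blood-water delivery
  across the blood-CSF barrier (ml/100 ml/min).

The M0 correction is what makes the delivery estimate independent of
ventricle size: the low-resolution functional ROI contains far more volume
than CSF, so the uncorrected equilibrium signal scales with ventricle size
while the delivered label does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimation import (
    PER_SECOND_TO_ML100ML_MIN,
    FitResult,
    fit_bcsfb,
    fit_buxton,
    fit_inversion_recovery,
)
from .signal_models import RelaxationSet

__all__ = [
    "AslSeries", "RoiSpec", "SubjectQuant",
    "pairwise_subtract", "roi_sum", "m0_correction",
    "flow_to_reporting_units", "total_delivery_rate", "cp_blood_flow",
    "percent_change", "cohort_compare", "correlate", "scan_rescan_error",
    "quantify_subject",
]


@dataclass
class AslSeries:
    """Multi-TI control/label acquisition.

    controls, labels : float arrays of shape (n_ti, n_rep, nx, ny[, nz])
    ti_list          : inversion times, seconds, strictly increasing
    te               : echo time, seconds
    voxel_dims       : voxel edge lengths, mm
    scheme           : labelling-geometry metadata (e.g. slice-selective
                       inversion width in mm for FAIR)
    """

    ti_list: np.ndarray
    controls: np.ndarray
    labels: np.ndarray
    te: float
    voxel_dims: tuple[float, float, float] = (0.625, 0.625, 2.4)
    scheme: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ti_list = np.asarray(self.ti_list, dtype=float)
        self.controls = np.asarray(self.controls, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.controls.shape != self.labels.shape:
            raise ValueError("controls and labels must have the same shape")
        if self.controls.shape[0] != self.ti_list.size:
            raise ValueError("first axis must index TI")
        if np.any(np.diff(self.ti_list) <= 0):
            raise ValueError("ti_list must be strictly increasing")
        if self.te <= 0:
            raise ValueError("te must be positive")

    @property
    def n_repetitions(self) -> int:
        return self.controls.shape[1]

    @property
    def voxel_volume(self) -> float:
        """mm^3 per voxel."""
        return float(np.prod(self.voxel_dims))


@dataclass
class RoiSpec:
    """Region of interest plus the volumes needed for the M0 correction."""

    mask: np.ndarray
    voxel_volume: float
    ventricle_volume: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def roi_volume(self) -> float:
        """mm^3 covered by the mask (mask count x voxel volume)."""
        return float(self.mask.sum()) * self.voxel_volume


@dataclass
class SubjectQuant:
    """Per-subject physiological quantities."""

    f_bcsfb: float                 # ml/100 ml (of CSF)/min
    cbf_cortex: float              # ml/100 g/min
    t1_csf: float                  # s
    t1_tissue: float               # s
    ventricle_volume: float        # mm^3
    total_delivery: float          # ul/min, over the functional ROI
    cp_blood_flow: float | None = None   # ml/100 g (of CP)/min
    fits: dict = field(default_factory=dict, repr=False)


def pairwise_subtract(series: AslSeries, order: str = "control-label"
                      ) -> np.ndarray:
    """Mean pairwise difference image per TI.

    Control and label repetitions are subtracted pairwise and averaged per
    TI; the default sign convention yields positive dM for delivered label.
    """
    if series.controls.shape != series.labels.shape:
        raise ValueError("mismatched control/label shapes")
    diff = series.controls - series.labels
    if order == "label-control":
        diff = -diff
    elif order != "control-label":
        raise ValueError(f"unknown subtraction order {order!r}")
    return diff.mean(axis=1)


def roi_sum(image: np.ndarray, roi: RoiSpec) -> float:
    """Sum of voxel values under the ROI mask."""
    image = np.asarray(image, dtype=float)
    if image.shape != roi.mask.shape:
        raise ValueError("image and ROI mask shapes differ")
    return float(image[roi.mask].sum())


def m0_correction(m0_fit: float, roi: RoiSpec) -> float:
    """Partial-volume correction of the ventricular equilibrium signal.

    Multiplies the fitted M0 by (functional ROI volume / ventricle volume),
    removing the dependence of the normalisation factor on ventricle size.
    """
    if roi.ventricle_volume is None or roi.ventricle_volume <= 0:
        raise ValueError("ventricle_volume must be positive for the "
                         "M0 correction")
    return m0_fit * roi.roi_volume / roi.ventricle_volume


def flow_to_reporting_units(f: float) -> float:
    """s^-1 -> ml/100 ml/min (x 6000)."""
    if f < 0:
        raise ValueError("f must be non-negative")
    return f * PER_SECOND_TO_ML100ML_MIN


def total_delivery_rate(f_ml100ml_min: float, roi_volume_mm3: float) -> float:
    """Total labelled-water delivery over the functional ROI, ul/min.

    (f / 100) x ROI volume, using mm^3 == ul. At the adult mean of
    24 ml/100 ml/min over the 11.25 mm^3 functional ROI this is 2.7 ul/min.
    """
    if f_ml100ml_min < 0 or roi_volume_mm3 < 0:
        raise ValueError("inputs must be non-negative")
    return f_ml100ml_min / 100.0 * roi_volume_mm3


def cp_blood_flow(total_ul_min: float, cp_mass_mg: float,
                  extraction: float = 1.0) -> float:
    """Choroid-plexus blood flow, ml/100 g/min, from the total delivery rate.

    Assumes the supplied extraction fraction (default 100%: every labelled
    blood-water molecule traversing the CP crosses into CSF), so blood flow =
    delivery / extraction, normalised per 100 g of CP tissue
    (ul/(min*mg) == ml/(min*g)).
    """
    if cp_mass_mg <= 0:
        raise ValueError("cp_mass must be positive")
    if not 0 < extraction <= 1:
        raise ValueError("extraction must lie in (0, 1]")
    return total_ul_min / extraction / cp_mass_mg * 100.0


def percent_change(baseline: float, post: float) -> float:
    """100 x (post - baseline) / baseline."""
    if baseline == 0:
        raise ValueError("baseline must be non-zero")
    return 100.0 * (post - baseline) / baseline


def cohort_compare(group_a, group_b, tail: str = "one",
                   welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test between cohorts.

    Returns (t, p). Pooled-variance by default (``welch=True`` for unequal
    variances); one-tailed by default, testing group_a > group_b.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p_two = stats.ttest_ind(a, b, equal_var=not welch)
    t = float(t)
    p_two = float(p_two)
    if tail == "two":
        return t, p_two
    if tail != "one":
        raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")
    # one-tailed, H1: mean(a) > mean(b)
    p = p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0
    return t, float(p)


def correlate(f_values, volumes) -> tuple[float, float]:
    """Pearson correlation between delivery rates and ventricle volumes.

    Returns (r, two-sided p).
    """
    x = np.asarray(f_values, dtype=float)
    y = np.asarray(volumes, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def scan_rescan_error(pairs) -> float:
    """Mean absolute difference between baseline and repeat measurements."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("pairs must be an (n, 2) array of "
                         "(baseline, repeat)")
    return float(np.mean(np.abs(arr[:, 1] - arr[:, 0])))


def _roi_series(series: AslSeries, roi: RoiSpec, order: str):
    """ROI-summed control signal and difference signal per TI."""
    dm_images = pairwise_subtract(series, order=order)
    ctrl_images = series.controls.mean(axis=1)
    ctrl = np.array([roi_sum(img, roi) for img in ctrl_images])
    dm = np.array([roi_sum(img, roi) for img in dm_images])
    return ctrl, dm


def quantify_subject(series_cortex: AslSeries, series_csf: AslSeries,
                     roi_cortex: RoiSpec, roi_ventricles: RoiSpec,
                     rel: RelaxationSet | None = None,
                     alpha: float = 1.0,
                     cp_mass_mg: float | None = None,
                     extraction: float = 1.0,
                     subtraction_order: str = "control-label",
                     fix_tau: float | None = None,
                     fix_beta: float | None = None) -> SubjectQuant:
    """Full single-subject pipeline.

    ``series_cortex`` is the short-TE acquisition (conventional perfusion),
    ``series_csf`` the ultra-long-TE acquisition that isolates ventricular
    CSF. Stages: pairwise subtraction -> ROI aggregation -> inversion-
    recovery fits of the control signals (M0, T1 per compartment) ->
    ventricle-volume M0 correction -> kinetic-model fits -> unit conversion.
    """
    rel = rel or RelaxationSet()

    # --- cortical (blood-brain barrier) branch, TE = 20 ms -----------------
    try:
        ctrl_ctx, dm_ctx = _roi_series(series_cortex, roi_cortex,
                                       subtraction_order)
        ir_ctx = fit_inversion_recovery(series_cortex.ti_list, ctrl_ctx,
                                        fix_beta=fix_beta)
        buxton = fit_buxton(
            series_cortex.ti_list, dm_ctx / ir_ctx["m0"],
            fixed={"alpha": alpha, "lambda_tissue": rel.lambda_tissue,
                   "t1_tissue": ir_ctx["t1"], "r1a": rel.r1a},
            fix_tau=fix_tau)
    except ValueError as exc:
        raise ValueError(f"cortical ASL stage: {exc}") from exc

    # --- ventricular (blood-CSF barrier) branch, TE = 220 ms ---------------
    try:
        ctrl_csf, dm_csf = _roi_series(series_csf, roi_ventricles,
                                       subtraction_order)
        ir_csf = fit_inversion_recovery(series_csf.ti_list, ctrl_csf,
                                        fix_beta=fix_beta)
        m0corr = m0_correction(ir_csf["m0"], roi_ventricles)
        bcsfb = fit_bcsfb(
            series_csf.ti_list, dm_csf / m0corr,
            fixed={"alpha": alpha, "phi": rel.phi_csf, "r1a": rel.r1a,
                   "r1app": 1.0 / ir_csf["t1"]},
            fix_tau=fix_tau)
    except ValueError as exc:
        raise ValueError(f"ventricular BCSFB-ASL stage: {exc}") from exc

    f_report = bcsfb.extras["f_ml100ml_min"]
    total = total_delivery_rate(f_report, roi_ventricles.roi_volume)
    cp_flow = (cp_blood_flow(total, cp_mass_mg, extraction)
               if cp_mass_mg is not None else None)

    return SubjectQuant(
        f_bcsfb=f_report,
        cbf_cortex=buxton.extras["cbf_ml100g_min"],
        t1_csf=ir_csf["t1"],
        t1_tissue=ir_ctx["t1"],
        ventricle_volume=float(roi_ventricles.ventricle_volume or np.nan),
        total_delivery=total,
        cp_blood_flow=cp_flow,
        fits={"ir_cortex": ir_ctx, "ir_csf": ir_csf,
              "buxton": buxton, "bcsfb": bcsfb},
    )
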