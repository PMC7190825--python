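"""File formats and run configuration.

On-disk layout for an acquisition: one NIfTI-1 volume per inversion time,
shape (nx, ny, nz, 2, n_repetitions) with axis 3 = (control, label), plus a
versioned JSON sidecar holding the protocol metadata. Field names mirror
BIDS-ASL where an equivalent exists (EchoTime, InversionTime — the
post-labelling delay of a FAIR acquisition). ROI masks are 0/1 NIfTI-1
volumes. Coordinates are 0-based voxel indices throughout; no world-space
resampling is performed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .quantification import AslSeries, RoiSpec
from .signal_models import RelaxationSet

__all__ = ["SIDECAR_VERSION", "RunConfig", "load_config",
           "write_asl_dataset", "read_asl_dataset",
           "read_roi_mask", "write_roi_mask"]

log = logging.getLogger("bcsfbasl")

SIDECAR_VERSION = "1.0"


@dataclass
class RunConfig:
    """Validated run configuration; defaults are the mouse 9.4 T protocol."""

    ti_list: tuple = (0.2, 0.75, 1.5, 2.75, 4.0, 6.5)   # s
    te_standard: float = 0.020          # s
    te_bcsfb: float = 0.220             # s
    repetitions_standard: int = 5
    repetitions_bcsfb: int = 20
    alpha: float = 1.0
    labelling_width_mm: float = 19.2
    noise_sd: float = 0.2
    relaxation: RelaxationSet = field(default_factory=RelaxationSet)
    fix_tau: float | None = None
    fix_beta: float | None = None
    magnitude_mode: bool = False
    subtraction_order: str = "control-label"
    exclude_2sd_outliers: bool = False
    extraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        ti = np.asarray(self.ti_list, dtype=float)
        if ti.size < 2 or np.any(np.diff(ti) <= 0):
            raise ValueError("ti_list must be >= 2 strictly increasing "
                             "inversion times")
        for name in ("te_standard", "te_bcsfb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("repetitions_standard", "repetitions_bcsfb"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.subtraction_order not in ("control-label", "label-control"):
            raise ValueError("subtraction_order must be 'control-label' "
                             "or 'label-control'")
        if not 0 < self.extraction <= 1:
            raise ValueError("extraction must lie in (0, 1]")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config; unknown keys are rejected by name."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path}: expected a mapping at top level")
    rel = raw.pop("relaxation", None)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config {path}: unknown fields {sorted(unknown)}")
    if "ti_list" in raw:
        raw["ti_list"] = tuple(raw["ti_list"])
    cfg = RunConfig(**raw)
    if rel is not None:
        cfg.relaxation = RelaxationSet(**rel)
    return cfg


def _nifti(data: np.ndarray, voxel_dims) -> nib.Nifti1Image:
    affine = np.diag(list(voxel_dims[:3]) + [1.0])
    return nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)


def write_asl_dataset(series: AslSeries, out_dir: str | Path,
                      prefix: str = "asl") -> Path:
    """Write one NIfTI per TI plus the JSON sidecar; returns the sidecar
    path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    volumes = []
    for i, ti in enumerate(series.ti_list):
        # (nx, ny, nz, control|label, rep)
        ctrl = series.controls[i]
        lab = series.labels[i]
        spatial = ctrl.shape[1:]
        nz = 1 if len(spatial) == 2 else spatial[2]
        nx, ny = spatial[0], spatial[1]
        stack = np.stack([ctrl, lab], axis=0)  # (2, rep, nx, ny)
        data = np.moveaxis(stack, (0, 1), (-2, -1)).reshape(
            nx, ny, nz, 2, series.n_repetitions)
        fname = f"{prefix}_ti{i:02d}.nii.gz"
        nib.save(_nifti(data, series.voxel_dims), out_dir / fname)
        volumes.append({"file": fname, "InversionTime": float(ti)})
    sidecar = {
        "SidecarVersion": SIDECAR_VERSION,
        "EchoTime": series.te,
        "Repetitions": series.n_repetitions,
        "VoxelDims": list(series.voxel_dims),
        "Scheme": series.scheme,
        "Volumes": volumes,
    }
    sidecar_path = out_dir / f"{prefix}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return sidecar_path


def read_asl_dataset(sidecar_path: str | Path) -> AslSeries:
    """Read a series back from its sidecar; volumes are re-ordered by
    their InversionTime regardless of listing order."""
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("EchoTime", "Volumes", "Repetitions"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path}: missing field {key!r}")
    vols = sorted(meta["Volumes"], key=lambda v: v["InversionTime"])
    ti_list, controls, labels = [], [], []
    shape = None
    for v in vols:
        if "file" not in v or "InversionTime" not in v:
            raise ValueError(f"sidecar {sidecar_path}: each volume entry "
                             "needs 'file' and 'InversionTime'")
        fpath = sidecar_path.parent / v["file"]
        if not fpath.exists():
            raise FileNotFoundError(
                f"volume listed in sidecar is missing: {fpath}")
        data = np.asarray(nib.load(fpath).dataobj, dtype=float)
        if data.ndim != 5 or data.shape[3] != 2:
            raise ValueError(f"{fpath}: expected (nx, ny, nz, 2, reps) "
                             f"layout, got shape {data.shape}")
        if shape is None:
            shape = data.shape
        elif data.shape != shape:
            raise ValueError(f"{fpath}: shape {data.shape} differs from "
                             f"first volume {shape}")
        nx, ny, nz, _, reps = data.shape
        if reps != meta["Repetitions"]:
            raise ValueError(f"{fpath}: repetition count {reps} does not "
                             f"match sidecar ({meta['Repetitions']})")
        arr = np.moveaxis(data, (-2, -1), (0, 1))  # (2, rep, nx, ny, nz)
        if nz == 1:
            arr = arr[..., 0]
        controls.append(arr[0])
        labels.append(arr[1])
        ti_list.append(float(v["InversionTime"]))
    return AslSeries(ti_list=np.asarray(ti_list),
                     controls=np.asarray(controls),
                     labels=np.asarray(labels),
                     te=float(meta["EchoTime"]),
                     voxel_dims=tuple(meta.get("VoxelDims", (0.625, 0.625,
                                                             2.4))),
                     scheme=meta.get("Scheme", {}))


def write_roi_mask(mask: np.ndarray, voxel_dims, path: str | Path) -> None:
    data = np.asarray(mask, dtype=np.uint8)
    if data.ndim == 2:
        data = data[..., None]
    nib.save(nib.Nifti1Image(data, np.diag(list(voxel_dims[:3]) + [1.0])),
             str(path))


def read_roi_mask(path: str | Path, voxel_volume: float,
                  ventricle_volume: float | None = None) -> RoiSpec:
    data = np.asarray(nib.load(str(path)).dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[..., 0]
    return RoiSpec(mask=data > 0, voxel_volume=voxel_volume,
                   ventricle_volume=ventricle_volume)
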