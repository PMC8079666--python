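"""File I/O: NIfTI image stacks and maps, CSV tables.

Complex echo stacks are written as magnitude/phase NIfTI pairs (phase in
radians, wrapped to (-pi, pi]) with echoes along the third axis; masks as
integer NIfTI; ROI curves, fit results and study tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fdm import FdmMaps
from .preprocess import CombinedStack
from .signal_model import EchoSchedule, RoiCurves
from .synthetic_mgre import SliceStack

__all__ = [
    "save_slice_stack",
    "load_slice_stack",
    "save_combined_stack",
    "load_combined_stack",
    "save_fdm_maps",
    "load_fdm_maps",
    "roi_curves_to_frame",
    "roi_curves_from_frame",
]


def _affine(pixel_mm: float, slice_mm: float = 5.0) -> np.ndarray:
    return np.diag([pixel_mm, pixel_mm, slice_mm, 1.0])


def _save_nifti(path: Path, array: np.ndarray, pixel_mm: float) -> None:
    # echoes (first axis, if 3-D) become the NIfTI third axis
    if array.ndim == 3:
        array = np.moveaxis(array, 0, -1)
    nib.save(nib.Nifti1Image(np.asarray(array), _affine(pixel_mm)), str(path))


def _load_nifti(path: Path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj)
    if arr.ndim == 3:
        arr = np.moveaxis(arr, -1, 0)
    return arr


def _wrap(phase: np.ndarray) -> np.ndarray:
    return np.pi - np.mod(np.pi - phase, 2.0 * np.pi)


def _save_complex(stem: Path, data: np.ndarray, pixel_mm: float) -> None:
    _save_nifti(stem.with_name(stem.name + "_mag.nii"), np.abs(data), pixel_mm)
    _save_nifti(
        stem.with_name(stem.name + "_phase.nii"), _wrap(np.angle(data)), pixel_mm
    )


def _load_complex(stem: Path) -> np.ndarray:
    mag = _load_nifti(stem.with_name(stem.name + "_mag.nii"))
    phase = _load_nifti(stem.with_name(stem.name + "_phase.nii"))
    return mag * np.exp(1j * phase)


def _schedule_record(schedule: EchoSchedule) -> dict:
    return {
        "te1": schedule.te1,
        "delta_te": schedule.delta_te,
        "n_echoes": schedule.n_echoes,
    }


def _schedule_from_record(rec: dict) -> EchoSchedule:
    return EchoSchedule(rec["te1"], rec["delta_te"], rec["n_echoes"])


def save_slice_stack(directory, stack: SliceStack) -> None:
    """Write a raw stack: one magnitude/phase NIfTI pair per channel x polarity."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_pol, n_ch = stack.data.shape[:2]
    for p in range(n_pol):
        for c in range(n_ch):
            _save_complex(
                directory / f"echo_pol{p}_ch{c:02d}", stack.data[p, c], stack.pixel_mm
            )
    _save_nifti(directory / "cc_mask.nii", stack.cc_mask.astype(np.int16), stack.pixel_mm)
    _save_nifti(directory / "labels.nii", stack.labels.astype(np.int16), stack.pixel_mm)
    meta = {
        "schedule": _schedule_record(stack.schedule),
        "n_polarities": n_pol,
        "n_channels": n_ch,
        "pixel_mm": stack.pixel_mm,
    }
    (directory / "stack.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_slice_stack(directory) -> SliceStack:
    """Read a raw stack written by :func:`save_slice_stack` (ground truth is not
    serialized; the loaded stack carries an empty truth record)."""
    directory = Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    schedule = _schedule_from_record(meta["schedule"])
    n_pol, n_ch = meta["n_polarities"], meta["n_channels"]
    data = None
    for p in range(n_pol):
        for c in range(n_ch):
            img = _load_complex(directory / f"echo_pol{p}_ch{c:02d}")
            if data is None:
                data = np.empty((n_pol, n_ch) + img.shape, dtype=complex)
            data[p, c] = img
    cc_mask = _load_nifti(directory / "cc_mask.nii").astype(bool)
    labels = _load_nifti(directory / "labels.nii").astype(int)
    return SliceStack(
        data=data,
        schedule=schedule,
        cc_mask=cc_mask,
        labels=labels,
        truth={},
        pixel_mm=meta["pixel_mm"],
    )


def save_combined_stack(directory, stack: CombinedStack, pixel_mm: float = 1.0) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _save_complex(directory / "combined", stack.data, pixel_mm)
    if stack.mask is not None:
        _save_nifti(directory / "mask.nii", stack.mask.astype(np.int16), pixel_mm)
    (directory / "combined.json").write_text(
        json.dumps({"schedule": _schedule_record(stack.schedule)}, sort_keys=True)
    )


def load_combined_stack(directory) -> CombinedStack:
    directory = Path(directory)
    meta = json.loads((directory / "combined.json").read_text())
    data = _load_complex(directory / "combined")
    mask_path = directory / "mask.nii"
    mask = _load_nifti(mask_path).astype(bool) if mask_path.exists() else None
    return CombinedStack(
        data=data, schedule=_schedule_from_record(meta["schedule"]), mask=mask
    )


def save_fdm_maps(directory, maps: FdmMaps, pixel_mm: float = 1.0) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _save_nifti(directory / "fdm_hz.nii", maps.maps_hz, pixel_mm)
    _save_nifti(directory / "fdm_valid.nii", maps.valid_mask.astype(np.int16), pixel_mm)
    (directory / "fdm.json").write_text(
        json.dumps({"schedule": _schedule_record(maps.schedule)}, sort_keys=True)
    )


def load_fdm_maps(directory) -> FdmMaps:
    directory = Path(directory)
    meta = json.loads((directory / "fdm.json").read_text())
    return FdmMaps(
        schedule=_schedule_from_record(meta["schedule"]),
        maps_hz=_load_nifti(directory / "fdm_hz.nii"),
        valid_mask=_load_nifti(directory / "fdm_valid.nii").astype(bool),
    )


def roi_curves_to_frame(curves_by_segment: dict) -> pd.DataFrame:
    """Tidy frame of ROI curves keyed by segment id.

    Columns: echo_index (1-based), te_ms, magnitude_norm, fdm_hz, segment.
    """
    rows = []
    for segment, curves in sorted(curves_by_segment.items()):
        te = curves.schedule.te_ms
        for n in range(curves.schedule.n_echoes):
            rows.append(
                {
                    "echo_index": n + 1,
                    "te_ms": te[n],
                    "magnitude_norm": curves.magnitude[n],
                    "fdm_hz": curves.fdm_hz[n],
                    "segment": segment,
                }
            )
    return pd.DataFrame(rows)


def roi_curves_from_frame(frame: pd.DataFrame) -> dict:
    """Inverse of :func:`roi_curves_to_frame`."""
    out = {}
    for segment, seg in frame.groupby("segment"):
        seg = seg.sort_values("echo_index")
        te = seg["te_ms"].to_numpy()
        if te.size < 3:
            raise ValueError("need >= 3 echoes per segment")
        d_te = np.diff(te)
        schedule = EchoSchedule(float(te[0]), float(d_te.mean()), int(te.size))
        out[segment] = RoiCurves(
            schedule=schedule,
            magnitude=seg["magnitude_norm"].to_numpy(),
            fdm_hz=seg["fdm_hz"].to_numpy(),
        )
    return out
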