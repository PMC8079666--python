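"""Frequency difference mapping (FDM).

Phase of the mGRE signal mixes three contributions: a TE-independent offset
(RF/receive phase), a linear-in-TE term from the macroscopic B0 field, and
the microstructural, non-linear-in-TE evolution caused by sub-voxel
compartments with distinct frequency offsets.  FDM isolates the last one.

The operator used throughout the package:

1. temporally unwrap the per-pixel phase across echoes;
2. take the linear reference through the first two echoes,
   ``phi_lin(TE) = phi_1 + (phi_2 - phi_1) * (TE - TE_1) / (TE_2 - TE_1)``;
3. report ``FDM_n = (phi_n - phi_lin(TE_n)) / (2 pi (TE_n - TE_1))`` in Hz
   for echoes n >= 3, with the first two echoes identically zero.

Adding any static phase map or any linear-in-TE field to the input leaves
the output unchanged (both are absorbed by the linear reference), which is
exactly the invariance the pre-processing chain requires.  Residual
eddy-current structure is removed spatially by per-echo 2-D polynomial
detrending.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_model import TWO_PI, EchoSchedule

__all__ = ["FdmMaps", "temporal_unwrap", "fdm_curve", "compute_fdm", "detrend_poly2d"]


@dataclass(frozen=True)
class FdmMaps:
    """Per-echo frequency-difference maps (Hz) with a validity mask."""

    schedule: EchoSchedule
    maps_hz: np.ndarray = field(repr=False)  # (n_echoes, ny, nx)
    valid_mask: np.ndarray = field(repr=False)  # (ny, nx) bool

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps_hz, dtype=float)
        mask = np.asarray(self.valid_mask, dtype=bool)
        if maps.ndim != 3 or maps.shape[0] != self.schedule.n_echoes:
            raise ValueError("maps_hz must have shape (n_echoes, ny, nx)")
        if mask.shape != maps.shape[1:]:
            raise ValueError("valid_mask must match the image grid")
        if np.any(maps[:2][:, mask] != 0.0):
            raise ValueError("first two echoes must be exactly zero")
        if not np.all(np.isfinite(maps[:, mask])):
            raise ValueError("FDM values must be finite inside the mask")
        object.__setattr__(self, "maps_hz", maps)
        object.__setattr__(self, "valid_mask", mask)


def temporal_unwrap(phase: np.ndarray, axis: int = -1) -> np.ndarray:
    """Unwrap phase along the echo axis.

    Adds integer multiples of 2*pi so successive differences lie in
    (-pi, pi].  Purely temporal, per pixel; no spatial unwrapping.
    """
    phase = np.asarray(phase, dtype=float)
    if phase.shape[axis] < 3:
        raise ValueError("need at least 3 echoes to unwrap")
    return np.unwrap(phase, axis=axis)


def _fdm_from_phase(phase: np.ndarray, schedule: EchoSchedule) -> np.ndarray:
    """Core FDM operator on unwrapped phase with echoes on the last axis."""
    te = schedule.te_s
    phi1 = phase[..., 0]
    phi2 = phase[..., 1]
    slope = (phi2 - phi1) / (te[1] - te[0])
    phi_lin = phi1[..., None] + slope[..., None] * (te - te[0])
    out = np.zeros_like(phase)
    dt = te[2:] - te[0]
    out[..., 2:] = (phase[..., 2:] - phi_lin[..., 2:]) / (TWO_PI * dt)
    return out


def fdm_curve(values: np.ndarray, schedule: EchoSchedule) -> np.ndarray:
    """FDM series (Hz) of a single complex signal curve."""
    values = np.asarray(values, dtype=complex)
    if values.shape[-1] != schedule.n_echoes:
        raise ValueError("curve length must equal n_echoes")
    if schedule.n_echoes < 3:
        raise ValueError("need at least 3 echoes")
    phase = temporal_unwrap(np.angle(values), axis=-1)
    return _fdm_from_phase(phase, schedule)


def compute_fdm(stack, mask: np.ndarray | None = None) -> FdmMaps:
    """Frequency-difference maps from a combined complex echo stack.

    ``stack`` is a :class:`fdm3pool.preprocess.CombinedStack`.  ``mask``
    selects the pixels to process (default: the whole image, so the spatial
    detrend that follows sees the full field of view); pixels outside it
    are left at zero and marked invalid.
    """
    schedule = stack.schedule
    if schedule.n_echoes < 3:
        raise ValueError("need at least 3 echoes")
    data = stack.data  # (n_echoes, ny, nx)
    if mask is None:
        mask = np.ones(data.shape[1:], dtype=bool)
    mask = np.asarray(mask).astype(bool)
    phase = np.angle(data[:, mask])  # (n_echoes, n_pix)
    unwrapped = temporal_unwrap(phase.T, axis=-1)  # (n_pix, n_echoes)
    fdm_pix = _fdm_from_phase(unwrapped, schedule)
    maps = np.zeros_like(data, dtype=float)
    maps[:, mask] = fdm_pix.T
    return FdmMaps(schedule=schedule, maps_hz=maps, valid_mask=mask)


def _poly2d_design(ny: int, nx: int, mask: np.ndarray, degree: int) -> np.ndarray:
    """Monomial design matrix in centered/scaled pixel coordinates."""
    yy, xx = np.mgrid[0:ny, 0:nx]
    # center and scale to [-1, 1] for conditioning
    x = (xx[mask] - (nx - 1) / 2.0) / max((nx - 1) / 2.0, 1.0)
    y = (yy[mask] - (ny - 1) / 2.0) / max((ny - 1) / 2.0, 1.0)
    cols = [x**i * y**j for i in range(degree + 1) for j in range(degree + 1 - i)]
    return np.stack(cols, axis=1)


def detrend_poly2d(
    fdm_maps: FdmMaps, degree: int = 3, fit_mask: np.ndarray | None = None
) -> FdmMaps:
    """Subtract a per-echo least-squares 2-D polynomial of total degree <= ``degree``.

    The polynomial is fitted over ``fit_mask`` (default: all valid pixels)
    and subtracted over all valid pixels.  Passing a fit mask that excludes
    the structure of interest estimates the global eddy-current residual
    without letting the polynomial absorb local microstructural signal.
    The operation is a linear projection, so it is idempotent and
    annihilates any input that is itself a polynomial of the given degree.
    """
    mask = fdm_maps.valid_mask
    if fit_mask is None:
        fit_mask = mask
    fit_mask = np.asarray(fit_mask, dtype=bool) & mask
    n_coef = (degree + 1) * (degree + 2) // 2
    n_fit = int(fit_mask.sum())
    if n_fit < n_coef:
        raise ValueError(
            f"need >= {n_coef} fit pixels for a degree-{degree} fit, have {n_fit}"
        )
    ny, nx = mask.shape
    design_fit = _poly2d_design(ny, nx, fit_mask, degree)
    if np.linalg.matrix_rank(design_fit) < n_coef:
        raise ValueError("rank-deficient polynomial design (mask too degenerate)")
    # one pseudo-inverse serves every echo (same support)
    pinv = np.linalg.pinv(design_fit)
    design_all = _poly2d_design(ny, nx, mask, degree)
    out = fdm_maps.maps_hz.copy()
    coefs = out[:, fit_mask] @ pinv.T  # (n_echoes, n_coef)
    out[:, mask] = out[:, mask] - coefs @ design_all.T
    return FdmMaps(schedule=fdm_maps.schedule, maps_hz=out, valid_mask=mask)
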