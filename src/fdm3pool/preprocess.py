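"""Raw-stack pre-processing: polarity correction, coil combination, ROI extraction.

Raw bipolar mGRE data arrive per receive channel and per read-gradient
polarity.  The chain implemented here mirrors a standard complex-data
pipeline:

1. complex multiplication of opposite-polarity acquisitions to cancel the
   echo-parity phase alternation caused by eddy currents / readout timing;
2. image-based coil-sensitivity estimation and sensitivity-weighted
   combination;
3. splitting of the corpus-callosum mask into anterior / mid / posterior
   thirds and ROI averaging of magnitude and FDM data per segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .signal_model import EchoSchedule, RoiCurves

__all__ = [
    "EchoStack",
    "CombinedStack",
    "polarity_correct",
    "estimate_sensitivities",
    "coil_combine",
    "split_cc_three",
    "roi_average",
]


@dataclass(frozen=True)
class EchoStack:
    """A per-echo complex image stack on one grid.

    ``data`` has shape ``(n_echoes, ny, nx)`` (single channel) or
    ``(n_channels, n_echoes, ny, nx)``.
    """

    data: np.ndarray = field(repr=False)
    schedule: EchoSchedule
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=complex)
        if data.ndim not in (3, 4):
            raise ValueError("data must be (n_echoes, ny, nx) or (n_ch, n_echoes, ny, nx)")
        echo_axis = 0 if data.ndim == 3 else 1
        if data.shape[echo_axis] != self.schedule.n_echoes:
            raise ValueError("echo axis length must equal schedule.n_echoes")
        object.__setattr__(self, "data", data)
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != data.shape[-2:]:
                raise ValueError("mask must match the image grid")
            object.__setattr__(self, "mask", mask)

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[-2:]


#: A polarity-corrected, coil-combined stack — same container, by convention
#: single-channel.
CombinedStack = EchoStack


def _wrap(phase: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - phase, 2.0 * np.pi)


def polarity_correct(stack_pos: EchoStack, stack_neg: EchoStack) -> CombinedStack:
    """Cancel polarity-odd phase by complex multiplication of the two polarities.

    Per pixel and echo, the combined phase is ``angle(S+ * S-) / 2`` and the
    combined magnitude ``sqrt(|S+| |S-|)``; any phase term with opposite sign
    in the two polarity groups cancels exactly.  The residual +/- pi
    half-angle ambiguity is resolved toward the phase of ``S+``.
    """
    if stack_pos.schedule != stack_neg.schedule:
        raise ValueError("polarity groups must share one echo schedule")
    if stack_pos.data.shape != stack_neg.data.shape:
        raise ValueError("polarity groups must share the image grid")
    prod = stack_pos.data * stack_neg.data
    half = np.angle(prod) / 2.0
    # pick the half-angle branch closest to the positive-polarity phase
    flip = np.abs(_wrap(np.angle(stack_pos.data) - half)) > np.pi / 2.0
    half = _wrap(half + np.where(flip, np.pi, 0.0))
    mag = np.sqrt(np.abs(stack_pos.data) * np.abs(stack_neg.data))
    return CombinedStack(
        data=mag * np.exp(1j * half),
        schedule=stack_pos.schedule,
        mask=stack_pos.mask,
    )


def estimate_sensitivities(
    first_echo_per_channel: np.ndarray,
    smooth_mm: float = 8.0,
    pixel_mm: float = 1.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Image-based coil-sensitivity estimates from the first-echo images.

    Each channel image is smoothed with a 2-D Gaussian (default 8 mm) and
    the set is normalized so the root-sum-of-squares magnitude is one —
    i.e. the smoothed first echo serves as the coil reference.  Returns an
    array of shape ``(n_channels, ny, nx)``.
    """
    imgs = np.asarray(first_echo_per_channel, dtype=complex)
    if imgs.ndim == 2:
        imgs = imgs[None]
    if imgs.ndim != 3:
        raise ValueError("expected (n_channels, ny, nx) first-echo images")
    if np.any(np.all(imgs == 0, axis=(1, 2))):
        raise ValueError("a channel is identically zero")
    sigma_px = smooth_mm / pixel_mm
    smoothed = np.empty_like(imgs)
    for c in range(imgs.shape[0]):
        smoothed[c] = gaussian_filter(imgs[c].real, sigma_px) + 1j * gaussian_filter(
            imgs[c].imag, sigma_px
        )
    rss = np.sqrt(np.sum(np.abs(smoothed) ** 2, axis=0))
    bad = rss == 0
    if mask is not None and np.any(bad & np.asarray(mask, dtype=bool)):
        raise ValueError("zero sensitivity inside the mask")
    rss = np.where(bad, 1.0, rss)
    return smoothed / rss


def coil_combine(
    stacks_per_channel: EchoStack, sensitivities: np.ndarray
) -> CombinedStack:
    """Sensitivity-weighted channel combination.

    ``combined = sum_c conj(s_c) S_c / sum_c |s_c|^2``; with exact
    sensitivities this recovers the underlying object signal.  Pixels with a
    zero denominator are set to zero and dropped from the output mask.
    """
    data = stacks_per_channel.data
    if data.ndim != 4:
        raise ValueError("expected multi-channel data (n_ch, n_echoes, ny, nx)")
    sens = np.asarray(sensitivities, dtype=complex)
    if sens.shape != (data.shape[0],) + data.shape[-2:]:
        raise ValueError("sensitivities must be (n_channels, ny, nx)")
    num = np.sum(np.conj(sens)[:, None] * data, axis=0)
    den = np.sum(np.abs(sens) ** 2, axis=0)
    bad = den == 0
    combined = num / np.where(bad, 1.0, den)
    combined[:, bad] = 0.0
    mask = stacks_per_channel.mask
    if mask is not None:
        mask = mask & ~bad
    return CombinedStack(data=combined, schedule=stacks_per_channel.schedule, mask=mask)


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the coordinate covariance, oriented toward +x."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return axis


def split_cc_three(cc_mask: np.ndarray) -> np.ndarray:
    """Partition a corpus-callosum mask into three equal-extent thirds.

    Pixels are projected on the mask's principal axis (the anterior–
    posterior direction for a mid-sagittal CC); the projected coordinate is
    quantized at pixel resolution and the distinct positions are split into
    three contiguous runs of equal count, any remainder going to the
    anterior bin.  Labels: 1 = anterior (low projection), 2 = mid,
    3 = posterior.
    """
    mask = np.asarray(cc_mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("cc_mask must be a non-empty 2-D mask")
    yy, xx = np.nonzero(mask)
    coords = np.stack([xx, yy], axis=1).astype(float)  # (x, y)
    axis = _principal_axis(coords)
    proj = coords @ axis
    q = np.round(proj - proj.min()).astype(int)
    positions = np.unique(q)
    n_pos = positions.size
    base = n_pos // 3
    sizes = [n_pos - 2 * base, base, base]  # remainder -> anterior
    edges = np.cumsum(sizes)
    pos_label = np.empty(n_pos, dtype=int)
    pos_label[: edges[0]] = 1
    pos_label[edges[0] : edges[1]] = 2
    pos_label[edges[1] :] = 3
    lookup = dict(zip(positions.tolist(), pos_label.tolist()))
    labels = np.zeros(mask.shape, dtype=int)
    labels[yy, xx] = [lookup[v] for v in q]
    return labels


def roi_average(
    combined: CombinedStack,
    fdm_maps,
    labels: np.ndarray,
    segment_id: int,
) -> RoiCurves:
    """ROI-averaged magnitude and FDM curves for one callosal segment.

    The magnitude curve is the per-echo mean of ``|S|`` over segment pixels,
    normalized to the first echo; the FDM curve is the per-echo mean of the
    frequency-difference maps over the same pixels.
    """
    labels = np.asarray(labels)
    sel = labels == segment_id
    if not sel.any():
        raise ValueError(f"segment {segment_id} is empty")
    mag = np.abs(combined.data[:, sel]).mean(axis=1)
    if mag[0] == 0:
        raise ValueError("zero first-echo ROI magnitude")
    fdm = fdm_maps.maps_hz[:, sel].mean(axis=1)
    return RoiCurves(schedule=combined.schedule, magnitude=mag / mag[0], fdm_hz=fdm)
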