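"""Three-pool complex mGRE signal model.

White-matter multi-echo gradient-echo (mGRE) signal is modelled as a
superposition of three water pools — myelin (m), intra-axonal (a) and
extra-axonal (e) water — each with its own signal fraction ``f``, frequency
offset ``omega`` (relative to the extra-axonal pool, which is the zero
reference) and effective transverse relaxation rate ``R2*``::

    S(t) = f_a exp(i w_a t - R2*_a t) + f_e exp(-R2*_e t)
         + f_m exp(i w_m t - R2*_m t)

with ``t`` the echo time in seconds, ``w`` in rad/s and rates in 1/s.  Echo
times are held in milliseconds at the interface (matching acquisition
protocols) and converted to seconds inside the exponentials; frequency
offsets are accepted and reported in Hz (``omega / 2 pi``) and stored in
rad/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = [
    "EchoSchedule",
    "ThreePoolParams",
    "ComplexSignalCurve",
    "RoiCurves",
    "make_te_schedule",
    "scan_duration",
    "synthesize_three_pool",
    "model_roi_curves",
]


@dataclass(frozen=True)
class EchoSchedule:
    """Arithmetic echo-time grid TE_n = te1 + (n-1) * delta_te, in ms."""

    te1: float
    delta_te: float
    n_echoes: int

    def __post_init__(self) -> None:
        if not (self.te1 > 0):
            raise ValueError(f"te1 must be > 0, got {self.te1}")
        if not (self.delta_te > 0):
            raise ValueError(f"delta_te must be > 0, got {self.delta_te}")
        if not (int(self.n_echoes) == self.n_echoes and self.n_echoes >= 3):
            raise ValueError(f"n_echoes must be an integer >= 3, got {self.n_echoes}")

    @property
    def te_ms(self) -> np.ndarray:
        """Echo times in ms, strictly increasing."""
        return self.te1 + self.delta_te * np.arange(self.n_echoes)

    @property
    def te_s(self) -> np.ndarray:
        """Echo times in seconds."""
        return self.te_ms * 1e-3

    @property
    def max_te_ms(self) -> float:
        return float(self.te1 + (self.n_echoes - 1) * self.delta_te)


@dataclass(frozen=True)
class ThreePoolParams:
    """Signal fractions, frequency offsets (rad/s) and R2* rates (1/s).

    The extra-axonal pool is the frequency reference (offset fixed at 0 by
    convention).  Fractions are *signal* fractions and are not forced to sum
    to one at the type level; the synthetic generator always draws fractions
    summing to one.
    """

    f_m: float
    f_a: float
    f_e: float
    omega_m: float  # rad/s
    omega_a: float  # rad/s
    r2s_m: float  # 1/s
    r2s_a: float  # 1/s
    r2s_e: float  # 1/s

    def __post_init__(self) -> None:
        for name in ("f_m", "f_a", "f_e"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("r2s_m", "r2s_a", "r2s_e"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @classmethod
    def from_hz(
        cls,
        f_m: float,
        f_a: float,
        f_e: float,
        omega_m_hz: float,
        omega_a_hz: float,
        r2s_m: float,
        r2s_a: float,
        r2s_e: float,
    ) -> "ThreePoolParams":
        """Build from frequency offsets expressed in Hz."""
        return cls(
            f_m=f_m,
            f_a=f_a,
            f_e=f_e,
            omega_m=TWO_PI * omega_m_hz,
            omega_a=TWO_PI * omega_a_hz,
            r2s_m=r2s_m,
            r2s_a=r2s_a,
            r2s_e=r2s_e,
        )

    @property
    def omega_m_hz(self) -> float:
        return self.omega_m / TWO_PI

    @property
    def omega_a_hz(self) -> float:
        return self.omega_a / TWO_PI

    @property
    def delta_omega(self) -> float:
        """omega_m - omega_a in rad/s."""
        return self.omega_m - self.omega_a

    @property
    def delta_omega_hz(self) -> float:
        """(omega_m - omega_a) / 2 pi, the myelin-axonal frequency split in Hz."""
        return self.delta_omega / TWO_PI

    def to_json_record(self) -> dict:
        """Flat JSON-serializable record with offsets in Hz."""
        return {
            "f_m": self.f_m,
            "f_a": self.f_a,
            "f_e": self.f_e,
            "omega_m_hz": self.omega_m_hz,
            "omega_a_hz": self.omega_a_hz,
            "r2s_m": self.r2s_m,
            "r2s_a": self.r2s_a,
            "r2s_e": self.r2s_e,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_record())

    @classmethod
    def from_json_record(cls, record: dict) -> "ThreePoolParams":
        return cls.from_hz(
            f_m=record["f_m"],
            f_a=record["f_a"],
            f_e=record["f_e"],
            omega_m_hz=record["omega_m_hz"],
            omega_a_hz=record["omega_a_hz"],
            r2s_m=record["r2s_m"],
            r2s_a=record["r2s_a"],
            r2s_e=record["r2s_e"],
        )

    @classmethod
    def from_json(cls, s: str) -> "ThreePoolParams":
        return cls.from_json_record(json.loads(s))


@dataclass(frozen=True)
class ComplexSignalCurve:
    """Complex signal values sampled on an echo schedule."""

    schedule: EchoSchedule
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=complex)
        object.__setattr__(self, "values", values)
        if values.shape != (self.schedule.n_echoes,):
            raise ValueError(
                f"expected {self.schedule.n_echoes} values, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("signal values must be finite")


@dataclass(frozen=True)
class RoiCurves:
    """ROI-averaged magnitude (normalized to echo 1) and FDM (Hz) curves."""

    schedule: EchoSchedule
    magnitude: np.ndarray = field(repr=False)
    fdm_hz: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        magnitude = np.asarray(self.magnitude, dtype=float)
        fdm_hz = np.asarray(self.fdm_hz, dtype=float)
        n = self.schedule.n_echoes
        if magnitude.shape != (n,) or fdm_hz.shape != (n,):
            raise ValueError("curve lengths must equal n_echoes")
        if not (np.all(np.isfinite(magnitude)) and np.all(np.isfinite(fdm_hz))):
            raise ValueError("curve values must be finite")
        if np.any(magnitude < 0):
            raise ValueError("magnitude values must be non-negative")
        if not np.isclose(magnitude[0], 1.0):
            raise ValueError("magnitude must be normalized to the first echo")
        object.__setattr__(self, "magnitude", magnitude)
        object.__setattr__(self, "fdm_hz", fdm_hz)


def make_te_schedule(te1: float, delta_te: float, n: int) -> EchoSchedule:
    """Build an arithmetic TE grid (all times in ms)."""
    return EchoSchedule(te1=te1, delta_te=delta_te, n_echoes=n)


def scan_duration(n_phase_encodes: int, tr: float, n_repeats: int) -> float:
    """Total acquisition time in seconds for a single-slice Cartesian scan.

    One TR acquires one phase-encode line; the full scan is
    ``n_phase_encodes * tr * n_repeats`` with ``tr`` in ms.
    """
    if not (int(n_phase_encodes) == n_phase_encodes and n_phase_encodes > 0):
        raise ValueError("n_phase_encodes must be a positive integer")
    if not tr > 0:
        raise ValueError("tr must be positive")
    if not (int(n_repeats) == n_repeats and n_repeats > 0):
        raise ValueError("n_repeats must be a positive integer")
    return n_phase_encodes * tr * 1e-3 * n_repeats


def three_pool_signal(params: ThreePoolParams, t_s: np.ndarray) -> np.ndarray:
    """Evaluate the three-pool signal at times ``t_s`` (seconds)."""
    t = np.asarray(t_s, dtype=float)
    s_a = params.f_a * np.exp((1j * params.omega_a - params.r2s_a) * t)
    s_e = params.f_e * np.exp(-params.r2s_e * t)
    s_m = params.f_m * np.exp((1j * params.omega_m - params.r2s_m) * t)
    return s_a + s_e + s_m


def synthesize_three_pool(
    params: ThreePoolParams, schedule: EchoSchedule
) -> ComplexSignalCurve:
    """Sample the three-pool signal on an echo schedule."""
    return ComplexSignalCurve(
        schedule=schedule, values=three_pool_signal(params, schedule.te_s)
    )


def model_roi_curves(params: ThreePoolParams, schedule: EchoSchedule) -> RoiCurves:
    """Model-predicted ROI curves: normalized magnitude and FDM in Hz.

    The FDM series is produced by the *same* frequency-difference operator
    applied to measured data (:func:`fdm3pool.fdm.fdm_curve`), so model and
    data share one phase-processing path and the fit is free of
    operator-choice bias.
    """
    from .fdm import fdm_curve  # local import: fdm depends on this module's types

    curve = synthesize_three_pool(params, schedule)
    mag = np.abs(curve.values)
    if mag[0] == 0:
        raise ValueError("first-echo magnitude is zero; cannot normalize")
    return RoiCurves(
        schedule=schedule,
        magnitude=mag / mag[0],
        fdm_hz=fdm_curve(curve.values, schedule),
    )
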