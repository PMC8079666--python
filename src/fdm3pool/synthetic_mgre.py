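"""Synthetic mGRE study generator with known ground truth.

Emulates the raw inputs of a single-slice 7 T bipolar mGRE protocol: a
mid-sagittal 1 x 1 mm, 256 x 256 phantom slice containing an arch-shaped
corpus callosum split into anterior / mid / posterior thirds, acquired over
25 bipolar echoes (TE1/dTE/TR = 1.62/1.23/100 ms), 20 repeats with read
polarity inverted half-way, multi-channel reception, smooth background
field and RF phase maps, an echo-parity-alternating eddy-current phase
that inverts with read polarity, and complex Gaussian noise.

Every nuisance that is added is stored in the output, so the clean
three-pool signal can be recovered analytically (noise off) — the closure
property the pre-processing tests rely on.

A second layer simulates multi-subject / multi-visit *studies* at the
ROI-curve level (the slow image chain is exercised separately): subject
ages, CAG repeats, group effects on the myelin fraction and the
myelin-axonal frequency split, segment-specific between-visit noise
mimicking the anterior-to-posterior reproducibility gradient, and a
synthetic executive-function score with a configurable group x age
interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_model import (
    TWO_PI,
    EchoSchedule,
    RoiCurves,
    ThreePoolParams,
    make_te_schedule,
)

__all__ = [
    "PhantomSpec",
    "NuisanceSpec",
    "StudySpec",
    "Phantom",
    "SliceStack",
    "default_schedule",
    "generate_phantom",
    "simulate_acquisition",
    "simulate_study",
]

#: Segment-wise parameter means used as generator defaults: anterior, mid,
#: posterior myelin fraction, axonal and myelin frequency offsets (Hz).
SEGMENT_FM_MEANS = (0.15, 0.15, 0.16)
SEGMENT_OMEGA_A_HZ_MEANS = (-8.5, -7.9, -8.5)
SEGMENT_OMEGA_M_HZ_MEANS = (31.4, 27.1, 27.3)
#: Segment-wise across-visit SDs (anterior, mid, posterior) reproducing the
#: posterior-to-anterior reproducibility gradient.
SEGMENT_FM_VISIT_SD = (0.08, 0.04, 0.02)
SEGMENT_OMEGA_A_VISIT_SD = (2.0, 1.1, 0.6)
SEGMENT_OMEGA_M_VISIT_SD = (10.2, 4.4, 2.1)

DEFAULT_R2S_M = 150.0
DEFAULT_R2S_A = 0.0
DEFAULT_R2S_E = 25.0


def default_schedule() -> EchoSchedule:
    """The acquisition TE grid: 25 echoes, TE1 1.62 ms, spacing 1.23 ms."""
    return make_te_schedule(1.62, 1.23, 25)


def _three_pool_params_for_fm(
    f_m: float, omega_a_hz: float, omega_m_hz: float,
    r2s_m: float = DEFAULT_R2S_M, r2s_a: float = DEFAULT_R2S_A,
    r2s_e: float = DEFAULT_R2S_E,
) -> ThreePoolParams:
    """Fractions sum to one with the non-myelin signal split evenly."""
    rest = (1.0 - f_m) / 2.0
    return ThreePoolParams.from_hz(
        f_m=f_m, f_a=rest, f_e=rest,
        omega_m_hz=omega_m_hz, omega_a_hz=omega_a_hz,
        r2s_m=r2s_m, r2s_a=r2s_a, r2s_e=r2s_e,
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue parameters of the mid-sagittal phantom slice."""

    grid: tuple[int, int] = (256, 256)
    pixel_mm: float = 1.0
    #: half-ellipse arc: center (as grid fractions), radii (px), radial band
    arc_center_frac: tuple[float, float] = (0.62, 0.5)  # (row, col)
    arc_radii_px: tuple[float, float] = (80.0, 35.0)  # (x, y)
    arc_band: tuple[float, float] = (0.85, 1.05)
    segment_fm_means: tuple[float, float, float] = SEGMENT_FM_MEANS
    segment_omega_a_hz: tuple[float, float, float] = SEGMENT_OMEGA_A_HZ_MEANS
    segment_omega_m_hz: tuple[float, float, float] = SEGMENT_OMEGA_M_HZ_MEANS
    r2s_m: float = DEFAULT_R2S_M
    r2s_a: float = DEFAULT_R2S_A
    r2s_e: float = DEFAULT_R2S_E
    #: between-pixel SDs inside the CC
    pixel_sd_fm: float = 0.01
    pixel_sd_omega_hz: float = 0.5
    pixel_sd_r2s: float = 3.0
    #: non-CC tissue is mono-exponential (single pool, no frequency offset):
    #: its FDM is identically zero, giving the per-echo spatial detrend a
    #: clean null reference everywhere outside the callosum
    background_tissue: ThreePoolParams = field(
        default_factory=lambda: ThreePoolParams.from_hz(
            f_m=0.0, f_a=0.0, f_e=1.0,
            omega_m_hz=0.0, omega_a_hz=0.0,
            r2s_m=150.0, r2s_a=0.0, r2s_e=20.0,
        )
    )


@dataclass(frozen=True)
class Phantom:
    """Per-pixel three-pool parameter maps plus CC mask and segment labels."""

    param_maps: dict = field(repr=False)  # name -> 2-D array
    cc_mask: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)  # 1 anterior, 2 mid, 3 posterior
    spec: PhantomSpec

    def segment_mean_params(self, segment_id: int) -> ThreePoolParams:
        sel = self.labels == segment_id
        if not sel.any():
            raise ValueError(f"segment {segment_id} is empty")
        m = {k: float(v[sel].mean()) for k, v in self.param_maps.items()}
        return ThreePoolParams.from_hz(
            f_m=m["f_m"], f_a=m["f_a"], f_e=m["f_e"],
            omega_m_hz=m["omega_m_hz"], omega_a_hz=m["omega_a_hz"],
            r2s_m=m["r2s_m"], r2s_a=m["r2s_a"], r2s_e=m["r2s_e"],
        )


def _cc_arc_geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Boolean CC mask and 1/2/3 labels (equal anterior-posterior extent)."""
    ny, nx = spec.grid
    cy = spec.arc_center_frac[0] * (ny - 1)
    cx = spec.arc_center_frac[1] * (nx - 1)
    rx, ry = spec.arc_radii_px
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
    mask = (r >= spec.arc_band[0]) & (r <= spec.arc_band[1]) & (yy <= cy)
    if not mask.any():
        raise ValueError("CC arc does not fit the grid")
    # equal thirds of the distinct anterior-posterior (column) positions;
    # anterior = low column, remainder columns assigned anteriorly
    cols = np.unique(xx[mask])
    base = cols.size // 3
    sizes = [cols.size - 2 * base, base, base]
    edges = np.cumsum(sizes)
    labels = np.zeros(spec.grid, dtype=int)
    col_label = np.empty(cols.size, dtype=int)
    col_label[: edges[0]] = 1
    col_label[edges[0] : edges[1]] = 2
    col_label[edges[1] :] = 3
    lut = dict(zip(cols.tolist(), col_label.tolist()))
    labels[mask] = [lut[c] for c in xx[mask]]
    return mask, labels


def generate_phantom(spec: PhantomSpec | None = None, seed: int = 0) -> Phantom:
    """Draw per-pixel three-pool parameters around segment-specific means.

    CC pixels get segment-mean parameters plus independent Gaussian
    between-pixel variation (fractions are renormalized so
    ``f_m + f_a + f_e = 1`` at every pixel); everything outside the CC is
    the background tissue.  Deterministic under a fixed seed.
    """
    if spec is None:
        spec = PhantomSpec()
    rng = np.random.default_rng(seed)
    mask, labels = _cc_arc_geometry(spec)
    bg = spec.background_tissue
    maps = {
        "f_m": np.full(spec.grid, bg.f_m),
        "f_a": np.full(spec.grid, bg.f_a),
        "f_e": np.full(spec.grid, bg.f_e),
        "omega_m_hz": np.full(spec.grid, bg.omega_m_hz),
        "omega_a_hz": np.full(spec.grid, bg.omega_a_hz),
        "r2s_m": np.full(spec.grid, bg.r2s_m),
        "r2s_a": np.full(spec.grid, bg.r2s_a),
        "r2s_e": np.full(spec.grid, bg.r2s_e),
    }
    for seg in (1, 2, 3):
        sel = labels == seg
        n = int(sel.sum())
        f_m = np.clip(
            spec.segment_fm_means[seg - 1] + spec.pixel_sd_fm * rng.standard_normal(n),
            0.01, 0.6,
        )
        maps["f_m"][sel] = f_m
        rest = (1.0 - f_m) / 2.0
        maps["f_a"][sel] = rest
        maps["f_e"][sel] = rest
        maps["omega_a_hz"][sel] = spec.segment_omega_a_hz[
            seg - 1
        ] + spec.pixel_sd_omega_hz * rng.standard_normal(n)
        maps["omega_m_hz"][sel] = spec.segment_omega_m_hz[
            seg - 1
        ] + spec.pixel_sd_omega_hz * rng.standard_normal(n)
        maps["r2s_m"][sel] = np.clip(
            spec.r2s_m + spec.pixel_sd_r2s * rng.standard_normal(n), 1.0, None
        )
        maps["r2s_a"][sel] = spec.r2s_a
        maps["r2s_e"][sel] = np.clip(
            spec.r2s_e + spec.pixel_sd_r2s * rng.standard_normal(n), 0.0, None
        )
    return Phantom(param_maps=maps, cc_mask=mask, labels=labels, spec=spec)


def _poly2d_map(coeffs: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
    """Evaluate a total-degree <= 3 polynomial on normalized coordinates."""
    ny, nx = grid
    yy, xx = np.mgrid[0:ny, 0:nx]
    x = (xx - (nx - 1) / 2.0) / ((nx - 1) / 2.0)
    y = (yy - (ny - 1) / 2.0) / ((ny - 1) / 2.0)
    terms = [x**i * y**j for i in range(4) for j in range(4 - i)]
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size != len(terms):
        raise ValueError(f"expected {len(terms)} polynomial coefficients")
    return sum(c * t for c, t in zip(coeffs, terms))


@dataclass(frozen=True)
class NuisanceSpec:
    """Acquisition nuisances added on top of the clean tissue signal."""

    #: background frequency map (Hz), total-degree-3 polynomial coefficients
    field_poly_coeffs: tuple = (4.0, 8.0, -5.0, 2.0, 6.0, -3.0, 1.5, -2.0, 2.5, -1.0)
    #: TE-independent RF/receive phase map (rad), same basis
    rf_phase_coeffs: tuple = (0.5, -0.8, 0.4, 0.2, 0.6, -0.3, 0.1, 0.3, -0.2, 0.1)
    #: eddy-current phase (rad): sign alternates with echo parity, inverts
    #: with read polarity
    eddy_phase_rad: float = 0.2
    n_channels: int = 4
    #: per-repeat complex noise SD as a fraction of the mean first-echo
    #: CC magnitude (0 disables noise)
    noise_sigma: float = 0.05
    #: replace the random smooth coil maps by unit sensitivities
    unit_coils: bool = False

    @classmethod
    def off(cls, n_channels: int = 1) -> "NuisanceSpec":
        """Identity nuisance: no field, no RF phase, no eddy, no noise, unit coils."""
        zeros = (0.0,) * 10
        return cls(
            field_poly_coeffs=zeros,
            rf_phase_coeffs=zeros,
            eddy_phase_rad=0.0,
            n_channels=n_channels,
            noise_sigma=0.0,
            unit_coils=True,
        )


@dataclass(frozen=True)
class SliceStack:
    """Raw per-polarity, per-channel, per-echo complex images plus truth.

    ``data`` has shape ``(2, n_channels, n_echoes, ny, nx)`` — polarity
    groups first (index 0 = positive read polarity), repeats already
    averaged within each polarity group.  ``truth`` records every generated
    ground-truth map (clean signal, field, RF phase, eddy phase, coil
    maps, parameter maps).
    """

    data: np.ndarray = field(repr=False)
    schedule: EchoSchedule
    cc_mask: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    truth: dict = field(repr=False)
    pixel_mm: float = 1.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=complex)
        if data.ndim != 5 or data.shape[0] != 2:
            raise ValueError("data must be (2, n_channels, n_echoes, ny, nx)")
        if data.shape[2] != self.schedule.n_echoes:
            raise ValueError("echo axis must match the schedule")
        if self.cc_mask.shape != data.shape[-2:]:
            raise ValueError("mask grid mismatch")
        object.__setattr__(self, "data", data)


def _coil_maps(rng: np.random.Generator, n_channels: int, grid) -> np.ndarray:
    """Smooth complex sensitivities: low-order polynomial magnitude + phase."""
    maps = np.empty((n_channels,) + tuple(grid), dtype=complex)
    for c in range(n_channels):
        mag = 1.0 + _poly2d_map(0.3 * rng.standard_normal(10), grid)
        mag = np.clip(mag, 0.2, None)
        phase = _poly2d_map(0.5 * rng.standard_normal(10), grid)
        maps[c] = mag * np.exp(1j * phase)
    return maps


def simulate_acquisition(
    phantom: Phantom,
    nuisance: NuisanceSpec | None = None,
    schedule: EchoSchedule | None = None,
    seed: int = 0,
    n_repeats: int = 20,
) -> SliceStack:
    """Simulate the bipolar multi-channel acquisition of a phantom slice.

    Pixel signal per polarity ``p`` (+1/-1), channel ``c`` and echo ``n``::

        S = S3pool(t_n) * exp(i (rf + 2 pi field_hz t_n + p (-1)^n eddy))
            * coil_c + noise

    Repeats are split evenly between the polarity groups and averaged, so
    noise is scaled by ``sqrt(n_repeats / 2)``.
    """
    if nuisance is None:
        nuisance = NuisanceSpec()
    if schedule is None:
        schedule = default_schedule()
    grid = phantom.cc_mask.shape
    maps = phantom.param_maps
    for arr in maps.values():
        if arr.shape != grid:
            raise ValueError("parameter maps and mask must share the grid")
    rng = np.random.default_rng(seed)
    te = schedule.te_s
    n_echoes = schedule.n_echoes
    wa = TWO_PI * maps["omega_a_hz"]
    wm = TWO_PI * maps["omega_m_hz"]
    clean = np.empty((n_echoes,) + grid, dtype=complex)
    for n, t in enumerate(te):
        clean[n] = (
            maps["f_a"] * np.exp((1j * wa - maps["r2s_a"]) * t)
            + maps["f_e"] * np.exp(-maps["r2s_e"] * t)
            + maps["f_m"] * np.exp((1j * wm - maps["r2s_m"]) * t)
        )
    field_hz = _poly2d_map(nuisance.field_poly_coeffs, grid)
    rf_phase = _poly2d_map(nuisance.rf_phase_coeffs, grid)
    if nuisance.unit_coils:
        coil_maps = np.ones((nuisance.n_channels,) + grid, dtype=complex)
    else:
        coil_maps = _coil_maps(rng, nuisance.n_channels, grid)
    parity = (-1.0) ** np.arange(n_echoes)

    n_av = max(n_repeats // 2, 1)
    sigma = 0.0
    if nuisance.noise_sigma > 0:
        ref = np.abs(clean[0][phantom.cc_mask]).mean()
        sigma = nuisance.noise_sigma * ref / np.sqrt(n_av)

    data = np.empty((2, nuisance.n_channels, n_echoes) + grid, dtype=complex)
    for ip, pol in enumerate((1.0, -1.0)):
        phase = (
            rf_phase[None]
            + TWO_PI * field_hz[None] * te[:, None, None]
            + pol * parity[:, None, None] * nuisance.eddy_phase_rad
        )
        modulated = clean * np.exp(1j * phase)
        for c in range(nuisance.n_channels):
            s = modulated * coil_maps[c]
            if sigma > 0:
                s = s + sigma * (
                    rng.standard_normal(s.shape) + 1j * rng.standard_normal(s.shape)
                )
            data[ip, c] = s
    truth = {
        "clean_signal": clean,
        "field_hz": field_hz,
        "rf_phase": rf_phase,
        "eddy_phase_rad": nuisance.eddy_phase_rad,
        "coil_maps": coil_maps,
        "param_maps": maps,
        "n_repeats": n_repeats,
        "noise_sigma": nuisance.noise_sigma,
        "seed": seed,
    }
    return SliceStack(
        data=data,
        schedule=schedule,
        cc_mask=phantom.cc_mask,
        labels=phantom.labels,
        truth=truth,
        pixel_mm=phantom.spec.pixel_mm,
    )


# ---------------------------------------------------------------------------
# Study-level simulation (ROI-curve fast path)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudySpec:
    """Cohort design and effect sizes for a simulated study.

    Defaults reproduce the study conditions: 19 premanifest HD carriers and
    21 controls (single visit) for the group analysis, CAG repeats drawn
    uniformly from 37-45, a negative group effect and a flatter age slope
    on the myelin fraction in HD, no group effect on the frequency split,
    and segment-specific between-visit noise giving the posterior < mid <
    anterior reproducibility gradient.  Reproducibility cohorts are the
    same machinery with ``n_hd=0, n_control=6, n_visits=5``.
    """

    n_hd: int = 19
    n_control: int = 21
    n_visits: int = 1
    age_range: tuple[float, float] = (21.0, 71.0)
    age_center: float = 45.0
    cag_range: tuple[int, int] = (37, 45)
    fm_segment_means: tuple = SEGMENT_FM_MEANS
    omega_a_hz_segment_means: tuple = SEGMENT_OMEGA_A_HZ_MEANS
    omega_m_hz_segment_means: tuple = SEGMENT_OMEGA_M_HZ_MEANS
    fm_group_effect: float = -0.04
    fm_age_slope_control: float = -0.0008
    fm_age_slope_hd: float = -0.0002
    domega_group_effect: float = 0.0
    domega_age_slope_hz: float = 0.05
    fm_between_subject_sd: float = 0.015
    omega_between_subject_sd_hz: float = 0.5
    fm_visit_sd: tuple = SEGMENT_FM_VISIT_SD
    omega_a_visit_sd_hz: tuple = SEGMENT_OMEGA_A_VISIT_SD
    omega_m_visit_sd_hz: tuple = SEGMENT_OMEGA_M_VISIT_SD
    r2s_m: float = DEFAULT_R2S_M
    r2s_a: float = DEFAULT_R2S_A
    r2s_e: float = DEFAULT_R2S_E
    #: first-echo SNR of the ROI-averaged complex curve; 0 disables noise.
    #: Default matches what the study's acquisition delivers: pixel SNR ~20
    #: per repeat and channel, 20 repeats, 32 receive channels, ~400 pixels
    #: per segment => ROI SNR ~ 20 * sqrt(20 * 32 * 400) / sqrt(2) ~ 7000.
    #: At this level fitted-parameter measurement noise is subdominant to
    #: the configured between-visit SDs, which are the *total* across-visit
    #: variability the generator is calibrated to reproduce.
    roi_snr: float = 7000.0
    exec_intercept: float = 5.0
    exec_group: float = 1.9
    exec_age_slope: float = 0.004
    exec_interaction: float = -0.06
    exec_noise_sd: float = 1.0
    exec_fm_coupling: float = 30.0
    #: which callosal segments to generate (the group analysis only needs
    #: the posterior segment, 3)
    segments: tuple = (1, 2, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        for seg in range(3):
            for is_hd in (False, True):
                slope = self.fm_age_slope_hd if is_hd else self.fm_age_slope_control
                for age in self.age_range:
                    mean = (
                        self.fm_segment_means[seg]
                        + (self.fm_group_effect if is_hd else 0.0)
                        + slope * (age - self.age_center)
                    )
                    if not (0.0 < mean < 1.0):
                        raise ValueError(
                            "effect sizes drive the mean myelin fraction out of (0, 1)"
                        )


def _noisy_roi_curves(
    params: ThreePoolParams,
    schedule: EchoSchedule,
    snr: float,
    rng: np.random.Generator,
) -> RoiCurves:
    from .fdm import fdm_curve
    from .signal_model import three_pool_signal

    s = three_pool_signal(params, schedule.te_s)
    if snr > 0:
        sigma = np.abs(s[0]) / snr
        s = s + sigma * (
            rng.standard_normal(s.shape) + 1j * rng.standard_normal(s.shape)
        )
    mag = np.abs(s)
    return RoiCurves(
        schedule=schedule, magnitude=mag / mag[0], fdm_hz=fdm_curve(s, schedule)
    )


def simulate_study(
    study: StudySpec | None = None,
    schedule: EchoSchedule | None = None,
    fit_curves: bool = True,
    fit_config=None,
    return_curves: bool = False,
) -> pd.DataFrame:
    """Simulate a cohort at the ROI-curve level and return the study table.

    One row per subject x visit x segment with the true generating
    parameters (``*_true`` columns) and — when ``fit_curves`` is on — the
    values recovered by synthesizing noisy ROI curves and refitting the
    three-pool model (the pipeline the real study runs per ROI).  With
    ``fit_curves=False`` the reported metrics are the true per-visit values
    (fast path for statistical calibration studies).

    With ``return_curves=True`` (requires ``fit_curves``) the generated ROI
    curves are also returned, keyed by ``(subject_id, visit, segment)``.
    """
    if study is None:
        study = StudySpec()
    if schedule is None:
        schedule = default_schedule()
    rng = np.random.default_rng(study.seed)
    if fit_curves:
        from .threepool_fit import FitConfig, fit_three_pool

        config = fit_config if fit_config is not None else FitConfig()
    if return_curves and not fit_curves:
        raise ValueError("return_curves requires fit_curves=True")

    curves_out = {}
    rows = []
    n_total = study.n_hd + study.n_control
    groups = ["HD"] * study.n_hd + ["control"] * study.n_control
    for i in range(n_total):
        group = groups[i]
        is_hd = group == "HD"
        age = rng.uniform(*study.age_range)
        cag = int(rng.integers(study.cag_range[0], study.cag_range[1] + 1)) if is_hd else None
        b_fm = study.fm_between_subject_sd * rng.standard_normal()
        b_oa = study.omega_between_subject_sd_hz * rng.standard_normal()
        b_om = study.omega_between_subject_sd_hz * rng.standard_normal()
        slope = study.fm_age_slope_hd if is_hd else study.fm_age_slope_control
        exec_score = (
            study.exec_intercept
            + (study.exec_group if is_hd else 0.0)
            + study.exec_age_slope * age
            + (study.exec_interaction * age if is_hd else 0.0)
            + study.exec_fm_coupling * b_fm
            + study.exec_noise_sd * rng.standard_normal()
        )
        for visit in range(1, study.n_visits + 1):
            for seg in study.segments:
                j = seg - 1
                fm = (
                    study.fm_segment_means[j]
                    + (study.fm_group_effect if is_hd else 0.0)
                    + slope * (age - study.age_center)
                    + b_fm
                    + study.fm_visit_sd[j] * rng.standard_normal()
                )
                fm = float(np.clip(fm, 0.02, 0.9))
                oa = (
                    study.omega_a_hz_segment_means[j]
                    + b_oa
                    + study.omega_a_visit_sd_hz[j] * rng.standard_normal()
                )
                oa = float(np.clip(oa, -29.0, -0.5))
                om = (
                    study.omega_m_hz_segment_means[j]
                    + (study.domega_group_effect if is_hd else 0.0)
                    + study.domega_age_slope_hz * (age - study.age_center)
                    + b_om
                    + study.omega_m_visit_sd_hz[j] * rng.standard_normal()
                )
                om = float(np.clip(om, 1.0, 49.0))
                truth = _three_pool_params_for_fm(
                    fm, oa, om, study.r2s_m, study.r2s_a, study.r2s_e
                )
                if fit_curves:
                    curves = _noisy_roi_curves(truth, schedule, study.roi_snr, rng)
                    res = fit_three_pool(curves, config)
                    fitted = res.params
                    converged = res.converged
                    if return_curves:
                        curves_out[(f"S{i + 1:03d}", visit, seg)] = curves
                else:
                    fitted = truth
                    converged = True
                rows.append(
                    {
                        "subject_id": f"S{i + 1:03d}",
                        "group": group,
                        "age": age,
                        "cag": cag,
                        "visit": visit,
                        "segment": seg,
                        "f_m": fitted.f_m,
                        "omega_a_hz": fitted.omega_a_hz,
                        "omega_m_hz": fitted.omega_m_hz,
                        "delta_omega_hz": fitted.delta_omega_hz,
                        "exec_score": exec_score,
                        "converged": converged,
                        "f_m_true": truth.f_m,
                        "omega_a_hz_true": truth.omega_a_hz,
                        "omega_m_hz_true": truth.omega_m_hz,
                        "delta_omega_hz_true": truth.delta_omega_hz,
                    }
                )
    table = pd.DataFrame(rows)
    if return_curves:
        return table, curves_out
    return table
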