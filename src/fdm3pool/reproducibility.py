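"""Test–retest reproducibility statistics.

Three tools quantify scan–rescan stability of the FDM / three-pool
analysis:

* the discrete Fréchet distance between FDM-vs-TE curves from different
  visits (the "dog-leash" distance over order-preserving couplings);
* coefficients of variation (CV = SD / mean, sample SD) of fitted
  parameters across visits;
* the modified signed-likelihood ratio test (MSLRT) for equality of
  coefficients of variation across k groups under a normal model
  (Krishnamoorthy–Lee style: profile likelihood over a common CV, with a
  Monte-Carlo small-sample moment correction of the likelihood-ratio
  statistic, referred to chi-square with k - 1 degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CurveSet",
    "discrete_frechet",
    "frechet_matrix",
    "cv_percent",
    "mslrt_cv_equality",
    "MslrtResult",
    "segment_cv_table",
]


@dataclass(frozen=True)
class CurveSet:
    """Per-visit FDM curves for one subject x segment, on a shared TE grid."""

    te_ms: np.ndarray = field(repr=False)
    curves_hz: np.ndarray = field(repr=False)  # (n_visits, n_echoes)

    def __post_init__(self) -> None:
        te = np.asarray(self.te_ms, dtype=float)
        curves = np.atleast_2d(np.asarray(self.curves_hz, dtype=float))
        if curves.shape[1] != te.size:
            raise ValueError("curves must share the echo grid")
        object.__setattr__(self, "te_ms", te)
        object.__setattr__(self, "curves_hz", curves)


def discrete_frechet(
    p: np.ndarray, q: np.ndarray, axis_weights: tuple[float, float] = (1.0, 1.0)
) -> float:
    """Discrete Fréchet distance between two point sequences.

    Points are rows of ``p`` and ``q`` (shape ``(n, 2)``); ``axis_weights``
    rescales the two axes before measuring Euclidean distances (FDM curves
    mix ms and Hz axes, left unscaled by default).  Computed by the
    standard dynamic program over monotone couplings.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if p.size == 0 or q.size == 0:
        raise ValueError("input sequences must be non-empty")
    w = np.asarray(axis_weights, dtype=float)
    d = np.sqrt(
        np.sum((p[:, None, :] * w - q[None, :, :] * w) ** 2, axis=2)
    )  # (n, m) pairwise distances
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]), d[i, j])
    return float(ca[-1, -1])


def frechet_matrix(
    curves: CurveSet, axis_weights: tuple[float, float] = (1.0, 1.0)
) -> np.ndarray:
    """Symmetric visit-by-visit matrix of discrete Fréchet distances."""
    n_visits = curves.curves_hz.shape[0]
    if n_visits < 2:
        raise ValueError("need >= 2 visits")
    pts = [
        np.stack([curves.te_ms, curves.curves_hz[v]], axis=1) for v in range(n_visits)
    ]
    out = np.zeros((n_visits, n_visits))
    for i in range(n_visits):
        for j in range(i + 1, n_visits):
            out[i, j] = out[j, i] = discrete_frechet(pts[i], pts[j], axis_weights)
    return out


def cv_percent(values) -> float:
    """Coefficient of variation in percent, 100 * sample SD / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    return float(100.0 * x.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# MSLRT for equality of coefficients of variation
# ---------------------------------------------------------------------------


def _profile_loglik_h0(
    n: np.ndarray, t_sum: np.ndarray, ss: np.ndarray, n_iter: int = 200
):
    """Constrained MLE under a common CV, by alternating profile updates.

    Arrays are vectorized over a leading replicate axis; group axis last.
    For fixed tau the per-group mean MLE solves
    ``n tau^2 mu^2 + T mu - SS = 0``; for fixed means the common-CV MLE is
    the pooled normalized residual variance.  Returns (loglik, tau, mu).
    """
    big_n = n.sum(axis=-1, keepdims=True)
    mu = t_sum / n
    q_over = lambda mu: ss / mu**2 - 2.0 * t_sum / mu + n
    tau2 = (q_over(mu)).sum(axis=-1, keepdims=True) / big_n
    for _ in range(n_iter):
        mu = (-t_sum + np.sqrt(t_sum**2 + 4.0 * n * tau2 * ss)) / (2.0 * n * tau2)
        tau2_new = (q_over(mu)).sum(axis=-1, keepdims=True) / big_n
        if np.all(np.abs(tau2_new - tau2) <= 1e-14 * tau2):
            tau2 = tau2_new
            break
        tau2 = tau2_new
    tau = np.sqrt(tau2)
    loglik = (
        -(n * np.log(tau * mu)).sum(axis=-1)
        - (q_over(mu) / (2.0 * tau2)).sum(axis=-1)
    )
    return loglik, tau[..., 0], mu


def _lrt_stat(n: np.ndarray, xbar: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Likelihood-ratio statistic for H0: common CV, from summary statistics.

    ``s2`` is the unbiased (n-1 denominator) sample variance; vectorized
    over a leading replicate axis.
    """
    t_sum = n * xbar
    ss = (n - 1) * s2 + n * xbar**2
    v_mle = (n - 1) * s2 / n  # MLE variances
    l1 = -(n / 2.0 * np.log(v_mle)).sum(axis=-1) - n.sum(axis=-1) / 2.0
    l0, _, _ = _profile_loglik_h0(n, t_sum, ss)
    return 2.0 * (l1 - l0)


@dataclass(frozen=True)
class MslrtResult:
    statistic: float
    p_value: float
    df: int
    lrt: float
    cv_percent_by_group: tuple


def mslrt_cv_equality(
    groups, n_sim: int = 2000, random_state: int = 12345
) -> MslrtResult:
    """Modified signed-likelihood ratio test for equality of k CVs.

    The likelihood-ratio statistic for a common coefficient of variation
    (normal model, profile MLE over the common CV) is moment-corrected with
    ``n_sim`` parametric simulations under the fitted null — matching its
    mean and variance to the chi-square(k-1) reference — and the corrected
    statistic is referred to chi-square with k - 1 degrees of freedom.
    Groups whose sample mean is negative are sign-flipped first, so the
    hypothesis concerns the magnitude of the CVs.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need >= 2 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs >= 2 values")
        if g.mean() == 0:
            raise ValueError("zero group mean: CV undefined")
        if g.std(ddof=1) == 0 and g.mean() == 0:
            raise ValueError("degenerate group")
    arrays = [g if g.mean() > 0 else -g for g in arrays]
    if any(g.std(ddof=1) == 0 for g in arrays):
        raise ValueError("zero-variance group: CV test undefined")
    n = np.array([g.size for g in arrays], dtype=float)
    xbar = np.array([g.mean() for g in arrays])
    s2 = np.array([g.var(ddof=1) for g in arrays])
    cvs = tuple(100.0 * np.sqrt(s2) / xbar)

    lrt = float(_lrt_stat(n, xbar, s2))

    # fitted null for the parametric moment correction
    t_sum = n * xbar
    ss = (n - 1) * s2 + n * xbar**2
    _, tau0, mu0 = _profile_loglik_h0(
        n[None, :], t_sum[None, :], ss[None, :]
    )
    tau0 = float(tau0[0])
    mu0 = mu0[0]

    rng = np.random.default_rng(random_state)
    sd0 = tau0 * mu0
    xbar_sim = rng.normal(mu0, sd0 / np.sqrt(n), size=(n_sim, k))
    s2_sim = (
        sd0**2 * rng.chisquare(n - 1, size=(n_sim, k)) / (n - 1)
    )
    lrt_sim = _lrt_stat(n[None, :], xbar_sim, s2_sim)

    df = k - 1
    m, sd = float(lrt_sim.mean()), float(lrt_sim.std(ddof=1))
    stat = max(0.0, df + np.sqrt(2.0 * df) * (lrt - m) / sd)
    p = float(sps.chi2.sf(stat, df))
    return MslrtResult(
        statistic=float(stat), p_value=p, df=df, lrt=lrt, cv_percent_by_group=cvs
    )


def segment_cv_table(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = ("f_m", "omega_a_hz", "omega_m_hz", "delta_omega_hz"),
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-segment reproducibility summary of fitted metrics across visits.

    Expects columns ``subject_id``, ``segment``, ``visit`` plus the metric
    columns.  For each metric and segment the summary CV is the mean of
    per-subject across-visit CVs (set ``pooled=True`` for the CV of values
    pooled over subjects instead); means and SDs are pooled over
    subject-visits either way.
    """
    rows = []
    for metric in metrics:
        for segment, seg_df in table.groupby("segment"):
            per_subject = [
                cv_percent(sub[metric].to_numpy())
                for _, sub in seg_df.groupby("subject_id")
                if sub.shape[0] >= 2
            ]
            values = seg_df[metric].to_numpy()
            if pooled or not per_subject:
                cv = cv_percent(values)
            else:
                cv = float(np.mean(per_subject))
            rows.append(
                {
                    "metric": metric,
                    "segment": segment,
                    "mean": float(values.mean()),
                    "sd": float(values.std(ddof=1)),
                    "cv_percent": cv,
                }
            )
    return pd.DataFrame(rows)
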