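"""Group comparison layer: t-tests, confidence intervals, circular statistics.

Linear metrics (band power, mean PAC, coherence, Eglob, PDC) are compared
between the two treatment groups with the classic pooled-variance two-sample
t-test, each week analyzed separately; summaries are means with 95%
confidence intervals.  Coupling phase shifts are angles, so their group
means use the circular mean and the Watson–Williams circular one-way F-test
(with the standard concentration correction), which is only trustworthy for
reasonably concentrated samples — results below the validity threshold are
returned but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "CircularSample",
    "two_sample_t",
    "circular_mean",
    "watson_williams",
    "summarize_ci",
]

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Result of one between-group test on one metric."""

    metric: str
    mean_a: float
    mean_b: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    statistic: float          # t or F
    statistic_name: str       # 't' or 'F'
    p: float
    n_a: int
    n_b: int
    df: float
    notes: str = ""

    @property
    def significant(self) -> bool:
        return self.p < ALPHA

    @property
    def stars(self) -> str:
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return ""


@dataclass
class CircularSample:
    """Angles in radians, wrapped to [−π, π)."""

    angles: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("angles must be a non-empty 1-D array")
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite angle")
        self.angles = np.mod(a + np.pi, 2 * np.pi) - np.pi

    @property
    def n(self) -> int:
        return self.angles.size


def summarize_ci(values) -> tuple[float, tuple[float, float]]:
    """Mean with 95% t confidence interval: mean ± t₀.₉₇₅,ₙ₋₁·sd/√n."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite value")
    mean = float(v.mean())
    half = float(stats.t.ppf(0.975, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size))
    return mean, (mean - half, mean + half)


def two_sample_t(a, b, metric: str = "", welch: bool = False) -> GroupComparison:
    """Two-sided two-sample t-test (pooled variance by default).

    Zero variance in both groups with equal means returns p = 1 by
    convention (no evidence of a difference, not an error).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite value in input")
    mean_a, ci_a = summarize_ci(a)
    mean_b, ci_b = summarize_ci(b)
    df = a.size + b.size - 2
    notes = ""
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if mean_a == mean_b:
            t, p = 0.0, 1.0
            notes = "zero variance in both groups"
        else:
            t, p = np.inf if mean_a > mean_b else -np.inf, 0.0
            notes = "zero variance, unequal means"
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
        if welch:
            df = float(res.df)
    return GroupComparison(
        metric, mean_a, mean_b, ci_a, ci_b, t, "t", p, a.size, b.size, df, notes
    )


def circular_mean(s: CircularSample) -> tuple[float, float]:
    """Mean direction and resultant length of exp(i·angles).

    A vanishing resultant leaves the direction undefined; NaN is returned
    for the angle in that case.
    """
    vec = np.mean(np.exp(1j * s.angles))
    r = float(abs(vec))
    angle = float(np.angle(vec)) if r > 1e-12 else float("nan")
    return angle, r


def _kappa_ml(rbar: float) -> float:
    """Maximum-likelihood von Mises concentration from the mean resultant."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def watson_williams(
    a: CircularSample, b: CircularSample, metric: str = ""
) -> GroupComparison:
    """Watson–Williams two-sample test for equal mean directions.

    One-way circular ANOVA F statistic with the 1 + 3/(8κ̂) concentration
    correction; p from F(1, N−2).  Valid for concentrated samples (pooled
    mean resultant ≥ 0.45); below that the result carries an
    'assumption violated' note rather than failing.
    """
    n1, n2 = a.n, b.n
    N = n1 + n2
    if N < 4:
        raise ValueError("too few angles for the Watson-Williams test")
    ang1, r1bar = circular_mean(a)
    ang2, r2bar = circular_mean(b)
    R1, R2 = n1 * r1bar, n2 * r2bar
    all_angles = np.concatenate([a.angles, b.angles])
    vec = np.sum(np.exp(1j * all_angles))
    R = float(abs(vec))
    rw = (R1 + R2) / N
    notes = ""
    if rw < 0.45:
        notes = "assumption violated: mean resultant < 0.45"
    kappa = _kappa_ml(rw)
    K = 1 + 3 / (8 * kappa) if kappa > 0 else 1.0
    denom = N - (R1 + R2)
    if denom <= 0:
        F = 0.0 if (R1 + R2 - R) <= 1e-12 else float("inf")
        p = 1.0 if F == 0.0 else 0.0
    else:
        F = float(K * (N - 2) * (R1 + R2 - R) / denom)
        F = max(F, 0.0)
        p = float(stats.f.sf(F, 1, N - 2))

    def arc_ci(ang: float, rbar: float, n: int) -> tuple[float, float]:
        # circular CI half-width (approximate, via the dispersion estimate)
        if not np.isfinite(ang) or rbar <= 0:
            return (float("nan"), float("nan"))
        Rn = n * rbar
        kap = _kappa_ml(rbar)
        if kap <= 0 or Rn <= 0:
            return (float("nan"), float("nan"))
        val = 2 * n * (2 * Rn**2 - n * stats.chi2.ppf(0.95, 1))
        if val <= 0:
            return (ang - np.pi, ang + np.pi)
        arg = np.sqrt(val) / (2 * Rn)
        if not np.isfinite(arg) or arg > 1:
            return (ang - np.pi, ang + np.pi)
        half = float(np.arccos(arg))
        return (ang - half, ang + half)

    return GroupComparison(
        metric, ang1, ang2, arc_ci(ang1, r1bar, n1), arc_ci(ang2, r2bar, n2),
        F, "F", p, n1, n2, N - 2, notes,
    )
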