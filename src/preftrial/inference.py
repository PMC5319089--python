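"""Variances, z-tests and confidence intervals for the trial contrasts.

Two variance regimes are provided.

*Unconditional* variances account for sampling variability of the preference
split in the choice arm and allow a different outcome variance in every
subgroup.  They are delta-method expansions of the ratio estimators: first
the variance of the numerator statistic ``T`` (or ``T*``), then a correction
for the random denominator ``2*alpha_hat*beta_hat*m``.

*Conditional* variances treat the preference split as fixed and assume a
common outcome variance, estimated by pooling the six observable subgroup
SDs.  On realistic data the two regimes are numerically very close, and the
conditional forms are available for the second contrasts as well.

All tests are large-sample normal: ``z = estimate / SE`` with two-sided
p-values and ``estimate ± z_crit * SE`` intervals.  A stratified bootstrap
is provided for cases without a closed-form variance (the unconditional
second contrasts).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from . import estimation
from .errors import (
    EstimationImpossibleError,
    PreferenceTrialError,
    UndefinedContrastError,
)
from .trial_data import ParticipantRecord, TrialSummary, _records_to_arrays

__all__ = [
    "VarianceInputs",
    "TestResult",
    "pooled_sd",
    "var_T",
    "var_contrast_unconditional",
    "var_contrast_conditional",
    "test_contrast",
    "bootstrap_se",
]


@dataclass(frozen=True)
class VarianceInputs:
    """Plug-in quantities entering the variance formulas.

    ``d_i`` measure how choosers of treatment i differ from the random arm
    on that treatment; ``e_i`` how they differ from undecideds on that
    treatment.  ``theta`` is the choice-arm allocation fraction.
    """

    d1: float
    d2: float
    e1: float
    e2: float
    theta: float
    var11: float
    var22: float
    var13: float
    var23: float
    var1: float
    var2: float

    @classmethod
    def from_summary(cls, s: TrialSummary) -> "VarianceInputs":
        has_undecided = s.m3 > 0
        return cls(
            d1=s.xbar1 - s.ybar1,
            d2=s.xbar2 - s.ybar2,
            e1=(s.xbar1 - s.vbar1) if has_undecided else 0.0,
            e2=(s.xbar2 - s.vbar2) if has_undecided else 0.0,
            theta=s.theta_hat,
            var11=s.s11**2,
            var22=s.s22**2,
            var13=s.s13**2 if has_undecided else 0.0,
            var23=s.s23**2 if has_undecided else 0.0,
            var1=s.s1**2,
            var2=s.s2**2,
        )


@dataclass(frozen=True)
class TestResult:
    """A tested contrast: estimate, SE, z, two-sided p and CI."""

    effect: str
    estimate: float
    se: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    level: float
    method: str
    formula_id: str
    statistic: float | None = None  # numerator statistic T / T*, when applicable
    statistic_var: float | None = None

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "estimate": self.estimate,
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "method": self.method,
            "formula_id": self.formula_id,
        }


# ---------------------------------------------------------------------------
# pooled SD
# ---------------------------------------------------------------------------


def pooled_sd(s: TrialSummary) -> float:
    """SD pooled over the observable subgroups (df = N − number of cells)."""
    cells = [
        (s.m1, s.s11), (s.m2, s.s22),
        (s.n13, s.s13), (s.n23, s.s23),
        (s.n1, s.s1), (s.n2, s.s2),
    ]
    ss = 0.0
    df = 0
    for n, sd in cells:
        if n == 0:
            continue
        if math.isnan(sd):
            raise EstimationImpossibleError(
                "a subgroup with fewer than 2 members has no sample SD; "
                "use the unconditional per-cell variance mode instead"
            )
        ss += (n - 1) * sd**2
        df += n - 1
    if df <= 0:
        raise EstimationImpossibleError("no degrees of freedom to pool an SD")
    return math.sqrt(ss / df)


# ---------------------------------------------------------------------------
# unconditional variances
# ---------------------------------------------------------------------------


def _which_sign(which: str) -> int:
    which = estimation.canonical_effect(which)
    if which == "selection1":
        return -1
    if which == "preference1":
        return +1
    raise UndefinedContrastError(
        f"closed-form unconditional variance exists only for the first "
        f"contrasts, not {which!r}; use the stratified bootstrap"
    )


def var_T(s: TrialSummary, which: str = "selection") -> float:
    """Variance of the numerator statistic T (selection) or T* (preference).

    The two formulas differ only in the sign pattern on the cross terms:
    ``(a d1 ∓ b d2)^2``, ``(a e1 ∓ b e2)^2`` and ``±2ab(d1 e2 − e1 d2)``.
    Assumes the random arm is split evenly between treatments.
    """
    sgn = _which_sign(which)
    if s.theta_hat >= 1.0:
        raise EstimationImpossibleError("random arm is empty (theta = 1)")
    vi = VarianceInputs.from_summary(s)
    a, b, g = s.alpha_hat, s.beta_hat, s.gamma_hat
    th = vi.theta
    d1, d2, e1, e2 = vi.d1, vi.d2, vi.e1, vi.e2
    term = (
        a * d1**2
        + b * d2**2
        - (a * d1 + sgn * b * d2) ** 2
        + (1 - g) ** 2 * (a * vi.var11 + b * vi.var22)
        + 2 * (th / (1 - th)) * (a**2 * vi.var1 + b**2 * vi.var2)
        + 2 * g * (a**2 * vi.var13 + b**2 * vi.var23)
        + g * (1 - 4 * g) * (a * e1 + sgn * b * e2) ** 2
        + g**2 * (a * e1**2 + b * e2**2)
        - 2
        * g
        * (
            a * (1 - 2 * a) * d1 * e1
            + b * (1 - 2 * b) * d2 * e2
            - sgn * 2 * a * b * (d1 * e2 - e1 * d2)
        )
    )
    return s.m * term


def var_contrast_unconditional(s: TrialSummary, which: str = "selection") -> float:
    """Delta-method variance of the first selection or preference contrast.

    Starts from ``var(T)`` and corrects for the sampling variability of the
    random denominator ``2*alpha_hat*beta_hat*m``.  Tiny negative values
    arising from the correction are clipped to 0 with a warning.
    """
    sgn = _which_sign(which)
    c = estimation.components(s)
    a, b, g, m = c.alpha_hat, c.beta_hat, c.gamma_hat, c.m
    vi = VarianceInputs.from_summary(s)
    d1, d2, e1, e2 = vi.d1, vi.d2, vi.e1, vi.e2
    if sgn < 0:
        T = (c.z1 - c.z2) - g * (c.w1 - c.w2)
        vt = var_T(s, "selection")
    else:
        T = (c.z1 + c.z2) - g * (c.w1 + c.w2)
        vt = var_T(s, "preference")
    corr = (
        a * (1 - 2 * a) * d1
        - b * (1 - 2 * b) * d2
        + sgn * a * b * ((1 - 4 * a) * e1 - (1 - 4 * b) * e2)
    )
    num = vt + (T**2 / (m * a * b)) * (a + b - 4 * a * b) - (2 * T * g / (a * b)) * corr
    var = num / (2 * a * b * m) ** 2
    if var < 0:
        warnings.warn(
            "delta-method variance correction produced a negative value; "
            "clipping to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        var = 0.0
    return var


# ---------------------------------------------------------------------------
# conditional (equal-variance, fixed-preference-split) variances
# ---------------------------------------------------------------------------


def var_contrast_conditional(s: TrialSummary, which: str) -> float:
    """Equal-variance, fixed-preference-split variance of a contrast.

    The two first contrasts share one value, as do the two second contrasts.
    Requires a defined pooled SD; the second-contrast form additionally
    requires an undecided stratum (gamma_hat > 0).
    """
    which = estimation.canonical_effect(which)
    sigma2 = pooled_sd(s) ** 2
    a, b, g = s.alpha_hat, s.beta_hat, s.gamma_hat
    m, th = s.m, s.theta_hat
    if th >= 1.0:
        raise EstimationImpossibleError("random arm is empty (theta = 1)")
    odds = th / (1 - th)
    if which in ("selection1", "preference1"):
        return (sigma2 / (4 * a**2 * b**2 * m)) * (
            (1 - g) ** 3 + 2 * (a**2 + b**2) * (g + odds)
        )
    if which in ("selection2", "preference2"):
        if g == 0:
            raise UndefinedContrastError(
                "second-contrast variance undefined without undecided participants"
            )
        return (sigma2 / (16 * a**2 * b**2 * g * m)) * (
            g * (1 - g) * (a - b) ** 2
            + 2 * (a**2 * (2 * b + g) ** 2 + b**2 * (2 * a + g) ** 2)
            + 2 * g * (a**2 + b**2) * odds
        )
    raise UndefinedContrastError(
        "conditional variance applies to the selection/preference contrasts; "
        "use pooled_sd for the treatment effect"
    )


def treatment_se(s: TrialSummary, method: str = "conditional") -> float:
    """SE of the direct treatment effect.

    ``conditional`` uses the pooled SD with the actual random-arm counts;
    ``unconditional`` uses the per-cell (Welch-style) variances.
    """
    if s.n1 == 0 or s.n2 == 0:
        raise EstimationImpossibleError("random-arm cell is empty")
    if method == "unconditional":
        return math.sqrt(s.s1**2 / s.n1 + s.s2**2 / s.n2)
    return pooled_sd(s) * math.sqrt(1 / s.n1 + 1 / s.n2)


# ---------------------------------------------------------------------------
# z-tests and confidence intervals
# ---------------------------------------------------------------------------


def _normal_test(estimate: float, se: float, level: float) -> tuple[float, float, float, float]:
    if se < 0 or not math.isfinite(se):
        raise PreferenceTrialError(f"invalid standard error {se!r}")
    if se == 0:
        z = 0.0 if estimate == 0 else math.copysign(math.inf, estimate)
    else:
        z = estimate / se
    p = 2 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    crit = stats.norm.ppf(0.5 + level / 2)
    return z, float(p), estimate - crit * se, estimate + crit * se


def test_contrast(
    s: TrialSummary,
    which: str,
    method: str = "conditional",
    level: float = 0.95,
    *,
    records: Sequence[ParticipantRecord] | None = None,
    n_boot: int = 2000,
    seed: int | None = None,
) -> TestResult:
    """Estimate one contrast and attach SE, z, p and a CI.

    ``method`` is ``"conditional"`` (pooled SD, preference split fixed),
    ``"unconditional"`` (per-cell variances, delta method; first contrasts
    and treatment effect only) or ``"bootstrap"`` (requires ``records``).
    """
    which = estimation.canonical_effect(which)
    if not 0 < level < 1:
        raise PreferenceTrialError("confidence level must be in (0, 1)")
    est = estimation.estimate(s, which)
    statistic = statistic_var = None
    if method == "bootstrap":
        if records is None:
            raise PreferenceTrialError("bootstrap method needs individual-level records")
        se = bootstrap_se(records, which, n_boot=n_boot, seed=seed)
        formula = "stratified-bootstrap"
    elif which == "treatment":
        if method not in ("conditional", "unconditional"):
            raise PreferenceTrialError(f"unknown method {method!r}")
        se = treatment_se(s, method)
        formula = f"{method}-treatment-se"
    elif method == "conditional":
        se = math.sqrt(var_contrast_conditional(s, which))
        formula = "conditional-equal-variance"
    elif method == "unconditional":
        se = math.sqrt(var_contrast_unconditional(s, which))
        c = estimation.components(s)
        if which == "selection1":
            statistic = (c.z1 - c.z2) - c.gamma_hat * (c.w1 - c.w2)
            statistic_var = var_T(s, "selection")
        else:
            statistic = (c.z1 + c.z2) - c.gamma_hat * (c.w1 + c.w2)
            statistic_var = var_T(s, "preference")
        formula = "unconditional-delta-method"
    else:
        raise PreferenceTrialError(f"unknown method {method!r}")
    if statistic is not None:
        # test on the numerator statistic: z = T / sqrt(var T).  The contrast
        # is T divided by a *random* denominator, and the delta-method SE
        # below inherits noise from the realised T in its correction terms,
        # which makes estimate/SE anticonservative; the numerator test keeps
        # the nominal level.  The delta-method SE still sets the interval.
        z, p, _, _ = _normal_test(statistic, math.sqrt(statistic_var), level)
        _, _, lo, hi = _normal_test(est.estimate, se, level)
    else:
        z, p, lo, hi = _normal_test(est.estimate, se, level)
    return TestResult(
        effect=which,
        estimate=est.estimate,
        se=se,
        z=z,
        p=p,
        ci_low=lo,
        ci_high=hi,
        level=level,
        method=method,
        formula_id=formula,
        statistic=statistic,
        statistic_var=statistic_var,
    )


# ---------------------------------------------------------------------------
# stratified bootstrap
# ---------------------------------------------------------------------------


def bootstrap_se(
    records: Sequence[ParticipantRecord],
    which: str,
    n_boot: int = 1000,
    seed: int | None = None,
) -> float:
    """Bootstrap SE of a contrast, resampling within the six observable cells.

    Stratifying by cell keeps every subgroup size fixed, so no resample can
    lose a required cell.  Deterministic for a given seed.
    """
    which = estimation.canonical_effect(which)
    if n_boot < 100:
        raise PreferenceTrialError("use at least 100 bootstrap resamples")
    records = list(records)
    is_choice, pref, treat, outcome = _records_to_arrays(records)
    masks = [
        is_choice & (pref == 0),
        is_choice & (pref == 1),
        is_choice & (pref == 2) & (treat == 0),
        is_choice & (pref == 2) & (treat == 1),
        ~is_choice & (treat == 0),
        ~is_choice & (treat == 1),
    ]
    cells = [outcome[mk] for mk in masks]
    estimation.estimate(_summary_like(cells), which)  # raises early on degenerate designs
    rng = np.random.default_rng(seed)
    fn = estimation._ESTIMATORS[which]
    out = np.empty(n_boot)
    for i in range(n_boot):
        resampled = [
            c[rng.integers(0, c.size, c.size)] if c.size else c for c in cells
        ]
        out[i] = fn(_summary_like(resampled)).estimate
    return float(np.std(out, ddof=1))


def _summary_like(cells: list[np.ndarray]) -> TrialSummary:
    """TrialSummary from six raw outcome vectors (chooser A/B, undecided A/B,
    random A/B)."""

    def ms(c: np.ndarray) -> tuple[float, float]:
        if c.size == 0:
            return math.nan, math.nan
        if c.size == 1:
            return float(c[0]), math.nan
        return float(np.mean(c)), float(np.std(c, ddof=1))

    stats_ = [ms(c) for c in cells]
    return TrialSummary(
        m1=cells[0].size, m2=cells[1].size,
        m3=cells[2].size + cells[3].size,
        n13=cells[2].size, n23=cells[3].size,
        n1=cells[4].size, n2=cells[5].size,
        xbar1=stats_[0][0], xbar2=stats_[1][0],
        vbar1=stats_[2][0], vbar2=stats_[3][0],
        ybar1=stats_[4][0], ybar2=stats_[5][0],
        s11=stats_[0][1], s22=stats_[1][1],
        s13=stats_[2][1], s23=stats_[3][1],
        s1=stats_[4][1], s2=stats_[5][1],
    )
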