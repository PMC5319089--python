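"""Testable characterisations of the undecided stratum, and the bias from
ignoring it.

Two simplifying assumptions about undecided participants recur in the
literature on this design:

* *no selection/preference effects for undecideds* — their expected outcome
  on each treatment equals the random-arm mean on that treatment
  (``mu_i3 = mu_i``); and
* the *exclusion restriction* — expected outcome depends only on the
  treatment received, so choosers and undecideds on the same treatment have
  the same mean (``mu_ii = mu_i3``).

Both are empirically testable here because the undecideds are re-randomised
inside the choice arm.  Adopting either assumption when it is false — or
simply discarding the undecideds — biases the selection and preference
estimators; :func:`bias_if_ignored` quantifies that bias analytically from a
generating model.
"""

from __future__ import annotations

import math

import pandas as pd

from . import estimation
from .errors import UndefinedContrastError
from .inference import TestResult, _normal_test, pooled_sd
from .simulate import ModelParams, solve_cell_means
from .trial_data import TrialSummary

__all__ = [
    "test_rucker_assumption",
    "test_exclusion_restriction",
    "joint_chi2",
    "bias_if_ignored",
    "drop_undecideds_estimate",
    "assumption_table",
]


def _pair_test(
    s: TrialSummary,
    diffs: tuple[float, float],
    counts: tuple[tuple[int, int], tuple[int, int]],
    names: tuple[str, str],
    formula: str,
    pooled: bool,
    cell_vars: tuple[tuple[float, float], tuple[float, float]],
    level: float,
) -> tuple[TestResult, TestResult]:
    if s.m3 == 0:
        raise UndefinedContrastError("no undecided participants to compare")
    sp = pooled_sd(s) if pooled else None
    out = []
    for diff, (na, nb), name, (va, vb) in zip(diffs, counts, names, cell_vars):
        if na == 0 or nb == 0:
            raise UndefinedContrastError(f"empty cell in comparison {name}")
        if pooled:
            se = sp * math.sqrt(1 / na + 1 / nb)
        else:
            se = math.sqrt(va / na + vb / nb)
        z, p, lo, hi = _normal_test(diff, se, level)
        out.append(
            TestResult(
                effect=name, estimate=diff, se=se, z=z, p=p,
                ci_low=lo, ci_high=hi, level=level,
                method="pooled" if pooled else "welch", formula_id=formula,
            )
        )
    return tuple(out)


def test_rucker_assumption(
    s: TrialSummary, *, pooled: bool = True, level: float = 0.95
) -> tuple[TestResult, TestResult]:
    """Test mu_i3 = mu_i: undecideds vs the random arm, per treatment.

    Compares the undecided mean with the random-arm mean on each treatment
    using a two-sample z-test (pooled SD by default, per-cell Welch
    variances with ``pooled=False``).
    """
    return _pair_test(
        s,
        diffs=(s.vbar1 - s.ybar1, s.vbar2 - s.ybar2),
        counts=((s.n13, s.n1), (s.n23, s.n2)),
        names=("undecided_vs_random_A", "undecided_vs_random_B"),
        formula="undecided-equals-random",
        pooled=pooled,
        cell_vars=((s.s13**2, s.s1**2), (s.s23**2, s.s2**2)),
        level=level,
    )


def test_exclusion_restriction(
    s: TrialSummary, *, pooled: bool = True, level: float = 0.95
) -> tuple[TestResult, TestResult]:
    """Test mu_ii = mu_i3: choosers vs undecideds on the same treatment."""
    return _pair_test(
        s,
        diffs=(s.xbar1 - s.vbar1, s.xbar2 - s.vbar2),
        counts=((s.m1, s.n13), (s.m2, s.n23)),
        names=("chooser_vs_undecided_A", "chooser_vs_undecided_B"),
        formula="exclusion-restriction",
        pooled=pooled,
        cell_vars=((s.s11**2, s.s13**2), (s.s22**2, s.s23**2)),
        level=level,
    )


def joint_chi2(pair: tuple[TestResult, TestResult]) -> tuple[float, float]:
    """Joint 2-df chi-square combining the two per-treatment z-tests.

    An extension beyond the per-treatment tests: under the joint null the
    two z statistics are approximately independent standard normals.
    """
    from scipy import stats

    stat = pair[0].z ** 2 + pair[1].z ** 2
    return float(stat), float(stats.chi2.sf(stat, df=2))


def assumption_table(s: TrialSummary, *, pooled: bool = True) -> pd.DataFrame:
    """Both assumption checks as a tidy table (assumption, cell, diff, z, p)."""
    rows = []
    for label, pair in (
        ("undecided = random arm", test_rucker_assumption(s, pooled=pooled)),
        ("exclusion restriction", test_exclusion_restriction(s, pooled=pooled)),
    ):
        for r, cell in zip(pair, ("A", "B")):
            rows.append(
                {"assumption": label, "treatment": cell,
                 "difference": r.estimate, "se": r.se, "z": r.z, "p": r.p}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bias from ignoring the undecided stratum
# ---------------------------------------------------------------------------


def drop_undecideds_estimate(
    s: TrialSummary, which: str, *, renormalize: bool = False
) -> float:
    """The first selection/preference contrast as a gamma=0-style analysis
    would compute it, i.e. discarding the undecideds' outcome data.

    With ``renormalize=False`` the undecided terms are simply dropped from
    the estimator while the observed preference proportions are kept; with
    ``renormalize=True`` the analysis pretends the undecideds never existed
    (proportions renormalised over deciders only).
    """
    which = estimation.canonical_effect(which)
    if which not in ("selection1", "preference1"):
        raise UndefinedContrastError("drop-undecideds analysis applies to the first contrasts")
    c = estimation.components(s)
    sgn = -1 if which == "selection1" else +1
    num = c.z1 + sgn * c.z2
    if renormalize:
        m_dec = s.m1 + s.m2
        a_star = s.m1 / m_dec
        b_star = s.m2 / m_dec
        return num / (2 * a_star * b_star * m_dec)
    return num / (2 * c.alpha_hat * c.beta_hat * c.m)


def bias_if_ignored(p: ModelParams, *, renormalize: bool = False) -> dict[str, float]:
    """Asymptotic bias of the drop-undecideds analysis for the first contrasts.

    Computed from the generating cell-mean grid: the probability limit of
    the gamma=0-style estimator minus the true contrast.  With the default
    (non-renormalised) form the bias vanishes exactly whenever the
    exclusion-restriction differences ``e1 = e2 = 0``, and it tends to 0 as
    the undecided fraction does.
    """
    if p.gamma < 0:
        raise ValueError("gamma must be >= 0")
    cm = solve_cell_means(p)
    a, b = p.alpha, p.beta
    d1 = cm.mu[0, 0] - cm.mu1
    d2 = cm.mu[1, 1] - cm.mu2
    factor = (a + b) if renormalize else 1.0
    plim_nu = factor * (a * d1 - b * d2) / (2 * a * b)
    plim_pi = factor * (a * d1 + b * d2) / (2 * a * b)
    return {
        "selection1": plim_nu - p.delta_nu,
        "preference1": plim_pi - p.delta_pi,
    }
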