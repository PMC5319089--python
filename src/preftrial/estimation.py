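"""Point estimators for the treatment, selection and preference effects.

Five contrasts are estimable in a two-stage preference trial with an
undecided stratum:

* ``treatment``    — direct effect of A vs B, from the random arm alone;
* ``selection1``   — outcome difference between would-be choosers of A and
  of B, regardless of treatment received;
* ``preference1``  — interaction between preferred and received treatment
  (difference of A−B effects between the two decided preference groups);
* ``selection2``   — undecided vs the average of the two decided groups, in
  outcome level;
* ``preference2``  — undecided vs decided, in treatment effect.

The first-stage randomisation makes the random-arm marginal mean a
preference-weighted average of the (partly unobservable) cell means, which
is what identifies the selection and preference contrasts.  Each contrast
has two algebraically equivalent computational routes: a compact form in the
``z``/``w`` building blocks below, and a "mean-form" plug-in directly on the
six observable means.  Both are implemented; the package computes with the
z/w forms and the mean forms serve as an internal cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import (
    DegenerateDesignError,
    EstimationImpossibleError,
    UndefinedContrastError,
)
from .trial_data import CellMeans, TrialSummary

EFFECTS = ("treatment", "selection1", "selection2", "preference1", "preference2")

_ALIASES = {
    "selection": "selection1",
    "preference": "preference1",
    "selection_2": "selection2",
    "preference_2": "preference2",
}


def canonical_effect(which: str) -> str:
    w = _ALIASES.get(which, which)
    if w not in EFFECTS:
        raise ValueError(f"unknown effect {which!r}; expected one of {EFFECTS}")
    return w


@dataclass(frozen=True)
class ContrastComponents:
    """The four weighted mean-difference building blocks.

    ``z_i = m_i (X̄_i − Ȳ_i)`` compares choosers of treatment i with the
    random arm on the same treatment; ``w_i = m_i (X̄_i − V̄_i)`` compares
    them with the undecideds on that treatment.  When there are no
    undecideds the ``w`` terms are defined as 0 (they are multiplied by
    ``gamma_hat = 0`` everywhere downstream).
    """

    z1: float
    z2: float
    w1: float
    w2: float
    alpha_hat: float
    beta_hat: float
    gamma_hat: float
    m: int


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate with provenance; variance is attached by inference."""

    effect: str
    estimate: float
    variance: float | None = None
    method: str | None = None
    formula_id: str = ""

    def __post_init__(self) -> None:
        if self.variance is not None and self.variance < 0:
            raise ValueError("variance must be >= 0")


def _check_design(s: TrialSummary) -> None:
    if s.m1 == 0 or s.m2 == 0:
        raise DegenerateDesignError(
            "both treatments must be chosen by someone in the choice arm "
            f"(m1={s.m1}, m2={s.m2}): denominators 2*alpha*beta*m vanish"
        )
    if s.n1 == 0 or s.n2 == 0:
        raise EstimationImpossibleError("random-arm cell is empty")
    if s.m3 > 0 and (s.n13 == 0 or s.n23 == 0):
        raise EstimationImpossibleError(
            "undecided participants present but one re-randomised cell is empty"
        )


def components(s: TrialSummary) -> ContrastComponents:
    """Compute z1, z2, w1, w2 and the empirical preference proportions."""
    _check_design(s)
    z1 = s.m1 * (s.xbar1 - s.ybar1)
    z2 = s.m2 * (s.xbar2 - s.ybar2)
    if s.m3 == 0:
        w1 = w2 = 0.0
    else:
        w1 = s.m1 * (s.xbar1 - s.vbar1)
        w2 = s.m2 * (s.xbar2 - s.vbar2)
    return ContrastComponents(
        z1=z1, z2=z2, w1=w1, w2=w2,
        alpha_hat=s.alpha_hat, beta_hat=s.beta_hat, gamma_hat=s.gamma_hat,
        m=s.m,
    )


# ---------------------------------------------------------------------------
# the five contrasts, z/w forms
# ---------------------------------------------------------------------------


def treatment_effect(s: TrialSummary) -> EffectEstimate:
    """Direct treatment effect: difference of random-arm means."""
    if s.n1 == 0 or s.n2 == 0:
        raise EstimationImpossibleError("random-arm cell is empty")
    return EffectEstimate(
        effect="treatment",
        estimate=s.ybar1 - s.ybar2,
        formula_id="random-arm-difference",
    )


def selection_effect(s: TrialSummary) -> EffectEstimate:
    """First selection contrast: would-be choosers of A vs of B."""
    c = components(s)
    est = ((c.z1 - c.z2) - c.gamma_hat * (c.w1 - c.w2)) / (
        2 * c.alpha_hat * c.beta_hat * c.m
    )
    return EffectEstimate(effect="selection1", estimate=est, formula_id="zw-first-selection")


def preference_effect(s: TrialSummary) -> EffectEstimate:
    """First preference contrast: treatment-by-preference interaction."""
    c = components(s)
    est = ((c.z1 + c.z2) - c.gamma_hat * (c.w1 + c.w2)) / (
        2 * c.alpha_hat * c.beta_hat * c.m
    )
    return EffectEstimate(effect="preference1", estimate=est, formula_id="zw-first-preference")


def _require_undecided(s: TrialSummary) -> None:
    if s.m3 == 0:
        raise UndefinedContrastError(
            "second contrasts compare the undecided stratum with the decided "
            "groups and are undefined when no participant is undecided"
        )


def selection_effect_2(s: TrialSummary) -> EffectEstimate:
    """Second selection contrast: undecided vs decided, in outcome level."""
    _require_undecided(s)
    c = components(s)
    est = (
        (c.z1 + c.z2) - (c.w1 + c.w2) + (c.alpha_hat - c.beta_hat) * (c.w1 - c.w2)
    ) / (4 * c.alpha_hat * c.beta_hat * c.m)
    return EffectEstimate(effect="selection2", estimate=est, formula_id="zw-second-selection")


def preference_effect_2(s: TrialSummary) -> EffectEstimate:
    """Second preference contrast: undecided vs decided, in treatment effect."""
    _require_undecided(s)
    c = components(s)
    est = (
        -(c.z1 - c.z2) + (c.w1 - c.w2) - (c.alpha_hat - c.beta_hat) * (c.w1 + c.w2)
    ) / (4 * c.alpha_hat * c.beta_hat * c.m)
    return EffectEstimate(effect="preference2", estimate=est, formula_id="zw-second-preference")


_ESTIMATORS = {
    "treatment": treatment_effect,
    "selection1": selection_effect,
    "preference1": preference_effect,
    "selection2": selection_effect_2,
    "preference2": preference_effect_2,
}


def estimate(s: TrialSummary, which: str) -> EffectEstimate:
    """Dispatch to the estimator for one of the five contrasts."""
    return _ESTIMATORS[canonical_effect(which)](s)


def estimate_all(s: TrialSummary) -> dict[str, EffectEstimate]:
    """All contrasts estimable from this summary (second contrasts skipped
    when there are no undecideds)."""
    out = {}
    for name, fn in _ESTIMATORS.items():
        try:
            out[name] = fn(s)
        except UndefinedContrastError:
            continue
    return out


# ---------------------------------------------------------------------------
# mean-form plug-ins: the same contrasts written directly in the observable
# subgroup means.  Algebraically identical to the z/w forms; kept as an
# independent computational route.
# ---------------------------------------------------------------------------


def _plugin_quantities(s: TrialSummary):
    _check_design(s)
    a, b, g = s.alpha_hat, s.beta_hat, s.gamma_hat
    x1, x2, y1, y2 = s.xbar1, s.xbar2, s.ybar1, s.ybar2
    # with gamma-hat = 0 the undecided means enter only via terms that are
    # multiplied by gamma-hat; zero them so NaN placeholders cannot propagate
    v1 = s.vbar1 if s.m3 > 0 else 0.0
    v2 = s.vbar2 if s.m3 > 0 else 0.0
    return a, b, g, x1, x2, v1, v2, y1, y2


def selection_effect_mean_form(s: TrialSummary) -> float:
    a, b, g, x1, x2, v1, v2, y1, y2 = _plugin_quantities(s)
    return 0.5 * (
        x1 * (1 + a / b) - y1 / b + y2 / a - x2 * (1 + b / a) - v2 * g / a + v1 * g / b
    )


def preference_effect_mean_form(s: TrialSummary) -> float:
    a, b, g, x1, x2, v1, v2, y1, y2 = _plugin_quantities(s)
    return 0.5 * (
        x1 * (1 + a / b) - y1 / b - y2 / a + x2 * (1 + b / a) + v1 * g / b + v2 * g / a
    )


def selection_effect_2_mean_form(s: TrialSummary) -> float:
    _require_undecided(s)
    a, b, g, x1, x2, v1, v2, y1, y2 = _plugin_quantities(s)
    return (
        a * (x1 - y1)
        + b * (x2 - y2)
        - 2 * a * b * (x1 + x2 - v1 - v2)
        - g * (a * (x1 - v1) + b * (x2 - v2))
    ) / (4 * a * b)


def preference_effect_2_mean_form(s: TrialSummary) -> float:
    _require_undecided(s)
    a, b, g, x1, x2, v1, v2, y1, y2 = _plugin_quantities(s)
    return (
        a * (y1 - x1)
        - b * (y2 - x2)
        + 2 * a * b * (x1 - x2 - v1 + v2)
        + g * (a * (x1 - v1) - b * (x2 - v2))
    ) / (4 * a * b)


MEAN_FORMS = {
    "selection1": selection_effect_mean_form,
    "preference1": preference_effect_mean_form,
    "selection2": selection_effect_2_mean_form,
    "preference2": preference_effect_2_mean_form,
}


# ---------------------------------------------------------------------------
# imputing the unobservable cells and reading contrasts off a full grid
# ---------------------------------------------------------------------------


def impute_unobservable_means(s: TrialSummary) -> CellMeans:
    """Fill the two unobservable cell means via the arm-equivalence identity.

    Choosers always receive their chosen treatment, so nobody who prefers B
    is ever observed on A (and vice versa).  But the random-arm mean on each
    treatment is the preference-weighted average of all three cell means on
    that treatment, which can be solved for the missing cell:

    ``mu12 = (mu1 - alpha*mu11 - gamma*mu13) / beta`` and symmetrically
    ``mu21 = (mu2 - beta*mu22 - gamma*mu23) / alpha``.
    """
    a, b, g, x1, x2, v1, v2, y1, y2 = _plugin_quantities(s)
    mu12 = (y1 - a * x1 - g * v1) / b
    mu21 = (y2 - b * x2 - g * v2) / a
    grid = [[x1, mu12, s.vbar1], [mu21, x2, s.vbar2]]
    return CellMeans(mu=grid, mu1=y1, mu2=y2)


def contrasts_from_grid(cm: CellMeans) -> dict[str, float]:
    """Evaluate all five contrasts from a full 2x3 grid plus marginals.

    Used both on imputed grids (consistency check against the z/w
    estimators) and on population grids from the simulator (round-trip
    check of the constraint solver).
    """
    mu = cm.mu
    d_by_group = mu[0] - mu[1]  # A-minus-B effect within each preference group
    return {
        "treatment": cm.mu1 - cm.mu2,
        "selection1": ((mu[0, 0] + mu[1, 0]) - (mu[0, 1] + mu[1, 1])) / 2.0,
        "preference1": ((mu[0, 0] - mu[1, 0]) - (mu[0, 1] - mu[1, 1])) / 2.0,
        "selection2": ((mu[0, 2] + mu[1, 2]) - (mu[0, 0] + mu[1, 0] + mu[0, 1] + mu[1, 1]) / 2.0) / 2.0,
        "preference2": ((d_by_group[0] + d_by_group[1]) / 2.0 - d_by_group[2]) / 2.0,
    }
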