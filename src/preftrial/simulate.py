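"""Trial simulator for the two-stage preference design.

Outcomes follow the linear model ``Y = mu + tau_i + nu_j + pi_ij + eps`` with
treatment effects ``tau``, selection effects ``nu`` (by preference group),
preference-by-treatment interactions ``pi`` and independent errors.  The
redundancies are removed by the usual constraints: ``tau1 + tau2 = 0``, the
preference-weighted sums ``a*nu1 + b*nu2 + g*nu3`` and
``a*pi_i1 + b*pi_i2 + g*pi_i3`` vanish, and ``pi_1j + pi_2j = 0``.

A generating model is specified by the grand mean, the five contrast values,
the preference probabilities, the choice-arm allocation fraction, the error
SD and the total sample size.  The default parameter values reproduce the
conditions of the bundled menstrual-bleeding trial (its observed preference
split, allocation fraction, pooled SD and effect estimates), so that
simulation studies validate the variance formulas under realistic
conditions without any external data.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import estimation, inference
from .errors import PreferenceTrialError, UndefinedContrastError, ValidationError
from .trial_data import (
    ARM_CHOICE,
    ARM_RANDOM,
    NO_PREFERENCE,
    TREATMENT_A,
    TREATMENT_B,
    CellMeans,
    ParticipantRecord,
    TrialSummary,
    _summary_from_arrays,
)

__all__ = [
    "ModelParams",
    "SimulationResult",
    "solve_cell_means",
    "expected_summary",
    "simulate_trial",
    "run_study",
]


@dataclass
class ModelParams:
    """Generating parameters for a simulated two-stage preference trial.

    Defaults mirror the bundled menstrual-bleeding trial: grand mean 11.15
    (bleeding score), treatment effect 12.1, selection/preference contrasts
    at the trial's full-precision estimates, preference probabilities
    19/130, 21/130, 90/130, choice-arm fraction 130/227, error SD 7.58 and
    N = 227.
    """

    mu: float = 11.15
    delta_tau: float = 12.1
    delta_nu: float = 3.05
    delta_nu2: float = 0.57
    delta_pi: float = 0.95
    delta_pi2: float = -3.23
    alpha: float = 19 / 130
    beta: float = 21 / 130
    gamma: float = 90 / 130
    theta: float = 130 / 227
    sigma: float = 7.58
    N: int = 227
    seed: int | None = None

    def __post_init__(self) -> None:
        probs = (self.alpha, self.beta, self.gamma)
        if any(p < 0 or p > 1 for p in probs):
            raise ValidationError("preference probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError(
                f"alpha + beta + gamma must sum to 1 (got {sum(probs):.6g})"
            )
        if self.alpha == 0 or self.beta == 0:
            raise ValidationError("alpha and beta must be positive")
        if not 0 < self.theta < 1:
            raise ValidationError("theta must lie strictly between 0 and 1")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.N < 12:
            raise ValidationError("N must be at least 12")

    def contrasts(self) -> dict[str, float]:
        return {
            "treatment": self.delta_tau,
            "selection1": self.delta_nu,
            "selection2": self.delta_nu2,
            "preference1": self.delta_pi,
            "preference2": self.delta_pi2,
        }

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


def solve_cell_means(p: ModelParams) -> CellMeans:
    """Solve the constraint system for the population 2x3 cell-mean grid.

    ``tau1 = -tau2 = delta_tau/2``; the ``nu`` and first-row ``pi`` vectors
    each solve a 3x3 linear system combining the weighted-sum constraint
    with the two contrast definitions; ``pi_2j = -pi_1j``.
    """
    a, b, g = p.alpha, p.beta, p.gamma
    if g == 0 and (p.delta_nu2 != 0 or p.delta_pi2 != 0):
        raise UndefinedContrastError(
            "second contrasts must be 0 when gamma = 0 (no undecided stratum)"
        )
    A_nu = np.array([[a, b, g], [1.0, -1.0, 0.0], [-0.5, -0.5, 1.0]])
    nu = np.linalg.solve(A_nu, [0.0, p.delta_nu, p.delta_nu2])
    A_pi = np.array([[a, b, g], [1.0, -1.0, 0.0], [0.5, 0.5, -1.0]])
    pi1 = np.linalg.solve(A_pi, [0.0, p.delta_pi, p.delta_pi2])
    tau = np.array([p.delta_tau / 2.0, -p.delta_tau / 2.0])
    pi = np.vstack([pi1, -pi1])
    grid = p.mu + tau[:, None] + nu[None, :] + pi
    mu1 = a * grid[0, 0] + b * grid[0, 1] + g * grid[0, 2]
    mu2 = a * grid[1, 0] + b * grid[1, 1] + g * grid[1, 2]
    return CellMeans(mu=grid, mu1=mu1, mu2=mu2)


def expected_summary(p: ModelParams) -> TrialSummary:
    """The six-cell summary implied by a generating model: expected counts
    (rounded to integers), population cell means and the common error SD.

    Useful for evaluating the variance formulas at the population inputs,
    e.g. to compare a formula against the empirical spread of estimates over
    simulated replicates.
    """
    cm = solve_cell_means(p)
    m = p.theta * p.N
    m1, m2, m3 = round(p.alpha * m), round(p.beta * m), round(p.gamma * m)
    n13 = m3 // 2
    n = p.N - (m1 + m2 + m3)
    n1 = n // 2
    return TrialSummary(
        m1=m1, m2=m2, m3=m3, n13=n13, n23=m3 - n13, n1=n1, n2=n - n1,
        xbar1=float(cm.mu[0, 0]), xbar2=float(cm.mu[1, 1]),
        vbar1=float(cm.mu[0, 2]), vbar2=float(cm.mu[1, 2]),
        ybar1=cm.mu1, ybar2=cm.mu2,
        s11=p.sigma, s22=p.sigma, s13=p.sigma, s23=p.sigma,
        s1=p.sigma, s2=p.sigma,
    )


# ---------------------------------------------------------------------------
# drawing one trial
# ---------------------------------------------------------------------------


def _coerce_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _split_even(idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Exact-halves treatment assignment for a block (odd leftover by a fair
    draw); returns 0/1 codes aligned with idx."""
    k = idx.size
    half = k // 2
    codes = np.zeros(k, dtype=np.int8)
    codes[half:] = 1
    if k % 2 == 1 and rng.random() < 0.5:
        codes = 1 - codes
    return codes[rng.permutation(k)]


def _draw_columns(
    p: ModelParams, rng: np.random.Generator, blocked: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw arm, preference, treatment and outcome for all N participants.

    RNG draw order is fixed (arm, preference, undecided randomisation,
    random-arm randomisation, noise) so a seed fully determines the trial.
    Random-arm preferences are drawn because they shape outcomes, but they
    are latent: record materialisation discards them.
    """
    grid = solve_cell_means(p).mu
    N = p.N
    if blocked:
        m = int(round(p.theta * N))
        is_choice = np.zeros(N, dtype=bool)
        is_choice[rng.permutation(N)[:m]] = True
    else:
        is_choice = rng.random(N) < p.theta
    u = rng.random(N)
    pref = np.int8(u > p.alpha) + np.int8(u > p.alpha + p.beta)
    treat = np.where(pref < 2, pref, np.int8(0)).astype(np.int8)
    undecided = is_choice & (pref == 2)
    random_arm = ~is_choice
    if blocked:
        for mask in (undecided, random_arm):
            idx = np.flatnonzero(mask)
            treat[idx] = _split_even(idx, rng)
    else:
        randomised = undecided | random_arm
        treat[randomised] = rng.integers(0, 2, int(randomised.sum()), dtype=np.int8)
    outcome = grid[treat, pref] + p.sigma * rng.standard_normal(N)
    return is_choice, pref, treat, outcome


def simulate_trial(
    p: ModelParams, seed=None, *, blocked: bool = False
) -> list[ParticipantRecord]:
    """Simulate one trial and return individual-level records.

    Each participant enters the choice arm with probability ``theta``;
    choice-arm preferences are multinomial(alpha, beta, gamma); choosers
    receive their preference; undecideds and random-arm participants are
    randomised 1:1 (independent fair draws by default, exact halves with
    ``blocked=True``).  Random-arm preference is latent and not recorded.
    """
    rng = _coerce_rng(p.seed if seed is None else seed)
    is_choice, pref, treat, outcome = _draw_columns(p, rng, blocked)
    trt_label = (TREATMENT_A, TREATMENT_B)
    records = []
    for i in range(p.N):
        if is_choice[i]:
            pr = NO_PREFERENCE if pref[i] == 2 else trt_label[pref[i]]
            records.append(
                ParticipantRecord(ARM_CHOICE, pr, trt_label[treat[i]], float(outcome[i]))
            )
        else:
            records.append(
                ParticipantRecord(ARM_RANDOM, None, trt_label[treat[i]], float(outcome[i]))
            )
    return records


# ---------------------------------------------------------------------------
# replicated studies
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Per-replicate estimates plus Monte-Carlo summaries."""

    params: ModelParams
    R: int
    seed: int | None
    level: float
    table: pd.DataFrame  # one row per successful replicate
    n_failed: int

    def summary(self) -> pd.DataFrame:
        """Per-effect Monte-Carlo summary: truth, mean estimate, bias,
        empirical SD, mean formula SEs and rejection rates."""
        truths = self.params.contrasts()
        rows = []
        for eff in estimation.EFFECTS:
            col = f"est_{eff}"
            if col not in self.table:
                continue
            est = self.table[col]
            row = {
                "effect": eff,
                "truth": truths[eff],
                "mean_estimate": est.mean(),
                "bias": est.mean() - truths[eff],
                "empirical_sd": est.std(ddof=1),
            }
            crit = _norm_crit(self.level)
            for kind in ("unconditional", "conditional"):
                se_col = f"se_{kind[:4]}_{eff}"
                if se_col in self.table:
                    se = self.table[se_col]
                    row[f"mean_se_{kind}"] = se.mean()
                    z_col = f"z_{kind[:4]}_{eff}"
                    z = self.table[z_col] if z_col in self.table else est / se
                    row[f"reject_{kind}"] = (z.abs() > crit).mean()
            rows.append(row)
        return pd.DataFrame(rows).set_index("effect")


def _norm_crit(level: float) -> float:
    from scipy import stats

    return float(stats.norm.ppf(0.5 + level / 2))


def run_study(
    p: ModelParams,
    R: int,
    seed: int | None = None,
    *,
    estimators: Sequence[str] = estimation.EFFECTS,
    level: float = 0.95,
    blocked: bool = False,
) -> SimulationResult:
    """Simulate R independent trials and collect estimates, SEs and tests.

    Replicate streams are spawned deterministically from the root seed, and
    a single replicate reproduces exactly what :func:`simulate_trial` +
    ``summarize`` + the estimators give for the same spawned stream.
    Replicates where an estimator is undefined (an empty required cell) are
    excluded and counted in ``n_failed``.
    """
    if R < 1:
        raise PreferenceTrialError("R must be >= 1")
    estimators = [estimation.canonical_effect(e) for e in estimators]
    if p.gamma == 0:
        estimators = [e for e in estimators if not e.endswith("2")]
    root = np.random.SeedSequence(p.seed if seed is None else seed)
    rows = []
    n_failed = 0
    for i, child in enumerate(root.spawn(R)):
        rng = np.random.default_rng(child)
        cols = _draw_columns(p, rng, blocked)
        try:
            s = _summary_from_arrays(*cols)
            row: dict[str, float] = {"replicate": i}
            for eff in estimators:
                row[f"est_{eff}"] = estimation.estimate(s, eff).estimate
                if eff == "treatment":
                    row[f"se_cond_{eff}"] = inference.treatment_se(s, "conditional")
                    row[f"se_unco_{eff}"] = inference.treatment_se(s, "unconditional")
                elif eff in ("selection1", "preference1"):
                    row[f"se_cond_{eff}"] = math.sqrt(
                        inference.var_contrast_conditional(s, eff)
                    )
                    res_u = inference.test_contrast(s, eff, method="unconditional")
                    row[f"se_unco_{eff}"] = res_u.se
                    row[f"z_unco_{eff}"] = res_u.z
                else:
                    row[f"se_cond_{eff}"] = math.sqrt(
                        inference.var_contrast_conditional(s, eff)
                    )
        except PreferenceTrialError:
            n_failed += 1
            continue
        rows.append(row)
    if not rows:
        raise PreferenceTrialError("every replicate failed; check the parameters")
    table = pd.DataFrame(rows)
    return SimulationResult(
        params=p, R=R, seed=seed, level=level, table=table, n_failed=n_failed
    )
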