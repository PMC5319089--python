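"""Data model and ingestion for two-stage randomised preference trials.

In this design every participant is first randomised between a *choice* arm
and a *random* arm.  Choice-arm participants who state a preference receive
the preferred treatment; those who are undecided are re-randomised between
the two treatments.  Random-arm participants are randomised in the usual way
and their (latent) preference is never observed.

The observable data therefore fall into six subgroups: choosers of A,
choosers of B, undecideds randomised to A or B, and random-arm participants
on A or B.  :class:`TrialSummary` holds the counts, means and sample SDs of
those six cells, which is all that every estimator in this package needs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EstimationImpossibleError, ValidationError

logger = logging.getLogger(__name__)

#: canonical category labels
ARM_CHOICE = "choice"
ARM_RANDOM = "random"
TREATMENT_A = "A"
TREATMENT_B = "B"
NO_PREFERENCE = "none"

_ARM_SYNONYMS = {
    "choice": ARM_CHOICE,
    "preference": ARM_CHOICE,
    "chooser": ARM_CHOICE,
    "random": ARM_RANDOM,
    "randomised": ARM_RANDOM,
    "randomized": ARM_RANDOM,
}
_PREF_SYNONYMS = {
    "a": TREATMENT_A,
    "b": TREATMENT_B,
    "none": NO_PREFERENCE,
    "undecided": NO_PREFERENCE,
    "no preference": NO_PREFERENCE,
    "indifferent": NO_PREFERENCE,
}


@dataclass(frozen=True, slots=True)
class ParticipantRecord:
    """One participant: trial arm, stated preference, treatment received, outcome.

    ``preference`` is ``None`` for random-arm participants (latent, never
    recorded) and ``"none"`` for choice-arm participants who declared no
    preference — an observed category, not missing data.
    """

    arm: str
    preference: str | None
    treatment: str
    outcome: float

    def __post_init__(self) -> None:
        if self.arm not in (ARM_CHOICE, ARM_RANDOM):
            raise ValidationError(f"unknown arm label {self.arm!r}")
        if self.treatment not in (TREATMENT_A, TREATMENT_B):
            raise ValidationError(f"unknown treatment label {self.treatment!r}")
        if self.arm == ARM_CHOICE:
            if self.preference not in (TREATMENT_A, TREATMENT_B, NO_PREFERENCE):
                raise ValidationError(
                    f"choice-arm record needs preference A/B/none, got {self.preference!r}"
                )
            if self.preference in (TREATMENT_A, TREATMENT_B) and self.treatment != self.preference:
                raise ValidationError(
                    f"chooser of {self.preference} recorded on treatment {self.treatment}"
                )
        elif self.preference is not None and self.preference not in (
            TREATMENT_A,
            TREATMENT_B,
            NO_PREFERENCE,
        ):
            raise ValidationError(f"unknown preference label {self.preference!r}")
        if not math.isfinite(self.outcome):
            raise ValidationError(f"outcome must be finite, got {self.outcome!r}")


@dataclass(frozen=True)
class TrialSummary:
    """Counts, means and sample SDs of the six observable subgroups.

    Index 1 refers to treatment A, index 2 to treatment B.  ``xbar``/``s11``
    etc. describe choosers, ``vbar``/``s13`` the undecideds after their
    re-randomisation, and ``ybar``/``s1`` the random arm.  SDs are sample SDs
    (denominator n−1) and are NaN when the cell has fewer than two members.
    """

    m1: int
    m2: int
    m3: int
    n13: int
    n23: int
    n1: int
    n2: int
    xbar1: float
    xbar2: float
    vbar1: float
    vbar2: float
    ybar1: float
    ybar2: float
    s11: float
    s22: float
    s13: float
    s23: float
    s1: float
    s2: float

    def __post_init__(self) -> None:
        for name in ("m1", "m2", "m3", "n13", "n23", "n1", "n2"):
            if getattr(self, name) < 0:
                raise ValidationError(f"count {name} must be >= 0")
        if self.n13 + self.n23 != self.m3:
            raise ValidationError("n13 + n23 must equal m3")
        for name in ("s11", "s22", "s13", "s23", "s1", "s2"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValidationError(f"SD {name} must be >= 0")

    # ----- derived design quantities -------------------------------------
    @property
    def m(self) -> int:
        """Choice-arm size m = m1 + m2 + m3."""
        return self.m1 + self.m2 + self.m3

    @property
    def n(self) -> int:
        """Random-arm size n = n1 + n2."""
        return self.n1 + self.n2

    @property
    def N(self) -> int:
        """Total analysable sample size."""
        return self.m + self.n

    @property
    def alpha_hat(self) -> float:
        """Observed proportion of the choice arm preferring A."""
        return self.m1 / self.m

    @property
    def beta_hat(self) -> float:
        return self.m2 / self.m

    @property
    def gamma_hat(self) -> float:
        """Observed proportion of the choice arm with no preference."""
        return self.m3 / self.m

    @property
    def theta_hat(self) -> float:
        """Observed fraction of the trial allocated to the choice arm."""
        return self.m / self.N

    # ----- transforms used throughout tests and docs ---------------------
    def swap_treatments(self) -> "TrialSummary":
        """Relabel A<->B; useful for checking sign symmetries."""
        return TrialSummary(
            m1=self.m2, m2=self.m1, m3=self.m3,
            n13=self.n23, n23=self.n13, n1=self.n2, n2=self.n1,
            xbar1=self.xbar2, xbar2=self.xbar1,
            vbar1=self.vbar2, vbar2=self.vbar1,
            ybar1=self.ybar2, ybar2=self.ybar1,
            s11=self.s22, s22=self.s11,
            s13=self.s23, s23=self.s13,
            s1=self.s2, s2=self.s1,
        )

    def shifted(self, c: float) -> "TrialSummary":
        """Add a constant to every outcome mean (SDs unchanged)."""
        return replace(
            self,
            xbar1=self.xbar1 + c, xbar2=self.xbar2 + c,
            vbar1=self.vbar1 + c, vbar2=self.vbar2 + c,
            ybar1=self.ybar1 + c, ybar2=self.ybar2 + c,
        )

    def scaled(self, k: float) -> "TrialSummary":
        """Multiply every outcome by k (means and SDs scale; SDs by |k|)."""
        a = abs(k)
        return replace(
            self,
            xbar1=self.xbar1 * k, xbar2=self.xbar2 * k,
            vbar1=self.vbar1 * k, vbar2=self.vbar2 * k,
            ybar1=self.ybar1 * k, ybar2=self.ybar2 * k,
            s11=self.s11 * a, s22=self.s22 * a,
            s13=self.s13 * a, s23=self.s23 * a,
            s1=self.s1 * a, s2=self.s2 * a,
        )


@dataclass(frozen=True)
class CellMeans:
    """The 2x3 grid of expected outcomes by treatment (rows: A, B) and
    preference group (columns: prefers-A, prefers-B, undecided), together
    with the random-arm marginal means.

    The first-stage randomisation forces the arm-equivalence identity
    ``mu_i = alpha*mu_i1 + beta*mu_i2 + gamma*mu_i3``, which is what lets the
    two unobservable cells (A-given-prefers-B and B-given-prefers-A) be
    imputed from observables.
    """

    mu: np.ndarray  # shape (2, 3)
    mu1: float
    mu2: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.mu, dtype=float)
        if grid.shape != (2, 3):
            raise ValidationError("cell-mean grid must be 2x3")
        object.__setattr__(self, "mu", grid)

    def arm_identity_gap(self, alpha: float, beta: float, gamma: float) -> float:
        """Max violation of the arm-equivalence identity (0 for a valid grid)."""
        g1 = self.mu1 - (alpha * self.mu[0, 0] + beta * self.mu[0, 1] + gamma * self.mu[0, 2])
        g2 = self.mu2 - (alpha * self.mu[1, 0] + beta * self.mu[1, 1] + gamma * self.mu[1, 2])
        return max(abs(g1), abs(g2))


# ---------------------------------------------------------------------------
# summarising individual-level records
# ---------------------------------------------------------------------------

_CELL_NAMES = (
    "choosers of A", "choosers of B",
    "undecided on A", "undecided on B",
    "random-arm A", "random-arm B",
)


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    if x.size == 0:
        return math.nan, math.nan
    if x.size == 1:
        return float(x[0]), math.nan
    return float(np.mean(x)), float(np.std(x, ddof=1))


def _summary_from_arrays(
    is_choice: np.ndarray,
    pref: np.ndarray,
    treat: np.ndarray,
    outcome: np.ndarray,
    *,
    require_estimable: bool = True,
) -> TrialSummary:
    """Build a :class:`TrialSummary` from columnar data.

    ``pref`` codes: 0 prefers A, 1 prefers B, 2 undecided, -1 unrecorded
    (random arm).  ``treat`` codes: 0 = A, 1 = B.  This helper is shared by
    :func:`summarize` and the simulation harness so that the two paths are
    bit-identical.
    """
    cells = [
        outcome[is_choice & (pref == 0)],
        outcome[is_choice & (pref == 1)],
        outcome[is_choice & (pref == 2) & (treat == 0)],
        outcome[is_choice & (pref == 2) & (treat == 1)],
        outcome[~is_choice & (treat == 0)],
        outcome[~is_choice & (treat == 1)],
    ]
    if require_estimable:
        for name, cell in zip(_CELL_NAMES, cells):
            if name.startswith("undecided"):
                continue
            if cell.size == 0:
                raise EstimationImpossibleError(
                    f"estimation impossible: subgroup '{name}' is empty"
                )
    stats = [_mean_sd(c) for c in cells]
    return TrialSummary(
        m1=int(cells[0].size), m2=int(cells[1].size),
        m3=int(cells[2].size + cells[3].size),
        n13=int(cells[2].size), n23=int(cells[3].size),
        n1=int(cells[4].size), n2=int(cells[5].size),
        xbar1=stats[0][0], xbar2=stats[1][0],
        vbar1=stats[2][0], vbar2=stats[3][0],
        ybar1=stats[4][0], ybar2=stats[5][0],
        s11=stats[0][1], s22=stats[1][1],
        s13=stats[2][1], s23=stats[3][1],
        s1=stats[4][1], s2=stats[5][1],
    )


def _records_to_arrays(
    records: Sequence[ParticipantRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    pref_code = {TREATMENT_A: 0, TREATMENT_B: 1, NO_PREFERENCE: 2, None: -1}
    is_choice = np.fromiter((r.arm == ARM_CHOICE for r in records), bool, len(records))
    pref = np.fromiter((pref_code[r.preference] for r in records), np.int8, len(records))
    treat = np.fromiter((r.treatment == TREATMENT_B for r in records), np.int8, len(records))
    outcome = np.fromiter((r.outcome for r in records), float, len(records))
    return is_choice, pref, treat, outcome


def summarize(
    records: Iterable[ParticipantRecord], *, require_estimable: bool = True
) -> TrialSummary:
    """Collapse individual-level records into the six-cell summary.

    Record validity (choosers treated according to their choice, known labels,
    finite outcomes) is enforced by :class:`ParticipantRecord` itself.  With
    ``require_estimable`` (default) an empty chooser or random-arm cell raises
    :class:`EstimationImpossibleError` naming the cell; pass ``False`` to
    summarise partial data (e.g. a single arm), in which case empty cells
    carry NaN means.
    """
    records = list(records)
    if not records:
        raise ValidationError("no records")
    return _summary_from_arrays(
        *_records_to_arrays(records), require_estimable=require_estimable
    )


# ---------------------------------------------------------------------------
# delimited-table ingestion
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {"arm": "arm", "preference": "preference",
                   "treatment": "treatment", "outcome": "outcome"}


def load_table(
    path,
    *,
    columns: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    treatment_labels: Mapping[str, str] | None = None,
) -> list[ParticipantRecord]:
    """Read participant records from a delimited text file.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    columns
        Maps the canonical names ``arm``, ``preference``, ``treatment``,
        ``outcome`` to the file's column names (defaults to identity).
    delimiter
        Field separator; sniffed when omitted.
    treatment_labels
        Maps raw treatment/preference labels to ``"A"``/``"B"``, e.g.
        ``{"medical": "A", "surgical": "B"}``.  Matching is case-insensitive.

    Rows with a missing outcome are dropped with a logged count (participants
    who refuse follow-up have no outcome to analyse).  Unknown category
    labels raise :class:`ValidationError` listing the offending values.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=delimiter, engine="python")
    missing_cols = [c for c in colmap.values() if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing columns: {missing_cols}")
    if df.empty:
        raise ValidationError("no records")

    n_total = len(df)
    outcome = pd.to_numeric(df[colmap["outcome"]], errors="coerce")
    keep = outcome.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing outcome", n_dropped)
    df = df.loc[keep]
    outcome = outcome.loc[keep]
    if df.empty:
        raise ValidationError("no records with a parseable outcome")

    treat_map = {"a": TREATMENT_A, "b": TREATMENT_B}
    if treatment_labels:
        treat_map.update({str(k).strip().lower(): v for k, v in treatment_labels.items()})

    def norm(value) -> str | None:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        s = str(value).strip().lower()
        return s if s else None

    bad: set[str] = set()
    records: list[ParticipantRecord] = []
    for (_, row), y in zip(df.iterrows(), outcome):
        arm_raw = norm(row[colmap["arm"]])
        pref_raw = norm(row[colmap["preference"]])
        trt_raw = norm(row[colmap["treatment"]])
        arm = _ARM_SYNONYMS.get(arm_raw) if arm_raw else None
        trt = treat_map.get(trt_raw) if trt_raw else None
        if pref_raw is None:
            pref = None
        else:
            pref = _PREF_SYNONYMS.get(pref_raw) or treat_map.get(pref_raw)
        if arm is None:
            bad.add(f"arm={arm_raw!r}")
            continue
        if trt is None:
            bad.add(f"treatment={trt_raw!r}")
            continue
        if pref_raw is not None and pref is None:
            bad.add(f"preference={pref_raw!r}")
            continue
        if arm == ARM_CHOICE and pref is None:
            bad.add("preference missing in choice arm")
            continue
        records.append(ParticipantRecord(arm=arm, preference=pref, treatment=trt, outcome=float(y)))
    if bad:
        raise ValidationError(f"unknown category labels: {sorted(bad)}")
    if not records:
        raise ValidationError("no records")
    logger.info("loaded %d of %d rows from %s", len(records), n_total, path)
    return records


# ---------------------------------------------------------------------------
# the bundled worked example: menstrual-bleeding trial, medical (A) vs
# surgical (B) management, outcome = bleeding score (higher is worse)
# ---------------------------------------------------------------------------


def example_trial() -> TrialSummary:
    """Six-cell summary of the bundled menstrual-bleeding trial.

    227 women with outcome data: 130 in the choice arm (19 chose medical,
    21 chose surgical, 90 undecided and re-randomised 45/45) and 97 in the
    random arm (49 medical, 48 surgical).  Treatment A is medical management,
    treatment B surgery.
    """
    return TrialSummary(
        m1=19, m2=21, m3=90, n13=45, n23=45, n1=49, n2=48,
        xbar1=16.6, xbar2=5.9,
        vbar1=18.4, vbar2=4.3,
        ybar1=17.2, ybar2=5.1,
        s11=8.7, s22=7.2,
        s13=10.7, s23=5.2,
        s1=5.2, s2=7.7,
    )


def _standardised_ramp(n: int) -> np.ndarray:
    """Deterministic length-n vector with sample mean 0 and sample SD 1."""
    if n < 2:
        return np.zeros(n)
    u = np.arange(1, n + 1, dtype=float) - (n + 1) / 2.0
    return u / np.std(u, ddof=1)


def reconstruct_records(summary: TrialSummary) -> list[ParticipantRecord]:
    """Deterministic individual-level reconstruction matching a summary's
    first two moments exactly (each cell is ``mean + sd * ramp``)."""
    cells = [
        (summary.m1, summary.xbar1, summary.s11, ARM_CHOICE, TREATMENT_A, TREATMENT_A),
        (summary.m2, summary.xbar2, summary.s22, ARM_CHOICE, TREATMENT_B, TREATMENT_B),
        (summary.n13, summary.vbar1, summary.s13, ARM_CHOICE, NO_PREFERENCE, TREATMENT_A),
        (summary.n23, summary.vbar2, summary.s23, ARM_CHOICE, NO_PREFERENCE, TREATMENT_B),
        (summary.n1, summary.ybar1, summary.s1, ARM_RANDOM, None, TREATMENT_A),
        (summary.n2, summary.ybar2, summary.s2, ARM_RANDOM, None, TREATMENT_B),
    ]
    records: list[ParticipantRecord] = []
    for n, mean, sd, arm, pref, trt in cells:
        if n == 0:
            continue
        sd = 0.0 if (n < 2 or math.isnan(sd)) else sd
        values = mean + sd * _standardised_ramp(n)
        records.extend(
            ParticipantRecord(arm=arm, preference=pref, treatment=trt, outcome=float(v))
            for v in values
        )
    return records


def example_records() -> list[ParticipantRecord]:
    """227 deterministic records reconstructing the example trial's moments."""
    return reconstruct_records(example_trial())


def example_data_path():
    """Path to the bundled CSV fixture (the reconstruction, one row per woman)."""
    return resources.files("preftrial").joinpath("data/bleeding_trial.csv")
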