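"""Cohort schema, eligibility screening, variable coding and descriptive statistics.

The analysis dataset is one row per patient: demographics, stroke
characteristics, days from stroke onset to the start of robot-assisted gait
training (RAGT), baseline walking independence (GAA, a 7-level scale),
SIAS impairment subscores, FIM cognitive items, and the GAA score after the
4-week training block.  The binary study outcome is *walking with
supervision or better*, defined as a 4-week GAA score >= 5.

All continuous and ordinal explanatory variables are dichotomized at their
sample median before modelling; nominal variables are dummy-coded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreeningRecord",
    "VariableSpec",
    "CohortTable",
    "BinaryDesign",
    "SCREENING_FILTERS",
    "GAA_SUPERVISION_CUTOFF",
    "apply_screening",
    "define_outcome",
    "dichotomize_at_median",
    "make_binary_design",
    "descriptive_table",
    "default_variable_specs",
]

#: GAA level at or above which a patient walks with supervision or better.
GAA_SUPERVISION_CUTOFF = 5


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningRecord:
    """One pre-eligibility patient row carrying the attributes the intake
    filters test.

    ``sias_lower_limb_motor_total`` is the sum of the three SIAS lower-limb
    motor items (hip flexion, knee extension, ankle dorsiflexion), each
    scored 0-5; eligibility requires a total of 5 or less (severe paresis).
    ``baseline_gaa`` must be 4 or less (unable to walk with supervision).
    """

    patient_id: str
    supratentorial: bool
    first_stroke: bool
    sias_lower_limb_motor_total: int
    baseline_gaa: int
    subarachnoid: bool
    neuro_comorbidity: bool
    declined: bool
    assessment_incomplete: bool
    sessions_completed: int

    def __post_init__(self) -> None:
        if not (0 <= int(self.sias_lower_limb_motor_total) <= 15):
            raise ValueError(
                f"record {self.patient_id!r}: SIAS lower-limb motor total "
                f"{self.sias_lower_limb_motor_total} outside [0, 15]"
            )
        if not (1 <= int(self.baseline_gaa) <= 7):
            raise ValueError(
                f"record {self.patient_id!r}: baseline GAA "
                f"{self.baseline_gaa} outside [1, 7]"
            )
        if int(self.sessions_completed) < 0:
            raise ValueError(
                f"record {self.patient_id!r}: negative session count"
            )


#: Exclusion filters in the order they are applied during intake screening.
#: Each record is attributed to the FIRST criterion it fails.
SCREENING_FILTERS: tuple[tuple[str, object], ...] = (
    ("non-supratentorial lesion", lambda r: not r.supratentorial),
    ("recurrent stroke", lambda r: not r.first_stroke),
    ("SIAS motor > 5", lambda r: r.sias_lower_limb_motor_total > 5),
    ("GAA > 4", lambda r: r.baseline_gaa > 4),
    ("subarachnoid hemorrhage", lambda r: r.subarachnoid),
    ("neurological comorbidity", lambda r: r.neuro_comorbidity),
    ("declined participation", lambda r: r.declined),
    ("assessment incomplete", lambda r: r.assessment_incomplete),
    ("<10 sessions", lambda r: r.sessions_completed < 10),
)


def apply_screening(
    records: Sequence[ScreeningRecord],
) -> tuple[list[ScreeningRecord], dict[str, int]]:
    """Run the eligibility cascade and tally exclusions by first failure.

    Filters are applied in the fixed order of :data:`SCREENING_FILTERS`;
    a record excluded by an earlier criterion is never counted under a
    later one, so ``len(included) + sum(tally.values()) == len(records)``.

    Returns ``(included, tally)`` where ``tally`` maps each exclusion
    reason (in application order) to its count.
    """
    if len(records) == 0:
        raise ValueError("no screening records supplied")
    tally: dict[str, int] = {name: 0 for name, _ in SCREENING_FILTERS}
    included: list[ScreeningRecord] = []
    for rec in records:
        if not isinstance(rec, ScreeningRecord):
            raise TypeError(f"malformed screening record: {rec!r}")
        for name, fails in SCREENING_FILTERS:
            if fails(rec):
                tally[name] += 1
                break
        else:
            included.append(rec)
    return included, tally


def screening_tally_to_json(tally: dict[str, int], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(tally, fh, indent=2)


# ---------------------------------------------------------------------------
# variable roster
# ---------------------------------------------------------------------------

Kind = Literal["nominal", "ordinal", "continuous"]
Role = Literal["exposure", "outcome", "excluded"]


@dataclass(frozen=True)
class VariableSpec:
    """Declares one cohort variable: measurement kind, modelling role and,
    for nominal variables, the ordered level labels (the *second* level is
    the one coded 1)."""

    name: str
    kind: Kind
    role: Role = "exposure"
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind == "nominal" and (self.levels is None or len(self.levels) < 2):
            raise ValueError(f"nominal variable {self.name!r} needs >= 2 levels")


def default_variable_specs() -> list[VariableSpec]:
    """The study roster: 16 explanatory variables plus the 4-week GAA from
    which the binary outcome is derived.

    The coded level of each nominal variable (listed second) matches the
    count reported in the baseline table: female, infarction, left side.
    """
    return [
        VariableSpec("age", "continuous"),
        VariableSpec("sex", "nominal", levels=("male", "female")),
        VariableSpec("stroke_type", "nominal", levels=("hemorrhage", "infarction")),
        VariableSpec("affected_side", "nominal", levels=("right", "left")),
        VariableSpec("days_to_ragt", "continuous"),
        VariableSpec("gaa_baseline", "ordinal"),
        VariableSpec("sias_hip_flexion", "ordinal"),
        VariableSpec("sias_knee_extension", "ordinal"),
        VariableSpec("sias_ankle_dorsiflexion", "ordinal"),
        VariableSpec("sias_touch", "ordinal"),
        VariableSpec("sias_position_sense", "ordinal"),
        VariableSpec("sias_trunk_verticality", "ordinal"),
        VariableSpec("sias_abdominal", "ordinal"),
        VariableSpec("fim_comprehension", "ordinal"),
        VariableSpec("fim_expression", "ordinal"),
        VariableSpec("fim_social_interaction", "ordinal"),
        VariableSpec("fim_problem_solving", "ordinal"),
        VariableSpec("fim_memory", "ordinal"),
        VariableSpec("gaa_4wk", "ordinal", role="outcome"),
    ]


#: Valid score range per instrument column (inclusive).
SCORE_RANGES: dict[str, tuple[int, int]] = {
    "gaa_baseline": (1, 7),
    "gaa_4wk": (1, 7),
    "sias_hip_flexion": (0, 5),
    "sias_knee_extension": (0, 5),
    "sias_ankle_dorsiflexion": (0, 5),
    "sias_touch": (0, 3),
    "sias_position_sense": (0, 3),
    "sias_trunk_verticality": (0, 3),
    "sias_abdominal": (0, 3),
    "fim_comprehension": (1, 7),
    "fim_expression": (1, 7),
    "fim_social_interaction": (1, 7),
    "fim_problem_solving": (1, 7),
    "fim_memory": (1, 7),
}


@dataclass
class CohortTable:
    """The analysis dataset: a complete-case patient table plus its roster."""

    data: pd.DataFrame
    specs: list[VariableSpec] = field(default_factory=default_variable_specs)

    def __post_init__(self) -> None:
        missing = [s.name for s in self.specs if s.name not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table lacks columns: {missing}")
        if self.data[[s.name for s in self.specs]].isna().any().any():
            raise ValueError("cohort table contains missing values")
        n_outcome = sum(s.role == "outcome" for s in self.specs)
        if n_outcome != 1:
            raise ValueError(f"exactly one outcome variable required, got {n_outcome}")
        for name, (lo, hi) in SCORE_RANGES.items():
            if name in self.data.columns:
                col = self.data[name]
                if (col < lo).any() or (col > hi).any():
                    raise ValueError(f"{name} outside valid range [{lo}, {hi}]")

    @property
    def n(self) -> int:
        return len(self.data)

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def outcome_source(self) -> str:
        return next(s.name for s in self.specs if s.role == "outcome")

    def to_csv(self, path: str) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, specs: list[VariableSpec] | None = None) -> "CohortTable":
        df = pd.read_csv(path)
        return cls(df, specs if specs is not None else default_variable_specs())


# ---------------------------------------------------------------------------
# outcome and coding
# ---------------------------------------------------------------------------

def define_outcome(cohort: CohortTable, cutoff: int = GAA_SUPERVISION_CUTOFF) -> np.ndarray:
    """Binary outcome: 1 iff the 4-week GAA score is >= ``cutoff``
    (walking with supervision or better)."""
    gaa = np.asarray(cohort.data[cohort.outcome_source])
    if ((gaa < 1) | (gaa > 7)).any():
        raise ValueError("4-week GAA scores outside 1-7")
    return (gaa >= cutoff).astype(int)


def dichotomize_at_median(
    values: Iterable[float], direction: Literal[">", ">="] = ">"
) -> tuple[np.ndarray, float]:
    """Split a numeric vector at its sample median.

    With ``direction=">"`` (default) a value is coded 1 iff it is strictly
    above the median; several SIAS items sit at their scale floor (median 0)
    and would code all-1 under ``>=``.  Returns ``(codes, split_point)``.

    Raises ``ValueError`` for constant input (degenerate column).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to dichotomize")
    if np.all(v == v[0]):
        raise ValueError("constant vector: dichotomization is degenerate")
    med = float(np.median(v))
    codes = (v > med) if direction == ">" else (v >= med)
    return codes.astype(int), med


@dataclass
class BinaryDesign:
    """Patients x coded-variable matrix in {0,1}, the binary outcome, and
    a per-column log of how each code was produced."""

    matrix: pd.DataFrame
    outcome: np.ndarray
    coding_log: dict[str, dict]
    degenerate: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)

    def coding_log_to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"coding": self.coding_log, "degenerate": self.degenerate},
                      fh, indent=2, default=float)


def make_binary_design(
    cohort: CohortTable,
    direction: Literal[">", ">="] = ">",
    outcome_cutoff: int = GAA_SUPERVISION_CUTOFF,
) -> BinaryDesign:
    """Code the cohort for modelling: nominal variables dummy-coded
    (second roster level = 1), continuous/ordinal variables dichotomized at
    the sample median, outcome = 4-week GAA >= cutoff.

    Constant columns are flagged degenerate, excluded with a warning, and
    recorded on the returned design.
    """
    cols: dict[str, np.ndarray] = {}
    log: dict[str, dict] = {}
    degenerate: list[str] = []
    for spec in cohort.specs:
        if spec.role != "exposure":
            continue
        raw = cohort.data[spec.name]
        if spec.kind == "nominal":
            assert spec.levels is not None
            unknown = set(raw.unique()) - set(spec.levels)
            if unknown:
                raise ValueError(f"{spec.name}: unknown levels {sorted(unknown)}")
            coded = (raw == spec.levels[1]).astype(int).to_numpy()
            if coded.min() == coded.max():
                degenerate.append(spec.name)
                warnings.warn(f"column {spec.name!r} is constant; excluded")
                continue
            cols[spec.name] = coded
            log[spec.name] = {"kind": "nominal", "level_coded_1": spec.levels[1]}
        else:
            try:
                coded, med = dichotomize_at_median(raw, direction=direction)
            except ValueError:
                degenerate.append(spec.name)
                warnings.warn(f"column {spec.name!r} is constant; excluded")
                continue
            cols[spec.name] = coded
            log[spec.name] = {"kind": spec.kind, "median": med,
                              "direction": direction}
    outcome = define_outcome(cohort, cutoff=outcome_cutoff)
    if outcome.min() == outcome.max():
        raise ValueError("outcome has a single class; modelling impossible")
    log["__outcome__"] = {"source": cohort.outcome_source,
                          "rule": f">= {outcome_cutoff}"}
    return BinaryDesign(pd.DataFrame(cols, index=cohort.data.index),
                        outcome, log, degenerate)


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.1f}"


def _quartiles(v: np.ndarray) -> tuple[float, float, float]:
    # linear-interpolation quartiles (type 7), the numpy default
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(q1), float(med), float(q3)


def descriptive_table(
    cohort: CohortTable,
    outcome: np.ndarray | None = None,
    group_labels: tuple[str, str] = ("walking with physical assistance",
                                     "walking with supervision"),
) -> pd.DataFrame:
    """Baseline characteristics, overall and by outcome group.

    Continuous variables are shown as ``mean (SD)``, ordinal as
    ``median [Q1, Q3]`` (quartiles by linear interpolation), nominal as
    ``n (%)`` of the coded level.  Display rounds to one decimal.
    """
    if outcome is None:
        outcome = define_outcome(cohort)
    groups: list[tuple[str, pd.DataFrame]] = [("overall", cohort.data)]
    groups.append((group_labels[0], cohort.data[outcome == 0]))
    groups.append((group_labels[1], cohort.data[outcome == 1]))

    rows: list[dict[str, str]] = []
    counts = {"variable": "n"}
    for gname, gdf in groups:
        counts[gname] = str(len(gdf))
    rows.append(counts)
    for spec in cohort.specs:
        if spec.role == "outcome":
            continue
        row = {"variable": spec.name}
        for gname, gdf in groups:
            v = gdf[spec.name]
            if spec.kind == "continuous" and spec.name != "days_to_ragt":
                row[gname] = f"{_fmt(v.mean())} ({_fmt(v.std(ddof=1))})"
            elif spec.kind == "nominal":
                assert spec.levels is not None
                k = int((v == spec.levels[1]).sum())
                pct = 100.0 * k / len(v) if len(v) else float("nan")
                row[gname] = f"{k} ({_fmt(pct)})"
            else:
                q1, med, q3 = _quartiles(v.to_numpy(dtype=float))
                row[gname] = f"{_fmt(med)} [{_fmt(q1)}, {_fmt(q3)}]"
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
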