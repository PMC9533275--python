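"""Cohort data structures shared by every pipeline stage.

A cohort is one row per participant with demographics (age in years,
education in years of schooling, gender coded 0 = male / 1 = female) and
raw scores on up to five verbal-memory tests:

====== ======================================== ============ ===========
name   test                                     score range  granularity
====== ======================================== ============ ===========
dsf    Digit Span Forward (longest span)        0 – 9        1
dsb    Digit Span Backward (longest span)       0 – 9        1
ravl_i Rey Auditory Verbal Learning, immediate  0 – 75       1
ravl_d Rey Auditory Verbal Learning, delayed    0 – 15       1
vpal   Verbal Paired Associates Learning        0 – 22.5     0.5
====== ======================================== ============ ===========

CSV files use the header ``id,age,education,gender,dsf,dsb,ravl_i,ravl_d,
vpal`` with gender written as ``m``/``f``; in memory gender is the 0/1
code used by the adjustment equations.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TEST_NAMES",
    "TEST_CATALOG",
    "ScoreSpec",
    "DemographicProfile",
    "CohortTable",
    "MarginalSpec",
    "SimulationSpec",
    "study_sample_spec",
    "amci_patient_spec",
    "STUDY_CORRELATIONS",
    "SIM_VARIABLES",
]

TEST_NAMES = ("dsf", "dsb", "ravl_i", "ravl_d", "vpal")

GENDER_CODES = {"m": 0, "f": 1}
GENDER_LABELS = {0: "m", 1: "f"}

CSV_COLUMNS = ["id", "age", "education", "gender", *TEST_NAMES]


@dataclass(frozen=True)
class ScoreSpec:
    """Admissible range and scoring granularity of one test."""

    lower: float
    upper: float
    granularity: float  # smallest score increment (0.5 for vpal)


TEST_CATALOG: dict[str, ScoreSpec] = {
    "dsf": ScoreSpec(0.0, 9.0, 1.0),
    "dsb": ScoreSpec(0.0, 9.0, 1.0),
    "ravl_i": ScoreSpec(0.0, 75.0, 1.0),
    "ravl_d": ScoreSpec(0.0, 15.0, 1.0),
    "vpal": ScoreSpec(0.0, 22.5, 0.5),
}

AGE_BOUNDS = (18, 84)
EDUCATION_BOUNDS = (5, 26)


@dataclass(frozen=True)
class DemographicProfile:
    """Demographics of one participant (gender: 0 = male, 1 = female)."""

    age: int
    education: int
    gender: int
    age_bounds: tuple[int, int] = AGE_BOUNDS
    education_bounds: tuple[int, int] = EDUCATION_BOUNDS

    def __post_init__(self) -> None:
        lo, hi = self.age_bounds
        if not lo <= self.age <= hi:
            raise ValueError(f"age {self.age} outside [{lo}, {hi}]")
        lo, hi = self.education_bounds
        if not lo <= self.education <= hi:
            raise ValueError(f"education {self.education} outside [{lo}, {hi}]")
        if self.gender not in (0, 1):
            raise ValueError(f"gender must be 0 (male) or 1 (female), got {self.gender}")


class CohortTable:
    """Per-participant demographics and raw test scores.

    Thin wrapper around a :class:`pandas.DataFrame` that enforces the score
    catalog and demographic completeness.  Not every cohort carries every
    test; absent tests are simply missing columns.
    """

    def __init__(self, df: pd.DataFrame, *, validate: bool = True):
        self.df = df.reset_index(drop=True)
        if "id" not in self.df.columns:
            self.df.insert(0, "id", np.arange(1, len(self.df) + 1))
        # canonical column order: id, demographics, tests, then extras
        order = [c for c in CSV_COLUMNS if c in self.df.columns]
        extras = [c for c in self.df.columns if c not in order]
        self.df = self.df[order + extras]
        if validate:
            self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(path)
        if df["gender"].dtype == object:
            df["gender"] = df["gender"].map(GENDER_CODES)
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["gender"] = out["gender"].map(GENDER_LABELS)
        out.to_csv(path, index=False, lineterminator="\n")

    # -- properties -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def tests(self) -> list[str]:
        return [t for t in TEST_NAMES if t in self.df.columns]

    def validate(self) -> None:
        for col in ("age", "education", "gender"):
            if col not in self.df.columns:
                raise ValueError(f"missing demographic column {col!r}")
            if self.df[col].isna().any():
                raise ValueError(f"missing values in demographic column {col!r}")
        bad_gender = ~self.df["gender"].isin([0, 1])
        if bad_gender.any():
            raise ValueError("gender must be coded 0 (male) / 1 (female)")
        for test in self.tests:
            spec = TEST_CATALOG[test]
            vals = self.df[test].dropna()
            if ((vals < spec.lower) | (vals > spec.upper)).any():
                raise ValueError(
                    f"{test} scores outside catalog bounds "
                    f"[{spec.lower}, {spec.upper}]"
                )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CohortTable(n={self.n}, tests={self.tests})"


# ---------------------------------------------------------------------------
# Simulation specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarginalSpec:
    """Target marginal of one continuous variable (truncated normal)."""

    mean: float
    sd: float
    lower: float
    upper: float
    granularity: float = 1.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.lower >= self.upper:
            raise ValueError("lower bound must be below upper bound")
        if not self.lower <= self.mean <= self.upper:
            warnings.warn(
                f"target mean {self.mean} outside bounds "
                f"[{self.lower}, {self.upper}]; values will be clipped",
                stacklevel=2,
            )


#: variable ordering used by the simulator and by correlation matrices
SIM_VARIABLES = ("gender", "age", "education", *TEST_NAMES)

# Sample correlations among (gender, age, education, DSF, DSB, RAVL-I,
# RAVL-D, VPAL) in the n = 204 remote-testing normative sample; gender
# correlations are point-biserial (0 = male, 1 = female).
STUDY_CORRELATIONS = np.array(
    [
        #  gen    age    edu    dsf    dsb   ravli  ravld   vpal
        [1.00,  0.06,  0.00, -0.21, -0.12,  0.24,  0.32,  0.10],
        [0.06,  1.00, -0.49, -0.21, -0.29, -0.46, -0.41, -0.55],
        [0.00, -0.49,  1.00,  0.14,  0.22,  0.39,  0.38,  0.40],
        [-0.21, -0.21,  0.14,  1.00,  0.52,  0.28,  0.21,  0.32],
        [-0.12, -0.29,  0.22,  0.52,  1.00,  0.31,  0.28,  0.32],
        [0.24, -0.46,  0.39,  0.28,  0.31,  1.00,  0.78,  0.65],
        [0.32, -0.41,  0.38,  0.21,  0.28,  0.78,  1.00,  0.57],
        [0.10, -0.55,  0.40,  0.32,  0.32,  0.65,  0.57,  1.00],
    ]
)

# Marginal targets of the normative sample (means/SDs as published; score
# bounds from the test catalog so simulated values can span the full range).
STUDY_MARGINALS: dict[str, MarginalSpec] = {
    "age": MarginalSpec(44.33, 18.51, 18, 84, 1.0),
    "education": MarginalSpec(14.98, 3.85, 5, 26, 1.0),
    "dsf": MarginalSpec(6.40, 1.15, 0, 9, 1.0),
    "dsb": MarginalSpec(5.01, 1.26, 0, 9, 1.0),
    "ravl_i": MarginalSpec(54.09, 9.12, 0, 75, 1.0),
    "ravl_d": MarginalSpec(11.82, 2.65, 0, 15, 1.0),
    "vpal": MarginalSpec(16.60, 4.25, 0, 22.5, 0.5),
}

STUDY_FEMALE_PROP = 127 / 204

# SYNTHETIC STAND-IN clinical score parameters for a simulated amnestic-MCI
# cohort.  The external face-to-face norms this comparison emulates do not
# ship with this package, so these means/SDs are placeholders chosen to sit
# well below the healthy means (roughly 2-3 healthy SDs); they are free
# configuration, not published values.
SYNTHETIC_AMCI_SCORE_PARAMS: dict[str, tuple[float, float]] = {
    "dsf": (5.2, 1.0),
    "dsb": (3.3, 1.0),
    "ravl_i": (28.0, 8.0),
    "ravl_d": (4.5, 2.8),
    "vpal": (8.0, 3.5),
}

# Elderly demographics typical of an amnestic-MCI clinical sample
# (synthetic stand-in, see above).
SYNTHETIC_AMCI_AGE = MarginalSpec(72.0, 6.0, 55, 84, 1.0)
SYNTHETIC_AMCI_EDUCATION = MarginalSpec(9.0, 3.5, 5, 18, 1.0)


@dataclass
class SimulationSpec:
    """Parameters driving a synthetic cohort draw.

    ``correlations`` is the target correlation matrix over ``variables``
    (symmetric, unit diagonal, entries in [-1, 1]).  For patient cohorts,
    ``score_params`` carries per-test clinical (mean, SD) pairs and
    ``age_education_r`` the target Pearson correlation between age and
    education, enforced to ``age_education_tol``.
    """

    n: int
    seed: int = 0
    female_prop: float = STUDY_FEMALE_PROP
    marginals: dict[str, MarginalSpec] = field(
        default_factory=lambda: dict(STUDY_MARGINALS)
    )
    variables: tuple[str, ...] = SIM_VARIABLES
    correlations: np.ndarray | None = None
    score_params: dict[str, tuple[float, float]] | None = None
    age_education_r: float = -0.22
    age_education_tol: float = 0.02

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not 0.0 < self.female_prop < 1.0:
            raise ValueError("female_prop must be in (0, 1)")
        if self.correlations is not None:
            r = np.asarray(self.correlations, dtype=float)
            k = len(self.variables)
            if r.shape != (k, k):
                raise ValueError(
                    f"correlation matrix shape {r.shape} does not match "
                    f"{k} variables"
                )
            if not np.allclose(r, r.T):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(r), 1.0):
                raise ValueError("correlation matrix must have unit diagonal")
            if np.any(np.abs(r) > 1.0 + 1e-12):
                raise ValueError("correlation entries must lie in [-1, 1]")
            self.correlations = r

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        if self.correlations is not None:
            payload["correlations"] = np.asarray(self.correlations).tolist()
        payload["marginals"] = {
            k: dataclasses.asdict(v) for k, v in self.marginals.items()
        }
        payload["variables"] = list(self.variables)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SimulationSpec":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text()
        payload = json.loads(source)
        payload["marginals"] = {
            k: MarginalSpec(**v) for k, v in payload["marginals"].items()
        }
        if payload.get("correlations") is not None:
            payload["correlations"] = np.asarray(payload["correlations"])
        payload["variables"] = tuple(payload["variables"])
        if payload.get("score_params") is not None:
            payload["score_params"] = {
                k: tuple(v) for k, v in payload["score_params"].items()
            }
        return cls(**payload)


def study_sample_spec(n: int = 204, seed: int = 0) -> SimulationSpec:
    """Spec emulating the published healthy normative sample (default n=204)."""
    return SimulationSpec(
        n=n,
        seed=seed,
        female_prop=STUDY_FEMALE_PROP,
        marginals=dict(STUDY_MARGINALS),
        variables=SIM_VARIABLES,
        correlations=STUDY_CORRELATIONS.copy(),
    )


def amci_patient_spec(n: int = 100, seed: int = 0,
                      age_education_r: float = -0.22) -> SimulationSpec:
    """Spec for the simulated clinical comparison cohort (default n=100).

    Test-score means/SDs are synthetic stand-ins for external clinical
    norms (see :data:`SYNTHETIC_AMCI_SCORE_PARAMS`).
    """
    return SimulationSpec(
        n=n,
        seed=seed,
        female_prop=0.5,
        marginals={
            "age": SYNTHETIC_AMCI_AGE,
            "education": SYNTHETIC_AMCI_EDUCATION,
        },
        variables=("gender", "age", "education", *TEST_NAMES),
        correlations=None,
        score_params=dict(SYNTHETIC_AMCI_SCORE_PARAMS),
        age_education_r=age_education_r,
    )
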