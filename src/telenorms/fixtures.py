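"""Published adjustment equations and correction-grid fixtures.

The five equations below are the published remote-setting norms,
transcribed verbatim (coefficients already sign-reversed, centering
constants as printed; gender coded 0 = male, 1 = female; natural
logarithm in the shifted-log term — the base that reproduces the printed
grid):

* DSF:    adjusted = raw + 0.0000017*(Age^3 - 128919) + 0.472*(Gender - 0.618)
* DSB:    adjusted = raw + 0.02*(Age - 43.62)
* RAVL-I: adjusted = raw - 6.72*(log(88 - Age) - 3.769)
          + 106.06*(1/Education - 0.0697) - 4.214*(Gender - 0.6)
* RAVL-D: adjusted = raw + 0.0481*(Age - 40.8)
          + 28.678*(1/Education - 0.0697) - 1.635*(Gender - 0.6)
* VPAL:   adjusted = raw + 1.357*(sqrt(Age) - 6.514)
          + 35.603*(1/Education - 0.0733) - 1.106*(Gender - 0.6)

``PUBLISHED_GRID`` holds the printed correction-grid cells (2 decimals)
on the age lattice 18…84, stratified by gender and crossed with
education where those covariates enter. ``validate_fixtures`` recomputes
every cell from the equations and reports deviations.

``PUBLISHED_ES_TABLE`` carries the published Equivalent-Score cutoffs and
tolerance limits as *plausibility* fixtures only: they derive from the
unavailable raw adjusted scores.  The printed VPAL row duplicates the DSF
row verbatim (almost certainly a typesetting error) and is flagged
``suspect``; it must not be treated as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .adjust import (
    AGE_LATTICE,
    AdjustmentEquation,
    Term,
    TransformSpec,
    build_grid,
)

__all__ = [
    "published_equations",
    "PUBLISHED_GRID",
    "PUBLISHED_ES_TABLE",
    "validate_fixtures",
    "FixtureReport",
]

_RANGES = {"age": (18.0, 84.0), "education": (5.0, 26.0),
           "gender": (0.0, 1.0)}


def published_equations() -> dict[str, AdjustmentEquation]:
    """The five published adjustment equations, as shipped fixtures."""
    def ranges(*covs: str) -> dict:
        return {c: _RANGES[c] for c in covs}

    return {
        "dsf": AdjustmentEquation(
            test="dsf",
            terms=[
                Term(TransformSpec("age", "cube"), 0.0000017, 128919.0),
                Term(TransformSpec("gender"), 0.472, 0.618),
            ],
            n=199,
            fit_ranges=ranges("age", "gender"),
        ),
        "dsb": AdjustmentEquation(
            test="dsb",
            terms=[Term(TransformSpec("age"), 0.02, 43.62)],
            n=199,
            fit_ranges=ranges("age"),
        ),
        "ravl_i": AdjustmentEquation(
            test="ravl_i",
            terms=[
                Term(TransformSpec("age", "shifted_log", 88.0), -6.72, 3.769),
                Term(TransformSpec("education", "reciprocal"), 106.06, 0.0697),
                Term(TransformSpec("gender"), -4.214, 0.6),
            ],
            n=180,
            fit_ranges=ranges("age", "education", "gender"),
        ),
        "ravl_d": AdjustmentEquation(
            test="ravl_d",
            terms=[
                Term(TransformSpec("age"), 0.0481, 40.8),
                Term(TransformSpec("education", "reciprocal"), 28.678, 0.0697),
                Term(TransformSpec("gender"), -1.635, 0.6),
            ],
            n=180,
            fit_ranges=ranges("age", "education", "gender"),
        ),
        "vpal": AdjustmentEquation(
            test="vpal",
            terms=[
                Term(TransformSpec("age", "sqrt"), 1.357, 6.514),
                Term(TransformSpec("education", "reciprocal"), 35.603, 0.0733),
                Term(TransformSpec("gender"), -1.106, 0.6),
            ],
            n=204,
            fit_ranges=ranges("age", "education", "gender"),
        ),
    }


def _row(text: str) -> tuple[float, ...]:
    return tuple(float(v) for v in text.split())


#: printed correction-grid cells, keyed (test, gender label, education);
#: gender '' / education None where the covariate is not in the equation;
#: 15 values per row on the age lattice 18 22 27 32 37 42 47 52 57 62 67 72 77 82 84
PUBLISHED_GRID: dict[tuple[str, str, int | None], tuple[float, ...]] = {
    ("dsf", "f", None): _row(
        "-0.03 -0.02 -0.01 0.02 0.05 0.09 0.14 0.20 0.28 0.37 0.47 0.60 0.74 0.90 0.97"),
    ("dsf", "m", None): _row(
        "-0.50 -0.49 -0.48 -0.46 -0.42 -0.38 -0.33 -0.27 -0.20 -0.11 0.00 0.12 0.27 0.43 0.50"),
    ("dsb", "", None): _row(
        "-0.51 -0.43 -0.33 -0.23 -0.13 -0.03 0.07 0.17 0.27 0.37 0.47 0.57 0.67 0.77 0.81"),
    ("ravl_i", "f", 5): _row(
        "8.91 9.31 9.84 10.41 11.04 11.73 12.51 13.38 14.39 15.57 17.00 18.83 21.35 25.42 28.15"),
    ("ravl_i", "f", 8): _row(
        "0.96 1.35 1.88 2.46 3.09 3.78 4.55 5.43 6.43 7.61 9.05 10.88 13.39 17.47 20.19"),
    ("ravl_i", "f", 13): _row(
        "-4.14 -3.75 -3.22 -2.64 -2.01 -1.32 -0.55 0.33 1.33 2.51 3.95 5.78 8.29 12.37 15.09"),
    ("ravl_i", "f", 16): _row(
        "-5.67 -5.28 -4.75 -4.17 -3.54 -2.85 -2.08 -1.20 -0.20 0.98 2.42 4.25 6.76 10.84 13.56"),
    ("ravl_i", "f", 18): _row(
        "-6.41 -6.01 -5.48 -4.91 -4.28 -3.59 -2.81 -1.94 -0.93 0.25 1.68 3.51 6.03 10.10 12.83"),
    ("ravl_i", "f", 21): _row(
        "-7.25 -6.85 -6.32 -5.75 -5.12 -4.43 -3.66 -2.78 -1.78 -0.59 0.84 2.67 5.19 9.26 11.98"),
    ("ravl_i", "m", 5): _row(
        "13.13 13.52 14.05 14.63 15.25 15.95 16.72 17.59 18.60 19.78 21.22 23.04 25.56 29.64 32.36"),
    ("ravl_i", "m", 8): _row(
        "5.17 5.57 6.10 6.67 7.30 7.99 8.77 9.64 10.64 11.83 13.26 15.09 17.61 21.68 24.41"),
    ("ravl_i", "m", 13): _row(
        "0.07 0.47 1.00 1.57 2.20 2.89 3.67 4.54 5.55 6.73 8.16 9.99 12.51 16.58 19.31"),
    ("ravl_i", "m", 16): _row(
        "-1.46 -1.06 -0.53 0.04 0.67 1.36 2.14 3.01 4.02 5.20 6.63 8.46 10.98 15.05 17.78"),
    ("ravl_i", "m", 18): _row(
        "-2.19 -1.80 -1.27 -0.69 -0.07 0.63 1.40 2.27 3.28 4.46 5.90 7.72 10.24 14.32 17.04"),
    ("ravl_i", "m", 21): _row(
        "-3.04 -2.64 -2.11 -1.54 -0.91 -0.21 0.56 1.43 2.44 3.62 5.05 6.88 9.40 13.47 16.20"),
    ("ravl_d", "f", 5): _row(
        "1.99 2.18 2.42 2.66 2.90 3.14 3.38 3.62 3.86 4.10 4.34 4.58 4.82 5.06 5.16"),
    ("ravl_d", "f", 8): _row(
        "-0.16 0.03 0.27 0.51 0.75 0.99 1.23 1.47 1.71 1.95 2.19 2.43 2.67 2.91 3.01"),
    ("ravl_d", "f", 13): _row(
        "-1.54 -1.35 -1.11 -0.87 -0.63 -0.39 -0.15 0.09 0.33 0.57 0.81 1.05 1.29 1.53 1.63"),
    ("ravl_d", "f", 16): _row(
        "-1.96 -1.76 -1.52 -1.28 -1.04 -0.80 -0.56 -0.32 -0.08 0.16 0.40 0.64 0.88 1.12 1.22"),
    ("ravl_d", "f", 18): _row(
        "-2.16 -1.96 -1.72 -1.48 -1.24 -1.00 -0.76 -0.52 -0.28 -0.04 0.20 0.44 0.68 0.92 1.02"),
    ("ravl_d", "f", 21): _row(
        "-2.38 -2.19 -1.95 -1.71 -1.47 -1.23 -0.99 -0.75 -0.51 -0.27 -0.03 0.21 0.45 0.69 0.79"),
    ("ravl_d", "m", 5): _row(
        "3.62 3.81 4.05 4.29 4.53 4.78 5.02 5.26 5.50 5.74 5.98 6.22 6.46 6.70 6.80"),
    ("ravl_d", "m", 8): _row(
        "1.47 1.66 1.90 2.14 2.38 2.62 2.87 3.11 3.35 3.59 3.83 4.07 4.31 4.55 4.64"),
    ("ravl_d", "m", 13): _row(
        "0.09 0.28 0.52 0.76 1.01 1.25 1.49 1.73 1.97 2.21 2.45 2.69 2.93 3.17 3.27"),
    ("ravl_d", "m", 16): _row(
        "-0.32 -0.13 0.11 0.35 0.59 0.83 1.07 1.31 1.55 1.79 2.03 2.28 2.52 2.76 2.85"),
    ("ravl_d", "m", 18): _row(
        "-0.52 -0.33 -0.09 0.15 0.39 0.63 0.87 1.11 1.35 1.60 1.84 2.08 2.32 2.56 2.65"),
    ("ravl_d", "m", 21): _row(
        "-0.75 -0.56 -0.32 -0.08 0.16 0.41 0.65 0.89 1.13 1.37 1.61 1.85 2.09 2.33 2.43"),
    ("vpal", "f", 5): _row(
        "0.99 1.59 2.28 2.91 3.48 4.02 4.53 5.01 5.47 5.91 6.34 6.74 7.14 7.52 7.67"),
    ("vpal", "f", 8): _row(
        "-1.68 -1.08 -0.39 0.24 0.81 1.35 1.86 2.34 2.80 3.24 3.67 4.07 4.47 4.85 5.00"),
    ("vpal", "f", 13): _row(
        "-3.40 -2.79 -2.10 -1.48 -0.90 -0.36 0.15 0.63 1.09 1.53 1.95 2.36 2.75 3.14 3.28"),
    ("vpal", "f", 16): _row(
        "-3.91 -3.30 -2.62 -1.99 -1.41 -0.87 -0.36 0.12 0.58 1.02 1.44 1.85 2.24 2.62 2.77"),
    ("vpal", "f", 18): _row(
        "-4.16 -3.55 -2.86 -2.24 -1.66 -1.12 -0.61 -0.13 0.33 0.77 1.19 1.60 1.99 2.37 2.52"),
    ("vpal", "f", 21): _row(
        "-4.44 -3.83 -3.15 -2.52 -1.94 -1.40 -0.89 -0.41 0.05 0.49 0.91 1.32 1.71 2.09 2.24"),
    ("vpal", "m", 5): _row(
        "2.09 2.70 3.39 4.01 4.59 5.13 5.64 6.12 6.58 7.02 7.44 7.85 8.24 8.62 8.77"),
    ("vpal", "m", 8): _row(
        "-0.58 0.03 0.72 1.34 1.92 2.46 2.97 3.45 3.91 4.35 4.77 5.18 5.57 5.95 6.10"),
    ("vpal", "m", 13): _row(
        "-2.29 -1.68 -1.00 -0.37 0.21 0.75 1.26 1.74 2.20 2.64 3.06 3.47 3.86 4.24 4.39"),
    ("vpal", "m", 16): _row(
        "-2.80 -2.20 -1.51 -0.88 -0.31 0.23 0.74 1.23 1.68 2.12 2.55 2.95 3.35 3.73 3.88"),
    ("vpal", "m", 18): _row(
        "-3.05 -2.44 -1.76 -1.13 -0.55 -0.01 0.50 0.98 1.44 1.88 2.30 2.71 3.10 3.48 3.63"),
    ("vpal", "m", 21): _row(
        "-3.33 -2.73 -2.04 -1.41 -0.84 -0.30 0.21 0.70 1.15 1.59 2.02 2.42 2.82 3.20 3.35"),
}


#: published Equivalent-Score cutoffs (upper bounds of ES 0..3 bands) and
#: tolerance limits, per test — plausibility fixtures only (data-dependent).
#: The VPAL row is a verbatim duplicate of the DSF row in print (flagged).
PUBLISHED_ES_TABLE: dict[str, dict] = {
    "dsf": {"cutoffs": (4.02, 5.52, 5.99, 6.19), "otl": 4.02, "itl": 4.97,
            "suspect": False},
    "dsb": {"cutoffs": (2.79, 3.79, 4.57, 4.81), "otl": 2.79, "itl": 3.45,
            "suspect": False},
    "ravl_i": {"cutoffs": (35.62, 47.19, 51.26, 54.34), "otl": 35.62,
               "itl": 43.79, "suspect": False},
    "ravl_d": {"cutoffs": (6.24, 9.99, 11.23, 12.15), "otl": 6.24,
               "itl": 8.62, "suspect": False},
    "vpal": {"cutoffs": (4.02, 5.52, 5.99, 6.19), "otl": 4.02, "itl": 4.97,
             "suspect": True},  # printed row duplicates DSF; not ground truth
}


@dataclass
class FixtureReport:
    """Result of recomputing the printed grid from the fixture equations."""

    max_abs_deviation: float
    n_cells: int
    failures: list[tuple[tuple, int, float, float]] = field(default_factory=list)
    tolerance: float = 0.005

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_fixtures(tolerance: float = 0.005) -> FixtureReport:
    """Recompute every printed grid cell from the fixture equations.

    Cells deviating from the transcription by more than ``tolerance``
    (default 0.005, i.e. exact at 2-decimal rounding) are listed as
    failures with (key, age, computed, printed).
    """
    eqs = published_equations()
    grids = {name: build_grid(eq) for name, eq in eqs.items()}
    max_dev = 0.0
    n_cells = 0
    failures: list[tuple[tuple, int, float, float]] = []
    for (test, gender, edu), printed in PUBLISHED_GRID.items():
        grid = grids[test]
        for age, expected in zip(AGE_LATTICE, printed):
            got = grid.cell(age, gender=gender, education=edu)
            dev = abs(got - expected)
            max_dev = max(max_dev, dev)
            n_cells += 1
            if dev > tolerance:
                failures.append(((test, gender, edu), age, got, expected))
    return FixtureReport(max_abs_deviation=max_dev, n_cells=n_cells,
                         failures=failures, tolerance=tolerance)
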