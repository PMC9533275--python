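"""Regression-based demographic adjustment of raw test scores.

The procedure, per test:

1. *Transformation screening* — for each demographic covariate, candidate
   functional forms (identity, cube, square root, reciprocal, shifted log
   ``ln(c - x)``) are compared in one-predictor least-squares regressions
   of the raw score; the best form per covariate (highest R²) is kept.
2. *Stepwise selection* — the best-form covariates compete in a
   bidirectional p-value stepwise least-squares regression (enter/remove
   at 0.05 by default).
3. *Mean-deviation refit* — retained covariates and the outcome are
   centered at their sample means, refit, and the coefficients are
   reversed in sign so that adding the resulting correction term to a raw
   score *removes* the demographic effect:

   ``adjusted = raw + sum_j beta_j * (g_j(covariate_j) - mean(g_j))``

   At the sample means the correction is exactly zero, so adjustment
   leaves the cohort mean unchanged.

The fitted :class:`AdjustmentEquation` maps raw to adjusted scores and
tabulates into the clinical correction grid (ages 18-84 on a fixed
lattice, crossed with education and stratified by gender when those
covariates enter).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CohortTable, DemographicProfile

__all__ = [
    "TransformSpec",
    "Term",
    "AdjustmentEquation",
    "CorrectionGrid",
    "descriptive_screen",
    "screen_transforms",
    "stepwise_fit",
    "fit_adjustment",
    "adjust_score",
    "adjust_table",
    "build_grid",
    "default_candidates",
    "round_half_away",
    "AGE_LATTICE",
    "EDUCATION_LATTICE",
]

logger = logging.getLogger(__name__)

COVARIATES = ("age", "education", "gender")

AGE_LATTICE = (18, 22, 27, 32, 37, 42, 47, 52, 57, 62, 67, 72, 77, 82, 84)
EDUCATION_LATTICE = (5, 8, 13, 16, 18, 21)

#: functional forms, in simplicity order (ties in R² break toward earlier)
FORMS = ("identity", "cube", "sqrt", "reciprocal", "shifted_log")


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention of the printed grids)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TransformSpec:
    """A covariate and the functional form applied to it.

    ``offset`` is the shift constant ``c`` of the shifted log ``ln(c - x)``
    and must exceed the covariate's maximum observed value; it is unused
    by the other forms.
    """

    covariate: str
    form: str = "identity"
    offset: float | None = None

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "shifted_log" and self.offset is None:
            raise ValueError("shifted_log requires an offset constant")

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if self.form == "identity":
            out = x
        elif self.form == "cube":
            out = x**3
        elif self.form == "sqrt":
            out = np.sqrt(x)
        elif self.form == "reciprocal":
            out = 1.0 / x
        else:  # shifted_log, natural logarithm
            out = np.log(self.offset - x)
        return out if out.ndim else float(out)

    def valid_on(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        if self.form == "shifted_log":
            return bool(self.offset > x.max())
        if self.form == "reciprocal":
            return bool(x.min() > 0)
        if self.form == "sqrt":
            return bool(x.min() >= 0)
        return True

    @property
    def label(self) -> str:
        c = self.covariate.capitalize()
        if self.form == "shifted_log":
            return f"log({self.offset:g}-{c})"
        return {"identity": c, "cube": f"{c}^3", "sqrt": f"sqrt({c})",
                "reciprocal": f"1/{c}"}[self.form]


def default_candidates(cohort_ages: np.ndarray | None = None,
                       log_offset: float | None = None
                       ) -> dict[str, list[TransformSpec]]:
    """Default candidate forms per covariate.

    The shifted-log offset defaults to max(observed age) + 4 (88 for an
    18-84 sample) unless given explicitly.
    """
    if log_offset is None:
        if cohort_ages is None:
            log_offset = 88.0
        else:
            log_offset = float(np.max(cohort_ages)) + 4.0
    return {
        "age": [
            TransformSpec("age", "identity"),
            TransformSpec("age", "cube"),
            TransformSpec("age", "sqrt"),
            TransformSpec("age", "shifted_log", log_offset),
        ],
        "education": [
            TransformSpec("education", "identity"),
            TransformSpec("education", "reciprocal"),
        ],
        "gender": [TransformSpec("gender", "identity")],
    }


# ---------------------------------------------------------------------------
# Descriptive screening
# ---------------------------------------------------------------------------

def descriptive_screen(cohort: CohortTable) -> dict:
    """Per-variable descriptives, normality flags, and correlation matrix.

    Skewness is the adjusted Fisher-Pearson standardized third moment and
    kurtosis is excess kurtosis (both bias-corrected); a variable is
    flagged non-normal iff |skewness| > 1 or |kurtosis| > 3.  Correlations
    are Pearson r; pairs involving the 0/1 gender code are therefore
    point-biserial.  Zero-variance variables get undefined moments and
    missing correlations, with a warning.
    """
    variables = ["gender", "age", "education", *cohort.tests]
    rows = []
    for name in variables:
        vals = cohort.df[name].dropna().to_numpy(dtype=float)
        if len(vals) < 3:
            raise ValueError(f"fewer than 3 non-missing values for {name!r}")
        if np.ptp(vals) == 0:
            warnings.warn(
                f"{name!r} has zero variance; moments and correlations "
                "undefined", stacklevel=2,
            )
            skew = kurt = np.nan
        else:
            skew = stats.skew(vals, bias=False)
            kurt = stats.kurtosis(vals, fisher=True, bias=False)
        flagged = bool(np.isnan(skew) or abs(skew) > 1 or abs(kurt) > 3)
        rows.append(
            {
                "variable": name,
                "mean": vals.mean(),
                "sd": vals.std(ddof=1),
                "min": vals.min(),
                "max": vals.max(),
                "skewness": skew,
                "kurtosis": kurt,
                "non_normal": flagged,
            }
        )
    desc = pd.DataFrame(rows).set_index("variable")

    sub = cohort.df[variables].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = sub.corr(method="pearson")
    for name in variables:
        if np.ptp(sub[name].dropna().to_numpy()) == 0:
            corr.loc[name, :] = np.nan
            corr.loc[:, name] = np.nan
    return {"descriptives": desc, "correlations": corr}


# ---------------------------------------------------------------------------
# Transformation screening
# ---------------------------------------------------------------------------

def _bivariate_r2(y: np.ndarray, x: np.ndarray) -> float:
    x = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), x).fit()
    return float(fit.rsquared)


def screen_transforms(
    cohort: CohortTable,
    test: str,
    candidates: Mapping[str, Sequence[TransformSpec]] | None = None,
) -> dict[str, list[tuple[TransformSpec, float]]]:
    """Rank candidate forms per covariate by one-predictor R².

    Invalid candidates (shifted log with offset not exceeding the observed
    maximum, reciprocal on non-positive values) are skipped with a
    warning.  Ties in R² break toward the simpler form (candidate order).
    """
    data = cohort.df.dropna(subset=[test])
    y = data[test].to_numpy(dtype=float)
    if candidates is None:
        candidates = default_candidates(data["age"].to_numpy())
    ranked: dict[str, list[tuple[TransformSpec, float]]] = {}
    for cov, specs in candidates.items():
        if not specs:
            raise ValueError(f"empty candidate list for {cov!r}")
        x = data[cov].to_numpy(dtype=float)
        scored: list[tuple[TransformSpec, float]] = []
        for spec in specs:
            if not spec.valid_on(x):
                warnings.warn(
                    f"skipping candidate {spec.label}: invalid on the "
                    f"observed range of {cov}", stacklevel=2,
                )
                continue
            scored.append((spec, _bivariate_r2(y, spec(x))))
        # stable sort keeps candidate (simplicity) order on exact ties
        scored.sort(key=lambda t: -t[1])
        ranked[cov] = scored
    return ranked


def best_forms(ranked: Mapping[str, list[tuple[TransformSpec, float]]]
               ) -> dict[str, TransformSpec]:
    return {cov: lst[0][0] for cov, lst in ranked.items() if lst}


# ---------------------------------------------------------------------------
# Stepwise fit and the adjustment equation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """One correction term: sign-reversed coefficient and centering constant."""

    transform: TransformSpec
    beta: float  # already sign-reversed: correction = beta * (g(x) - center)
    center: float  # sample mean of the transformed covariate

    def correction(self, value: float | np.ndarray) -> float | np.ndarray:
        return self.beta * (self.transform(value) - self.center)


@dataclass
class AdjustmentEquation:
    """Fitted demographic-correction equation for one test.

    ``adjusted = raw + sum(term.correction(covariate value))``.  An empty
    term list means the adjusted score equals the raw score.
    """

    test: str
    terms: list[Term] = field(default_factory=list)
    r2: float = 0.0
    adj_r2: float = 0.0
    rmse: float = float("nan")
    n: int = 0
    fit_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = [t.transform.covariate for t in self.terms]
        if len(seen) != len(set(seen)):
            raise ValueError("each covariate may appear at most once")

    @property
    def covariates(self) -> list[str]:
        return [t.transform.covariate for t in self.terms]

    def correction(self, demo: Mapping[str, float] | DemographicProfile) -> float:
        if isinstance(demo, DemographicProfile):
            demo = {"age": demo.age, "education": demo.education,
                    "gender": demo.gender}
        total = 0.0
        for term in self.terms:
            cov = term.transform.covariate
            value = float(demo[cov])
            rng = self.fit_ranges.get(cov)
            if rng is not None and not rng[0] <= value <= rng[1]:
                logger.warning(
                    "extrapolation: %s=%s outside fitting range %s for %s",
                    cov, value, rng, self.test,
                )
            total += term.correction(value)
        return total

    def formula(self) -> str:
        parts = [
            f"{t.beta:+g}*({t.transform.label} - {t.center:g})"
            for t in self.terms
        ]
        return f"adjusted = raw {' '.join(parts)}" if parts else "adjusted = raw"

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "test": self.test,
            "terms": [
                {
                    "covariate": t.transform.covariate,
                    "form": t.transform.form,
                    "offset": t.transform.offset,
                    "beta": t.beta,
                    "center": t.center,
                }
                for t in self.terms
            ],
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "rmse": self.rmse,
            "n": self.n,
            "fit_ranges": {k: list(v) for k, v in self.fit_ranges.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AdjustmentEquation":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text()
        payload = json.loads(source)
        terms = [
            Term(
                TransformSpec(d["covariate"], d["form"], d.get("offset")),
                d["beta"],
                d["center"],
            )
            for d in payload["terms"]
        ]
        return cls(
            test=payload["test"],
            terms=terms,
            r2=payload.get("r2", 0.0),
            adj_r2=payload.get("adj_r2", 0.0),
            rmse=payload.get("rmse", float("nan")),
            n=payload.get("n", 0),
            fit_ranges={
                k: tuple(v) for k, v in payload.get("fit_ranges", {}).items()
            },
        )


def stepwise_fit(
    cohort: CohortTable,
    test: str,
    forms: Mapping[str, TransformSpec] | None = None,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
) -> AdjustmentEquation:
    """Bidirectional p-value stepwise fit, then mean-deviation refit.

    Covariates (each in its best transformation) enter while their t-test
    p-value beats ``alpha_enter`` and leave while it exceeds
    ``alpha_remove``.  The final model is refit on mean-centered
    covariates and outcome; coefficients are stored sign-reversed with
    their centering constants so the equation *corrects* raw scores.
    """
    data = cohort.df.dropna(subset=[test])
    y = data[test].to_numpy(dtype=float)
    if forms is None:
        forms = best_forms(screen_transforms(cohort, test))

    transformed = {cov: np.asarray(spec(data[cov].to_numpy(dtype=float)))
                   for cov, spec in forms.items()}

    included: list[str] = []
    while True:
        changed = False
        # forward: best new candidate by p-value
        candidates = [c for c in forms if c not in included]
        best_p, best_c = 1.0, None
        for cand in candidates:
            x = sm.add_constant(
                np.column_stack([transformed[c] for c in included + [cand]])
            )
            fit = sm.OLS(y, x).fit()
            p = fit.pvalues[-1]
            if p < best_p:
                best_p, best_c = p, cand
        if best_c is not None and best_p < alpha_enter:
            included.append(best_c)
            changed = True
        # backward: drop the worst included covariate
        if included:
            x = sm.add_constant(
                np.column_stack([transformed[c] for c in included])
            )
            fit = sm.OLS(y, x).fit()
            pvals = fit.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > alpha_remove:
                included.pop(worst)
                changed = True
        if not changed:
            break

    fit_ranges = {
        cov: (float(data[cov].min()), float(data[cov].max()))
        for cov in included
    }

    if not included:
        logger.info("%s: no covariate entered; adjusted score = raw score", test)
        return AdjustmentEquation(
            test=test, terms=[], r2=0.0, adj_r2=0.0,
            rmse=float(np.std(y, ddof=1)), n=len(y), fit_ranges={},
        )

    # mean-deviation refit: center covariates and outcome, reverse signs
    centers = {c: float(transformed[c].mean()) for c in included}
    xc = np.column_stack([transformed[c] - centers[c] for c in included])
    yc = y - y.mean()
    fit = sm.OLS(yc, sm.add_constant(xc)).fit()
    betas = fit.params[1:]
    k = len(included)
    resid_df = len(y) - k - 1
    rmse = float(np.sqrt(fit.ssr / resid_df)) if resid_df > 0 else 0.0
    terms = [
        Term(forms[cov], -float(b), centers[cov])
        for cov, b in zip(included, betas)
    ]
    return AdjustmentEquation(
        test=test,
        terms=terms,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        rmse=rmse,
        n=len(y),
        fit_ranges=fit_ranges,
    )


def fit_adjustment(cohort: CohortTable, test: str,
                   alpha_enter: float = 0.05,
                   alpha_remove: float = 0.05) -> AdjustmentEquation:
    """Full per-test pipeline: screen transformations, then stepwise fit."""
    ranked = screen_transforms(cohort, test)
    return stepwise_fit(cohort, test, best_forms(ranked),
                        alpha_enter, alpha_remove)


# ---------------------------------------------------------------------------
# Applying equations
# ---------------------------------------------------------------------------

def adjust_score(
    eq: AdjustmentEquation,
    raw: float,
    demo: Mapping[str, float] | DemographicProfile,
) -> float:
    """Demographically adjusted score (unrounded; display rounding is separate)."""
    return float(raw) + eq.correction(demo)


def adjust_table(eq: AdjustmentEquation, cohort: CohortTable) -> pd.Series:
    """Vectorized adjustment of a cohort's raw scores for ``eq.test``."""
    df = cohort.df
    corr = np.zeros(len(df))
    for term in eq.terms:
        cov = term.transform.covariate
        vals = df[cov].to_numpy(dtype=float)
        rng = eq.fit_ranges.get(cov)
        if rng is not None:
            n_out = int(((vals < rng[0]) | (vals > rng[1])).sum())
            if n_out:
                logger.warning(
                    "extrapolation: %d %s values outside fitting range %s "
                    "for %s", n_out, cov, rng, eq.test,
                )
        corr += np.asarray(term.correction(vals))
    return df[eq.test].astype(float) + corr


# ---------------------------------------------------------------------------
# Correction grid
# ---------------------------------------------------------------------------

@dataclass
class CorrectionGrid:
    """Clinical correction grid: correction values on an age lattice,
    crossed with education and stratified by gender where those enter the
    equation.  Cells are rounded half-away-from-zero to 2 decimals."""

    test: str
    ages: tuple[int, ...]
    table: pd.DataFrame  # columns: gender ('' if absent), education, ages...

    def cell(self, age: int, gender: str | None = None,
             education: int | None = None) -> float:
        t = self.table
        if gender is not None:
            t = t[t["gender"] == gender]
        if education is not None:
            t = t[t["education"] == education]
        if len(t) != 1:
            raise KeyError(
                f"grid lookup for {self.test} (gender={gender}, "
                f"education={education}) matched {len(t)} rows"
            )
        return float(t.iloc[0][age])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, lineterminator="\n")


def build_grid(
    eq: AdjustmentEquation,
    ages: Iterable[int] = AGE_LATTICE,
    educations: Iterable[int] = EDUCATION_LATTICE,
) -> CorrectionGrid:
    """Tabulate the equation's correction term on the clinical lattice."""
    ages = tuple(ages)
    has_edu = "education" in eq.covariates
    has_gender = "gender" in eq.covariates
    edu_levels: tuple = tuple(educations) if has_edu else (None,)
    gender_levels = (("f", 1), ("m", 0)) if has_gender else (("", None),)

    rows = []
    for glabel, gcode in gender_levels:
        for edu in edu_levels:
            row: dict = {"gender": glabel, "education": edu}
            for age in ages:
                demo = {"age": age}
                if edu is not None:
                    demo["education"] = edu
                if gcode is not None:
                    demo["gender"] = gcode
                # suppress the extrapolation logger for lattice points: the
                # lattice is inside the design range by construction
                value = sum(
                    t.correction(demo[t.transform.covariate]) for t in eq.terms
                )
                row[age] = round_half_away(value, 2)
            rows.append(row)
    return CorrectionGrid(eq.test, ages, pd.DataFrame(rows))
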