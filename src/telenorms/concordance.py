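"""Agreement between two normative scoring systems on a patient cohort.

One system supplies the *reference* impairment classification (emulating
externally published norms), the other the *predicted* classification
(the newly fitted norms).  Per test the module reports the 2x2 confusion
matrix, accuracy, ROC/AUC of the continuous adjusted score against the
reference flag, Cohen's kappa, and Gwet's AC1 (the chance-corrected
agreement index robust to marginal imbalance), each with a 95% CI.

Conventions:

* impairment: adjusted score <= cutoff (default cutoff = the system's
  outer tolerance limit, i.e. Equivalent Score 0);
* AUC: Mann-Whitney rank statistic, oriented so that *lower* adjusted
  scores predict impairment, ties counted half; CI by DeLong (default)
  or a seeded percentile bootstrap;
* kappa CI: large-sample standard error sqrt(po(1-po)) / ((1-pe) sqrt(n));
* AC1 CI: Gwet's linearized variance estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .adjust import AdjustmentEquation, adjust_table
from .cohort import CohortTable
from .norms import ESThresholds, assign_es

__all__ = [
    "NormativeSystem",
    "ConfusionMatrix",
    "Estimate",
    "AgreementStats",
    "classify",
    "cross_tabulate",
    "cohen_kappa",
    "gwet_ac1",
    "auc_mann_whitney",
    "delong_ci",
    "agreement_stats",
    "run_comparison",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class NormativeSystem:
    """A named adjustment equation plus an impairment rule.

    ``cutoff`` is in adjusted-score units; if omitted it defaults to the
    outer tolerance limit of ``thresholds`` (Equivalent Score 0).
    """

    name: str
    equation: AdjustmentEquation
    thresholds: ESThresholds | None = None
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.cutoff is None:
            if self.thresholds is None:
                raise ValueError(
                    f"system {self.name!r} needs either a cutoff or "
                    "Equivalent-Score thresholds"
                )
            self.cutoff = self.thresholds.c0

    def impaired(self, adjusted: np.ndarray) -> np.ndarray:
        return np.asarray(adjusted) <= self.cutoff


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 cross-classification: (reference impaired/normal) x
    (predicted impaired/normal).  ``a`` = both impaired, ``b`` = reference
    impaired only, ``c`` = predicted impaired only, ``d`` = both normal."""

    a: int
    b: int
    c: int
    d: int
    ref_label: str = "reference"
    pred_label: str = "predicted"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.a, self.b], [self.c, self.d]],
            index=pd.Index(["impaired", "normal"], name=self.ref_label),
            columns=pd.Index(["impaired", "normal"], name=self.pred_label),
        )


def classify(cohort: CohortTable, system: NormativeSystem, test: str
             ) -> pd.DataFrame:
    """Adjusted score, impairment flag, and Equivalent Score per row.

    Rows with missing demographics or missing raw scores are excluded
    (count logged via warning).
    """
    if test != system.equation.test:
        raise ValueError(
            f"system {system.name!r} fits {system.equation.test!r}, "
            f"not {test!r}"
        )
    df = cohort.df
    needed = ["age", "education", "gender", test]
    mask = df[needed].notna().all(axis=1)
    if (~mask).any():
        warnings.warn(
            f"{int((~mask).sum())} rows with missing data excluded for "
            f"{test}", stacklevel=2,
        )
    sub = CohortTable(df[mask], validate=False)
    adjusted = adjust_table(system.equation, sub).to_numpy()
    out = pd.DataFrame(
        {
            "id": sub.df["id"].to_numpy(),
            "adjusted": adjusted,
            "impaired": system.impaired(adjusted),
        }
    )
    if system.thresholds is not None:
        out["es"] = assign_es(adjusted, system.thresholds)
    return out


def cross_tabulate(ref: np.ndarray, pred: np.ndarray,
                   ref_label: str = "reference",
                   pred_label: str = "predicted") -> ConfusionMatrix:
    """2x2 counts from two equal-length binary flag vectors."""
    ref = np.asarray(ref, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if ref.shape != pred.shape:
        raise ValueError("flag vectors must have equal length")
    return ConfusionMatrix(
        a=int((ref & pred).sum()),
        b=int((ref & ~pred).sum()),
        c=int((~ref & pred).sum()),
        d=int((~ref & ~pred).sum()),
        ref_label=ref_label,
        pred_label=pred_label,
    )


@dataclass(frozen=True)
class Estimate:
    value: float
    lo: float = float("nan")
    hi: float = float("nan")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.value, self.lo, self.hi)


def cohen_kappa(cm: ConfusionMatrix) -> Estimate:
    """Cohen's kappa with product-of-marginals chance agreement.

    Undefined (NaN, with warning) when the chance agreement is 1, i.e.
    both raters use a single category.
    """
    n = cm.n
    po = (cm.a + cm.d) / n
    ref_imp = (cm.a + cm.b) / n
    pred_imp = (cm.a + cm.c) / n
    pe = ref_imp * pred_imp + (1 - ref_imp) * (1 - pred_imp)
    if pe >= 1.0 - 1e-12:
        warnings.warn("degenerate marginals: kappa undefined", stacklevel=2)
        return Estimate(float("nan"))
    kappa = (po - pe) / (1 - pe)
    se = np.sqrt(po * (1 - po)) / ((1 - pe) * np.sqrt(n))
    return Estimate(kappa, max(kappa - _Z95 * se, -1.0),
                    min(kappa + _Z95 * se, 1.0))


def gwet_ac1(cm: ConfusionMatrix) -> Estimate:
    """Gwet's AC1 for two raters and a binary category.

    Chance agreement p_gamma = 2*pi*(1-pi) with pi the mean of the two
    raters' impaired proportions; the variance is Gwet's linearized
    estimator, computable from the four cell counts.
    """
    n = cm.n
    po = (cm.a + cm.d) / n
    pi = ((cm.a + cm.b) + (cm.a + cm.c)) / (2.0 * n)
    pg = 2.0 * pi * (1.0 - pi)
    if pg >= 1.0 - 1e-12:
        warnings.warn("degenerate marginals: AC1 undefined", stacklevel=2)
        return Estimate(float("nan"))
    ac1 = (po - pg) / (1.0 - pg)
    if n < 2:
        return Estimate(ac1)
    # per-item linearization: items in cell a/d agree, b/c disagree; the
    # item-level chance term is (1-pi), pi, or 1/2 respectively
    cells = (
        (cm.a, 1.0, 1.0 - pi),
        (cm.d, 1.0, pi),
        (cm.b, 0.0, 0.5),
        (cm.c, 0.0, 0.5),
    )
    var = 0.0
    for count, agree, pg_i in cells:
        if count == 0:
            continue
        gamma_i = (agree - pg) / (1.0 - pg)
        star = gamma_i - 2.0 * (1.0 - ac1) * (pg_i - pg) / (1.0 - pg)
        var += count * (star - ac1) ** 2
    var /= n * (n - 1)
    se = np.sqrt(var)
    return Estimate(ac1, max(ac1 - _Z95 * se, -1.0), min(ac1 + _Z95 * se, 1.0))


def _auc_components(scores: np.ndarray, impaired: np.ndarray
                    ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus DeLong structural components, via midranks.

    Predictor orientation: impairment is the positive class and lower
    adjusted scores predict it, so the working predictor is ``-scores``.
    """
    x = -np.asarray(scores, dtype=float)
    pos = np.asarray(impaired, dtype=bool)
    m, k = int(pos.sum()), int((~pos).sum())
    if m == 0 or k == 0:
        raise ValueError("need both impaired and normal cases for AUC")
    all_r = stats.rankdata(x)  # midranks: ties counted half
    pos_r = stats.rankdata(x[pos])
    neg_r = stats.rankdata(x[~pos])
    auc = (all_r[pos].sum() - m * (m + 1) / 2.0) / (m * k)
    v10 = (all_r[pos] - pos_r) / k          # per-impaired components
    v01 = 1.0 - (all_r[~pos] - neg_r) / m   # per-normal components
    return float(auc), v10, v01


def auc_mann_whitney(scores: np.ndarray, impaired: np.ndarray) -> float:
    """Rank-statistic AUC of adjusted scores against the reference flag."""
    auc, _, _ = _auc_components(scores, impaired)
    return auc


def delong_ci(scores: np.ndarray, impaired: np.ndarray) -> Estimate:
    """AUC with DeLong 95% confidence interval."""
    auc, v10, v01 = _auc_components(scores, impaired)
    var = 0.0
    if len(v10) > 1:
        var += np.var(v10, ddof=1) / len(v10)
    if len(v01) > 1:
        var += np.var(v01, ddof=1) / len(v01)
    se = np.sqrt(var)
    return Estimate(auc, max(auc - _Z95 * se, 0.0), min(auc + _Z95 * se, 1.0))


def _bootstrap_auc_ci(scores: np.ndarray, impaired: np.ndarray,
                      n_boot: int, rng: np.random.Generator) -> Estimate:
    scores = np.asarray(scores, dtype=float)
    impaired = np.asarray(impaired, dtype=bool)
    n = len(scores)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        if impaired[idx].all() or not impaired[idx].any():
            aucs[i] = np.nan
            continue
        aucs[i] = auc_mann_whitney(scores[idx], impaired[idx])
    point = auc_mann_whitney(scores, impaired)
    lo, hi = np.nanpercentile(aucs, [2.5, 97.5])
    return Estimate(point, float(lo), float(hi))


@dataclass
class AgreementStats:
    """Agreement between two normative systems on one test."""

    accuracy: float
    auc: Estimate
    kappa: Estimate
    ac1: Estimate

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc.as_tuple(),
            "kappa": self.kappa.as_tuple(),
            "ac1": self.ac1.as_tuple(),
        }


def agreement_stats(
    cm: ConfusionMatrix,
    ref: np.ndarray | None = None,
    predictor_scores: np.ndarray | None = None,
    auc_ci: str = "delong",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> AgreementStats:
    """Accuracy, AUC, Cohen's kappa, and Gwet's AC1 for a 2x2 table.

    ``predictor_scores`` are the continuous adjusted scores under the
    predicting system, required for AUC; without them AUC is NaN.
    """
    accuracy = (cm.a + cm.d) / cm.n
    if predictor_scores is not None and ref is not None:
        ref = np.asarray(ref, dtype=bool)
        if len(ref) != cm.n:
            raise ValueError("reference flags inconsistent with table size")
        if ref.all() or not ref.any():
            warnings.warn(
                "reference classification has a single class; AUC undefined",
                stacklevel=2,
            )
            auc = Estimate(float("nan"))
        elif auc_ci == "bootstrap":
            auc = _bootstrap_auc_ci(predictor_scores, ref, n_boot,
                                    rng or np.random.default_rng())
        else:
            auc = delong_ci(predictor_scores, ref)
    else:
        auc = Estimate(float("nan"))
    return AgreementStats(
        accuracy=accuracy,
        auc=auc,
        kappa=cohen_kappa(cm),
        ac1=gwet_ac1(cm),
    )


@dataclass
class ComparisonResult:
    """Per-test output of :func:`run_comparison`."""

    stats: AgreementStats
    confusion: ConfusionMatrix
    roc: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_comparison(
    patients: CohortTable,
    system_new: NormativeSystem | dict[str, NormativeSystem],
    system_ref: NormativeSystem | dict[str, NormativeSystem],
    tests: list[str] | None = None,
    seed: int = 0,
    auc_ci: str = "delong",
) -> dict[str, ComparisonResult]:
    """Full normative-system comparison over a set of tests.

    ``system_ref`` supplies the reference classification, ``system_new``
    the prediction and the continuous AUC predictor.  Systems may be
    given per test (dict) or as a single system.  Tests missing from
    either side are skipped with a warning.
    """
    if tests is None:
        tests = patients.tests
    rng = np.random.default_rng(seed)
    results: dict[str, ComparisonResult] = {}
    for test in tests:
        try:
            new = system_new[test] if isinstance(system_new, dict) else system_new
            ref = system_ref[test] if isinstance(system_ref, dict) else system_ref
        except KeyError:
            warnings.warn(f"no normative system for {test}; skipped",
                          stacklevel=2)
            continue
        if test not in patients.tests:
            warnings.warn(f"{test} missing from patient cohort; skipped",
                          stacklevel=2)
            continue
        pred_rows = classify(patients, new, test)
        ref_rows = classify(patients, ref, test)
        merged = pred_rows.merge(ref_rows, on="id", suffixes=("_new", "_ref"))
        cm = cross_tabulate(
            merged["impaired_ref"], merged["impaired_new"],
            ref_label=ref.name, pred_label=new.name,
        )
        st = agreement_stats(
            cm,
            ref=merged["impaired_ref"].to_numpy(),
            predictor_scores=merged["adjusted_new"].to_numpy(),
            auc_ci=auc_ci,
            rng=rng,
        )
        roc = _roc_points(merged["adjusted_new"].to_numpy(),
                          merged["impaired_ref"].to_numpy())
        results[test] = ComparisonResult(stats=st, confusion=cm, roc=roc)
    return results


def _roc_points(scores: np.ndarray, impaired: np.ndarray) -> pd.DataFrame:
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(impaired, dtype=int),
                              -np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": -thr})
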