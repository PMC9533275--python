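"""Normative scoring of adjusted test scores.

Converts a sample of demographically adjusted scores into:

* non-parametric **tolerance limits** on the population 5th centile —
  the outer limit (OTL, conservative lower bound, 95% confidence) and
  the inner limit (ITL), both order statistics chosen by exact binomial
  enumeration (no normal approximation);
* **Equivalent Scores** (ES), the 5-level ordinal normative scale used in
  Italian neuropsychology: ES 0 at or below the OTL, ES 4 above the
  sample median, ES 1-3 filling the region in between by equal-frequency
  rank tertiles;
* an empirical **percentile table** (type-7 linear interpolation of
  order statistics, the convention recorded in output metadata).

Rank conventions.  With B ~ Binomial(n, p) counting observations below
the p-th centile:

* outer rank r = the largest integer with P(B <= r-1) <= 1 - gamma, so
  the r-th order statistic undershoots the centile with confidence gamma;
* inner rank s = the smallest integer with P(B <= s) >= gamma — the
  convention that reproduces the rank tables of the Equivalent-Score
  literature (e.g. n = 204 gives ranks 5 and 16).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ToleranceLimits",
    "ESThresholds",
    "PercentileTable",
    "tolerance_limits",
    "tolerance_ranks",
    "es_thresholds",
    "assign_es",
    "percentile_table",
    "DEFAULT_PERCENTILE_LEVELS",
]

DEFAULT_PERCENTILE_LEVELS: tuple[int, ...] = (
    99, 95, 90, 85, 80, 75, 70, 65, 60, 55, 50,
    45, 40, 35, 30, 25, 20, 15, 10, 5, 4, 3, 2, 1,
)


@dataclass(frozen=True)
class ToleranceLimits:
    """Outer/inner non-parametric tolerance limits on the p-th centile."""

    otl: float
    itl: float
    outer_rank: int
    inner_rank: int
    n: int
    p: float = 0.05
    gamma: float = 0.95

    def __post_init__(self) -> None:
        if self.otl > self.itl:
            raise ValueError("OTL must not exceed ITL")


def _min_n(p: float, gamma: float) -> int:
    # smallest n with (1-p)^n <= 1-gamma, i.e. a valid outer rank r = 1
    return math.ceil(math.log(1.0 - gamma) / math.log(1.0 - p))


def tolerance_ranks(n: int, p: float = 0.05, gamma: float = 0.95
                    ) -> tuple[int, int]:
    """Outer and inner order-statistic ranks by exact binomial enumeration."""
    cdf = stats.binom.cdf(np.arange(0, n + 1), n, p)
    valid_outer = np.nonzero(cdf[:-1] <= 1.0 - gamma)[0]  # indices r-1
    if valid_outer.size == 0:
        raise ValueError(
            f"n = {n} too small for a valid outer tolerance rank at "
            f"p = {p}, gamma = {gamma}; need n >= {_min_n(p, gamma)}"
        )
    outer = int(valid_outer[-1]) + 1
    inner = int(np.searchsorted(cdf, gamma, side="left"))
    return outer, inner


def tolerance_limits(adjusted: Sequence[float], p: float = 0.05,
                     gamma: float = 0.95) -> ToleranceLimits:
    """Exact-binomial tolerance limits of a sample of adjusted scores."""
    x = np.sort(np.asarray(adjusted, dtype=float))
    n = len(x)
    outer, inner = tolerance_ranks(n, p, gamma)
    return ToleranceLimits(
        otl=float(x[outer - 1]),
        itl=float(x[inner - 1]),
        outer_rank=outer,
        inner_rank=inner,
        n=n,
        p=p,
        gamma=gamma,
    )


@dataclass
class ESThresholds:
    """Equivalent-Score band cutoffs for one test.

    Bands follow the "<= upper bound" convention: ES 0 iff x <= c0 (the
    OTL), ES k iff c(k-1) < x <= ck for k in 1..3 with c3 the sample
    median, ES 4 iff x > c3.
    """

    test: str
    c0: float
    c1: float
    c2: float
    c3: float
    median: float
    limits: ToleranceLimits
    degenerate: bool = False

    @property
    def cutoffs(self) -> tuple[float, float, float, float]:
        return (self.c0, self.c1, self.c2, self.c3)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "test": self.test,
            "cutoffs": list(self.cutoffs),
            "median": self.median,
            "degenerate": self.degenerate,
            "limits": {
                "otl": self.limits.otl, "itl": self.limits.itl,
                "outer_rank": self.limits.outer_rank,
                "inner_rank": self.limits.inner_rank,
                "n": self.limits.n, "p": self.limits.p,
                "gamma": self.limits.gamma,
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ESThresholds":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text()
        payload = json.loads(source)
        limits = ToleranceLimits(**payload["limits"])
        c0, c1, c2, c3 = payload["cutoffs"]
        return cls(test=payload["test"], c0=c0, c1=c1, c2=c2, c3=c3,
                   median=payload["median"], limits=limits,
                   degenerate=payload.get("degenerate", False))


def es_thresholds(adjusted: Sequence[float], limits: ToleranceLimits,
                  test: str = "") -> ESThresholds:
    """Equivalent-Score cutoffs from a sample and its tolerance limits.

    ES 0 is bounded by the OTL and ES 4 by the median.  Observations in
    (OTL, median] are split by rank into three consecutive groups of as
    equal as possible size (remainders to the lower groups first); the
    maxima of the first two groups give c1 and c2.  Tied or too-sparse
    regions collapse with a warning and set ``degenerate``.
    """
    x = np.sort(np.asarray(adjusted, dtype=float))
    c0 = limits.otl
    median = float(np.median(x))
    region = x[(x > c0) & (x <= median)]
    k = len(region)
    degenerate = False
    if k < 3:
        warnings.warn(
            f"only {k} observations between OTL and median; Equivalent-"
            "Score bands collapse", stacklevel=2,
        )
        degenerate = True
        c1 = c2 = region[-1] if k else c0
    else:
        base, rem = divmod(k, 3)
        n1 = base + (1 if rem >= 1 else 0)
        n2 = base + (1 if rem >= 2 else 0)
        c1 = float(region[n1 - 1])
        c2 = float(region[n1 + n2 - 1])
    cuts = [c0, c1, c2, median]
    if len({round(c, 12) for c in cuts}) < 4:
        warnings.warn(
            f"tied Equivalent-Score cutoffs {cuts}; bands collapse",
            stacklevel=2,
        )
        degenerate = True
    return ESThresholds(test=test, c0=float(c0), c1=float(c1), c2=float(c2),
                        c3=median, median=median, limits=limits,
                        degenerate=degenerate)


def assign_es(x: float | np.ndarray, th: ESThresholds) -> int | np.ndarray:
    """Equivalent Score of an adjusted score (0 impaired … 4 above median)."""
    arr = np.asarray(x, dtype=float)
    es = np.full(arr.shape, 4, dtype=int)
    es[arr <= th.c3] = 3
    es[arr <= th.c2] = 2
    es[arr <= th.c1] = 1
    es[arr <= th.c0] = 0
    return int(es) if es.ndim == 0 else es


@dataclass
class PercentileTable:
    """Empirical percentiles of adjusted scores at fixed levels."""

    test: str
    levels: tuple[int, ...]
    values: tuple[float, ...]
    method: str = "linear"  # type-7 interpolation of order statistics

    def value_at(self, level: int) -> float:
        return self.values[self.levels.index(level)]

    def rounded(self, decimals: int = 1) -> dict[int, float]:
        return {lv: round(v, decimals) for lv, v in zip(self.levels, self.values)}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "test": self.test,
            "levels": list(self.levels),
            "values": list(self.values),
            "method": self.method,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PercentileTable":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text()
        payload = json.loads(source)
        return cls(test=payload["test"], levels=tuple(payload["levels"]),
                   values=tuple(payload["values"]),
                   method=payload.get("method", "linear"))


def percentile_table(adjusted: Sequence[float],
                     levels: Sequence[int] = DEFAULT_PERCENTILE_LEVELS,
                     test: str = "") -> PercentileTable:
    """Empirical quantiles at the table's levels (type-7 convention)."""
    x = np.asarray(adjusted, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    values = np.quantile(x, np.asarray(levels) / 100.0, method="linear")
    return PercentileTable(test=test, levels=tuple(int(v) for v in levels),
                           values=tuple(float(v) for v in values))
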