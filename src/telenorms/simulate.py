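"""Synthetic cohort generation.

Two generators stand in for data that cannot be redistributed:

* :func:`simulate_healthy_cohort` emulates the healthy normative sample —
  a Gaussian copula with the published correlation targets, mapped to
  truncated-normal marginals with the published means/SDs and bounds.
  Gender is a latent Gaussian thresholded at the target female proportion;
  its latent correlations are pre-inflated by the point-biserial
  attenuation factor so the published gender correlations survive
  thresholding.
* :func:`simulate_patient_cohort` emulates the simulated clinical
  comparison cohort: per-test scores drawn Normal(mean, SD) and clipped to
  the catalog, with age and education paired so their realized Pearson
  correlation hits a target (default -0.22) within a tolerance (default
  0.02), by bisection over the latent copula correlation.

Identical :class:`~telenorms.cohort.SimulationSpec` (including seed) gives
byte-identical CSV output.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .cohort import (
    TEST_CATALOG,
    CohortTable,
    MarginalSpec,
    SimulationSpec,
)

__all__ = [
    "simulate_healthy_cohort",
    "simulate_patient_cohort",
    "nearest_correlation",
]

_PSD_FLOOR = 1e-8


def nearest_correlation(r: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Repair a symmetric matrix into a valid correlation matrix.

    Eigenvalues below ``floor`` are clipped up, then the matrix is rescaled
    back to unit diagonal.  Raises if the result is still not positive
    semidefinite (within tolerance), naming the offending eigenvalue.
    """
    r = np.asarray(r, dtype=float)
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    if w.min() >= 0:
        return r
    w_clipped = np.clip(w, floor, None)
    fixed = (v * w_clipped) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    w2 = np.linalg.eigvalsh(fixed)
    if w2.min() < -_PSD_FLOOR:
        raise ValueError(
            "correlation matrix not positive semidefinite after repair: "
            f"smallest eigenvalue {w2.min():.3e}"
        )
    return fixed


def _truncnorm_params(m: MarginalSpec) -> tuple[float, float, float, float]:
    """Parent (loc, scale) and standardized (a, b) of a truncated normal
    whose *realized* mean and SD on [lower, upper] match the targets.

    The naive choice loc = mean, scale = sd realizes the wrong moments
    under asymmetric truncation, so the parent parameters are solved by
    moment matching.  If matching fails (bounds inconsistent with the
    requested mean ± SD) the naive parameters are used with a warning;
    clipping then handles the excess.
    """
    from scipy.optimize import least_squares

    span = m.upper - m.lower

    def params_of(ab: np.ndarray) -> tuple[float, float]:
        a, b = ab
        scale = span / (b - a)
        return m.lower - a * scale, scale

    def resid(ab: np.ndarray) -> np.ndarray:
        if ab[1] - ab[0] < 1e-6:
            return np.array([1e3, 1e3])
        loc, scale = params_of(ab)
        mom = stats.truncnorm.stats(*ab, loc=loc, scale=scale, moments="mv")
        # the mean is weighted above the SD: near the feasibility edge the
        # SD may be unattainable and the mean must not drift to compensate
        return np.array(
            [(mom[0] - m.mean) / m.sd, 0.5 * (np.sqrt(mom[1]) - m.sd) / m.sd]
        )

    a0 = (m.lower - m.mean) / m.sd
    b0 = (m.upper - m.mean) / m.sd
    sol = least_squares(
        resid, np.clip([a0, b0], -5.9, 5.9),
        bounds=([-6.0, -6.0], [6.0, 6.0]), xtol=1e-13, ftol=1e-13,
    )
    loc, scale = params_of(sol.x)
    mean_err, sd_err = sol.fun[0] * m.sd, 2.0 * sol.fun[1] * m.sd
    if abs(mean_err) > 0.05 * m.sd or abs(sd_err) > 0.15 * m.sd:
        warnings.warn(
            f"bounds [{m.lower}, {m.upper}] inconsistent with target "
            f"mean {m.mean} ± SD {m.sd} (best truncated-normal fit off by "
            f"{mean_err:+.3g} / {sd_err:+.3g}); proceeding with clipping",
            stacklevel=3,
        )
    return loc, scale, float(sol.x[0]), float(sol.x[1])


_PARAM_CACHE: dict[MarginalSpec, tuple[float, float, float, float]] = {}


def _marginal_ppf(u: np.ndarray, m: MarginalSpec) -> np.ndarray:
    if m not in _PARAM_CACHE:
        _PARAM_CACHE[m] = _truncnorm_params(m)
    loc, scale, a, b = _PARAM_CACHE[m]
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)


def _round_to_granularity(x: np.ndarray, granularity: float) -> np.ndarray:
    return np.round(x / granularity) * granularity


def _finalize(x: np.ndarray, m: MarginalSpec) -> np.ndarray:
    """Round to the variable's granularity and clip to its bounds."""
    out = _round_to_granularity(x, m.granularity)
    return np.clip(out, m.lower, m.upper)


# equal-probability quadrature grid for the linear-loading integrals
_QUAD_U = (np.arange(20001) + 0.5) / 20001
_QUAD_Z = stats.norm.ppf(_QUAD_U)


def _linear_loading(m: MarginalSpec) -> float:
    """corr(g(Z), Z) of the full marginal map g (truncate, round, clip).

    The first Hermite coefficient of the monotone marginal transform: a
    pair of transformed variables realizes approximately
    loading_i * loading_j * rho at latent correlation rho, so dividing
    the targets by the loadings de-attenuates the copula.
    """
    g = _finalize(_marginal_ppf(_QUAD_U, m), m)
    sd = g.std()
    if sd == 0:
        return 1.0
    return float(np.mean(g * _QUAD_Z) / sd)


def _gender_loading(female_prop: float) -> float:
    """corr(1{Z >= tau}, Z) with tau at the 1 - female_prop quantile.

    This is the point-biserial attenuation phi(tau)/sqrt(p(1-p)) of
    thresholding a latent Gaussian; the threshold is on the upper tail so
    the female code 1 correlates *positively* with the latent variable.
    """
    tau = stats.norm.ppf(1.0 - female_prop)
    p = female_prop
    return float(stats.norm.pdf(tau) / np.sqrt(p * (1.0 - p)))


def _latent_matrix(spec: SimulationSpec) -> np.ndarray:
    """Latent copula correlation de-attenuated per variable, PSD-repaired."""
    r = np.asarray(spec.correlations, dtype=float).copy()
    loadings = np.array([
        _gender_loading(spec.female_prop) if name == "gender"
        else _linear_loading(spec.marginals[name])
        for name in spec.variables
    ])
    scale = np.outer(loadings, loadings)
    latent = np.clip(r / scale, -0.99, 0.99)
    np.fill_diagonal(latent, 1.0)
    return nearest_correlation(latent)


def simulate_healthy_cohort(spec: SimulationSpec) -> CohortTable:
    """Draw a synthetic healthy normative cohort from a Gaussian copula.

    Continuous variables are quantile-mapped to truncated normals with the
    spec's means/SDs and bounds, then rounded to their granularity (integer
    years; the test catalog's score steps) and clipped.  Gender is the
    latent Gaussian thresholded at the female-proportion quantile.
    """
    if spec.correlations is None:
        raise ValueError("spec.correlations is required for a healthy cohort")
    for name in spec.variables:
        if name != "gender" and name not in spec.marginals:
            raise ValueError(f"no marginal target for variable {name!r}")
    latent = _latent_matrix(spec)
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(latent + np.eye(len(latent)) * _PSD_FLOOR)
    z = rng.standard_normal((spec.n, len(spec.variables))) @ chol.T
    u = stats.norm.cdf(z)

    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(spec.variables):
        if name == "gender":
            # female (1) on the upper latent tail, matching the positive
            # orientation of the published point-biserial correlations
            cols[name] = (u[:, j] >= 1.0 - spec.female_prop).astype(int)
            continue
        m = spec.marginals[name]
        cols[name] = _finalize(_marginal_ppf(u[:, j], m), m)
    for name in ("age", "education"):
        if name in cols:
            cols[name] = cols[name].astype(int)
    import pandas as pd

    df = pd.DataFrame(cols)
    order = ["gender", "age", "education"] + [
        v for v in spec.variables if v in TEST_CATALOG
    ]
    return CohortTable(df[order])


def _pair_to_target(age: np.ndarray, edu: np.ndarray, target: float,
                    tol: float, rng: np.random.Generator,
                    max_iter: int = 200) -> np.ndarray:
    """Reorder ``edu`` so corr(age, edu) hits ``target`` within ``tol``.

    A Gaussian latent vector correlated with the age ranks at latent level
    ``rho`` decides the pairing; ``rho`` is tuned by bisection on the
    realized correlation, which is monotone in ``rho`` up to discretization
    noise.  Raises if the target is unattainable within ``max_iter``.
    """
    n = len(age)
    age_z = stats.norm.ppf((stats.rankdata(age) - 0.5) / n)
    noise = rng.standard_normal(n)
    edu_sorted = np.sort(edu)

    def realized(rho: float) -> tuple[float, np.ndarray]:
        lat = rho * age_z + np.sqrt(max(0.0, 1.0 - rho * rho)) * noise
        paired = edu_sorted[np.argsort(np.argsort(lat))]
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(age, paired)[0, 1]
        return r, paired

    lo, hi = -0.999, 0.999
    r_lo, _ = realized(lo)
    r_hi, _ = realized(hi)
    if not (min(r_lo, r_hi) - tol <= target <= max(r_lo, r_hi) + tol):
        raise ValueError(
            f"target correlation {target} unattainable: realizable range "
            f"about [{r_lo:.3f}, {r_hi:.3f}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid, paired = realized(mid)
        if abs(r_mid - target) <= tol:
            return paired
        if (r_mid < target) == (r_lo < target):
            lo, r_lo = mid, r_mid
        else:
            hi, r_hi = mid, r_mid
    raise ValueError(
        f"target correlation {target} not reached within {max_iter} "
        f"bisection steps (discretization too coarse for tol={tol})"
    )


def simulate_patient_cohort(spec: SimulationSpec) -> CohortTable:
    """Draw a simulated clinical cohort with clinical score levels.

    Each test score is Normal(mean, SD) per ``spec.score_params``, rounded
    to the test's granularity and clipped to the catalog.  Age and
    education are drawn from their marginals and paired so the realized
    Pearson correlation equals ``spec.age_education_r`` within
    ``spec.age_education_tol``.
    """
    if not spec.score_params:
        raise ValueError("spec.score_params is required for a patient cohort")
    rng = np.random.default_rng(spec.seed)

    age_m = spec.marginals["age"]
    edu_m = spec.marginals["education"]
    age = _finalize(_marginal_ppf(rng.uniform(size=spec.n), age_m), age_m)
    edu = _finalize(_marginal_ppf(rng.uniform(size=spec.n), edu_m), edu_m)
    edu = _pair_to_target(age, edu, spec.age_education_r,
                          spec.age_education_tol, rng)

    gender = (rng.uniform(size=spec.n) <= spec.female_prop).astype(int)

    cols = {
        "gender": gender,
        "age": age.astype(int),
        "education": edu.astype(int),
    }
    for test, (mean, sd) in spec.score_params.items():
        cat = TEST_CATALOG[test]
        if mean - sd < cat.lower or mean + sd > cat.upper:
            warnings.warn(
                f"{test}: catalog bounds [{cat.lower}, {cat.upper}] "
                f"inconsistent with mean {mean} ± SD {sd}; clipping",
                stacklevel=2,
            )
        raw = rng.normal(mean, sd, size=spec.n)
        raw = _round_to_granularity(raw, cat.granularity)
        cols[test] = np.clip(raw, cat.lower, cat.upper)

    import pandas as pd

    return CohortTable(pd.DataFrame(cols))
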