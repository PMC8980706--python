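"""Erf-model dose-detectability curves, fitting, and dose-reduction potential.

The psychometric model links dose d (CTDIvol, mGy) to 2AFC proportion
correct:

    D(d) = 1/2 * (1 + erf(alpha * d^beta / sqrt(2))) = Phi(alpha * d^beta)

with Phi the standard normal CDF and alpha > 0 (1/mGy^beta), beta > 0
dimensionless.  D(0) = 0.5 (pure guessing) and D -> 1 as d -> infinity.
The sqrt(2) inside the erf is absorbable into alpha, so the model is
identical to a cumulative-Gaussian psychometric function in alpha*d^beta.

Dose-reduction potential of a test algorithm relative to a reference is
obtained by closed-form curve inversion: find the dose at which the test
curve matches the reference curve's detectability at the investigated dose,

    d_eq = (erfinv(2D - 1) * sqrt(2) / alpha)^(1/beta) = (Phi^-1(D)/alpha)^(1/beta),

and report 100 * (1 - d_eq / d_ref) percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

__all__ = [
    "PsychometricFit",
    "DoseReductionSummary",
    "psychometric_value",
    "invert_dose",
    "fit_psychometric",
    "equivalent_dose",
    "dose_reduction_table",
    "summarize_average",
    "percent_reduction",
]

FitMode = Literal["aggregate-ls", "trial-binomial-ml"]

# optimizer search box (log-alpha, log-beta); wider than the multistart grid
_LOG_ALPHA_BOUNDS = (np.log(1e-8), np.log(1e3))
_LOG_BETA_BOUNDS = (np.log(1e-2), np.log(10.0))


@dataclass
class PsychometricFit:
    """Fitted (alpha, beta) for one algorithm, with diagnostics."""

    alpha: float
    beta: float
    residual_ss: float
    n_points: int
    fit_mode: str
    algorithm: str | None = None
    converged: bool = True
    non_identifiable: bool = False
    objective: float = field(default=np.nan)

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be strictly positive")


@dataclass
class DoseReductionSummary:
    """Unweighted mean and range of per-dose percent reductions."""

    test_algorithm: str
    reference_algorithm: str
    average_reduction: float
    min_reduction: float
    max_reduction: float


def _params(fit) -> tuple[float, float]:
    if isinstance(fit, PsychometricFit):
        return fit.alpha, fit.beta
    alpha, beta = fit
    return float(alpha), float(beta)


def psychometric_value(alpha: float, beta: float, dose) -> float | np.ndarray:
    """Detectability D(dose) = Phi(alpha * dose^beta), in [0.5, 1).

    Vectorized over `dose`.  Raises for non-positive parameters or a
    negative dose.
    """
    if not (alpha > 0 and beta > 0):
        raise ValueError("alpha and beta must be strictly positive")
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = ndtr(alpha * d**beta)
    return float(out) if np.isscalar(dose) else out


def invert_dose(fit, target_detectability: float) -> float:
    """Dose at which the fitted curve attains `target_detectability`.

    Closed form: d = (Phi^-1(D) / alpha)^(1/beta).  A target at or below
    the 0.5 guessing floor returns 0 with a warning (any dose at or below
    zero would do); a target >= 1 is unattainable and raises.
    """
    alpha, beta = _params(fit)
    if target_detectability >= 1.0:
        raise ValueError("target detectability >= 1 is unattainable")
    if target_detectability <= 0.5:
        if target_detectability < 0.5:
            warnings.warn(
                "target detectability below the 0.5 guessing floor; returning 0",
                stacklevel=2,
            )
        return 0.0
    return float((ndtri(target_detectability) / alpha) ** (1.0 / beta))


def _as_points(points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        dose = points["dose_mGy"].to_numpy(dtype=float)
        prop = points["detectability"].to_numpy(dtype=float)
        n = (
            points["n_trials"].to_numpy(dtype=float)
            if "n_trials" in points
            else np.ones_like(dose)
        )
    else:
        arr = np.asarray(list(points), dtype=float)
        dose, prop = arr[:, 0], arr[:, 1]
        n = arr[:, 2] if arr.shape[1] > 2 else np.ones_like(dose)
    return dose, prop, n


def fit_psychometric(
    points,
    mode: FitMode = "aggregate-ls",
    weighted: bool = False,
) -> PsychometricFit:
    """Fit (alpha, beta) to per-dose detectability points.

    `points` is a DataFrame with columns dose_mGy / detectability /
    optional n_trials, or a sequence of (dose, proportion[, n]) tuples.

    aggregate-ls minimizes the (optionally n-weighted) sum of squared
    residuals between observed proportions and D(dose); trial-binomial-ml
    maximizes the binomial log-likelihood of the per-dose correct counts.
    Either way the optimizer is a bounded quasi-Newton run from a 5x5
    multistart grid (alpha log-spaced in [1e-4, 10], beta in [0.1, 5]);
    the best start wins, ties broken toward smaller beta.
    """
    dose, prop, n = _as_points(points)
    if len(np.unique(dose)) < 2:
        raise ValueError("need at least 2 distinct doses to fit")
    if np.any((prop < 0) | (prop > 1)):
        raise ValueError("proportions must lie in [0, 1]")

    w = n if (weighted and mode == "aggregate-ls") else np.ones_like(dose)
    k = prop * n  # correct counts for the ML mode

    def objective(x: np.ndarray) -> float:
        alpha, beta = np.exp(x)
        p = ndtr(alpha * dose**beta)
        if mode == "aggregate-ls":
            return float(np.sum(w * (prop - p) ** 2))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(-np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))

    starts = [
        (np.log(a0), np.log(b0))
        for a0 in np.logspace(-4, 1, 5)
        for b0 in np.linspace(0.1, 5.0, 5)
    ]
    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0=np.array(x0),
            method="L-BFGS-B",
            bounds=[_LOG_ALPHA_BOUNDS, _LOG_BETA_BOUNDS],
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
        )
        cand = (res.fun, np.exp(res.x[1]), res)
        if best is None or cand[:2] < best[:2]:  # ties -> smaller beta
            best = cand
    _, _, res = best
    alpha, beta = np.exp(res.x)

    pfit = ndtr(alpha * dose**beta)
    rss = float(np.sum((prop - pfit) ** 2))
    non_ident = bool(np.all(prop <= 0.5))
    if non_ident:
        warnings.warn(
            "all observed proportions at or below chance; "
            "alpha is not identifiable (pinned near its lower bound)",
            stacklevel=2,
        )
    return PsychometricFit(
        alpha=float(alpha),
        beta=float(beta),
        residual_ss=rss,
        n_points=len(dose),
        fit_mode=mode,
        converged=bool(res.success),
        non_identifiable=non_ident,
        objective=float(res.fun),
    )


def equivalent_dose(fit_ref, fit_test, reference_dose: float) -> float:
    """Dose at which `fit_test` matches `fit_ref`'s detectability at `reference_dose`."""
    if reference_dose <= 0:
        raise ValueError("reference_dose must be positive")
    a, b = _params(fit_ref)
    return invert_dose(fit_test, psychometric_value(a, b, reference_dose))


def percent_reduction(reference_dose: float, equivalent_dose: float) -> float:
    """Dose-reduction potential, percent: 100 * (1 - d_eq / d_ref)."""
    if reference_dose <= 0:
        raise ValueError("reference_dose must be positive")
    return 100.0 * (1.0 - equivalent_dose / reference_dose)


def dose_reduction_table(
    fits: Mapping[str, PsychometricFit],
    reference_algorithm: str,
    doses: Sequence[float],
) -> pd.DataFrame:
    """Equivalent dose and percent reduction per test algorithm per dose.

    Long-format frame with one row per (reference dose, test algorithm);
    reductions are kept unrounded here, report rounding is applied only
    when writing report files.
    """
    if reference_algorithm not in fits:
        raise ValueError(f"no fit for reference algorithm {reference_algorithm!r}")
    ref = fits[reference_algorithm]
    rows = []
    for d in doses:
        for name, fit in fits.items():
            if name == reference_algorithm:
                continue
            d_eq = equivalent_dose(ref, fit, d)
            rows.append(
                {
                    "reference_algorithm": reference_algorithm,
                    "reference_dose_mGy": float(d),
                    "algorithm": name,
                    "equivalent_dose_mGy": d_eq,
                    "reduction_pct": percent_reduction(d, d_eq),
                }
            )
    return pd.DataFrame(rows)


def summarize_average(rows: pd.DataFrame, test_algorithm: str) -> DoseReductionSummary:
    """Unweighted mean and range of a test algorithm's per-dose reductions."""
    sub = rows[rows["algorithm"] == test_algorithm]
    if len(sub) == 0:
        raise ValueError(f"no rows for algorithm {test_algorithm!r}")
    red = sub["reduction_pct"].to_numpy(dtype=float)
    refs = sub["reference_algorithm"].unique()
    return DoseReductionSummary(
        test_algorithm=test_algorithm,
        reference_algorithm=refs[0] if len(refs) == 1 else "mixed",
        average_reduction=float(red.mean()),
        min_reduction=float(red.min()),
        max_reduction=float(red.max()),
    )
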