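"""Synthetic reader responses for the 2AFC study.

Two generative models are provided, mirroring the two analysis models:

* ``curve`` mode draws each response from the erf psychometric curve of the
  record's (algorithm, lesion type): P(correct) = Phi(alpha * dose^beta).
  The 0.5 guessing floor is built in.
* ``logit`` mode draws responses from a logit-scale mixed model with fixed
  effects for dose (per mGy), lesion type and algorithm, plus Gaussian
  random intercepts for reader and for the signal-present image unit.  No
  guessing floor is imposed, matching a mixed logistic regression of raw
  correctness.

Default parameter sets emulate the 20-reader liver-phantom study this
package models; see docs/methods.md for their derivation.
"""

from __future__ import annotations

import math
from typing import Annotated, Literal, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.special import expit, ndtr

from ._seeds import child_rng
from .design import (
    DEFAULT_ALGORITHMS,
    DEFAULT_LESION_TYPES,
)


class ConfigurationError(ValueError):
    """A schedule/truth mismatch or invalid generative configuration."""


class CurveParams(BaseModel):
    alpha: float = Field(gt=0, description="1/mGy^beta")
    beta: float = Field(gt=0, description="dimensionless exponent")


class CurveTruth(BaseModel):
    """Per-(algorithm, lesion type) psychometric parameters."""

    mode: Literal["curve"] = "curve"
    curves: dict[str, dict[str, CurveParams]]  # algorithm -> lesion_type -> params
    rng_seed: int | None = None

    def params_for(self, algorithm: str, lesion_type: str) -> CurveParams:
        try:
            return self.curves[algorithm][lesion_type]
        except KeyError:
            raise ConfigurationError(
                f"no curve parameters for ({algorithm!r}, {lesion_type!r})"
            ) from None


class LogitTruth(BaseModel):
    """Logit-scale coefficients plus random-intercept standard deviations.

    All coefficients are log-odds; dose_slope is log-odds per mGy.  Offsets
    omit their reference level (implicitly zero).
    """

    mode: Literal["logit"] = "logit"
    intercept: float
    dose_slope: float
    lesion_type_offsets: dict[str, float]
    algorithm_offsets: dict[str, float]
    reader_re_sd: float = Field(ge=0)
    image_re_sd: float = Field(ge=0)
    rng_seed: int | None = None


GroundTruth = Annotated[Union[CurveTruth, LogitTruth], Field(discriminator="mode")]

# Aggregate-level (alpha, beta) per algorithm, anchored so each algorithm's
# curve matches FBP detectability (~0.72 at 5 mGy, ~0.93 at 25 mGy) at the
# study's reported equivalent doses.
DEFAULT_CURVE_PARAMS: dict[str, tuple[float, float]] = {
    "FBP": (0.2302, 0.5772),
    "IR50": (0.2929, 0.5371),
    "DLL": (0.2446, 0.6051),
    "DLM": (0.3259, 0.5460),
    "DLH": (0.3902, 0.5409),
}

# Multiplies alpha per lesion insert; ordering follows the study's per-insert
# difficulty (6 mm hyperdense easiest, 4 mm hyperdense near chance at 5 mGy).
DEFAULT_LESION_ALPHA_SCALE: dict[str, float] = {
    "4 mm hyperdense": 0.45,
    "6 mm hyperdense": 1.75,
    "8 mm hyperdense": 1.45,
    "8 mm hypodense": 1.00,
}


def default_curve_truth(lesion_scale: bool = True) -> CurveTruth:
    """Curve-mode ground truth emulating the study's fitted dose responses.

    With ``lesion_scale=False`` every lesion type shares its algorithm's
    aggregate curve, which makes pooled detectability follow a single
    analytic curve — convenient for end-to-end recovery checks.
    """
    curves = {}
    for algo in DEFAULT_ALGORITHMS:
        a, b = DEFAULT_CURVE_PARAMS[algo]
        curves[algo] = {
            lt: CurveParams(
                alpha=a * (DEFAULT_LESION_ALPHA_SCALE[lt] if lesion_scale else 1.0),
                beta=b,
            )
            for lt in DEFAULT_LESION_TYPES
        }
    return CurveTruth(curves=curves)


def default_logit_truth(
    reader_re_sd: float = 0.5, image_re_sd: float = 0.3
) -> LogitTruth:
    """Logit-mode ground truth with coefficients set to the study's adjusted ORs."""
    return LogitTruth(
        intercept=math.log(0.44),
        dose_slope=math.log(1.14),
        lesion_type_offsets={
            "4 mm hyperdense": 0.0,
            "6 mm hyperdense": math.log(15.6),
            "8 mm hyperdense": math.log(8.81),
            "8 mm hypodense": math.log(4.07),
        },
        algorithm_offsets={
            "FBP": 0.0,
            "IR50": math.log(1.44),
            "DLL": math.log(1.41),
            "DLM": math.log(2.05),
            "DLH": math.log(3.20),
        },
        reader_re_sd=reader_re_sd,
        image_re_sd=image_re_sd,
    )


def _curve_probabilities(schedule: pd.DataFrame, truth: CurveTruth) -> np.ndarray:
    keys = schedule[["algorithm", "lesion_type"]].drop_duplicates()
    p = np.empty(len(schedule))
    for algo, lt in keys.itertuples(index=False):
        params = truth.params_for(algo, lt)
        mask = (
            (schedule["algorithm"] == algo) & (schedule["lesion_type"] == lt)
        ).to_numpy()
        d = schedule.loc[mask, "dose_mGy"].to_numpy(dtype=float)
        p[mask] = ndtr(params.alpha * d**params.beta)
    return p


def _logit_probabilities(
    schedule: pd.DataFrame, truth: LogitTruth, rng: np.random.Generator
) -> np.ndarray:
    def offsets(column: str, table: dict[str, float]) -> np.ndarray:
        levels = schedule[column].unique()
        missing = [lv for lv in levels if lv not in table]
        if missing:
            raise ConfigurationError(f"no {column} offset for {missing}")
        return schedule[column].map(table).to_numpy(dtype=float)

    eta = (
        truth.intercept
        + truth.dose_slope * schedule["dose_mGy"].to_numpy(dtype=float)
        + offsets("lesion_type", truth.lesion_type_offsets)
        + offsets("algorithm", truth.algorithm_offsets)
    )
    # one intercept per level, drawn in sorted-level order for determinism
    for column, sd in [("reader_id", truth.reader_re_sd), ("image_unit_id", truth.image_re_sd)]:
        levels = np.sort(schedule[column].unique())
        draws = dict(zip(levels, sd * rng.standard_normal(len(levels))))
        eta = eta + schedule[column].map(draws).to_numpy(dtype=float)
    return expit(eta)


def simulate_responses(
    schedule: pd.DataFrame, truth: CurveTruth | LogitTruth, seed: int
) -> pd.DataFrame:
    """Draw a response for every scheduled comparison.

    The schedule must already carry `signal_side` (see
    :func:`lcdetect.design.randomize_presentation`).  Reproducible from
    `seed`: random effects use the "random_effects" child stream, the
    Bernoulli responses the "responses" stream.
    """
    if schedule["signal_side"].isna().any():
        raise ValueError("schedule has unassigned signal_side; randomize first")
    out = schedule.copy()
    if truth.mode == "curve":
        p = _curve_probabilities(out, truth)
    else:
        p = _logit_probabilities(out, truth, child_rng(seed, "random_effects"))
    correct = child_rng(seed, "responses").random(len(out)) < p
    sides = out["signal_side"].to_numpy(dtype=object)
    flipped = np.where(sides == "left", "right", "left")
    out["correct"] = pd.array(correct, dtype="boolean")
    out["chosen_side"] = pd.array(np.where(correct, sides, flipped), dtype="string")
    return out


def inject_invalid(records: pd.DataFrame, k: int, seed: int) -> pd.DataFrame:
    """Flag exactly `k` responses invalid (e.g. reader misclassification)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > len(records):
        raise ValueError(f"k={k} exceeds number of records ({len(records)})")
    out = records.copy()
    if k == 0:
        return out
    idx = child_rng(seed, "invalid").choice(len(out), size=k, replace=False)
    out.iloc[idx, out.columns.get_loc("valid")] = False
    return out
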