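"""Configuration, file I/O and the end-to-end analysis pipeline.

A single JSON config drives everything: study design, generative ground
truth, analysis options, and the seed.  `run_pipeline` simulates (or loads)
a trial table and produces the study's result tables — detectability per
cell, paired differences, psychometric fits, dose-reduction potential and
mixed-logistic odds ratios — plus a manifest with the config hash, seed and
per-file checksums.  Reruns with the same config are byte-identical.

CSV is the sole interchange format: UTF-8, comma-separated, "." decimal,
booleans as 0/1, full float precision in data tables.  Report files (the
publication-style layouts) apply the display rounding instead: percentage
points to one decimal, odds ratios to two decimals, mGy to one decimal and
percent reductions to whole percent.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import detectability as det
from . import psychometric as psy
from ._seeds import DEFAULT_SEED
from .design import StudyDesign, TRIAL_COLUMNS, build_design, default_design, randomize_presentation
from .glmm import GlmmSpec, fit_glmm, odds_ratios
from .simulate import (
    CurveTruth,
    GroundTruth,
    LogitTruth,
    default_curve_truth,
    inject_invalid,
    simulate_responses,
)

TABLE_FILES = [
    "detectability.csv",
    "differences.csv",
    "psychometric_fits.csv",
    "dose_reduction.csv",
    "glmm_odds_ratios.csv",
]


class AnalysisConfig(BaseModel):
    reference_algorithms: list[str] = ["FBP", "IR50"]
    fit_mode: str = "aggregate-ls"
    subgroup: str | None = None
    run_glmm: bool = True
    glmm_algorithm_reference: str = "FBP"


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (JSON-serializable)."""

    design: StudyDesign = Field(default_factory=default_design)
    truth: GroundTruth = Field(default_factory=default_curve_truth)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    n_invalid: int = Field(default=1, ge=0)
    seed: int = DEFAULT_SEED
    metadata: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _references_exist(self):
        for algo in self.analysis.reference_algorithms:
            if algo not in self.design.algorithms:
                raise ValueError(f"reference algorithm {algo!r} not in design")
        return self


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        return PipelineConfig.model_validate(json.load(fh))


def config_hash(config: PipelineConfig) -> str:
    """SHA-256 of the canonical (key-sorted) JSON form of the config."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_trials(records: pd.DataFrame, path: str | Path) -> None:
    """Trial table CSV: booleans as 0/1, doses as decimal mGy."""
    out = records.copy()
    for col in ("correct", "valid"):
        mask = out[col].notna()
        out[col] = out[col].astype(object)
        out.loc[mask, col] = out.loc[mask, col].astype(int)
    out.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Load and validate a trial table CSV; names any missing column."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing column(s): {', '.join(missing)}")
    df["correct"] = pd.array(df["correct"], dtype="Int64").astype("boolean")
    df["valid"] = df["valid"].astype(bool)
    for col in ("signal_side", "chosen_side"):
        df[col] = df[col].astype("string")
    return df[TRIAL_COLUMNS]


def simulate_trials(config: PipelineConfig) -> pd.DataFrame:
    """Design -> randomized schedule -> simulated responses -> invalid flags."""
    schedule = build_design(config.design)
    schedule = randomize_presentation(schedule, config.seed)
    records = simulate_responses(schedule, config.truth, config.seed)
    return inject_invalid(records, config.n_invalid, config.seed)


def fit_all_algorithms(
    records: pd.DataFrame, mode: str = "aggregate-ls"
) -> dict[str, psy.PsychometricFit]:
    """One pooled psychometric fit per algorithm (mean detectability per dose)."""
    cells = det.aggregate(records, ["algorithm", "dose_mGy"])
    fits = {}
    for algo, sub in cells.groupby("algorithm", observed=True):
        fit = psy.fit_psychometric(sub, mode=mode)
        fit.algorithm = algo
        fits[algo] = fit
    return fits


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    records: pd.DataFrame | None = None,
) -> dict:
    """Run every analysis stage and write the result bundle.

    If `records` is None a trial table is simulated from the config.  On a
    stage failure the manifest is still written, marked incomplete, with
    the outputs of completed stages preserved, and the error re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status = "complete"
    written: list[str] = []
    error: Exception | None = None
    try:
        if records is None:
            records = simulate_trials(config)
        write_trials(records, out / "trials.csv")
        written.append("trials.csv")

        cleaned, log = det.clean_responses(records)
        if config.analysis.subgroup:
            cleaned = det.subgroup(cleaned, config.analysis.subgroup)

        cells = det.aggregate(cleaned, ["algorithm", "dose_mGy"])
        cells.to_csv(out / "detectability.csv", index=False)
        written.append("detectability.csv")

        diffs = pd.concat(
            [det.compare_all(cleaned, ref) for ref in config.analysis.reference_algorithms],
            ignore_index=True,
        )
        diffs.to_csv(out / "differences.csv", index=False)
        written.append("differences.csv")

        fits = fit_all_algorithms(cleaned, mode=config.analysis.fit_mode)
        pd.DataFrame(
            [
                {
                    "algorithm": f.algorithm,
                    "alpha": f.alpha,
                    "beta": f.beta,
                    "residual_ss": f.residual_ss,
                    "n_points": f.n_points,
                    "fit_mode": f.fit_mode,
                }
                for f in fits.values()
            ]
        ).to_csv(out / "psychometric_fits.csv", index=False)
        written.append("psychometric_fits.csv")

        reductions = pd.concat(
            [
                psy.dose_reduction_table(fits, ref, config.design.doses)
                for ref in config.analysis.reference_algorithms
            ],
            ignore_index=True,
        )
        reductions.to_csv(out / "dose_reduction.csv", index=False)
        written.append("dose_reduction.csv")

        if config.analysis.run_glmm:
            spec = GlmmSpec(
                algorithm_reference=config.analysis.glmm_algorithm_reference,
                lesion_reference=config.design.lesion_types[0],
            )
            gfit = fit_glmm(cleaned, spec)
            or_tab = odds_ratios(gfit)
            vc = pd.DataFrame(
                [
                    {"term": f"re_sd[{k}]", "estimate": v, "se": float("nan"),
                     "OR": float("nan"), "ci_low": float("nan"),
                     "ci_high": float("nan"), "p_value": float("nan"),
                     "reference": False}
                    for k, v in gfit.re_sd.items()
                ]
            )
            pd.concat([or_tab, vc], ignore_index=True).to_csv(
                out / "glmm_odds_ratios.csv", index=False
            )
            written.append("glmm_odds_ratios.csv")

        (out / "exclusions.json").write_text(json.dumps(log, indent=1))
        written.append("exclusions.json")
    except Exception as exc:  # stage failure: preserve prior outputs
        status = "incomplete"
        error = exc

    lines = [
        f"status={status}",
        f"config_sha256={config_hash(config)}",
        f"seed={config.seed}",
    ]
    for name in written:
        lines.append(f"{_sha256(out / name)}  {name}")
    (out / "manifest.txt").write_text("\n".join(lines) + "\n")
    if error is not None:
        raise error
    return {"status": status, "files": written, "out_dir": str(out)}


def write_report(results_dir: str | Path, report_dir: str | Path | None = None) -> list[str]:
    """Publication-style rounded layouts from a result bundle.

    Three files: paired differences (p.p., one decimal), odds ratios (two
    decimals) and dose-reduction (mGy one decimal, whole percent).  The
    whole-percent rounding happens here only; averages elsewhere always use
    unrounded reductions.
    """
    src = Path(results_dir)
    dst = Path(report_dir) if report_dir else src
    dst.mkdir(parents=True, exist_ok=True)
    written = []

    diffs = pd.read_csv(src / "differences.csv")
    for col in ("mean_diff_pp", "ci_low_pp", "ci_high_pp"):
        diffs[col] = diffs[col].round(1)
    diffs["p_value"] = diffs["p_value"].round(3)
    diffs.to_csv(dst / "report_differences.csv", index=False)
    written.append("report_differences.csv")

    red = pd.read_csv(src / "dose_reduction.csv")
    red["equivalent_dose_mGy"] = red["equivalent_dose_mGy"].round(1)
    red["reduction_pct"] = red["reduction_pct"].round(0).astype(int)
    red.to_csv(dst / "report_dose_reduction.csv", index=False)
    written.append("report_dose_reduction.csv")

    or_path = src / "glmm_odds_ratios.csv"
    if or_path.exists():
        ors = pd.read_csv(or_path)
        for col in ("OR", "ci_low", "ci_high"):
            ors[col] = ors[col].round(2)
        ors["p_value"] = ors["p_value"].round(3)
        ors.to_csv(dst / "report_odds_ratios.csv", index=False)
        written.append("report_odds_ratios.csv")
    return written
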