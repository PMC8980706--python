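"""Study design and trial-schedule construction for a 2AFC reader study.

The design is a full factorial: every reader sees every combination of
reconstruction algorithm, dose level (CTDIvol, mGy), lesion type, scan
repetition and signal-present slice exactly once.  The default instance is
the 20-reader liver-phantom protocol this package models: 5 doses
{5, 10, 15, 20, 25} mGy x 5 algorithms {FBP, IR50, DLL, DLM, DLH} x
4 lesion inserts x 3 scans x 2 slices = 600 comparisons per reader.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from ._seeds import child_rng

#: canonical trial-table column order (the CSV interchange schema)
TRIAL_COLUMNS = [
    "reader_id",
    "reader_group",
    "algorithm",
    "dose_mGy",
    "lesion_type",
    "scan_index",
    "slice_index",
    "image_unit_id",
    "signal_side",
    "chosen_side",
    "correct",
    "valid",
]

RADIOLOGIST = "radiologist"
NON_RADIOLOGIST = "non-radiologist"

DEFAULT_DOSES = [5.0, 10.0, 15.0, 20.0, 25.0]
DEFAULT_ALGORITHMS = ["FBP", "IR50", "DLL", "DLM", "DLH"]
DEFAULT_LESION_TYPES = [
    "4 mm hyperdense",
    "6 mm hyperdense",
    "8 mm hyperdense",
    "8 mm hypodense",
]


class Reader(BaseModel):
    """A study reader with its subgroup label."""

    id: str
    group: Literal["radiologist", "non-radiologist"]


class StudyDesign(BaseModel):
    """Full-factorial 2AFC study layout.

    Invariants enforced on construction: all counts >= 1, doses strictly
    positive and strictly increasing, labels unique within each factor.
    """

    readers: list[Reader]
    doses: list[float]
    algorithms: list[str]
    lesion_types: list[str]
    scans_per_dose: int = Field(ge=1)
    signal_present_slices_per_scan: int = Field(ge=1)

    @field_validator("readers", "doses", "algorithms", "lesion_types")
    @classmethod
    def _non_empty(cls, v):
        if len(v) == 0:
            raise ValueError("factor list must be non-empty")
        return v

    @field_validator("doses")
    @classmethod
    def _doses_increasing(cls, v):
        if any(d <= 0 for d in v):
            raise ValueError("doses must be strictly positive")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("doses must be strictly increasing")
        return v

    @model_validator(mode="after")
    def _unique_labels(self):
        ids = [r.id for r in self.readers]
        for name, labels in [
            ("reader ids", ids),
            ("algorithms", self.algorithms),
            ("lesion_types", self.lesion_types),
        ]:
            if len(set(labels)) != len(labels):
                raise ValueError(f"{name} must be unique")
        return self

    @property
    def trials_per_reader(self) -> int:
        return (
            self.signal_present_slices_per_scan
            * self.scans_per_dose
            * len(self.lesion_types)
            * len(self.doses)
            * len(self.algorithms)
        )

    @property
    def n_trials(self) -> int:
        return len(self.readers) * self.trials_per_reader


def default_design(n_readers: int = 20) -> StudyDesign:
    """The 20-reader protocol: 10 radiologists followed by 10 non-radiologists.

    `n_readers` may be reduced for scaled-down simulations; the first half is
    always labelled radiologist.
    """
    readers = [
        Reader(
            id=f"R{i + 1:02d}",
            group=RADIOLOGIST if i < n_readers // 2 else NON_RADIOLOGIST,
        )
        for i in range(n_readers)
    ]
    return StudyDesign(
        readers=readers,
        doses=DEFAULT_DOSES,
        algorithms=DEFAULT_ALGORITHMS,
        lesion_types=DEFAULT_LESION_TYPES,
        scans_per_dose=3,
        signal_present_slices_per_scan=2,
    )


def image_unit_id(dose: float, lesion_type: str, scan: int, slice_: int) -> str:
    """Identifier of the unique signal-present image.

    Deterministic in (dose, lesion_type, scan, slice): the level of the
    image random effect shared by all readers and algorithms viewing the
    same reconstructed slice.
    """
    return f"d{dose:g}|{lesion_type}|s{scan}|z{slice_}"


def build_design(design: StudyDesign) -> pd.DataFrame:
    """Enumerate the full trial schedule, one row per comparison per reader.

    Responses (`signal_side`, `chosen_side`, `correct`) are left unset;
    `valid` is True everywhere.
    """
    idx = pd.MultiIndex.from_product(
        [
            [r.id for r in design.readers],
            design.algorithms,
            design.doses,
            design.lesion_types,
            range(1, design.scans_per_dose + 1),
            range(1, design.signal_present_slices_per_scan + 1),
        ],
        names=[
            "reader_id",
            "algorithm",
            "dose_mGy",
            "lesion_type",
            "scan_index",
            "slice_index",
        ],
    )
    df = idx.to_frame(index=False)
    group_of = {r.id: r.group for r in design.readers}
    df["reader_group"] = df["reader_id"].map(group_of)
    df["image_unit_id"] = [
        image_unit_id(d, lt, sc, sl)
        for d, lt, sc, sl in zip(
            df["dose_mGy"], df["lesion_type"], df["scan_index"], df["slice_index"]
        )
    ]
    df["signal_side"] = pd.Series(pd.NA, index=df.index, dtype="string")
    df["chosen_side"] = pd.Series(pd.NA, index=df.index, dtype="string")
    df["correct"] = pd.Series(pd.NA, index=df.index, dtype="boolean")
    df["valid"] = True
    return df[TRIAL_COLUMNS]


def randomize_presentation(schedule: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Assign the signal-present side and shuffle presentation order.

    The signal side is a fair coin per record; the record order is permuted
    independently within each reader's session.  Fully reproducible from
    `seed` (child streams "sides" and "order").
    """
    out = schedule.copy()
    rng_sides = child_rng(seed, "sides")
    sides = np.where(rng_sides.random(len(out)) < 0.5, "left", "right")
    out["signal_side"] = pd.array(sides, dtype="string")

    rng_order = child_rng(seed, "order")
    # permute rows within each reader block; reader blocks keep schedule order
    key = np.empty(len(out), dtype=np.int64)
    codes, _ = pd.factorize(out["reader_id"], sort=False)
    for c in np.unique(codes):
        mask = codes == c
        key[mask] = rng_order.permutation(mask.sum())
    order = np.lexsort((key, codes))
    return out.iloc[order].reset_index(drop=True)
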