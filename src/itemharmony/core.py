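"""Shared value types: the missing marker, QC flags, and study datasets.

The in-memory missing marker is IEEE NaN carried in float arrays, never a
numeric sentinel code: raw codes such as 96-99 or -5 are masked to NaN at
recode time and cannot survive into downstream stages as ordinary numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: In-memory missing marker. Raw sentinel codes are mapped to this and only
#: this; no harmonized vector ever encodes missingness as a magic number.
MISSING = float("nan")

#: The closed set of flag kinds the QC battery can emit.
FLAG_KINDS = frozenset(
    {
        "missing_code",
        "no_variability",
        "scale_discrepancy",
        "reverse_candidate",
        "conditional_item",
        "summary_score",
        "sparse_cell",
        "undeclared_code",
        "missing_variable",
    }
)


def is_missing(values) -> np.ndarray:
    """Element-wise missingness mask for a harmonized/raw value vector."""
    return np.isnan(np.asarray(values, dtype=float))


def as_values(values) -> np.ndarray:
    """Coerce a value vector to a float array (NaN = missing)."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("item value vectors must be one-dimensional")
    return arr


@dataclass(frozen=True)
class QCFlag:
    """One detected comparability problem.

    ``evidence`` is a JSON-serializable payload with enough numeric detail
    (the offending codes, the correlation and pair count, the cell counts)
    that the finding can be recomputed independently from the inputs.
    ``study_id`` is ``"pooled"`` for cross-study findings.
    """

    kind: str
    construct_id: str
    study_id: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FLAG_KINDS:
            raise ValueError(f"unknown flag kind {self.kind!r}")

    def to_record(self) -> dict:
        return {
            "kind": self.kind,
            "construct_id": self.construct_id,
            "study_id": self.study_id,
            "evidence": json.dumps(self.evidence, sort_keys=True),
        }


def flags_to_frame(flags) -> pd.DataFrame:
    """Tabulate a flag list as a DataFrame (one row per flag)."""
    cols = ["kind", "construct_id", "study_id", "evidence"]
    if not flags:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([f.to_record() for f in flags], columns=cols)


@dataclass
class StudyDataset:
    """One study's respondent-by-item table.

    ``items`` maps a column name -- a raw source variable before recoding,
    or a harmonized construct id after -- to a float vector aligned with
    ``respondent_ids``. Missing responses are NaN.
    """

    study_id: str
    respondent_ids: list
    items: dict

    def __post_init__(self):
        n = len(self.respondent_ids)
        clean = {}
        for name, vec in self.items.items():
            arr = as_values(vec)
            if arr.shape[0] != n:
                raise ValueError(
                    f"item {name!r} in study {self.study_id!r} has length "
                    f"{arr.shape[0]}, expected {n}"
                )
            clean[name] = arr
        self.items = clean

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.items)
        df.insert(0, "respondent_id", self.respondent_ids)
        return df

    def copy_with(self, items: dict) -> "StudyDataset":
        return StudyDataset(self.study_id, list(self.respondent_ids), dict(items))


def read_study_data(path, study_id: str, delimiter: str = "\t") -> StudyDataset:
    """Read a study table: first column respondent id, the rest raw items."""
    df = pd.read_csv(path, sep=delimiter)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a respondent-id column plus items")
    rid = df.iloc[:, 0].tolist()
    items = {c: df[c].to_numpy(dtype=float) for c in df.columns[1:]}
    return StudyDataset(study_id, rid, items)


def write_study_data(ds: StudyDataset, path, delimiter: str = "\t") -> None:
    df = ds.to_frame()
    # integers where possible, empty cell for NaN -- keeps raw files tidy
    df.to_csv(path, sep=delimiter, index=False, float_format="%.10g")
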