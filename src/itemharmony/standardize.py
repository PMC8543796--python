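"""Deterministic standardization of raw study codes into harmonized scores.

Transforms follow a fixed order when composed by the pipeline:
mask missing codes -> shift one-based scales to zero -> reverse polarity
(when the crosswalk authorizes it) -> dichotomize / collapse sparse
categories. Every operation is a pure, total function: same inputs, same
outputs, bit-exact. Missing entries (NaN) propagate and are never invented
or dropped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, QCFlag, as_values, is_missing
from .errors import RangeError, RecodeParseError, UndomainedCodeError

__all__ = [
    "RecodeRule",
    "HarmonizedItem",
    "AuditLog",
    "NoOpShiftWarning",
    "apply_recode",
    "reverse_code",
    "shift_to_zero",
    "dichotomize",
    "collapse_sparse",
]


class NoOpShiftWarning(UserWarning):
    """shift_to_zero was requested for an already zero-based item."""


@dataclass(frozen=True)
class RecodeRule:
    """A finite map from raw codes to harmonized scores or missing.

    ``mapping`` sends each integer raw code either to a non-negative
    integer harmonized score or to ``None`` (missing). The rule is total
    over the item's declared response options and missing codes; raw codes
    outside the domain are an error at application time, never silently
    passed through.
    """

    mapping: dict
    # (min, max) over harmonized scores; (None, None) if all codes map to NA
    declared_range: tuple = (None, None)

    def __post_init__(self):
        scores = [v for v in self.mapping.values() if v is not None]
        for code in self.mapping:
            if not isinstance(code, (int, np.integer)):
                raise RecodeParseError(f"raw code {code!r} is not an integer")
        for v in scores:
            if v < 0:
                raise RecodeParseError(
                    f"harmonized score {v} is negative; harmonized scales are 0-based"
                )
        rng = (min(scores), max(scores)) if scores else (None, None)
        if self.declared_range == (None, None):
            object.__setattr__(self, "declared_range", rng)

    @classmethod
    def parse(cls, text: str) -> "RecodeRule":
        """Parse the compact recode grammar, e.g. ``"1->1;5->0;6,96,97,98,99->NA"``.

        Semicolon-separated clauses; each clause maps one or more
        comma-separated integer raw codes to a harmonized integer score or
        the token ``NA`` (missing).
        """
        mapping: dict = {}
        text = text.strip()
        if not text:
            raise RecodeParseError("empty recode string")
        for clause in text.split(";"):
            clause = clause.strip()
            if not clause:
                continue
            if "->" not in clause:
                raise RecodeParseError(f"clause {clause!r} lacks '->'")
            lhs, rhs = clause.split("->", 1)
            rhs = rhs.strip()
            if rhs.upper() == "NA":
                target = None
            else:
                try:
                    target = int(rhs)
                except ValueError:
                    raise RecodeParseError(
                        f"target {rhs!r} is neither an integer nor 'NA'"
                    ) from None
            for tok in lhs.split(","):
                tok = tok.strip()
                try:
                    code = int(tok)
                except ValueError:
                    raise RecodeParseError(
                        f"raw code {tok!r} is not an integer"
                    ) from None
                if code in mapping:
                    raise RecodeParseError(f"raw code {code} mapped twice")
                mapping[code] = target
        return cls(mapping)

    def to_text(self) -> str:
        """Serialize back to the compact grammar (codes grouped by target)."""
        groups: dict = {}
        for code in sorted(self.mapping):
            groups.setdefault(self.mapping[code], []).append(code)
        parts = []
        # deterministic clause order: by harmonized score, NA last
        for target in sorted((t for t in groups if t is not None)):
            codes = ",".join(str(c) for c in groups[target])
            parts.append(f"{codes}->{target}")
        if None in groups:
            codes = ",".join(str(c) for c in groups[None])
            parts.append(f"{codes}->NA")
        return ";".join(parts)

    @property
    def domain(self) -> frozenset:
        return frozenset(self.mapping)


@dataclass
class HarmonizedItem:
    """One (construct, study) item after standardization.

    By convention a higher harmonized value indicates a worse / more severe
    presentation of the symptom; reversal happens upstream so this class
    can assume the convention.
    """

    construct_id: str
    study_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = as_values(self.values)

    @property
    def n_levels(self) -> int:
        obs = self.values[~is_missing(self.values)]
        return int(np.unique(obs).size)


def apply_recode(raw_values, rule: RecodeRule) -> np.ndarray:
    """Element-wise recode of raw codes into harmonized scores.

    Raw NaN (a blank cell in the source file) stays missing. Any observed
    raw code outside the rule's domain raises, naming the code and its
    frequency -- undeclared codes are a crosswalk defect, not data to pass
    through.
    """
    raw = as_values(raw_values)
    out = np.full(raw.shape, MISSING)
    obs = ~is_missing(raw)
    codes = raw[obs]
    if np.any(codes != np.round(codes)):
        bad = codes[codes != np.round(codes)][0]
        raise UndomainedCodeError(bad, int(np.sum(codes == bad)))
    for code in np.unique(codes).astype(int):
        if code not in rule.mapping:
            raise UndomainedCodeError(int(code), int(np.sum(codes == code)))
    mapped = np.array(
        [MISSING if rule.mapping[int(c)] is None else float(rule.mapping[int(c)]) for c in codes]
    )
    out[obs] = mapped
    return out


def reverse_code(values, max_level: int) -> np.ndarray:
    """Flip item polarity: each non-missing v becomes ``max_level - v``.

    An involution: applying it twice restores the input.
    """
    v = as_values(values)
    obs = ~is_missing(v)
    if np.any(v[obs] < 0) or np.any(v[obs] > max_level):
        bad = v[obs][(v[obs] < 0) | (v[obs] > max_level)][0]
        raise RangeError(
            f"value {bad} outside [0, {max_level}]; reverse_code requires "
            f"0-based values within max_level"
        )
    out = v.copy()
    out[obs] = max_level - v[obs]
    return out


def shift_to_zero(values) -> np.ndarray:
    """Shift a one-based scale down by one point so the minimum is 0.

    If the observed minimum is already 0 the call is a no-op and emits
    :class:`NoOpShiftWarning` -- double-shifting is guarded against, never
    performed.
    """
    v = as_values(values)
    obs = ~is_missing(v)
    if not np.any(obs) or np.nanmin(v) <= 0:
        warnings.warn(
            "shift_to_zero called on an already zero-based (or empty) item; no-op",
            NoOpShiftWarning,
            stacklevel=2,
        )
        return v.copy()
    out = v.copy()
    out[obs] = v[obs] - 1.0
    return out


def dichotomize(values) -> np.ndarray:
    """Truncate an ordinal 0-based item to binary: 0 stays 0, >=1 becomes 1."""
    v = as_values(values)
    out = v.copy()
    obs = ~is_missing(v)
    out[obs] = np.where(v[obs] >= 1, 1.0, v[obs])
    return out


def collapse_sparse(values, min_cell: int, construct_id: str = "", study_id: str = ""):
    """Collapse an ordinal item to binary when some response cell is sparse.

    If the item has three or more observed levels and any level's count
    falls below ``min_cell``, the item is dichotomized (0 kept, >=1
    truncated to 1). Binary and constant items are left alone. The decision
    is returned as a ``sparse_cell`` QC flag so the transform is auditable.

    Returns ``(values, flag_or_None)``.
    """
    if min_cell < 1:
        raise ValueError("min_cell must be >= 1")
    v = as_values(values)
    obs = v[~is_missing(v)]
    if obs.size == 0:
        flag = QCFlag(
            "sparse_cell", construct_id, study_id, {"reason": "all missing", "counts": {}}
        )
        return v.copy(), flag
    levels, counts = np.unique(obs, return_counts=True)
    if levels.size < 3 or counts.min() >= min_cell:
        return v.copy(), None
    collapsed = dichotomize(v)
    flag = QCFlag(
        "sparse_cell",
        construct_id,
        study_id,
        {
            "counts": {str(int(l)): int(c) for l, c in zip(levels, counts)},
            "min_cell": int(min_cell),
            "action": "dichotomized",
        },
    )
    return collapsed, flag


@dataclass
class AuditLog:
    """Machine-readable trail of every applied standardization transform."""

    records: list = field(default_factory=list)

    def record(self, study_id: str, construct_id: str, operation: str, **params):
        self.records.append(
            {
                "study_id": study_id,
                "construct_id": construct_id,
                "operation": operation,
                "params": dict(sorted(params.items())),
            }
        )

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(r, sort_keys=True) for r in self.records)

    def write(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_jsonl() + ("\n" if self.records else ""))
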