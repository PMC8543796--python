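"""Automated cross-study comparability checks.

The battery detects, before any model is fit: numeric missing-data
sentinels still sitting in raw codes (codes in 90-100 or negative),
no-variability items, cross-study scale discrepancies (different
min/max for the same construct), reverse-polarity candidates (items with
sizable negative correlations against the rest of their study), and
conditional (skip-pattern) items that would violate local independence.

Every check is a pure function of its inputs: re-running yields identical
flags, and each flag carries the numeric evidence needed to recompute it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import QCFlag, StudyDataset, is_missing
from .crosswalk import Crosswalk
from .errors import StructuralError

__all__ = [
    "QCFlag",
    "StudyDataset",
    "QCThresholds",
    "detect_missing_codes",
    "detect_no_variability",
    "crosstab_ranges",
    "detect_reverse_candidates",
    "exclude_conditional",
    "endorsement_report",
]


class QCThresholds:
    """Default thresholds for the comparability battery.

    reverse_r: an item is a reverse-coding candidate when its correlation
        with another item in the same study is below this (default -0.2).
    min_overlap: minimum pairwise-complete observations for a correlation
        to be trusted (conditional items create blockwise missingness).
    min_cell: minimum count per ordinal response cell before collapsing.
    """

    def __init__(self, reverse_r: float = -0.2, min_overlap: int = 20, min_cell: int = 5):
        self.reverse_r = reverse_r
        self.min_overlap = min_overlap
        self.min_cell = min_cell

    def to_dict(self) -> dict:
        return {
            "reverse_r": self.reverse_r,
            "min_overlap": self.min_overlap,
            "min_cell": self.min_cell,
        }


def detect_missing_codes(raw_item, construct_id: str = "", study_id: str = ""):
    """Flag raw codes that look like numeric missing-data sentinels.

    Operates on raw (pre-recode) values only. Fires when the maximum
    observed value lies in [90, 100] or any value is negative; the payload
    lists the suspect codes.
    """
    v = np.asarray(raw_item, dtype=float)
    obs = v[~is_missing(v)]
    if obs.size == 0:
        return None
    suspects = sorted(
        {float(u) for u in np.unique(obs) if (90 <= u <= 100) or u < 0}
    )
    if (90 <= obs.max() <= 100) or (obs.min() < 0):
        return QCFlag(
            "missing_code",
            construct_id,
            study_id,
            {"suspect_codes": suspects, "max": float(obs.max()), "min": float(obs.min())},
        )
    return None


def detect_no_variability(item, construct_id: str = "", study_id: str = ""):
    """Flag items whose non-missing values are constant (min == max).

    An all-missing vector is also flagged, with evidence "all missing".
    """
    v = np.asarray(item, dtype=float)
    obs = v[~is_missing(v)]
    if obs.size == 0:
        return QCFlag(
            "no_variability", construct_id, study_id, {"reason": "all missing"}
        )
    lo, hi = float(obs.min()), float(obs.max())
    if lo == hi:
        return QCFlag(
            "no_variability",
            construct_id,
            study_id,
            {"constant_value": lo, "n_obs": int(obs.size)},
        )
    return None


def crosstab_ranges(datasets, cw: Crosswalk):
    """Cross-tabulate observed (min, max) per construct and study.

    Returns ``(table, flags)`` where ``table`` has one row per
    (construct, study) with the observed min and max, and a construct
    carried by two or more studies is flagged ``scale_discrepancy`` iff
    its (min, max) pair is not identical across all of them.
    """
    by_study = {ds.study_id: ds for ds in datasets}
    rows = []
    for m in sorted(cw.mappings, key=lambda m: (m.construct_id, m.study_id)):
        ds = by_study.get(m.study_id)
        if ds is None:
            continue
        # harmonized datasets key items by construct, raw ones by variable
        if m.construct_id in ds.items:
            v = ds.items[m.construct_id]
        elif m.source_variable in ds.items:
            v = ds.items[m.source_variable]
        else:
            continue
        obs = v[~is_missing(v)]
        if obs.size == 0:
            rows.append((m.construct_id, m.study_id, np.nan, np.nan))
        else:
            rows.append((m.construct_id, m.study_id, float(obs.min()), float(obs.max())))
    table = pd.DataFrame(rows, columns=["construct_id", "study_id", "min", "max"])
    flags = []
    for construct, grp in table.groupby("construct_id", sort=True):
        if len(grp) < 2:
            continue
        pairs = {(lo, hi) for lo, hi in zip(grp["min"], grp["max"])}
        if len(pairs) > 1:
            flags.append(
                QCFlag(
                    "scale_discrepancy",
                    construct,
                    "pooled",
                    {
                        "ranges": {
                            s: [lo, hi]
                            for s, lo, hi in zip(grp["study_id"], grp["min"], grp["max"])
                        }
                    },
                )
            )
    return table, flags


def detect_reverse_candidates(
    ds: StudyDataset, threshold: float = -0.2, min_overlap: int = 20
):
    """Flag items that correlate negatively with other items in the study.

    Computes the within-study Pearson intercorrelation matrix on
    pairwise-complete observations (pairs with fewer than ``min_overlap``
    joint observations are skipped) and flags every item whose correlation
    with at least one other item falls below ``threshold``. The payload
    records the most negative partner, the correlation, and the pair count.
    """
    usable = {
        name: v
        for name, v in ds.items.items()
        if detect_no_variability(v) is None
    }
    if len(usable) < 2:
        warnings.warn(
            f"study {ds.study_id!r}: fewer than 2 items with variability; "
            f"reverse-candidate check skipped",
            stacklevel=2,
        )
        return []
    df = pd.DataFrame(usable)
    corr = df.corr(method="pearson", min_periods=min_overlap)
    n_pair = df.notna().astype(int).T @ df.notna().astype(int)
    flags = []
    for name in df.columns:
        r = corr[name].drop(labels=[name])
        r = r.dropna()
        if r.empty or r.min() >= threshold:
            continue
        partner = r.idxmin()
        flags.append(
            QCFlag(
                "reverse_candidate",
                name,
                ds.study_id,
                {
                    "partner": str(partner),
                    "r": float(r.min()),
                    "n_pairs": int(n_pair.loc[name, partner]),
                    "threshold": float(threshold),
                },
            )
        )
    return flags


def suggest_reversals(ds: StudyDataset, min_overlap: int = 20):
    """Partition a study's items by polarity and return the minority group.

    The flag-level check (:func:`detect_reverse_candidates`) marks every
    item touching a sizable negative correlation, which in a study with
    reversed items includes their correctly-coded partners. This helper
    resolves the ambiguity: items are split by the sign of their loading
    on the leading eigenvector of the pairwise-complete correlation
    matrix (the dominant direction of shared variance), oriented so the
    majority is positive; the negative-loading minority is the suggested
    reversal set. The final decision stays with the analyst via the
    crosswalk.
    """
    usable = {
        name: v for name, v in ds.items.items() if detect_no_variability(v) is None
    }
    if len(usable) < 3:
        return []
    df = pd.DataFrame(usable)
    corr = df.corr(method="pearson", min_periods=min_overlap).fillna(0.0).to_numpy()
    np.fill_diagonal(corr, 1.0)
    vals, vecs = np.linalg.eigh(corr)
    lead = vecs[:, -1]
    if np.sum(lead > 0) < np.sum(lead < 0):
        lead = -lead
    names = list(df.columns)
    return sorted(names[i] for i in range(len(names)) if lead[i] < 0)


def exclude_conditional(ds: StudyDataset, cw: Crosswalk):
    """Remove skip-pattern (gated) items from a study.

    Items whose crosswalk row declares a ``gate_variable`` are removed --
    they are administered only conditional on another item's response and
    are redundant with it, inflating apparent reliability if retained.
    Returns ``(filtered dataset, flags)``, one ``conditional_item`` flag
    per removed item. Gate cycles are a structural error.
    """
    study_maps = {m.construct_id: m for m in cw.for_study(ds.study_id)}
    # map source variables back to constructs so gate chains can be followed
    var_to_construct = {m.source_variable: m.construct_id for m in study_maps.values()}
    gated = {}
    for construct, m in study_maps.items():
        if m.gate_variable:
            gated[construct] = var_to_construct.get(m.gate_variable, m.gate_variable)
    # cycle detection over the construct-level gate graph
    for start in gated:
        seen = {start}
        cur = gated.get(start)
        while cur is not None:
            if cur in seen:
                raise StructuralError(
                    f"study {ds.study_id!r}: gate cycle involving {sorted(seen)}"
                )
            seen.add(cur)
            cur = gated.get(cur)
    flags = []
    kept = {}
    for name, v in ds.items.items():
        if name in gated:
            flags.append(
                QCFlag(
                    "conditional_item",
                    name,
                    ds.study_id,
                    {"gate": gated[name]},
                )
            )
        else:
            kept[name] = v
    return ds.copy_with(kept), flags


def endorsement_report(ds: StudyDataset) -> pd.DataFrame:
    """Per-item category frequencies, missing proportion, endorsement rate.

    The endorsement rate is the mean of the non-missing values -- for a
    binary item, the fraction endorsed. Category counts are exact.
    """
    rows = []
    for name in sorted(ds.items):
        v = ds.items[name]
        miss = is_missing(v)
        obs = v[~miss]
        levels, counts = (
            np.unique(obs, return_counts=True) if obs.size else (np.array([]), np.array([]))
        )
        rows.append(
            {
                "item": name,
                "n": int(v.size),
                "n_missing": int(miss.sum()),
                "prop_missing": float(miss.mean()) if v.size else np.nan,
                "counts": {f"{l:g}": int(c) for l, c in zip(levels, counts)},
                "endorsement": float(obs.mean()) if obs.size else np.nan,
            }
        )
    return pd.DataFrame(rows)
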