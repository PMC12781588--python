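"""Matched-control selection for discovery cases.

Greedy nearest-neighbour matching: each case, in input order, receives up
to ``ratio`` controls that agree exactly on the categorical covariates
(sex and batch by default) and are nearest in age; without replacement
each control is used once.  Ties in age difference are broken by pool
order, making the assignment fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import pandas as pd

from .errors import MatchingError
from .io_qc import SampleSheet


@dataclass
class MatchSpec:
    ratio: int = 4
    exact_on: tuple[str, ...] = ("sex", "batch")
    nearest_on: str = "age"
    with_replacement: bool = False
    allow_partial: bool = False

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise MatchingError("matching ratio must be >= 1")


def match_controls(
    cases: SampleSheet, pool: SampleSheet, spec: MatchSpec | None = None
) -> pd.DataFrame:
    """Assign controls to cases; returns (case_id, control_id, age_diff) rows.

    Raises :class:`MatchingError` naming any case that cannot be fully
    matched, unless ``spec.allow_partial`` (then a warning is issued and
    the partial assignment returned).
    """
    spec = spec or MatchSpec()
    case_df = cases.data
    pool_df = pool.data
    overlap = set(case_df["sample_id"]) & set(pool_df["sample_id"])
    if overlap:
        raise MatchingError(f"control pool overlaps cases: {sorted(overlap)[:5]}")
    used: set[str] = set()
    rows = []
    unmatched: list[str] = []
    for _, case in case_df.iterrows():
        eligible = pool_df
        for cov in spec.exact_on:
            eligible = eligible[eligible[cov] == case[cov]]
        if not spec.with_replacement:
            eligible = eligible[~eligible["sample_id"].isin(used)]
        # stable sort keeps pool order on age-difference ties
        diffs = (eligible[spec.nearest_on] - case[spec.nearest_on]).abs()
        eligible = eligible.assign(_diff=diffs).sort_values("_diff", kind="mergesort")
        chosen = eligible.head(spec.ratio)
        if len(chosen) < spec.ratio:
            unmatched.append(str(case["sample_id"]))
        for _, ctrl in chosen.iterrows():
            rows.append(
                {
                    "case_id": case["sample_id"],
                    "control_id": ctrl["sample_id"],
                    "age_diff": float(ctrl["_diff"]),
                }
            )
            if not spec.with_replacement:
                used.add(str(ctrl["sample_id"]))
    if unmatched:
        msg = f"insufficient eligible controls for cases: {unmatched}"
        if spec.allow_partial:
            warnings.warn(msg)
        else:
            raise MatchingError(msg)
    return pd.DataFrame(rows, columns=["case_id", "control_id", "age_diff"])
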