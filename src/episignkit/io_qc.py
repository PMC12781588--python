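"""Methylation matrix I/O and array-level quality control.

Beta values (fraction methylated signal, in [0, 1]) are held probes x
samples in a :class:`BetaMatrix`.  Quality control follows the standard
blood-array workflow: samples with an excess of failed probes are dropped
first, then probes are removed for blocklist membership (SNP-overlapping,
cross-reactive, sex-chromosome) or for detection failure (detection
p-value above threshold in at least one retained sample).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, ValidationError

GROUPS = ("case", "control", "database", "query")


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions.

    ``values`` is a pandas DataFrame indexed by probe id with sample-id
    columns; all entries must lie in [0, 1] (NaN allowed for flagged
    missing values).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate probe ids: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            p, s = np.argwhere(bad & ~np.isnan(arr))[0]
            raise FormatError(
                f"beta value {arr[p, s]} outside [0, 1] at probe "
                f"{self.values.index[p]!r}, sample {self.values.columns[s]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, ids: Iterable[str]) -> "BetaMatrix":
        ids = list(ids)
        missing = set(ids) - set(self.values.columns)
        if missing:
            raise AlignmentError(f"unknown sample ids: {sorted(missing)[:5]}")
        return BetaMatrix(self.values[ids])

    def subset_probes(self, ids: Iterable[str]) -> "BetaMatrix":
        ids = list(ids)
        missing = set(ids) - set(self.values.index)
        if missing:
            raise AlignmentError(f"unknown probe ids: {sorted(missing)[:5]}")
        return BetaMatrix(self.values.loc[ids])


@dataclass
class SampleSheet:
    """Per-sample metadata: group, sex, age, batch, optional cell fractions.

    ``data`` requires columns sample_id, group, sex, age, batch.  Cell
    fractions, when present, are columns prefixed ``cf_`` and must sum to
    1 per sample.  ``disorder_label`` is optional.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "group", "sex", "age", "batch")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in sample sheet")
        bad_groups = set(self.data["group"]) - set(GROUPS)
        if bad_groups:
            raise FormatError(f"unknown group labels: {sorted(bad_groups)}")
        cf = self.cell_fraction_columns
        if cf:
            sums = self.data[cf].sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValidationError("cell fractions do not sum to 1 per sample")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def cell_fraction_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("cf_")]

    def subset(self, ids: Iterable[str]) -> "SampleSheet":
        ids = list(ids)
        sub = self.data.set_index("sample_id").loc[ids].reset_index()
        return SampleSheet(sub)

    def ids_in_group(self, group: str) -> list[str]:
        return list(self.data.loc[self.data["group"] == group, "sample_id"])


@dataclass
class ProbeBlocklist:
    """Probe exclusion lists; the three sets may overlap."""

    snp_overlap: set[str] = field(default_factory=set)
    cross_reactive: set[str] = field(default_factory=set)
    sex_chromosome: set[str] = field(default_factory=set)

    def union(self) -> set[str]:
        return self.snp_overlap | self.cross_reactive | self.sex_chromosome


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a probes x samples TSV/CSV (first column probe id, header row
    of sample ids) into a :class:`BetaMatrix`.

    Values outside [0, 1], ragged rows, duplicate ids or non-numeric
    cells raise :class:`FormatError` naming the offending location.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_nan = coerced.isna() & df[col].notna()
        if newly_nan.any():
            row = df.index[newly_nan.to_numpy().argmax()]
            raise FormatError(f"{path}: non-numeric cell at probe {row!r}, sample {col!r}")
        df[col] = coerced
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    beta.values.to_csv(path, sep=sep, index_label="probe_id")


def read_detection_p(path: str | Path) -> pd.DataFrame:
    """Detection p-value matrix, same layout as the beta matrix."""
    return read_beta_matrix(path).values


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, dtype={"sample_id": str, "batch": str}))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, index=False)


def read_probe_list(path: str | Path) -> set[str]:
    """One probe id per line; blank lines and ``#`` comments ignored."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_blocklist_dir(directory: str | Path) -> ProbeBlocklist:
    """Load ``snp_overlap.txt``, ``cross_reactive.txt``, ``sex_chromosome.txt``
    from a directory; missing files yield empty sets."""
    directory = Path(directory)
    kwargs = {}
    for name in ("snp_overlap", "cross_reactive", "sex_chromosome"):
        p = directory / f"{name}.txt"
        kwargs[name] = read_probe_list(p) if p.exists() else set()
    return ProbeBlocklist(**kwargs)


def sample_qc(
    detection_p: pd.DataFrame,
    failure_threshold: float = 0.05,
    p_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-sample probe-failure fractions and exclusion flags.

    A sample is excluded iff its fraction of probes with detection
    p-value > ``p_threshold`` exceeds ``failure_threshold`` (default: more
    than 5% probe failure).
    """
    if detection_p.size == 0:
        raise ValidationError("empty detection p-value matrix")
    frac = (detection_p.to_numpy(dtype=float) > p_threshold).mean(axis=0)
    return pd.DataFrame(
        {
            "sample_id": list(detection_p.columns),
            "failure_fraction": frac,
            "excluded": frac > failure_threshold,
        }
    )


def filter_probes(
    beta: BetaMatrix,
    detection_p: pd.DataFrame,
    blocklist: ProbeBlocklist,
    p_threshold: float = 0.1,
) -> tuple[BetaMatrix, dict[str, int]]:
    """Remove blocklisted probes and probes failing detection.

    A probe fails detection if its p-value exceeds ``p_threshold`` in at
    least one retained sample (strictest reading; configurable threshold).
    Removal reasons are prioritized blocklist-first so the returned counts
    partition the removed set.  Returns the filtered matrix and a mapping
    ``{reason: count}`` whose values sum to the number removed.
    """
    if list(detection_p.index) != beta.probe_ids or list(detection_p.columns) != beta.sample_ids:
        raise AlignmentError("detection p matrix is not aligned with the beta matrix")
    probe_index = beta.values.index
    blocked = probe_index.isin(blocklist.union())
    failing = (detection_p.to_numpy(dtype=float) > p_threshold).any(axis=1)
    removed_block = int(blocked.sum())
    removed_detp = int((failing & ~blocked).sum())
    keep = ~(blocked | failing)
    counts = {
        "blocklist": removed_block,
        "detection_p": removed_detp,
        "removed_total": removed_block + removed_detp,
        "retained": int(keep.sum()),
    }
    return BetaMatrix(beta.values.loc[keep]), counts
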