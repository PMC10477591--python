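"""Reading, validation and normalization of abundance and metadata tables.

Abundance tables are delimited text (TSV by default) with one header row and
one identifier column; either orientation is accepted and normalized to
samples-in-rows. Values may be raw counts or already-relative proportions:
closure to relative abundance is always applied downstream and is idempotent
for relative input.

Two small reference tables ship with the package: the metadata of the
16-sample metastatic/non-metastatic colorectal cancer cohort the method was
developed on, and a registry of three published control-vs-CRC cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "DatasetDescriptor",
    "read_abundance_table",
    "write_abundance_table",
    "normalize_relative_abundance",
    "read_metadata",
    "align_samples",
    "load_mcrc_metadata",
    "load_crc_registry",
    "MCRC_GROUP_LABELS",
]

#: Canonical group -> binary label mapping for the packaged mCRC cohort
#: (metastatic disease is the positive class).
MCRC_GROUP_LABELS: Mapping[str, int] = {"mCRC": 1, "non-mCRC": 0}


@dataclass(frozen=True)
class AbundanceTable:
    """A samples × taxa matrix of nonnegative abundances."""

    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        if values.ndim != 2:
            raise ValueError("abundance values must be a 2-D matrix")
        if values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.feature_ids)} features"
            )
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if list(ids).count(i) > 1})
                raise ValueError(f"duplicate {name} identifiers: {dupes}")
        if not np.all(np.isfinite(values)):
            raise ValueError("abundance values must be finite")
        if np.any(values < 0):
            raise ValueError("abundance values must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def select_samples(self, ids: Sequence[str]) -> "AbundanceTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return AbundanceTable(tuple(ids), self.feature_ids, self.values[rows])


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample clinical record with a binary disease label."""

    sample_id: str
    label: int
    group_name: str
    age: int | None = None

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.age is not None and self.age < 0:
            raise ValueError("age must be nonnegative")


@dataclass(frozen=True)
class DatasetDescriptor:
    """Size summary of a published cohort."""

    name: str
    n_total: int
    n_control: int
    n_disease: int

    def __post_init__(self):
        if self.n_total != self.n_control + self.n_disease:
            raise ValueError(
                f"{self.name}: n_total={self.n_total} != "
                f"{self.n_control} + {self.n_disease}"
            )


# ----------------------------------------------------------------------
# readers / writers


def read_abundance_table(
    path: str | Path,
    orientation: str = "samples_in_rows",
    sep: str = "\t",
) -> AbundanceTable:
    """Read a delimited abundance table.

    Parameters
    ----------
    path
        Delimited text file with one header row and one identifier column.
    orientation
        ``"samples_in_rows"`` (default) or ``"samples_in_columns"``; the
        returned table is always samples-in-rows.
    """
    if orientation not in ("samples_in_rows", "samples_in_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if orientation == "samples_in_columns":
        df = df.T
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return AbundanceTable(
        tuple(str(s) for s in df.index),
        tuple(str(f) for f in df.columns),
        values,
    )


def write_abundance_table(table: AbundanceTable, path: str | Path, sep: str = "\t") -> None:
    """Write samples-in-rows TSV; full float precision so reads round-trip."""
    df = pd.DataFrame(table.values, index=list(table.sample_ids),
                      columns=list(table.feature_ids))
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, float_format="%.17g")


def normalize_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Close each sample to relative abundance (row sums to 1).

    Idempotent for already-relative input. A sample with zero total abundance
    has no composition and is rejected.
    """
    sums = table.values.sum(axis=1)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        bad = [table.sample_ids[i] for i in zero]
        raise ValueError(f"zero-sum sample(s), cannot normalize: {bad}")
    return AbundanceTable(table.sample_ids, table.feature_ids,
                          table.values / sums[:, None])


def read_metadata(
    path: str | Path,
    group_to_label: Mapping[str, int],
    sep: str = "\t",
) -> list[SampleMetadata]:
    """Read a sample metadata table and assign binary labels.

    The ``group_to_label`` mapping is explicit and mandatory: which clinical
    group is the positive class must never be inferred, since a silently
    flipped label inverts the AUC.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    group_col = cols.get("group") or cols.get("group_name")
    if group_col is None:
        raise ValueError(f"{path}: missing required column 'group'")
    records: list[SampleMetadata] = []
    for _, row in df.iterrows():
        sample_id = row[cols["sample_id"]]
        if pd.isna(sample_id) or str(sample_id).strip() == "":
            raise ValueError(f"{path}: row with missing sample_id")
        group = str(row[group_col])
        if group not in group_to_label:
            raise ValueError(
                f"unknown group {group!r} for sample {sample_id!r}; "
                f"known groups: {sorted(group_to_label)}"
            )
        age = None
        if "age" in cols and not pd.isna(row[cols["age"]]):
            age = int(float(row[cols["age"]]))
        records.append(SampleMetadata(str(sample_id), int(group_to_label[group]),
                                      group, age))
    return records


def align_samples(
    table: AbundanceTable, metadata: Sequence[SampleMetadata]
) -> tuple[AbundanceTable, np.ndarray]:
    """Restrict table and labels to their common samples, in metadata order."""
    in_table = set(table.sample_ids)
    kept = [m for m in metadata if m.sample_id in in_table]
    if not kept:
        raise ValueError("no samples shared between abundance table and metadata")
    ids = [m.sample_id for m in kept]
    labels = np.array([m.label for m in kept], dtype=np.int64)
    return table.select_samples(ids), labels


# ----------------------------------------------------------------------
# packaged reference tables


def _data_path(name: str):
    return resources.files("mvcvib.data").joinpath(name)


def load_mcrc_metadata(
    group_to_label: Mapping[str, int] = MCRC_GROUP_LABELS,
) -> list[SampleMetadata]:
    """The packaged 16-sample mCRC / non-mCRC cohort metadata."""
    with resources.as_file(_data_path("mcrc_cohort_metadata.tsv")) as p:
        return read_metadata(p, group_to_label)


def load_crc_registry() -> list[DatasetDescriptor]:
    """Size registry of the three published control-vs-CRC cohorts."""
    with resources.as_file(_data_path("crc_dataset_registry.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return [
        DatasetDescriptor(str(r["name"]), int(r["n_total"]),
                          int(r["n_control"]), int(r["n_disease"]))
        for _, r in df.iterrows()
    ]
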