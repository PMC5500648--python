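"""Reading, writing and validation of structural-connectome data.

A subject's structural connectivity (SC) matrix is an M x M symmetric matrix
of nonnegative integers: entry (i, j) counts the tractography streamlines
whose two endpoints fall in brain modules i and j of an M-module parcellation.
This module provides the SC container, the streamline-endpoint counting step
that produces it, and plain-TSV interchange for SC matrices, cohort metadata
and atlas labels.

File dialects
-------------
* SC matrix: TSV, no header, M rows x M columns of integer literals, one file
  per subject named ``<subject_id>.tsv``.
* Cohort metadata: TSV with header
  ``subject_id  group  age  sex  education_years``; file order defines the
  subject order of every downstream subject-space matrix.
* Atlas: TSV with header ``module_index  module_name``; module indices are
  1-based everywhere in files and reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ConnectivityMatrix",
    "Cohort",
    "AtlasPartition",
    "StreamlineTable",
    "count_streamlines_to_sc",
    "read_sc_matrix",
    "write_sc_matrix",
    "read_cohort",
    "write_cohort",
    "read_atlas",
    "write_atlas",
]

COHORT_COLUMNS = ["subject_id", "group", "age", "sex", "education_years"]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One subject's M x M symmetric streamline-count matrix."""

    subject_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValidationError(
                f"SC matrix for {self.subject_id!r} must be square, got shape {counts.shape}"
            )
        if counts.shape[0] < 2:
            raise ValidationError(
                f"SC matrix for {self.subject_id!r} needs at least 2 modules"
            )
        if not np.issubdtype(counts.dtype, np.number):
            raise ValidationError(f"SC matrix for {self.subject_id!r} is not numeric")
        if np.any(counts != np.round(counts)):
            i, j = np.argwhere(counts != np.round(counts))[0]
            raise ValidationError(
                f"SC matrix for {self.subject_id!r} has non-integer entry at "
                f"({i + 1}, {j + 1})"
            )
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"SC matrix for {self.subject_id!r} has negative entry at "
                f"({i + 1}, {j + 1})"
            )
        asym = np.argwhere(counts != counts.T)
        if asym.size:
            i, j = asym[0]
            raise ValidationError(
                f"SC matrix for {self.subject_id!r} is asymmetric: "
                f"({i + 1}, {j + 1})={counts[i, j]} vs ({j + 1}, {i + 1})={counts[j, i]}"
            )
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_modules(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class Cohort:
    """Ordered subject records; row order defines all subject-space matrices."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing column(s) {missing}")
        dup = df["subject_id"][df["subject_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate subject_id {dup.iloc[0]!r} in cohort")
        blank = df["group"].isna() | (df["group"].astype(str).str.strip() == "")
        if blank.any():
            sid = df.loc[blank, "subject_id"].iloc[0]
            raise ValidationError(f"subject {sid!r} has an empty group label")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])

    @property
    def groups(self) -> np.ndarray:
        """Per-subject group labels, aligned with subject order."""
        return self.table["group"].to_numpy()

    @property
    def group_sizes(self) -> dict[str, int]:
        """Group sizes keyed by label, in order of first appearance."""
        sizes: dict[str, int] = {}
        for g in self.table["group"]:
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def subset(self, groups: Sequence[str]) -> "Cohort":
        """Subjects belonging to ``groups``, cohort order preserved."""
        unknown = set(groups) - set(self.table["group"])
        if unknown:
            raise ValidationError(f"unknown group label(s) {sorted(unknown)}")
        mask = self.table["group"].isin(list(groups))
        return Cohort(self.table[mask].reset_index(drop=True))


@dataclass(frozen=True)
class AtlasPartition:
    """The M-module brain parcellation used to define SC matrices."""

    module_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.module_names) < 2:
            raise ValidationError("atlas needs at least 2 modules")
        if len(set(self.module_names)) != len(self.module_names):
            raise ValidationError("atlas module names must be unique")
        object.__setattr__(self, "module_names", tuple(self.module_names))

    @classmethod
    def default(cls, n_modules: int) -> "AtlasPartition":
        return cls(tuple(f"module_{i}" for i in range(1, n_modules + 1)))

    @property
    def n_modules(self) -> int:
        return len(self.module_names)


@dataclass(frozen=True)
class StreamlineTable:
    """Streamline endpoint assignments: one row per reconstructed streamline."""

    rows: pd.DataFrame

    REQUIRED = ("streamline_id", "endpoint_a_module", "endpoint_b_module")

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"streamline table missing column(s) {missing}")
        object.__setattr__(self, "rows", df.reset_index(drop=True))

    @classmethod
    def from_endpoints(
        cls, endpoints: Iterable[tuple[int, int]]
    ) -> "StreamlineTable":
        pairs = list(endpoints)
        return cls(
            pd.DataFrame(
                {
                    "streamline_id": [f"s{k}" for k in range(len(pairs))],
                    "endpoint_a_module": [a for a, _ in pairs],
                    "endpoint_b_module": [b for _, b in pairs],
                }
            )
        )


def count_streamlines_to_sc(
    table: StreamlineTable, atlas: AtlasPartition, subject_id: str = "subject"
) -> ConnectivityMatrix:
    """Count streamlines per unordered module pair into an SC matrix.

    SC(i, j) is the number of streamlines with endpoint set {i, j}; a
    streamline with both endpoints in module i increments the diagonal
    SC(i, i) by one.  Symmetric by construction.
    """
    m = atlas.n_modules
    a = table.rows["endpoint_a_module"].to_numpy()
    b = table.rows["endpoint_b_module"].to_numpy()
    for name, col in (("endpoint_a_module", a), ("endpoint_b_module", b)):
        bad = np.where((col < 1) | (col > m) | (col != np.round(col)))[0]
        if bad.size:
            row = table.rows.iloc[bad[0]]
            raise ValidationError(
                f"streamline {row['streamline_id']!r} (row {bad[0]}): "
                f"{name}={row[name]} outside [1, {m}]"
            )
    counts = np.zeros((m, m), dtype=np.int64)
    if len(a):
        np.add.at(counts, (a.astype(int) - 1, b.astype(int) - 1), 1)
        np.add.at(counts, (b.astype(int) - 1, a.astype(int) - 1), 1)
        # each streamline touched the matrix twice; self-loops landed twice
        # on the diagonal, so halving the diagonal leaves one count per loop
        np.fill_diagonal(counts, np.diagonal(counts) // 2)
    return ConnectivityMatrix(subject_id=subject_id, counts=counts)


def read_sc_matrix(
    path: str | Path,
    atlas: AtlasPartition | None = None,
    subject_id: str | None = None,
) -> ConnectivityMatrix:
    """Read one subject's SC matrix from headerless integer TSV.

    If ``atlas`` is given the matrix dimension is checked against it.
    ``subject_id`` defaults to the file stem.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None)
    except Exception as exc:  # malformed file
        raise ValidationError(f"{path}: cannot parse as TSV ({exc})") from exc
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric entries present")
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(
            f"{path}: expected a square matrix, got shape {values.shape}"
        )
    if atlas is not None and values.shape[0] != atlas.n_modules:
        raise ValidationError(
            f"{path}: expected {atlas.n_modules}x{atlas.n_modules} matrix, "
            f"got {values.shape[0]}x{values.shape[1]}"
        )
    return ConnectivityMatrix(
        subject_id=subject_id if subject_id is not None else path.stem,
        counts=values,
    )


def write_sc_matrix(sc: ConnectivityMatrix, path: str | Path) -> None:
    """Write an SC matrix as headerless integer TSV (round-trips exactly)."""
    np.savetxt(Path(path), sc.counts, fmt="%d", delimiter="\t")


def read_cohort(path: str | Path) -> Cohort:
    """Read cohort metadata TSV; file order becomes the subject order."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "group": str, "sex": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return Cohort(df[COHORT_COLUMNS].copy())


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cohort.table.to_csv(Path(path), sep="\t", index=False)


def read_atlas(path: str | Path) -> AtlasPartition:
    df = pd.read_csv(Path(path), sep="\t")
    for col in ("module_index", "module_name"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    df = df.sort_values("module_index")
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(df["module_index"].to_numpy(), expected):
        raise ValidationError(f"{path}: module_index must be 1..M without gaps")
    return AtlasPartition(tuple(df["module_name"].astype(str)))


def write_atlas(atlas: AtlasPartition, path: str | Path) -> None:
    pd.DataFrame(
        {
            "module_index": np.arange(1, atlas.n_modules + 1),
            "module_name": list(atlas.module_names),
        }
    ).to_csv(Path(path), sep="\t", index=False)
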