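"""Canonical in-memory containers shared by all readers, statistics, and outputs.

The hub object is :class:`CopyNumberMatrix`: a cell x chromosome matrix of
non-negative integer copy numbers with an explicit missing-entry mask.  Every
reader (FISH tables, SKY karyotypes, binned sc-WGS states) produces one, and
every statistic and plot consumes one.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SOURCES = ("FISH", "SKY", "scWGS")

AUTOSOMES = tuple(str(i) for i in range(1, 23))
HUMAN_CHROMOSOMES = AUTOSOMES + ("X", "Y")


def normalize_chromosome(label: str) -> str:
    """Normalize a chromosome label: strip a leading ``chr`` prefix and
    uppercase sex chromosomes, so ``chr1``/``1`` and ``x``/``X`` unify
    across platforms."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.lower() in ("x", "y"):
        s = s.upper()
    return s


@dataclass
class CopyNumberMatrix:
    """Cell x chromosome integer copy-number matrix.

    Parameters
    ----------
    cell_ids : list of str
        Ordered unique cell identifiers (length N).
    chromosomes : list of str
        Ordered unique chromosome labels (length T), normalized.
    counts : (N, T) int ndarray
        Entry (n, t) is the copy number of chromosome t in cell n.  Entries
        under the missing mask are ignored by every statistic.
    source : str
        One of ``FISH``, ``SKY``, ``scWGS``.
    missing_mask : (N, T) bool ndarray
        True where the entry is unobserved.
    """

    cell_ids: list
    chromosomes: list
    counts: np.ndarray
    source: str
    missing_mask: np.ndarray = None

    def __post_init__(self):
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.chromosomes = [normalize_chromosome(c) for c in self.chromosomes]
        self.counts = np.asarray(self.counts)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.counts.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        n, t = self.counts.shape
        if n < 1 or t < 1:
            raise ValueError("matrix must have at least one cell and one chromosome")
        if len(self.cell_ids) != n or len(self.chromosomes) != t:
            raise ValueError("cell_ids/chromosomes lengths do not match counts shape")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell identifiers must be unique")
        if len(set(self.chromosomes)) != t:
            raise ValueError("chromosome labels must be unique")
        if self.missing_mask.shape != self.counts.shape:
            raise ValueError("missing_mask shape must match counts shape")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        obs = self.counts[~self.missing_mask]
        if obs.size and not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(obs, 1), 0)):
                raise ValueError("observed copy numbers must be integers")
        self.counts = self.counts.astype(np.int64, copy=False)
        if obs.size and (self.counts[~self.missing_mask] < 0).any():
            bad = np.argwhere((self.counts < 0) & ~self.missing_mask)
            n0, t0 = bad[0]
            raise ValueError(
                f"negative copy number at cell {self.cell_ids[n0]!r}, "
                f"chromosome {self.chromosomes[t0]!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_chromosomes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, indices) -> "CopyNumberMatrix":
        idx = np.asarray(indices)
        return CopyNumberMatrix(
            [self.cell_ids[i] for i in idx],
            list(self.chromosomes),
            self.counts[idx],
            self.source,
            self.missing_mask[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame (cells x chromosomes); missing entries NaN."""
        vals = self.counts.astype(float)
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.cell_ids, columns=self.chromosomes)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, source: str) -> "CopyNumberMatrix":
        mask = frame.isna().to_numpy()
        counts = frame.fillna(0).to_numpy()
        return cls(list(frame.index), list(frame.columns), counts, source, mask)


@dataclass
class GroupAssignment:
    """Mapping of cell identifiers to experimental group labels."""

    mapping: dict

    def __post_init__(self):
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}

    def groups(self) -> list:
        seen = {}
        for g in self.mapping.values():
            if g:
                seen.setdefault(g, None)
        return list(seen)

    def label_of(self, cell_id: str):
        return self.mapping.get(str(cell_id))


@dataclass
class EuploidReference:
    """Expected euploid copy number per chromosome (default 2 everywhere).

    A sex-aware human reference (X=1, Y=1 for male karyotypes, etc.) can be
    expressed by listing explicit per-chromosome values.
    """

    euploid_copy: dict = field(default_factory=dict)
    default: int = 2

    def __post_init__(self):
        self.euploid_copy = {
            normalize_chromosome(k): int(v) for k, v in self.euploid_copy.items()
        }
        for chrom, e in self.euploid_copy.items():
            if e < 1:
                raise ValueError(f"euploid copy for {chrom!r} must be >= 1, got {e}")
        if self.default < 1:
            raise ValueError("default euploid copy must be >= 1")

    def copy_for(self, chromosome: str) -> int:
        return self.euploid_copy.get(normalize_chromosome(chromosome), self.default)

    def vector(self, chromosomes) -> np.ndarray:
        return np.array([self.copy_for(c) for c in chromosomes], dtype=np.int64)

    @classmethod
    def female_human(cls) -> "EuploidReference":
        return cls({"Y": 1}, default=2)  # Y absent; e=1 avoids zero division issues

    @classmethod
    def male_human(cls) -> "EuploidReference":
        return cls({"X": 1, "Y": 1}, default=2)


@dataclass
class ValidationReport:
    """Result of :func:`validate_matrix`: named problems, no mutation."""

    unlabeled_cells: list = field(default_factory=list)
    empty_groups: list = field(default_factory=list)
    fully_missing_cells: list = field(default_factory=list)
    key_only_cells: list = field(default_factory=list)

    def is_clean(self) -> bool:
        return not (
            self.unlabeled_cells
            or self.empty_groups
            or self.fully_missing_cells
            or self.key_only_cells
        )


def validate_matrix(matrix: CopyNumberMatrix, groups: GroupAssignment) -> ValidationReport:
    """Check a matrix against its group key without modifying either.

    Lists cells missing group labels, group labels with no cells, cells whose
    entries are all missing, and key entries with no matching cell.  Raises if
    no labeled cell remains.
    """
    report = ValidationReport()
    matrix_cells = set(matrix.cell_ids)
    labeled = set()
    for cid in matrix.cell_ids:
        g = groups.label_of(cid)
        if g is None or g == "":
            report.unlabeled_cells.append(cid)
        else:
            labeled.add(cid)
    used_groups = {groups.label_of(c) for c in labeled}
    for g in groups.groups():
        if g not in used_groups:
            report.empty_groups.append(g)
    for key_cell in groups.mapping:
        if key_cell not in matrix_cells:
            report.key_only_cells.append(key_cell)
    all_missing = matrix.missing_mask.all(axis=1)
    for i in np.flatnonzero(all_missing):
        report.fully_missing_cells.append(matrix.cell_ids[i])
    if not labeled:
        raise ValueError("no cells remain after removing cells without a group label")
    if report.key_only_cells:
        warnings.warn(
            f"{len(report.key_only_cells)} key entries have no matching cell "
            "in the matrix; they are ignored",
            stacklevel=2,
        )
    return report


def stratify(matrix: CopyNumberMatrix, groups: GroupAssignment):
    """Partition the matrix cells by group label.

    Returns a list of ``(group_label, sub_matrix)`` in first-appearance order
    of the labels among the matrix cells.  Cells without a (non-empty) label
    are excluded with a warning; chromosome order is preserved.
    """
    order = []
    members = {}
    dropped = 0
    for i, cid in enumerate(matrix.cell_ids):
        g = groups.label_of(cid)
        if g is None or g == "":
            dropped += 1
            continue
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(i)
    if dropped:
        warnings.warn(f"{dropped} cells without a group label were excluded", stacklevel=2)
    if not order:
        raise ValueError("no labeled cells to stratify")
    return [(g, matrix.subset_cells(members[g])) for g in order]


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        for d in ("\t", ";", ","):
            if d in sample:
                return d
        return ","


def read_group_key(path) -> GroupAssignment:
    """Read a two-column group key (header ``cell_id,group``); the delimiter
    is auto-detected among comma, tab, and semicolon."""
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = _sniff_delimiter(sample)
        reader = csv.reader(fh, delimiter=delim)
        rows = [r for r in reader if r and any(f.strip() for f in r)]
    if not rows:
        raise ValueError(f"empty group key file: {path}")
    header = [h.strip().lower() for h in rows[0]]
    if len(header) < 2:
        raise ValueError(f"group key must have two columns, got header {rows[0]!r}")
    body = rows[1:] if header[0] in ("cell_id", "cell", "id") else rows
    mapping = {}
    for r in body:
        if len(r) < 2:
            raise ValueError(f"malformed group key row: {r!r}")
        cid, grp = r[0].strip(), r[1].strip()
        if cid in mapping:
            raise ValueError(f"duplicate cell id in group key: {cid!r}")
        mapping[cid] = grp
    return GroupAssignment(mapping)


def write_group_key(groups: GroupAssignment, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "group"])
        for cid, g in groups.mapping.items():
            w.writerow([cid, g])


def concatenate(matrices) -> CopyNumberMatrix:
    """Stack matrices over cells (shared chromosome set required)."""
    matrices = list(matrices)
    first = matrices[0]
    for m in matrices[1:]:
        if m.chromosomes != first.chromosomes:
            raise ValueError("matrices must share an identical chromosome ordering")
        if m.source != first.source:
            raise ValueError("matrices must share a source tag")
    return CopyNumberMatrix(
        [c for m in matrices for c in m.cell_ids],
        list(first.chromosomes),
        np.vstack([m.counts for m in matrices]),
        first.source,
        np.vstack([m.missing_mask for m in matrices]),
    )
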