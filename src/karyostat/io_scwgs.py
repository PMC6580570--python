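"""Reduction of binned single-cell WGS copy-number states to chromosomes.

Input is the integer copy-number state matrix an upstream caller emits after
aligning, binning, and segmenting low-coverage single-cell reads: leading
CHR/START/END columns (BED convention, 0-based half-open) followed by one
integer column per cell.  This module does not touch reads; it collapses the
bin-level states to one whole-chromosome copy number per cell by a
bin-length-weighted average rounded to the nearest integer (halves away
from zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CopyNumberMatrix, normalize_chromosome

_COORD_ALIASES = {"chr": "CHR", "#chr": "CHR", "chrom": "CHR", "chromosome": "CHR",
                  "start": "START", "end": "END", "stop": "END"}


@dataclass
class BinnedCopyNumberTable:
    """Genomic bins x cells integer copy-number state matrix."""

    bins: list  # ordered (chromosome, start, end), 0-based half-open
    cell_ids: list
    cell_states: np.ndarray  # (n_bins, n_cells) int; negative = missing
    missing_mask: np.ndarray = None

    def __post_init__(self):
        self.cell_states = np.asarray(self.cell_states, dtype=np.int64)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.cell_states.shape, dtype=bool)
        per_chrom = {}
        for i, (chrom, start, end) in enumerate(self.bins):
            if end <= start:
                raise ValueError(
                    f"bin {chrom}:{start}-{end} has non-positive length"
                )
            per_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in per_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping bins on chromosome {chrom}: "
                        f"[{s1},{e1}) and [{s2},{e2})"
                    )
        obs = self.cell_states[~self.missing_mask]
        if obs.size and (obs < 0).any():
            raise ValueError("copy-number states must be non-negative integers")


def read_binned_table(path) -> BinnedCopyNumberTable:
    """Read a delimited bin-state matrix with CHR/START/END leading columns.

    Header variants (``#CHR``, ``chrom``, lower case) are normalized; any
    non-integer state is an error naming the offending bin.
    """
    table = pd.read_csv(path, sep=None, engine="python")
    rename = {}
    for col in table.columns[:3]:
        key = str(col).strip().lower()
        if key in _COORD_ALIASES:
            rename[col] = _COORD_ALIASES[key]
    table = table.rename(columns=rename)
    for required in ("CHR", "START", "END"):
        if required not in table.columns:
            raise ValueError(f"binned table {path} lacks a {required} column")
    cell_cols = [c for c in table.columns if c not in ("CHR", "START", "END")]
    if not cell_cols:
        raise ValueError(f"binned table {path} has no cell columns")
    bins = [
        (normalize_chromosome(r.CHR), int(r.START), int(r.END))
        for r in table.itertuples()
    ]
    raw = table[cell_cols].to_numpy()
    mask = pd.isna(raw)
    states = np.zeros(raw.shape, dtype=np.int64)
    for (i, j) in np.argwhere(~mask):
        v = float(raw[i, j])
        if not v.is_integer():
            chrom, start, end = bins[i]
            raise ValueError(
                f"non-integer state {raw[i, j]!r} for cell {cell_cols[j]!r} "
                f"in bin {chrom}:{start}-{end}"
            )
        states[i, j] = int(v)
    return BinnedCopyNumberTable(bins, [str(c) for c in cell_cols], states, mask)


def _round_half_away(x: float) -> int:
    # np.round rounds halves to even; the convention here is away from zero
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


def collapse_to_chromosomes(table: BinnedCopyNumberTable) -> CopyNumberMatrix:
    """Length-weighted reduction of bin states to whole-chromosome counts.

    For each (cell, chromosome): count = round(sum state_b * len_b / sum
    len_b) over that cell's observed bins, halves rounded away from zero.
    Bins missing for a cell are excluded and the weights renormalized; a
    chromosome with no observed bin for a cell becomes a missing entry.
    The result always lies between the min and max bin state involved, and
    splitting any bin into two of the same state changes nothing.
    """
    chroms, chrom_rows = [], {}
    for i, (chrom, start, end) in enumerate(table.bins):
        if chrom not in chrom_rows:
            chrom_rows[chrom] = []
            chroms.append(chrom)
        chrom_rows[chrom].append(i)
    lengths = np.array([end - start for _, start, end in table.bins], dtype=np.float64)
    n_cells = len(table.cell_ids)
    counts = np.zeros((n_cells, len(chroms)), dtype=np.int64)
    mask = np.zeros((n_cells, len(chroms)), dtype=bool)
    for t, chrom in enumerate(chroms):
        rows = np.array(chrom_rows[chrom])
        for j in range(n_cells):
            obs = rows[~table.missing_mask[rows, j]]
            total = lengths[obs].sum()
            if total <= 0:
                mask[j, t] = True
                continue
            weighted = float(
                (table.cell_states[obs, j] * lengths[obs]).sum() / total
            )
            counts[j, t] = _round_half_away(weighted)
    return CopyNumberMatrix(list(table.cell_ids), chroms, counts, "scWGS", mask)


def write_binned_table(table: BinnedCopyNumberTable, path) -> None:
    """Serialize a bin-state table as tab-delimited text (missing blank)."""
    frame = pd.DataFrame(
        table.cell_states.astype(object), columns=table.cell_ids
    )
    frame = frame.mask(table.missing_mask, "")
    frame.insert(0, "CHR", [b[0] for b in table.bins])
    frame.insert(1, "START", [b[1] for b in table.bins])
    frame.insert(2, "END", [b[2] for b in table.bins])
    frame.to_csv(path, sep="\t", index=False)
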