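"""Reader/writer for FISH count tables.

A FISH table is delimited text with one row per cell: the first column is the
cell identifier, each remaining column the signal count for one probed
chromosome.  Blank or NA entries become missing-mask entries; any other
non-numeric value is an error, never silently treated as missing.
"""

from __future__ import annotations

import csv

import numpy as np

from .datamodel import (
    CopyNumberMatrix,
    GroupAssignment,
    _sniff_delimiter,
    read_group_key,
)

NA_SPELLINGS = {"", "na", "nan"}


def _parse_count(token: str, row_label: str, col_label: str):
    s = token.strip()
    if s.lower() in NA_SPELLINGS:
        return None
    try:
        val = float(s)
    except ValueError:
        raise ValueError(
            f"non-numeric count {token!r} at cell {row_label!r}, column {col_label!r}"
        ) from None
    if not val.is_integer():
        raise ValueError(
            f"non-integer count {token!r} at cell {row_label!r}, column {col_label!r}"
        )
    return int(val)


def read_fish_counts(path) -> CopyNumberMatrix:
    """Read a FISH count table into a copy-number matrix (source FISH)."""
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        reader = csv.reader(fh, delimiter=_sniff_delimiter(sample))
        rows = [r for r in reader if r and any(f.strip() for f in r)]
    if len(rows) < 2:
        raise ValueError(f"FISH table {path} needs a header and at least one cell row")
    header = [h.strip() for h in rows[0]]
    if len(header) < 2 or not header[0]:
        raise ValueError(f"malformed FISH header: {rows[0]!r}")
    chromosomes = header[1:]
    cell_ids, counts, mask = [], [], []
    for r in rows[1:]:
        if len(r) != len(header):
            raise ValueError(f"row for cell {r[0]!r} has {len(r)} fields, expected {len(header)}")
        cid = r[0].strip()
        if cid in cell_ids:
            raise ValueError(f"duplicate cell id {cid!r}")
        cell_ids.append(cid)
        row_counts, row_mask = [], []
        for chrom, tok in zip(chromosomes, r[1:]):
            v = _parse_count(tok, cid, chrom)
            row_counts.append(0 if v is None else v)
            row_mask.append(v is None)
        counts.append(row_counts)
        mask.append(row_mask)
    return CopyNumberMatrix(
        cell_ids, chromosomes, np.array(counts), "FISH", np.array(mask)
    )


def read_fish_table(path, key_path) -> tuple:
    """Read a FISH table plus its group key."""
    return read_fish_counts(path), read_group_key(key_path)


def write_fish_counts(matrix: CopyNumberMatrix, path, delimiter: str = ",") -> None:
    """Write a matrix in the FISH table format (missing entries blank).

    Writing then reading reproduces counts, mask, and ordering exactly.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["cell_id", *matrix.chromosomes])
        for n, cid in enumerate(matrix.cell_ids):
            row = [
                "" if matrix.missing_mask[n, t] else int(matrix.counts[n, t])
                for t in range(matrix.n_chromosomes)
            ]
            w.writerow([cid, *row])
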