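"""ISCN karyotype parsing for spectral karyotyping (SKY) data.

Karyotype strings like ``47,XY,+8`` encode the modal chromosome number, the
sex-chromosome complement, and aberrations.  This reader extracts *numerical*
whole-chromosome gains and losses only: structural tokens (translocations,
deletions, inversions, markers, ...) carry no whole-chromosome copy change
and are collected as unparsed tokens rather than rejected.  Full ISCN
grammar (breakpoints, derivative-chromosome arithmetic) is out of scope.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    AUTOSOMES,
    HUMAN_CHROMOSOMES,
    CopyNumberMatrix,
    GroupAssignment,
    read_group_key,
)

_NUMERICAL_TOKEN = re.compile(r"^([+-])(\d{1,2}|[XY])$", re.IGNORECASE)
_BRACKETED = re.compile(r"\[[^\]]*\]")
_MODAL = re.compile(r"^(\d{1,3})(?:[~-]\d{1,3})?$")
_SEX = re.compile(r"^[XY]+$", re.IGNORECASE)


@dataclass
class KaryotypeRecord:
    """One parsed per-cell karyotype."""

    cell_id: str
    iscn_string: str
    modal_total: int
    sex_complement: str
    numerical_events: list = field(default_factory=list)  # (chromosome, +1/-1)
    unparsed_tokens: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)  # chromosome -> copy number
    consistent: bool = True


def parse_iscn(iscn_string: str, cell_id: str = "") -> KaryotypeRecord:
    """Parse one ISCN karyotype string into whole-chromosome copy counts.

    The leading modal number sets the baseline ploidy (nearest multiple of
    23: 46 -> 2 per autosome, 69 -> 3, 92 -> 4); sex-chromosome counts come
    from the complement string (number of X and Y letters) adjusted by
    ``+X``/``-Y`` tokens; each ``+N``/``-N`` token shifts one autosome.
    Mosaic karyotypes (clones separated by ``/``) use the first clone with a
    warning; modal-number ranges (``44~47``) use the first number;
    clone-size brackets (``[12]``) are stripped.

    The derived counts are checked against the reported modal total; a
    mismatch sets ``consistent=False`` on the record, never a silent fix.
    """
    raw = iscn_string.strip()
    if not raw:
        raise ValueError("empty ISCN string")
    clones = _BRACKETED.sub("", raw).split("/")
    if len(clones) > 1:
        warnings.warn(
            f"mosaic karyotype {iscn_string!r}: using first clone only", stacklevel=2
        )
    tokens = [t.strip() for t in clones[0].split(",") if t.strip()]
    if not tokens:
        raise ValueError(f"no tokens in ISCN string {iscn_string!r}")

    m = _MODAL.match(tokens[0])
    if not m:
        raise ValueError(f"unparseable modal chromosome number in {iscn_string!r}")
    modal_total = int(m.group(1))
    ploidy = max(1, round(modal_total / 23))

    rest = tokens[1:]
    sex = ""
    if rest and _SEX.match(rest[0]):
        sex = rest[0].upper()
        rest = rest[1:]

    counts = {c: ploidy for c in AUTOSOMES}
    counts["X"] = sex.count("X")
    counts["Y"] = sex.count("Y")

    events, unparsed = [], []
    for tok in rest:
        nm = _NUMERICAL_TOKEN.match(tok)
        if nm:
            sign = 1 if nm.group(1) == "+" else -1
            chrom = nm.group(2).upper()
            if chrom not in HUMAN_CHROMOSOMES:
                unparsed.append(tok)
                continue
            counts[chrom] += sign
            events.append((chrom, sign))
        else:
            unparsed.append(tok)
    for chrom, c in counts.items():
        if c < 0:
            raise ValueError(
                f"karyotype {iscn_string!r} implies negative count for chromosome {chrom}"
            )
    consistent = sum(counts.values()) == modal_total
    return KaryotypeRecord(
        cell_id=cell_id,
        iscn_string=iscn_string,
        modal_total=modal_total,
        sex_complement=sex,
        numerical_events=events,
        unparsed_tokens=unparsed,
        counts=counts,
        consistent=consistent,
    )


def karyotypes_to_matrix(records, key_path=None) -> tuple:
    """Assemble parsed karyotypes into a matrix over chromosomes 1-22, X, Y.

    Returns ``(CopyNumberMatrix, GroupAssignment or None)``; inconsistent
    records (derived counts vs reported modal total) are flagged with a
    warning listing the cells, never corrected.
    """
    records = list(records)
    if not records:
        raise ValueError("no karyotype records")
    bad = [r.cell_id or r.iscn_string for r in records if not r.consistent]
    if bad:
        warnings.warn(
            f"{len(bad)} karyotypes whose token arithmetic does not match the "
            f"reported modal number: {bad}",
            stacklevel=2,
        )
    cell_ids = [r.cell_id or f"cell{i + 1}" for i, r in enumerate(records)]
    counts = np.array(
        [[r.counts[c] for c in HUMAN_CHROMOSOMES] for r in records], dtype=np.int64
    )
    matrix = CopyNumberMatrix(cell_ids, list(HUMAN_CHROMOSOMES), counts, "SKY")
    groups = read_group_key(key_path) if key_path is not None else None
    return matrix, groups


def read_sky_table(path, key_path=None) -> tuple:
    """Read a spreadsheet (.xlsx) or delimited text with ``cell_id`` and
    ``karyotype`` columns and parse each row's ISCN string."""
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        table = pd.read_excel(path)
    else:
        table = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip().lower(): c for c in table.columns}
    if "cell_id" not in cols or "karyotype" not in cols:
        raise ValueError(
            f"SKY table must have 'cell_id' and 'karyotype' columns, got {list(table.columns)}"
        )
    records = [
        parse_iscn(str(row[cols["karyotype"]]), cell_id=str(row[cols["cell_id"]]))
        for _, row in table.iterrows()
    ]
    return karyotypes_to_matrix(records, key_path)
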