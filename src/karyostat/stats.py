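"""Population-level aneuploidy statistics.

Implements six literature-derived summaries of numerical chromosomal
variation in a population of single cells:

* ``I``  — instability index: mean across chromosomes of the percentage of
  cells deviating from the modal copy number, scaled to percent.
* ``A``  — ANCA: average number of copy-number-altered chromosomes per cell.
* ``AN`` — ANCA normalized by the number of chromosomes measured.
* ``D``  — aneuploidy score: mean absolute deviation from the euploid copy
  number over all observed (cell, chromosome) entries.
* ``H``  — heterogeneity score: rank-weighted spread of copy-number states
  per chromosome; 0 when all cells agree, maximal when every cell differs.
* ``(P_A, P_D, P_P)`` — proportions of aneuploid / diploid / polyploid cells.

All statistics are computed over observed entries only; masked entries never
contribute to numerators or denominators.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CopyNumberMatrix, EuploidReference

STATISTIC_NAMES = ("I", "ANCA", "normANCA", "D", "H")


@dataclass
class ChromosomeStateTally:
    """State-count bookkeeping for one chromosome across the population."""

    chromosome: str
    state_counts: dict
    n_cells: int
    modal_state: int
    modal_count: int
    nonmodal_fraction: float
    n_states: int


@dataclass
class GroupStatistics:
    """The six population summaries for one (group, source) stratum."""

    group: str
    source: str
    n_cells: int
    n_chromosomes: int
    instability_index: float
    anca: float
    normalized_anca: float
    aneuploidy_score: float
    heterogeneity_score: float
    ploidy_proportions: tuple

    def as_dict(self) -> dict:
        p_a, p_d, p_p = self.ploidy_proportions
        return {
            "group": self.group,
            "source": self.source,
            "n_cells": self.n_cells,
            "n_chromosomes": self.n_chromosomes,
            "I": self.instability_index,
            "ANCA": self.anca,
            "normANCA": self.normalized_anca,
            "D": self.aneuploidy_score,
            "H": self.heterogeneity_score,
            "P_A": p_a,
            "P_D": p_d,
            "P_P": p_p,
        }


@dataclass
class ChromosomeStatistics:
    """Per-chromosome A, AN, D, H for one stratum (computed with T = 1).

    The instability index and ploidy proportions are population-of-cells
    features and are not reported per chromosome.
    """

    group: str
    source: str
    chromosome: str
    n_cells: int
    anca: float
    normalized_anca: float
    aneuploidy_score: float
    heterogeneity_score: float

    def as_dict(self) -> dict:
        return {
            "group": self.group,
            "source": self.source,
            "chromosome": self.chromosome,
            "n_cells": self.n_cells,
            "ANCA": self.anca,
            "normANCA": self.normalized_anca,
            "D": self.aneuploidy_score,
            "H": self.heterogeneity_score,
        }


def _observed_column(matrix: CopyNumberMatrix, t: int) -> np.ndarray:
    col = matrix.counts[:, t]
    return col[~matrix.missing_mask[:, t]]


def tally_chromosome(
    matrix: CopyNumberMatrix, chromosome: str, ref: EuploidReference | None = None
) -> ChromosomeStateTally:
    """Tally copy-number states of one chromosome over non-missing entries.

    The modal state is the most frequent one; ties are broken toward the
    state closest to the euploid copy number, then toward the smaller state.
    Only the modal *count* feeds the instability index, so tie-breaking
    affects the reported modal state label only.
    """
    if chromosome not in matrix.chromosomes:
        raise KeyError(f"chromosome {chromosome!r} not in matrix")
    t = matrix.chromosomes.index(chromosome)
    observed = _observed_column(matrix, t)
    if observed.size == 0:
        raise ValueError(f"all entries missing for chromosome {chromosome!r}")
    counts = Counter(int(v) for v in observed)
    e_t = (ref or EuploidReference()).copy_for(chromosome)
    modal_count = max(counts.values())
    candidates = [s for s, c in counts.items() if c == modal_count]
    modal_state = min(candidates, key=lambda s: (abs(s - e_t), s))
    n = observed.size
    return ChromosomeStateTally(
        chromosome=chromosome,
        state_counts=dict(sorted(counts.items())),
        n_cells=n,
        modal_state=modal_state,
        modal_count=modal_count,
        nonmodal_fraction=1.0 - modal_count / n,
        n_states=len(counts),
    )


# ---------------------------------------------------------------------------
# Fast array-level evaluators.
#
# These operate directly on (counts, missing_mask, euploid_vector) and are
# the computational core: the public matrix-level functions and the
# permutation test (which evaluates statistics tens of thousands of times)
# both route through them.
# ---------------------------------------------------------------------------


def _instability_from_arrays(counts: np.ndarray, mask: np.ndarray) -> float:
    total = 0.0
    n_chrom = counts.shape[1]
    for t in range(n_chrom):
        col = counts[~mask[:, t], t]
        if col.size == 0:
            raise ValueError(f"all entries missing for chromosome index {t}")
        modal = np.bincount(col).max()
        total += 1.0 - modal / col.size
    return 100.0 * total / n_chrom


def _anca_from_arrays(counts: np.ndarray, mask: np.ndarray, e: np.ndarray) -> float:
    altered = (counts != e[np.newaxis, :]) & ~mask
    observed_any = (~mask).any(axis=1)
    q = altered.sum(axis=1)[observed_any]
    if q.size == 0:
        raise ValueError("no cells with observed entries")
    return float(q.mean())


def _aneuploidy_from_arrays(counts: np.ndarray, mask: np.ndarray, e: np.ndarray) -> float:
    dev = np.abs(counts - e[np.newaxis, :])
    n_obs = (~mask).sum()
    if n_obs == 0:
        raise ValueError("no observed entries")
    return float(dev[~mask].sum() / n_obs)


def _heterogeneity_column(col: np.ndarray) -> float:
    """Rank-weighted state spread for one chromosome: sort the state counts
    descending as m_0 >= m_1 >= ... and return (sum_f f*m_f) / N_t."""
    if col.size == 0:
        raise ValueError("all entries missing for a chromosome")
    m = np.sort(np.bincount(col))[::-1]
    m = m[m > 0]
    return float((np.arange(m.size) * m).sum() / col.size)


def _heterogeneity_from_arrays(counts: np.ndarray, mask: np.ndarray) -> float:
    vals = []
    for t in range(counts.shape[1]):
        col = counts[~mask[:, t], t]
        vals.append(_heterogeneity_column(col))
    return float(np.mean(vals))


_ARRAY_EVALUATORS = {
    "I": lambda c, m, e: _instability_from_arrays(c, m),
    "ANCA": _anca_from_arrays,
    "normANCA": lambda c, m, e: _anca_from_arrays(c, m, e) / c.shape[1],
    "D": _aneuploidy_from_arrays,
    "H": lambda c, m, e: _heterogeneity_from_arrays(c, m),
}


def evaluate_statistic(
    name: str, matrix: CopyNumberMatrix, ref: EuploidReference | None = None
) -> float:
    """Evaluate one named statistic (``I``, ``ANCA``, ``normANCA``, ``D``,
    ``H``) on a matrix."""
    if name not in _ARRAY_EVALUATORS:
        raise KeyError(f"unknown statistic {name!r}; choose from {STATISTIC_NAMES}")
    e = (ref or EuploidReference()).vector(matrix.chromosomes)
    return _ARRAY_EVALUATORS[name](matrix.counts, matrix.missing_mask, e)


# ---------------------------------------------------------------------------
# Public matrix-level statistics
# ---------------------------------------------------------------------------


def instability_index(matrix: CopyNumberMatrix) -> float:
    """Instability index I = 100 * mean_t(1 - p̂_t / N_t), the mean across
    chromosomes of the fraction of cells not at the modal copy number,
    in percent.  0 when every cell carries the modal state everywhere;
    bounded above by 100*(1 - 1/N)."""
    return _instability_from_arrays(matrix.counts, matrix.missing_mask)


def anca(matrix: CopyNumberMatrix, ref: EuploidReference | None = None) -> float:
    """ANCA score A: mean over cells of the number of chromosomes whose
    observed copy number differs from the euploid reference."""
    e = (ref or EuploidReference()).vector(matrix.chromosomes)
    return _anca_from_arrays(matrix.counts, matrix.missing_mask, e)


def normalized_anca(matrix: CopyNumberMatrix, ref: EuploidReference | None = None) -> float:
    """AN = A / T, making panels with different probe counts comparable."""
    return anca(matrix, ref) / matrix.n_chromosomes


def aneuploidy_score(matrix: CopyNumberMatrix, ref: EuploidReference | None = None) -> float:
    """Aneuploidy score D: mean |c_{n,t} - e_t| over observed entries."""
    e = (ref or EuploidReference()).vector(matrix.chromosomes)
    return _aneuploidy_from_arrays(matrix.counts, matrix.missing_mask, e)


def heterogeneity_score(matrix: CopyNumberMatrix) -> float:
    """Heterogeneity score H.

    Per chromosome the state counts are sorted descending (m_0 >= m_1 >= ...)
    and weighted by their rank: sum_f f*m_f.  H is the mean over chromosomes
    of this quantity divided by the per-chromosome observed cell count.  H
    depends only on the multiset of state counts, never on the state labels;
    it is 0 iff each chromosome shows a single state and reaches its maximum
    (N-1)/2 when every cell carries a distinct state.
    """
    return _heterogeneity_from_arrays(matrix.counts, matrix.missing_mask)


def classify_cell(counts, ref_counts) -> str:
    """Classify one cell as ``diploid``, ``polyploid``, or ``aneuploid``.

    ``counts`` and ``ref_counts`` are aligned per-chromosome vectors of the
    observed copy numbers and the euploid reference (missing chromosomes
    already removed).  Diploid (euploid): every count equals its reference.
    Polyploid: counts are a uniform integer multiple >= 2 of the reference
    (whole-genome duplication).  Anything else — including uniform reductions
    below euploid — is aneuploid.
    """
    c = np.asarray(counts, dtype=np.int64)
    e = np.asarray(ref_counts, dtype=np.int64)
    if c.size == 0:
        raise ValueError("cell has no observed counts")
    if np.array_equal(c, e):
        return "diploid"
    ratios = c / e
    r = ratios[0]
    if r >= 2 and float(r).is_integer() and np.all(ratios == r):
        return "polyploid"
    return "aneuploid"


def ploidy_proportions(
    matrix: CopyNumberMatrix, ref: EuploidReference | None = None
) -> tuple:
    """Proportions (P_A, P_D, P_P) of aneuploid, diploid (euploid), and
    polyploid cells; the three components sum to exactly 1.  Cells with no
    observed entries are dropped with a warning."""
    e = (ref or EuploidReference()).vector(matrix.chromosomes)
    tallies = {"aneuploid": 0, "diploid": 0, "polyploid": 0}
    dropped = 0
    for n in range(matrix.n_cells):
        obs = ~matrix.missing_mask[n]
        if not obs.any():
            dropped += 1
            continue
        tallies[classify_cell(matrix.counts[n, obs], e[obs])] += 1
    if dropped:
        warnings.warn(f"{dropped} cells with no observed entries were dropped", stacklevel=2)
    total = sum(tallies.values())
    if total == 0:
        raise ValueError("no cells with observed entries")
    return (
        tallies["aneuploid"] / total,
        tallies["diploid"] / total,
        tallies["polyploid"] / total,
    )


def summarize_group(
    matrix: CopyNumberMatrix,
    ref: EuploidReference | None = None,
    group: str = "all",
) -> GroupStatistics:
    """Compute all six statistics for one stratum."""
    ref = ref or EuploidReference()
    return GroupStatistics(
        group=group,
        source=matrix.source,
        n_cells=matrix.n_cells,
        n_chromosomes=matrix.n_chromosomes,
        instability_index=instability_index(matrix),
        anca=anca(matrix, ref),
        normalized_anca=normalized_anca(matrix, ref),
        aneuploidy_score=aneuploidy_score(matrix, ref),
        heterogeneity_score=heterogeneity_score(matrix),
        ploidy_proportions=ploidy_proportions(matrix, ref),
    )


def summarize_chromosomes(
    matrix: CopyNumberMatrix,
    ref: EuploidReference | None = None,
    group: str = "all",
) -> list:
    """Per-chromosome A, AN, D, H for one stratum, each computed with T = 1.

    With T = 1 the ANCA and its normalized form coincide.  For a complete
    matrix the mean over chromosomes of per-chromosome D (or H) equals the
    aggregate score.
    """
    ref = ref or EuploidReference()
    out = []
    for t, chrom in enumerate(matrix.chromosomes):
        obs = ~matrix.missing_mask[:, t]
        if not obs.any():
            raise ValueError(f"all entries missing for chromosome {chrom!r}")
        col = matrix.counts[obs, t]
        e_t = ref.copy_for(chrom)
        a = float((col != e_t).mean())
        d = float(np.abs(col - e_t).mean())
        h = _heterogeneity_column(col)
        out.append(
            ChromosomeStatistics(
                group=group,
                source=matrix.source,
                chromosome=chrom,
                n_cells=int(obs.sum()),
                anca=a,
                normalized_anca=a,
                aneuploidy_score=d,
                heterogeneity_score=h,
            )
        )
    return out


def group_summary_table(strata, ref: EuploidReference | None = None) -> pd.DataFrame:
    """Group-level summary table over ``(group, matrix)`` strata."""
    return pd.DataFrame([summarize_group(m, ref, group=g).as_dict() for g, m in strata])


def chromosome_summary_table(strata, ref: EuploidReference | None = None) -> pd.DataFrame:
    """Chromosome-level summary table over ``(group, matrix)`` strata."""
    rows = []
    for g, m in strata:
        rows.extend(s.as_dict() for s in summarize_chromosomes(m, ref, group=g))
    return pd.DataFrame(rows)
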