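"""Label-shuffling hypothesis tests between experimental groups.

The null hypothesis is that each group has the same value of a chosen
population statistic (I, ANCA, normANCA, D, or H).  All cell labels across
all groups are shuffled jointly (group sizes preserved) B times; each
unordered group pair's permuted absolute difference is compared with its
observed one.  P-values use the add-one convention p = (1 + #{permuted >=
observed}) / (1 + B), so the smallest attainable p with B permutations is
1/(B+1) — at the default B = 500, 1/501 ≈ 0.002.  Benjamini-Hochberg
q-values correct across the pairwise tests of one run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datamodel import CopyNumberMatrix, EuploidReference, GroupAssignment
from .stats import _ARRAY_EVALUATORS, STATISTIC_NAMES

DEFAULT_PERMUTATIONS = 500
SIGNIFICANCE_THRESHOLD = 0.05


@dataclass
class PermutationResult:
    """Pairwise observed differences, permutation P-values, BH q-values."""

    statistic_name: str
    pairs: list  # (group_a, group_b)
    observed_diff: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    n_permutations: int
    seed: int
    group_values: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_a": [a for a, _ in self.pairs],
                "group_b": [b for _, b in self.pairs],
                "statistic": self.statistic_name,
                "observed_diff": self.observed_diff,
                "p": self.p_values,
                "q": self.q_values,
                "B": self.n_permutations,
                "seed": self.seed,
            }
        )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j >= i} (m/j) * p_(j), capped at 1; q >= p element-wise.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def permutation_test(
    matrix: CopyNumberMatrix,
    groups: GroupAssignment,
    statistic_name: str,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    ref: EuploidReference | None = None,
) -> PermutationResult:
    """Permutation test of group differences in one population statistic.

    Requires at least two groups with at least one cell each.  Identical
    seed and inputs give identical p-values.
    """
    if statistic_name not in STATISTIC_NAMES:
        raise KeyError(
            f"unknown statistic {statistic_name!r}; choose from {STATISTIC_NAMES}"
        )
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    labels = []
    keep = []
    for i, cid in enumerate(matrix.cell_ids):
        g = groups.label_of(cid)
        if g:
            labels.append(g)
            keep.append(i)
    if len(keep) < len(matrix.cell_ids):
        matrix = matrix.subset_cells(keep)
    labels = np.array(labels)
    group_names = list(dict.fromkeys(labels))
    if len(group_names) < 2:
        raise ValueError("permutation testing requires at least two groups")
    group_idx = {g: np.flatnonzero(labels == g) for g in group_names}
    for g, idx in group_idx.items():
        if idx.size == 0:
            raise ValueError(f"group {g!r} has no cells")

    e = (ref or EuploidReference()).vector(matrix.chromosomes)
    evaluate = _ARRAY_EVALUATORS[statistic_name]
    counts, mask = matrix.counts, matrix.missing_mask

    def group_stats(index_map) -> dict:
        return {
            g: evaluate(counts[idx], mask[idx], e) for g, idx in index_map.items()
        }

    observed = group_stats(group_idx)
    pairs = list(combinations(group_names, 2))
    observed_diff = np.array([abs(observed[a] - observed[b]) for a, b in pairs])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(pairs), dtype=np.int64)
    n_cells = len(labels)
    sizes = np.cumsum([group_idx[g].size for g in group_names])[:-1]
    for _ in range(n_permutations):
        perm = rng.permutation(n_cells)
        blocks = np.split(perm, sizes)
        perm_stats = {
            g: evaluate(counts[idx], mask[idx], e)
            for g, idx in zip(group_names, blocks)
        }
        perm_diff = np.array([abs(perm_stats[a] - perm_stats[b]) for a, b in pairs])
        exceed += perm_diff >= observed_diff
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return PermutationResult(
        statistic_name=statistic_name,
        pairs=pairs,
        observed_diff=observed_diff,
        p_values=p,
        q_values=bh_adjust(p),
        n_permutations=n_permutations,
        seed=seed,
        group_values=observed,
    )


def pairwise_heatmap_table(
    result: PermutationResult, use_q: bool = False
) -> pd.DataFrame:
    """Symmetric group x group table of p (or q) values, diagonal NaN."""
    names = list(dict.fromkeys([g for pair in result.pairs for g in pair]))
    table = pd.DataFrame(np.nan, index=names, columns=names)
    vals = result.q_values if use_q else result.p_values
    for (a, b), v in zip(result.pairs, vals):
        table.loc[a, b] = v
        table.loc[b, a] = v
    return table
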