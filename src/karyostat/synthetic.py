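"""Synthetic single-cell populations with controllable ploidy structure.

Every statistic, test, and plot in the package is exercisable without any
download: populations are drawn from a simple generative model in which each
cell starts euploid, is whole-genome doubled with a set probability, and
then each (cell, chromosome) independently gains or loses one copy with a
per-event missegregation probability (direction equiprobable).  Single-step
±1 missegregation keeps binomial expectations analytically checkable:
E[q_n] ≈ rate·T and E[ANCA] follows directly, so distributional tests can
assert agreement within sampling error.

No biological realism is attempted — no selection, lineage structure, or
CNV hotspots; see the package methods note for what that implies about
passing tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    CopyNumberMatrix,
    EuploidReference,
    GroupAssignment,
    concatenate,
)
from .io_scwgs import BinnedCopyNumberTable

DEFAULT_CHROMOSOMES = ("1", "2", "3", "4")


@dataclass
class PopulationSpec:
    """Generative parameters for one cell population.

    missegregation_rate is the per-(cell, chromosome) probability of a ±1
    copy change; polyploid_fraction the probability a cell is whole-genome
    doubled before missegregation.  Counts are clipped to [0, max_state].
    """

    n_cells: int = 100
    chromosomes: tuple = DEFAULT_CHROMOSOMES
    euploid: EuploidReference = field(default_factory=EuploidReference)
    missegregation_rate: float = 0.0
    polyploid_fraction: float = 0.0
    max_state: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("missegregation_rate", "polyploid_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def generate_population(
    spec: PopulationSpec, source: str = "FISH", cell_prefix: str = "cell"
) -> CopyNumberMatrix:
    """Draw one population; deterministic under the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    t = len(spec.chromosomes)
    e = spec.euploid.vector(spec.chromosomes)
    base = np.tile(e, (spec.n_cells, 1))
    doubled = rng.random(spec.n_cells) < spec.polyploid_fraction
    base[doubled] *= 2
    events = rng.random((spec.n_cells, t)) < spec.missegregation_rate
    direction = rng.choice([-1, 1], size=(spec.n_cells, t))
    counts = np.clip(base + events * direction, 0, spec.max_state)
    ids = [f"{cell_prefix}{i + 1}" for i in range(spec.n_cells)]
    return CopyNumberMatrix(ids, list(spec.chromosomes), counts, source)


def generate_group_study(specs: dict, source: str = "FISH") -> tuple:
    """Concatenate per-group populations into one labeled study.

    ``specs`` maps group label -> PopulationSpec; cell ids are prefixed with
    the group label so they are unique across groups.
    """
    if not specs:
        raise ValueError("need at least one group")
    matrices, mapping = [], {}
    for group, spec in specs.items():
        m = generate_population(spec, source=source, cell_prefix=f"{group}_cell")
        matrices.append(m)
        for cid in m.cell_ids:
            if cid in mapping:
                raise ValueError(f"duplicate cell id across groups: {cid!r}")
            mapping[cid] = group
    return concatenate(matrices), GroupAssignment(mapping)


def severity_gradient_study(
    rates=(0.0, 0.1, 0.3),
    n_cells: int = 100,
    chromosomes: tuple = DEFAULT_CHROMOSOMES,
    polyploid_fraction: float = 0.05,
    seed: int = 0,
) -> tuple:
    """Three-arm study (Control, TreatmentA, TreatmentB by default) with
    increasing missegregation rates — the canonical demonstration input."""
    names = ["Control", "TreatmentA", "TreatmentB"][: len(rates)]
    names += [f"Treatment{chr(ord('A') + i)}" for i in range(len(names) - 1, len(rates) - 1)]
    specs = {
        name: PopulationSpec(
            n_cells=n_cells,
            chromosomes=chromosomes,
            missegregation_rate=rate,
            polyploid_fraction=polyploid_fraction,
            seed=seed + i,
        )
        for i, (name, rate) in enumerate(zip(names, rates))
    }
    return generate_group_study(specs)


def matrix_to_binned_table(
    matrix: CopyNumberMatrix, bins_per_chromosome: int = 5, bin_size: int = 1_000_000
) -> BinnedCopyNumberTable:
    """Expand whole-chromosome counts into a synthetic bin-state table with
    per-chromosome uniform states, so the sc-WGS reader round-trips the
    drawn counts exactly."""
    bins, rows, mask_rows = [], [], []
    for t, chrom in enumerate(matrix.chromosomes):
        for b in range(bins_per_chromosome):
            bins.append((chrom, b * bin_size, (b + 1) * bin_size))
            rows.append(matrix.counts[:, t])
            mask_rows.append(matrix.missing_mask[:, t])
    return BinnedCopyNumberTable(
        bins, list(matrix.cell_ids), np.array(rows), np.array(mask_rows)
    )


def random_karyotypes(n: int, seed: int = 0) -> list:
    """Build (iscn_string, expected_counts) pairs from random numerical
    events, for exercising the ISCN parser against known truth."""
    rng = np.random.default_rng(seed)
    out = []
    autosomes = [str(i) for i in range(1, 23)]
    for _ in range(n):
        sex = rng.choice(["XX", "XY"])
        counts = {c: 2 for c in autosomes}
        counts["X"] = sex.count("X")
        counts["Y"] = sex.count("Y")
        n_events = int(rng.integers(0, 4))
        chroms = rng.choice(autosomes, size=n_events, replace=False)
        tokens = []
        for chrom in chroms:
            delta = int(rng.choice([-1, 1]))
            counts[chrom] += delta
            tokens.append(("+" if delta > 0 else "-") + chrom)
        total = sum(counts.values())
        iscn = ",".join([str(total), str(sex)] + sorted(tokens, key=lambda s: int(s[1:])))
        out.append((iscn, counts))
    return out
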