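"""Plot-ready data and rendered figures for ploidy-state visualization.

Four families: the aneuploidy-vs-heterogeneity scatter (one point per
group x source), the ternary plot of diploid/polyploid/aneuploid cell
proportions, the bivariate percentage heatmap (joint copy-number grid for a
chromosome pair), and the group-ordered copy-number heatmap.  Every figure
is backed by a pure data function so coordinates can be asserted and
serialized independently of rendering; a multi-page PDF export collects the
rendered figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.backends.backend_pdf import PdfPages

from .datamodel import CopyNumberMatrix, EuploidReference, GroupAssignment, stratify

PLOIDY_SUM_TOL = 1e-6
_SOURCE_MARKERS = {"FISH": "o", "scWGS": "^", "SKY": "s"}


@dataclass
class BivariatePercentageGrid:
    """Joint copy-number distribution of two chromosomes, in percent.

    ``percent[i, j]`` is the percentage of jointly-observed cells with count
    ``states_x[i]`` on chrom_x and ``states_y[j]`` on chrom_y; entries sum
    to 100.  Axes cover the observed states plus the euploid state (so the
    bold euploid gridline always exists), extended by one state each side
    for visual margin.
    """

    chrom_x: str
    chrom_y: str
    states_x: np.ndarray
    states_y: np.ndarray
    percent: np.ndarray
    n_cells: int
    euploid_marks: tuple


def bivariate_grid(
    matrix: CopyNumberMatrix,
    chrom_x: str,
    chrom_y: str,
    ref: EuploidReference | None = None,
) -> BivariatePercentageGrid:
    """Tally the joint copy-number states of two chromosomes.

    Cells missing either count are excluded (pairwise-complete); at least
    one jointly-observed cell is required.
    """
    ref = ref or EuploidReference()
    for c in (chrom_x, chrom_y):
        if c not in matrix.chromosomes:
            raise KeyError(f"chromosome {c!r} not in matrix")
    tx = matrix.chromosomes.index(chrom_x)
    ty = matrix.chromosomes.index(chrom_y)
    both = ~(matrix.missing_mask[:, tx] | matrix.missing_mask[:, ty])
    n_pair = int(both.sum())
    if n_pair == 0:
        raise ValueError(f"no cells jointly observed for {chrom_x!r} and {chrom_y!r}")
    cx = matrix.counts[both, tx]
    cy = matrix.counts[both, ty]
    e_x, e_y = ref.copy_for(chrom_x), ref.copy_for(chrom_y)

    def axis_states(vals, e):
        lo = min(int(vals.min()), e) - 1
        hi = max(int(vals.max()), e) + 1
        return np.arange(max(lo, 0), hi + 1)

    states_x = axis_states(cx, e_x)
    states_y = axis_states(cy, e_y)
    percent = np.zeros((states_x.size, states_y.size))
    x_pos = {s: i for i, s in enumerate(states_x)}
    y_pos = {s: j for j, s in enumerate(states_y)}
    for a, b in zip(cx, cy):
        percent[x_pos[int(a)], y_pos[int(b)]] += 1
    percent *= 100.0 / n_pair
    return BivariatePercentageGrid(
        chrom_x, chrom_y, states_x, states_y, percent, n_pair, (e_x, e_y)
    )


def all_pairwise_grids(
    matrix: CopyNumberMatrix, ref: EuploidReference | None = None
) -> list:
    """One grid per unordered chromosome pair, C(T, 2) in canonical order."""
    if matrix.n_chromosomes < 2:
        raise ValueError("need at least two chromosomes for pairwise grids")
    return [
        bivariate_grid(matrix, a, b, ref)
        for a, b in combinations(matrix.chromosomes, 2)
    ]


def scatter_dh(group_stats) -> pd.DataFrame:
    """One point per (group, source) stratum: x = aneuploidy score D,
    y = heterogeneity score H; color encodes group, marker shape source."""
    stats = list(group_stats)
    if not stats:
        raise ValueError("need at least one stratum")
    return pd.DataFrame(
        {
            "group": [s.group for s in stats],
            "source": [s.source for s in stats],
            "D": [s.aneuploidy_score for s in stats],
            "H": [s.heterogeneity_score for s in stats],
        }
    )


def ternary_coordinates(group_stats) -> pd.DataFrame:
    """Barycentric coordinates (P_D, P_P, P_A) per stratum.

    The coordinates ARE the ploidy proportions; a pure-diploid population
    sits at the diploid vertex, an even mixture at the centroid.
    """
    rows = []
    for s in group_stats:
        p_a, p_d, p_p = s.ploidy_proportions
        if abs(p_a + p_d + p_p - 1.0) > PLOIDY_SUM_TOL:
            raise ValueError(
                f"ploidy proportions of {s.group!r} sum to {p_a + p_d + p_p}, not 1"
            )
        rows.append(
            {"group": s.group, "source": s.source, "P_D": p_d, "P_P": p_p, "P_A": p_a}
        )
    return pd.DataFrame(rows)


def copy_number_heatmap_data(
    matrix: CopyNumberMatrix, groups: GroupAssignment
) -> pd.DataFrame:
    """Cells x chromosomes counts reordered into contiguous group blocks;
    missing entries are NaN (rendered as a distinct category)."""
    frames = []
    for g, sub in stratify(matrix, groups):
        frame = sub.to_frame()
        frame.insert(0, "group", g)
        frames.append(frame)
    return pd.concat(frames)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_scatter_dh(data: pd.DataFrame, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    groups = list(dict.fromkeys(data["group"]))
    cmap = plt.get_cmap("tab10")
    colors = {g: cmap(i % 10) for i, g in enumerate(groups)}
    for _, row in data.iterrows():
        ax.scatter(
            row["D"],
            row["H"],
            color=colors[row["group"]],
            marker=_SOURCE_MARKERS.get(row["source"], "o"),
            s=60,
            label=f"{row['group']} ({row['source']})",
        )
    ax.set_xlabel("Aneuploidy score (D)")
    ax.set_ylabel("Heterogeneity score (H)")
    ax.legend(fontsize=7)
    ax.set_title("Aneuploidy vs heterogeneity by group")
    return ax.figure


def _barycentric_to_xy(p_d, p_p, p_a):
    # vertices: diploid (0,0), polyploid (1,0), aneuploid (0.5, sqrt(3)/2)
    x = p_p + 0.5 * p_a
    y = (np.sqrt(3) / 2) * p_a
    return x, y


def render_ternary(data: pd.DataFrame, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    tri_x = [0, 1, 0.5, 0]
    tri_y = [0, 0, np.sqrt(3) / 2, 0]
    ax.plot(tri_x, tri_y, color="black", lw=1)
    groups = list(dict.fromkeys(data["group"]))
    cmap = plt.get_cmap("tab10")
    colors = {g: cmap(i % 10) for i, g in enumerate(groups)}
    for _, row in data.iterrows():
        x, y = _barycentric_to_xy(row["P_D"], row["P_P"], row["P_A"])
        ax.scatter(
            x,
            y,
            color=colors[row["group"]],
            marker=_SOURCE_MARKERS.get(row["source"], "o"),
            s=60,
            label=f"{row['group']} ({row['source']})",
        )
    ax.text(-0.03, -0.05, "Diploid", ha="right")
    ax.text(1.03, -0.05, "Polyploid", ha="left")
    ax.text(0.5, np.sqrt(3) / 2 + 0.04, "Aneuploid", ha="center")
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(fontsize=7, loc="upper left", bbox_to_anchor=(0.75, 1.0))
    ax.set_title("Ploidy composition")
    return ax.figure


def render_bivariate_grid(grid: BivariatePercentageGrid, ax=None, cmap="Reds"):
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    mesh = ax.pcolormesh(
        np.arange(grid.states_x.size + 1) - 0.5,
        np.arange(grid.states_y.size + 1) - 0.5,
        grid.percent.T,
        cmap=cmap,
        vmin=0,
    )
    ax.figure.colorbar(mesh, ax=ax, label="% of cells")
    ax.set_xticks(range(grid.states_x.size), [str(s) for s in grid.states_x])
    ax.set_yticks(range(grid.states_y.size), [str(s) for s in grid.states_y])
    e_x, e_y = grid.euploid_marks
    for val, states, axis in ((e_x, grid.states_x, "x"), (e_y, grid.states_y, "y")):
        pos = np.flatnonzero(states == val)
        if pos.size:
            line = ax.axvline if axis == "x" else ax.axhline
            line(pos[0], color="black", lw=2, alpha=0.6)
    ax.set_xlabel(f"Copies of chromosome {grid.chrom_x}")
    ax.set_ylabel(f"Copies of chromosome {grid.chrom_y}")
    ax.set_title(
        f"Joint states of {grid.chrom_x} and {grid.chrom_y} (N = {grid.n_cells})"
    )
    return ax.figure


def render_copy_number_heatmap(data: pd.DataFrame, ax=None, cmap="coolwarm"):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    values = data.drop(columns="group").to_numpy(dtype=float)
    masked = np.ma.masked_invalid(values)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("lightgrey")
    mesh = ax.pcolormesh(masked, cmap=cm)
    ax.figure.colorbar(mesh, ax=ax, label="copy number")
    ax.set_xticks(
        np.arange(values.shape[1]) + 0.5, list(data.columns[1:]), fontsize=7
    )
    boundaries = np.flatnonzero(data["group"].to_numpy()[:-1] != data["group"].to_numpy()[1:])
    for b in boundaries:
        ax.axhline(b + 1, color="black", lw=1)
    ax.set_ylabel("cells (grouped)")
    ax.set_title("Copy-number states by group")
    ax.invert_yaxis()
    return ax.figure


def export_pdf(figures, path) -> int:
    """Write figures to a multi-page PDF, one page each, in the given
    (deterministic) order; returns the page count."""
    figures = list(figures)
    if not figures:
        raise ValueError("no figures to export")
    with PdfPages(path) as pdf:
        for fig in figures:
            pdf.savefig(fig)
            plt.close(fig)
    return len(figures)


def standard_report_figures(
    matrix: CopyNumberMatrix,
    groups: GroupAssignment,
    ref: EuploidReference | None = None,
) -> list:
    """Render the full figure set in canonical page order: scatter, ternary,
    pairwise grids (per group), copy-number heatmap."""
    from .stats import summarize_group

    strata = stratify(matrix, groups)
    stats = [summarize_group(m, ref, group=g) for g, m in strata]
    figures = [
        render_scatter_dh(scatter_dh(stats)),
        render_ternary(ternary_coordinates(stats)),
    ]
    if matrix.n_chromosomes >= 2:
        for g, sub in strata:
            for grid in all_pairwise_grids(sub, ref):
                fig = render_bivariate_grid(grid)
                fig.axes[0].set_title(f"{g}: " + fig.axes[0].get_title(), fontsize=9)
                figures.append(fig)
    figures.append(render_copy_number_heatmap(copy_number_heatmap_data(matrix, groups)))
    return figures
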