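import numpy as np
import pytest

import karyostat as ks
from karyostat.stats import summarize_group
from karyostat.synthetic import PopulationSpec, generate_group_study, generate_population
from karyostat.viz import (
    all_pairwise_grids,
    bivariate_grid,
    copy_number_heatmap_data,
    export_pdf,
    scatter_dh,
    standard_report_figures,
    ternary_coordinates,
)

from conftest import make_matrix


def test_bivariate_grid_hand_tally():
    m = make_matrix([[2, 2], [2, 2], [2, 3], [3, 3]])
    grid = bivariate_grid(m, "1", "2")
    assert grid.n_cells == 4
    lookup = {
        (x, y): grid.percent[i, j]
        for i, x in enumerate(grid.states_x)
        for j, y in enumerate(grid.states_y)
    }
    assert lookup[(2, 2)] == pytest.approx(50.0)
    assert lookup[(2, 3)] == pytest.approx(25.0)
    assert lookup[(3, 3)] == pytest.approx(25.0)
    assert grid.percent.sum() == pytest.approx(100.0)


def test_degenerate_population_single_cell_entry():
    grid = bivariate_grid(make_matrix([[2, 2]] * 5), "1", "2")
    assert grid.percent.max() == pytest.approx(100.0)
    assert grid.euploid_marks == (2, 2)


def test_grid_axes_always_include_euploid_state():
    m = make_matrix([[6, 7], [7, 6]])
    grid = bivariate_grid(m, "1", "2")
    assert 2 in grid.states_x and 2 in grid.states_y


def test_grid_excludes_pairwise_incomplete_cells():
    mask = np.array([[False, True], [False, False], [False, False]])
    m = make_matrix([[2, 2], [2, 3], [3, 2]], mask=mask)
    grid = bivariate_grid(m, "1", "2")
    assert grid.n_cells == 2
    assert grid.percent.sum() == pytest.approx(100.0)


def test_grid_sums_to_100_for_random_populations():
    for seed in range(5):
        m = generate_population(
            PopulationSpec(n_cells=60, missegregation_rate=0.3, seed=seed)
        )
        grid = bivariate_grid(m, "1", "2")
        assert grid.percent.sum() == pytest.approx(100.0)


@pytest.mark.parametrize("t, expected", [(2, 1), (3, 3), (4, 6), (5, 10), (8, 28)])
def test_pairwise_grid_count_is_t_choose_2(t, expected):
    m = make_matrix(np.full((3, t), 2), chromosomes=[str(i + 1) for i in range(t)])
    assert len(all_pairwise_grids(m)) == expected


def test_pairwise_grids_require_two_chromosomes():
    with pytest.raises(ValueError):
        all_pairwise_grids(make_matrix([[2], [3]], ["1"]))


def test_scatter_points_equal_summary_scores():
    m = make_matrix([[2, 3], [4, 4], [2, 2]])
    s = summarize_group(m, group="G")
    data = scatter_dh([s])
    assert data.loc[0, "D"] == s.aneuploidy_score
    assert data.loc[0, "H"] == s.heterogeneity_score
    euploid = summarize_group(make_matrix([[2, 2]] * 3), group="E")
    point = scatter_dh([euploid])
    assert (point.loc[0, "D"], point.loc[0, "H"]) == (0.0, 0.0)


def test_ternary_coordinates_are_the_proportions():
    m = make_matrix([[2, 2], [4, 4], [2, 3]])
    s = summarize_group(m, group="G")
    coords = ternary_coordinates([s])
    p_a, p_d, p_p = s.ploidy_proportions
    assert coords.loc[0, ["P_D", "P_P", "P_A"]].tolist() == pytest.approx([p_d, p_p, p_a])
    vertex = summarize_group(make_matrix([[2, 2]] * 4), group="V")
    v = ternary_coordinates([vertex])
    assert v.loc[0, ["P_D", "P_P", "P_A"]].tolist() == [1.0, 0.0, 0.0]


def test_heatmap_rows_form_contiguous_group_blocks(four_group_assignment):
    m = make_matrix([[2, 2], [2, 3], [4, 4], [2, 2]])
    data = copy_number_heatmap_data(m, four_group_assignment)
    assert list(data["group"]) == ["A", "A", "B", "B"]
    values = data.drop(columns="group").to_numpy()
    assert np.array_equal(values, m.counts)


def test_heatmap_missing_entries_are_nan(four_group_assignment):
    mask = np.zeros((4, 2), dtype=bool)
    mask[1, 0] = True
    m = make_matrix([[2, 2], [2, 3], [4, 4], [2, 2]], mask=mask)
    data = copy_number_heatmap_data(m, four_group_assignment)
    assert np.isnan(data.drop(columns="group").to_numpy()).sum() == 1


def test_export_pdf_page_count(tmp_path):
    matrix, groups = generate_group_study(
        {
            "A": PopulationSpec(n_cells=10, missegregation_rate=0.2, seed=0),
            "B": PopulationSpec(n_cells=10, missegregation_rate=0.2, seed=1),
        }
    )
    figures = standard_report_figures(matrix, groups)
    # scatter + ternary + C(4,2) grids per group x 2 groups + heatmap
    assert len(figures) == 2 + 6 * 2 + 1
    path = tmp_path / "report.pdf"
    assert export_pdf(figures, path) == len(figures)
    assert path.stat().st_size > 0
    with pytest.raises(ValueError):
        export_pdf([], tmp_path / "empty.pdf")
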