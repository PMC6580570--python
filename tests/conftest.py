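import numpy as np
import pytest

from karyostat import CopyNumberMatrix, GroupAssignment


def make_matrix(rows, chromosomes=None, source="FISH", mask=None, cell_ids=None):
    rows = np.asarray(rows)
    n, t = rows.shape
    if chromosomes is None:
        chromosomes = [str(i + 1) for i in range(t)]
    if cell_ids is None:
        cell_ids = [f"cell{i + 1}" for i in range(n)]
    return CopyNumberMatrix(cell_ids, chromosomes, rows, source, mask)


@pytest.fixture
def two_cell_matrix():
    """Cells [[2,3],[2,2]] with euploid reference 2: the worked micro-example
    (A = 0.5, AN = 0.25, D = 0.25)."""
    return make_matrix([[2, 3], [2, 2]])


@pytest.fixture
def four_group_assignment():
    return GroupAssignment(
        {"cell1": "A", "cell2": "A", "cell3": "B", "cell4": "B"}
    )
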