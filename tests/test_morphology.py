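"""Shape and distribution indices: worked examples, closed forms, symmetry
invariances, and agreement with brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from popgrid import morphology as m
from popgrid.clustering import Cluster

from conftest import cluster_of, grid_from_counts, single_region_table

S_TETROMINO = [(0, 0), (0, 1), (1, 1), (1, 2)]
L_TETROMINO = [(0, 0), (0, 1), (0, 2), (1, 0)]
T_TETROMINO = [(0, 0), (1, 0), (2, 0), (1, 1)]


# -- independent brute-force oracles ----------------------------------------

def brute_dmax(cells):
    best = 0.0
    cells = list(cells)
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            (c1, r1), (c2, r2) = cells[i], cells[j]
            best = max(best, math.hypot(c1 - c2, r1 - r2))
    return best


def brute_perimeter(cells):
    cellset = set(cells)
    edges = 0
    for (c, r) in cellset:
        for nb in ((c + 1, r), (c - 1, r), (c, r + 1), (c, r - 1)):
            if nb not in cellset:
                edges += 1
    return edges


def brute_cl(cells, counts):
    """Expected inhabitant-pair distance / sqrt(S) by explicit enumeration."""
    cells = list(cells)
    n = sum(counts.values())
    total = 0.0
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            (c1, r1), (c2, r2) = cells[i], cells[j]
            total += counts[cells[i]] * counts[cells[j]] * math.hypot(c1 - c2, r1 - r2)
    return total / (n * (n - 1) / 2) / math.sqrt(len(cells))


def random_polyomino(rng, max_cells=25):
    cells = {(0, 0)}
    target = int(rng.integers(2, max_cells + 1))
    while len(cells) < target:
        c, r = list(cells)[rng.integers(len(cells))]
        nb = [(c + 1, r), (c - 1, r), (c, r + 1), (c, r - 1)]
        cells.add(nb[rng.integers(4)])
    return cells


# -- longest pairwise distance and roundness --------------------------------

def test_dmax_s_tetromino():
    assert m.longest_pairwise_distance(cluster_of(S_TETROMINO)) == pytest.approx(math.sqrt(5))


def test_dmax_adjacent_pair_and_line():
    assert m.longest_pairwise_distance(cluster_of([(0, 0), (1, 0)])) == 1.0
    k = 17
    assert m.longest_pairwise_distance(cluster_of([(c, 0) for c in range(k)])) == k - 1


def test_dmax_single_cell_degenerate():
    assert m.longest_pairwise_distance(cluster_of([(3, 4)])) == 0.0


def test_roundness_worked_example():
    """Four cells with longest distance sqrt(5) give Roundness 1.019."""
    assert round(m.roundness(cluster_of(S_TETROMINO)), 3) == 1.019


def test_roundness_line_closed_form():
    assert m.roundness(cluster_of([(c, 0) for c in range(10)])) == \
        pytest.approx(40 / (81 * math.pi))


def test_roundness_t_tetromino():
    assert m.roundness(cluster_of(T_TETROMINO)) == pytest.approx(4 / math.pi)


def test_hull_and_brute_force_paths_agree(rng):
    for _ in range(20):
        cells = random_polyomino(rng, 40)
        pts = np.asarray(sorted(cells), dtype=float)
        from scipy.spatial import ConvexHull
        from scipy.spatial.distance import pdist
        hull_d = float(pdist(pts[ConvexHull(pts).vertices]).max()) if len(pts) > 3 else None
        d = m.longest_pairwise_distance(cluster_of(cells))
        assert d == pytest.approx(brute_dmax(cells))
        if hull_d is not None:
            assert d == pytest.approx(hull_d)


# -- perimeter and irregularity ---------------------------------------------

@pytest.mark.parametrize("cells,expected", [
    ([(c, r) for c in range(2) for r in range(2)], 8),     # 2x2 square
    ([(c, 0) for c in range(10)], 22),                     # 1x10 line
    ([(c, r) for c in range(3) for r in range(3)
      if (c, r) != (1, 1)], 16),                           # ring: 12 outer + 4 hole
])
def test_perimeter_examples(cells, expected):
    assert m.perimeter(cluster_of(cells)) == expected


@pytest.mark.parametrize("cells,expected", [
    ([(c, 0) for c in range(10)], 2 * math.log(22) / math.log(10)),
    ([(c, r) for c in range(2) for r in range(2)], 3.0),
    ([(c, r) for c in range(10) for r in range(10)],
     2 * math.log(40) / math.log(100)),
])
def test_irregularity_examples(cells, expected):
    assert m.irregularity(cluster_of(cells)) == pytest.approx(expected, abs=5e-4)


def test_line_closed_forms_all_k():
    for k in range(2, 51):
        line = cluster_of([(c, 0) for c in range(k)])
        assert m.roundness(line) == pytest.approx(4 * k / (math.pi * (k - 1) ** 2))
        assert m.irregularity(line) == pytest.approx(
            2 * math.log(2 * k + 2) / math.log(k))


# -- characteristic length, heterogeneity, gender ---------------------------

def _grid_with(counts, gender=0.5):
    return grid_from_counts({cell: (int(round(n * gender)), n - int(round(n * gender)))
                             for cell, n in counts.items()})


def test_cl_l_tetromino_uniform():
    counts = {cell: 2 for cell in L_TETROMINO}
    grid = _grid_with(counts)
    cl = m.characteristic_length(cluster_of(L_TETROMINO), grid, 2005)
    assert cl == pytest.approx(34.6011 / 28 / 2, abs=2e-4)
    assert cl == pytest.approx(brute_cl(L_TETROMINO, counts))


def test_cl_all_in_one_cell_is_zero():
    grid = grid_from_counts({(0, 0): (3, 4), (1, 0): (0, 0)})
    cl = m.characteristic_length(cluster_of([(0, 0)]), grid, 2005)
    assert cl == 0.0


def test_cl_single_pair():
    grid = grid_from_counts({(0, 0): (1, 0), (1, 0): (1, 0)})
    cl = m.characteristic_length(cluster_of([(0, 0), (1, 0)]), grid, 2005)
    assert cl == pytest.approx(1 / math.sqrt(2))


def test_heterogeneity_worked_examples():
    """Counts (5,1,1,1) give CV = 1.00 (sample SD); (2,2,2,2) give 0.00."""
    cells = L_TETROMINO
    grid = _grid_with(dict(zip(cells, [5, 1, 1, 1])))
    assert m.heterogeneity(cluster_of(cells), grid, 2005) == pytest.approx(1.0)
    grid2 = _grid_with(dict(zip(cells, [2, 2, 2, 2])))
    assert m.heterogeneity(cluster_of(cells), grid2, 2005) == 0.0


def test_heterogeneity_scale_invariance():
    cells = L_TETROMINO
    grid = _grid_with(dict(zip(cells, [10, 2, 2, 2])))
    assert m.heterogeneity(cluster_of(cells), grid, 2005) == pytest.approx(1.0)


def test_heterogeneity_zero_iff_uniform(rng):
    cells = random_polyomino(rng, 12)
    counts = {cell: int(rng.integers(1, 9)) for cell in cells}
    grid = _grid_with(counts)
    het = m.heterogeneity(cluster_of(cells), grid, 2005)
    assert (het == 0.0) == (len(set(counts.values())) == 1)


def test_gender_fraction_examples():
    grid = grid_from_counts({(0, 0): (3, 1), (1, 0): (1, 3)})
    assert m.gender_fraction(cluster_of([(0, 0), (1, 0)]), grid, 2005) == 0.5
    grid_f = grid_from_counts({(0, 0): (4, 0)})
    assert m.gender_fraction(cluster_of([(0, 0)]), grid_f, 2005) == 1.0


# -- central cell and region join -------------------------------------------

def test_central_cell_line_and_plus():
    assert m.central_cell(cluster_of([(c, 0) for c in range(5)])) == (2.0, 0.0)
    plus = [(1, 0), (0, 1), (1, 1), (2, 1), (1, 2)]
    assert m.central_cell(cluster_of(plus)) == (1.0, 1.0)


def test_central_cell_four_way_tie():
    square = [(0, 0), (1, 0), (0, 1), (1, 1)]
    assert m.central_cell(cluster_of(square)) == (0.5, 0.5)


def test_central_cell_matches_bfs_oracle(rng):
    """Closeness argmax equals an explicit per-node BFS computation."""
    for _ in range(15):
        cells = random_polyomino(rng, 30)
        sums = {}
        for start in cells:
            dist = {start: 0}
            queue = [start]
            while queue:
                nxt = []
                for (c, r) in queue:
                    for nb in ((c + 1, r), (c - 1, r), (c, r + 1), (c, r - 1)):
                        if nb in cells and nb not in dist:
                            dist[nb] = dist[(c, r)] + 1
                            nxt.append(nb)
                queue = nxt
            sums[start] = sum(dist.values())
        best = min(sums.values())
        tied = [cell for cell, s in sums.items() if s == best]
        expect = (sum(c for c, _ in tied) / len(tied),
                  sum(r for _, r in tied) / len(tied))
        assert m.central_cell(cluster_of(cells)) == pytest.approx(expect)


def test_region_join_uses_central_cell():
    import popgrid.grid_io as gio
    table = gio.RegionAttributeTable(pd.DataFrame([
        ("A", 40.0, 0.6, 0, 1, 0, 10),
        ("B", 45.0, 0.7, 2, 10, 0, 10),
    ], columns=list(gio.REGION_COLUMNS)))
    line = cluster_of([(c, 0) for c in range(7)])  # central cell (3, 0) in B
    assert m.assign_region_attributes(line, table) == (45.0, 0.7)


# -- symmetry invariances ----------------------------------------------------

def _transforms():
    return [
        lambda c, r: (c + 7, r - 3),     # translation
        lambda c, r: (-r, c),            # 90 degree rotation
        lambda c, r: (-c, r),            # reflection
        lambda c, r: (r - 2, -c + 5),    # rotation + translation
    ]


@pytest.mark.parametrize("tf_index", range(4))
def test_shape_indices_invariant_under_isometry(rng, tf_index):
    tf = _transforms()[tf_index]
    for _ in range(10):
        cells = random_polyomino(rng, 20)
        counts = {cell: int(rng.integers(1, 20)) for cell in cells}
        moved = {tf(*cell): n for cell, n in counts.items()}
        g1, g2 = _grid_with(counts), _grid_with(moved)
        c1, c2 = cluster_of(cells), cluster_of(moved.keys())
        assert m.roundness(c1) == pytest.approx(m.roundness(c2))
        assert m.irregularity(c1) == pytest.approx(m.irregularity(c2))
        assert m.characteristic_length(c1, g1, 2005) == \
            pytest.approx(m.characteristic_length(c2, g2, 2005))
        assert m.heterogeneity(c1, g1, 2005) == \
            pytest.approx(m.heterogeneity(c2, g2, 2005))


def test_concentrating_mass_at_center_minimizes_cl():
    """CL is smallest when the most populated cell sits at the geographical
    centre and largest at the periphery: over all placements of a mass m
    with a uniform remainder, CL is minimized exactly at the cell with the
    smallest Euclidean distance sum (the numerator is (m-1) * sum_j d_pj
    plus a placement-independent constant), checked on all enumerated
    4-cell shapes against the brute-force oracle."""
    tetrominoes = {
        "I": [(c, 0) for c in range(4)],
        "O": [(0, 0), (1, 0), (0, 1), (1, 1)],
        "T": T_TETROMINO,
        "S": S_TETROMINO,
        "L": L_TETROMINO,
    }
    for cells in tetrominoes.values():
        sums = {a: sum(math.hypot(a[0] - b[0], a[1] - b[1]) for b in cells)
                for a in cells}
        central = min(cells, key=sums.get)
        peripheral = max(cells, key=sums.get)
        for mass in (2, 5, 8):
            cls = {}
            for target in cells:
                counts = {cell: (mass if cell == target else 1) for cell in cells}
                cls[target] = brute_cl(cells, counts)
                grid = _grid_with(counts)
                assert m.characteristic_length(cluster_of(cells), grid, 2005) == \
                    pytest.approx(cls[target])
            assert cls[central] == pytest.approx(min(cls.values()))
            assert cls[peripheral] == pytest.approx(max(cls.values()))


# -- feature table -----------------------------------------------------------

def test_density_worked_example(region_table):
    """Four cells and eight inhabitants give Density 2.00."""
    counts = dict(zip(L_TETROMINO, [5, 1, 1, 1]))
    grid = _grid_with(counts)
    feats = m.build_feature_table([cluster_of(L_TETROMINO)], grid, region_table)
    assert feats.loc[0, "density"] == pytest.approx(2.00)
    assert feats.loc[0, "S"] == 4


def test_feature_table_row_per_cluster_and_determinism(rng, region_table):
    cells_a = random_polyomino(rng, 15)
    cells_b = {(c + 40, r) for c, r in random_polyomino(rng, 15)}
    counts = {cell: int(rng.integers(1, 30)) for cell in cells_a | cells_b}
    grid = _grid_with(counts)
    clusters = [cluster_of(cells_a, 1), cluster_of(cells_b, 2)]
    f1 = m.build_feature_table(clusters, grid, region_table)
    f2 = m.build_feature_table(list(reversed(clusters)), grid, region_table)
    assert len(f1) == 2
    pd.testing.assert_frame_equal(f1, f2)
    assert list(f1.columns) == list(m.FEATURE_COLUMNS)


def test_feature_table_matches_elementwise_functions(rng, region_table):
    """The fast feature-table path agrees with the public per-index functions."""
    for _ in range(10):
        cells = random_polyomino(rng, 25)
        counts = {cell: int(rng.integers(1, 40)) for cell in cells}
        grid = _grid_with(counts)
        cl = cluster_of(cells)
        feats = m.build_feature_table([cl], grid, region_table).iloc[0]
        assert feats["L"] == m.perimeter(cl) == brute_perimeter(cells)
        assert feats["roundness"] == pytest.approx(m.roundness(cl))
        assert feats["irregularity"] == pytest.approx(m.irregularity(cl))
        assert feats["cl"] == pytest.approx(m.characteristic_length(cl, grid, 2005))
        assert feats["heterogeneity"] == pytest.approx(m.heterogeneity(cl, grid, 2005))
        assert feats["gender"] == pytest.approx(m.gender_fraction(cl, grid, 2005))


def test_single_cell_cluster_is_hard_error(region_table):
    grid = grid_from_counts({(0, 0): (2, 2)})
    with pytest.raises(ValueError, match="undefined"):
        m.build_feature_table([cluster_of([(0, 0)])], grid, region_table)
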