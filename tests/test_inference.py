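"""Exact topological inference: KS distance, lattice-walk path counting
against exhaustive enumeration, permutation oracle, subnetwork extraction."""

import math
from itertools import combinations

import numpy as np
import pytest

from tractopo import inference
from tractopo.inference import (
    count_paths_within_band,
    exact_pvalue,
    ks_distance,
    permutation_pvalue,
    subnetwork_betti_at,
)
from tractopo.topology import FiltrationGrid, ParticipantGraph, betti_curve


def brute_force_path_count(q, band):
    """Enumerate all C(2q, q) monotone paths and count in-band ones."""
    n = 0
    for pos in combinations(range(2 * q), q):
        x = y = 0
        pset = set(pos)
        ok = True
        for s in range(2 * q):
            if s in pset:
                x += 1
            else:
                y += 1
            if abs(x - y) >= band:
                ok = False
                break
        if ok:
            n += 1
    return n


class TestKSDistance:
    def test_identical_curves_have_zero_distance(self):
        a = np.array([1.0, 2.0, 5.0])
        assert ks_distance(a, a)[0] == 0.0

    def test_constant_offset_gives_that_constant(self):
        a = np.array([1.0, 2.0, 5.0])
        assert ks_distance(a, a + 3.5)[0] == pytest.approx(3.5)

    def test_matches_exhaustive_scan_and_breaks_ties_low(self):
        rng = np.random.default_rng(0)
        thr = np.linspace(0, 1, 50)
        a, b = rng.normal(size=50), rng.normal(size=50)
        D, lam = ks_distance(a, b, thr)
        diffs = np.abs(a - b)
        assert D == pytest.approx(diffs.max())
        assert lam == pytest.approx(thr[np.flatnonzero(
            diffs == diffs.max())[0]])
        # explicit tie
        D2, lam2 = ks_distance(np.array([0, 2.0, 2.0]),
                               np.array([0, 0.0, 0.0]),
                               np.array([0.1, 0.2, 0.3]))
        assert (D2, lam2) == (2.0, pytest.approx(0.2))

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            ks_distance(np.zeros(3), np.zeros(4))


class TestExactPvalue:
    def test_dp_equals_exhaustive_enumeration_small_q(self):
        for q in range(1, 7):
            for band in range(0, q + 2):
                assert count_paths_within_band(q, band) \
                    == brute_force_path_count(q, band)

    def test_q2_band1_has_no_admissible_paths(self):
        # every first step leaves the diagonal, so all 6 paths deviate
        assert count_paths_within_band(2, 1) == 0
        assert exact_pvalue(0.5, 2)[0] == 1.0

    def test_zero_distance_gives_p_one(self):
        assert exact_pvalue(0.0, 148)[0] == 1.0

    def test_band_beyond_grid_gives_p_zero(self):
        assert exact_pvalue(10.5, 10)[0] == 0.0

    def test_unconstrained_band_counts_all_paths(self):
        q = 10
        assert count_paths_within_band(q, q + 1) == math.comb(2 * q, q)

    def test_p_non_increasing_in_distance(self):
        q = 60
        ps = [exact_pvalue(d, q)[0] for d in np.linspace(0, q, 40)]
        assert (np.diff(ps) <= 1e-15).all()
        assert ps[0] == 1.0

    def test_large_q_exact_integer_arithmetic(self):
        # C(296, 148) overflows doubles; the DP must still be exact
        q = 148
        total = math.comb(2 * q, q)
        a = count_paths_within_band(q, q + 1)
        assert a == total
        p, band = exact_pvalue(20.03, q)
        assert band == 21
        assert 0.0 < p < 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_pvalue(-1.0, 5)
        with pytest.raises(ValueError):
            exact_pvalue(1.0, 0)


def _curve_matrix(rng, n_per_group, offset, G=60, scale=4.0):
    """Monotone-ish synthetic Betti-0 curves for two groups."""
    base = np.cumsum(rng.random(G))
    base = base / base[-1] * 20
    mat, labels = [], []
    for g, shift in (("A", 0.0), ("B", offset)):
        for _ in range(n_per_group):
            mat.append(base + shift + rng.normal(0, scale, G).cumsum() / G)
            labels.append(g)
    return np.asarray(mat), np.array([l == "A" for l in labels])


class TestPermutation:
    def test_identical_groups_give_large_p(self):
        rng = np.random.default_rng(1)
        mat, mask = _curve_matrix(rng, 15, offset=0.0)
        p, _ = permutation_pvalue(mat, mask, n_perm=500, seed=2)
        assert p > 0.05

    def test_huge_offset_reaches_minimum_p(self):
        rng = np.random.default_rng(3)
        mat, mask = _curve_matrix(rng, 15, offset=50.0)
        p, _ = permutation_pvalue(mat, mask, n_perm=999, seed=4)
        assert p == pytest.approx(1 / 1000)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        mat, mask = _curve_matrix(rng, 10, offset=1.0)
        p1, _ = permutation_pvalue(mat, mask, n_perm=300, seed=7)
        p2, _ = permutation_pvalue(mat, mask, n_perm=300, seed=7)
        assert p1 == p2

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.zeros((3, 5)), np.array([True, False, False]))


def test_exact_p_is_conservative_against_permutation_oracle():
    """The lattice-walk null treats the two mean curves as exchangeable unit
    walks; relative to the participant-label permutation null this is
    systematically conservative, and the two agree when the effect is so
    large that both tests saturate."""
    rng = np.random.default_rng(8)
    for offset in (0.0, 2.0, 4.0, 8.0, 16.0):
        mat, mask = _curve_matrix(rng, 20, offset=offset)
        D = float(np.max(np.abs(mat[mask].mean(0) - mat[~mask].mean(0))))
        p_exact, _ = exact_pvalue(D, 20)
        p_perm, _ = permutation_pvalue(mat, mask, n_perm=1000, seed=9)
        se = math.sqrt(p_perm * (1 - p_perm) / 1000)
        assert p_exact >= p_perm - 3 * se
        if offset >= 16.0:
            assert p_exact <= p_perm + 3 * se  # both saturate near zero


class TestSubnetwork:
    def _graphs(self):
        ei = np.array([0, 1, 2, 0])
        ej = np.array([1, 2, 3, 2])
        w = np.array([0.9, 0.8, 0.2, 0.7])
        return {"p1": ParticipantGraph("p1", list("abcd"), ei, ej, w)}

    def test_threshold_above_all_weights_gives_isolated_nodes(self):
        out = subnetwork_betti_at(1.5, self._graphs())
        row = out.iloc[0]
        assert (row["betti0"], row["betti1"], row["betti_ratio"]) == (4, 0, 0)

    def test_threshold_below_all_weights_gives_euler_count(self):
        out = subnetwork_betti_at(0.0, self._graphs())
        row = out.iloc[0]
        assert row["betti0"] == 1
        assert row["betti1"] == 4 - 4 + 1
        assert row["betti_ratio"] == pytest.approx(1.0)

    def test_agrees_with_direct_curve_evaluation(self):
        g = next(iter(self._graphs().values()))
        grid = FiltrationGrid(np.array([0.0, 0.5, 0.85, 1.0]))
        c = betti_curve(g, grid)
        for k, lam in enumerate(grid.thresholds):
            out = subnetwork_betti_at(lam, {"p1": g}).iloc[0]
            assert out["betti0"] == c.betti0[k]
            assert out["betti1"] == c.betti1[k]


def test_compare_groups_end_to_end(small_cohort, small_qc, small_wscores):
    from tractopo import wscore as ws
    from tractopo.topology import build_grid, betti_curves, graphs_from_wtable
    _, _, wt = small_wscores
    norm = ws.minmax_normalize(wt)
    graphs = graphs_from_wtable(norm)
    grid = build_grid(graphs, n_linear=40, augment_mst=True)
    curves = betti_curves(graphs, grid)
    labels = dict(zip(small_cohort.meta["participant_id"],
                      small_cohort.meta["group"]))
    res = inference.compare_groups(curves, labels, "CN", "non-amnestic",
                                   curve_type="betti0", n_perm=200, seed=1)
    assert res.q == next(iter(curves.values())).n_nodes
    assert 0.0 <= res.p_exact <= 1.0
    assert res.band == math.ceil(res.ks_distance)
    assert np.any(np.isclose(grid.thresholds, res.argmax_threshold))
    res1 = inference.compare_groups(curves, labels, "CN", "amnestic",
                                    curve_type="betti1")
    e_max = max(int(c.edge_count.max()) for c in curves.values())
    assert res1.q == max(1, e_max - next(iter(curves.values())).n_nodes + 1)
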