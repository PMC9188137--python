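"""Geometric map, tile scoring, thresholding, two-step and multi-genome paths."""

import numpy as np
import pytest

from geoseed import (
    GHParams,
    MaskedSequence,
    PatternSet,
    Seed,
    TWO_STEP_PRESET,
    Tile,
    assign_chunk,
    compute_lambda,
    compute_smax,
    geometric_map,
    group_into_tiles,
    load_bundled_patterns,
    multi_genome_map,
    parse_pattern,
    run_geometric_hashing,
    score_tile,
    select_tiles_by_count,
    tile_key,
    two_step_filter,
)
from geoseed.synthetic import random_dna


def S(i, j, s1="a", s2="b"):
    return Seed(coords=((s1, i), (s2, j)))


class TestGeometricMap:
    def test_positive_difference(self):
        assert geometric_map(S(25_000, 12_000), 10_000) == ("a", "b", 1)

    def test_negative_difference_floors_toward_minus_infinity(self):
        assert geometric_map(S(0, 15_000), 10_000) == ("a", "b", -2)

    @pytest.mark.parametrize("F", [1, 7, 10_000])
    def test_zero_difference(self, F):
        assert geometric_map(S(123, 123), F) == ("a", "b", 0)

    def test_same_tile_bound(self):
        """Any two members of one tile differ by less than F in i - j."""
        rng = np.random.default_rng(0)
        seeds = [S(int(i), int(j)) for i, j in rng.integers(0, 50_000, size=(500, 2))]
        F = 10_000
        by_tile = {}
        for s in seeds:
            by_tile.setdefault(geometric_map(s, F), []).append(s)
        for members in by_tile.values():
            diffs = [s.i - s.j for s in members]
            assert max(diffs) - min(diffs) < F

    def test_multi_genome_offsets(self):
        s = Seed(coords=(("a", 50_000), ("b", 37_000), ("c", 61_000)))
        assert multi_genome_map(s, 10_000) == ("a", "b", "c", 1, -2)

    def test_multi_genome_reduces_to_pairwise(self):
        s = S(25_000, 12_000)
        assert multi_genome_map(s, 10_000) == geometric_map(s, 10_000)

    def test_translation_invariance(self):
        s = Seed(coords=(("a", 50_000), ("b", 37_000), ("c", 61_000)))
        t = Seed(coords=(("a", 50_777), ("b", 37_777), ("c", 61_777)))
        assert multi_genome_map(s, 10_000) == multi_genome_map(t, 10_000)


class TestAssignChunk:
    def test_hand_example(self):
        params = GHParams(F=10_000, b=50, h=400)
        assert assign_chunk(S(25_000, 12_000), params) == (15, 92)

    def test_subtile_range_endpoints(self):
        params = GHParams(F=10_000, b=50, h=400)
        assert assign_chunk(S(10_000, 10_000), params)[0] == 0  # d = 0
        assert assign_chunk(S(19_999, 10_000), params)[0] == 49  # d = F - 1

    def test_origin_chunk(self):
        assert assign_chunk(S(0, 0), GHParams())[1] == 0

    def test_subtile_in_range_for_negative_diagonals(self):
        params = GHParams(F=10_000, b=50, h=400)
        rng = np.random.default_rng(1)
        for i, j in rng.integers(0, 40_000, size=(200, 2)):
            r, s = assign_chunk(S(int(i), int(j)), params)
            assert 0 <= r < params.b and s >= 0


class TestComputeSmax:
    def brute(self, key, lengths, params):
        (_, _, off) = key
        n1, n2 = lengths["a"], lengths["b"]
        best = -1
        for i in range(n1):
            for j in range(n2):
                if (i - j) // params.F == off:
                    best = max(best, (i + j) // params.h)
        return best

    @pytest.mark.parametrize("off", [-2, -1, 0, 1])
    @pytest.mark.parametrize("n1, n2", [(60, 45), (30, 70)])
    def test_equals_brute_force_band_scan(self, off, n1, n2):
        params = GHParams(F=25, b=5, h=10)
        lengths = {"a": n1, "b": n2}
        key = ("a", "b", off)
        expected = self.brute(key, lengths, params)
        if expected < 0:
            with pytest.raises(ValueError):
                compute_smax(key, lengths, params)
        else:
            assert compute_smax(key, lengths, params) == expected

    def test_worked_example(self):
        params = GHParams(F=10_000, b=50, h=400)
        lengths = {"a": 100_000, "b": 100_000}
        # max i+j subject to 0 <= i-j < 10^4: i = 99,999, j = 99,999
        assert compute_smax(("a", "b", 0), lengths, params) == (99_999 + 99_999) // 400

    def test_huge_chunk_gives_zero(self):
        params = GHParams(F=10_000, b=50, h=300_000)
        assert compute_smax(("a", "b", 0), {"a": 1000, "b": 1000}, params) == 0

    def test_halving_under_doubled_h(self):
        lengths = {"a": 5000, "b": 5000}
        a = compute_smax(("a", "b", 0), lengths, GHParams(F=1000, h=100))
        b = compute_smax(("a", "b", 0), lengths, GHParams(F=1000, h=200))
        assert b in (a // 2, (a - 1) // 2)

    def test_band_outside_rectangle_errors(self):
        with pytest.raises(ValueError):
            compute_smax(("a", "b", 50), {"a": 100, "b": 100}, GHParams(F=10))

    def test_three_genome_brute_force(self):
        params = GHParams(F=20, b=4, h=15)
        lengths = {"a": 40, "b": 35, "c": 30}
        for o2 in (-1, 0, 1):
            for o3 in (-1, 0):
                best = -1
                for i1 in range(40):
                    for i2 in range(35):
                        if (i1 - i2) // 20 != o2:
                            continue
                        for i3 in range(30):
                            if (i1 - i3) // 20 == o3:
                                best = max(best, (i1 + i2 + i3) // 15)
                key = ("a", "b", "c", o2, o3)
                if best < 0:
                    with pytest.raises(ValueError):
                        compute_smax(key, lengths, params)
                else:
                    assert compute_smax(key, lengths, params) == best


class TestScoring:
    def test_chunk_area_and_lambda(self):
        params = GHParams(F=10_000, b=50, h=400, n1=1e6, n2=1e6)
        # A = h F / b = 80,000
        assert compute_lambda(params, L=1) == pytest.approx(80_000 / 1e12)
        assert compute_lambda(params, L=10) == pytest.approx(10 * 80_000 / 1e12)

    def test_lambda_requires_positive_totals(self):
        with pytest.raises(ValueError):
            compute_lambda(GHParams(), L=5)

    def test_single_chunk_closed_form(self):
        params = GHParams(b=50, p_norm=6)
        for c in (1, 7, 100):
            tile = Tile(key=("a", "b", 0), chunk_counts={(3, 5): c}, smax=99)
            assert score_tile(tile, params, lam=0.01) == pytest.approx(c / 50.0)

    def test_empty_tile_scores_zero(self):
        tile = Tile(key=("a", "b", 0), smax=10)
        assert score_tile(tile, GHParams(), lam=0.5) == 0.0

    def test_even_split_scores_lower_by_pnorm_factor(self):
        params = GHParams(b=50, p_norm=6)
        c, q = 60, 12
        single = Tile(key=("a", "b", 0), chunk_counts={(0, 0): c}, smax=199)
        even = Tile(
            key=("a", "b", 0),
            chunk_counts={(0, s): c // q for s in range(q)},
            smax=199,
        )
        s1 = score_tile(single, params, lam=0.02)
        s2 = score_tile(even, params, lam=0.02)
        assert s2 == pytest.approx(s1 * q ** (1 / 6.0) / q)

    def test_score_monotone_in_chunk_counts(self):
        params = GHParams()
        base = {(0, 0): 3, (1, 4): 2}
        t0 = Tile(key=("a", "b", 0), chunk_counts=dict(base), smax=50)
        s0 = score_tile(t0, params, lam=0.1)
        for rc in [(0, 0), (2, 2)]:
            grown = dict(base)
            grown[rc] = grown.get(rc, 0) + 1
            t1 = Tile(key=("a", "b", 0), chunk_counts=grown, smax=50)
            assert score_tile(t1, params, lam=0.1) >= s0

    def test_invalid_lambda_rejected(self):
        tile = Tile(key=("a", "b", 0), chunk_counts={(0, 0): 1}, smax=1)
        with pytest.raises(ValueError):
            score_tile(tile, GHParams(), lam=0.0)


class TestRunGeometricHashing:
    def _lengths(self):
        return {"a": 60_000, "b": 60_000}

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(5)
        cands = [S(int(i), int(j)) for i, j in rng.integers(0, 50_000, size=(200, 2))]
        params = GHParams(tau_score=0.0)
        passed, report = run_geometric_hashing(cands, self._lengths(), params)
        assert {c.coords for c in passed} == {c.coords for c in cands}
        assert report["passed"].all()
        assert all(c.stage == "ghash-pass" for c in passed)

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(6)
        cands = [S(int(i), int(j)) for i, j in rng.integers(0, 50_000, size=(300, 2))]
        passed, _ = run_geometric_hashing(
            cands, self._lengths(), GHParams(tau_score=1.0)
        )
        assert {c.coords for c in passed} <= {c.coords for c in cands}

    def test_concentrated_tile_beats_isolated_seed(self):
        """100 clustered candidates pass; a lone candidate in its own tile fails."""
        cluster = [S(30_000 + 7 * t, 10_000 + 7 * t) for t in range(100)]
        lone = [S(5_000, 45_000)]
        cands = cluster + lone
        params = GHParams(tau_score=None)
        probe = GHParams(tau_score=float("inf"))
        _, report = run_geometric_hashing(cands, self._lengths(), probe)
        scores = dict(zip(report["tile"], report["score"]))
        s_cluster = scores["a|b|2"]
        s_lone = scores["a|b|-4"]
        assert s_lone < s_cluster
        params.tau_score = (s_lone + s_cluster) / 2
        passed, _ = run_geometric_hashing(cands, self._lengths(), params)
        assert {c.coords for c in passed} == {c.coords for c in cluster}

    def test_different_sequence_pairs_never_share_tiles(self):
        cands = [S(100, 100, "a", "b"), S(100, 100, "c", "d")]
        tiles = group_into_tiles(cands, GHParams())
        assert len(tiles) == 2

    def test_tile_partition_equals_per_candidate_recomputation(self):
        rng = np.random.default_rng(8)
        cands = [S(int(i), int(j)) for i, j in rng.integers(0, 50_000, size=(2000, 2))]
        params = GHParams()
        tiles = group_into_tiles(cands, params)
        # every candidate in exactly one tile, and in the tile g maps it to
        assert sum(t.count for t in tiles.values()) == len(cands)
        for key, tile in tiles.items():
            for s in tile.members:
                assert tile_key(s, params.F) == key
            assert sum(tile.chunk_counts.values()) == tile.count

    def test_multi_genome_two_path_equals_pairwise(self):
        rng = np.random.default_rng(11)
        cands = [S(int(i), int(j)) for i, j in rng.integers(0, 50_000, size=(400, 2))]
        params = GHParams(tau_score=1.0)
        p1, r1 = run_geometric_hashing(cands, self._lengths(), params)
        # identical seeds expressed through the s-genome code path
        n_totals = (60_000.0, 60_000.0)
        p2, r2 = run_geometric_hashing(cands, self._lengths(), params, n_totals)
        assert [c.coords for c in p1] == [c.coords for c in p2]
        assert np.allclose(r1["score"], r2["score"])

    def test_missing_threshold_rejected(self):
        with pytest.raises(ValueError, match="tau_score"):
            run_geometric_hashing([S(1, 1)], {"a": 10, "b": 10}, GHParams())


class TestTwoStep:
    def _inputs(self, rng):
        # a planted identical block (gene proxy) inside random backgrounds
        core = random_dna(rng, 3_000)
        res1 = random_dna(rng, 20_000) + core + random_dna(rng, 17_000)
        res2 = random_dna(rng, 5_000) + core + random_dna(rng, 32_000)
        s1 = [MaskedSequence("a", "g1", res1)]
        s2 = [MaskedSequence("b", "g2", res2)]
        return s1, s2

    def test_preset_matches_published_configuration(self):
        assert TWO_STEP_PRESET == {"k_prime": 19, "k": 8, "tau_prime": 3, "tau_score": 3.0}
        high = load_bundled_patterns("weight19")
        low = load_bundled_patterns("weight8")
        assert list(high)[0].weight == TWO_STEP_PRESET["k_prime"]
        assert low.weight == TWO_STEP_PRESET["k"] and low.m == 4

    def test_weight_ordering_enforced(self, rng):
        s1, s2 = self._inputs(rng)
        low = load_bundled_patterns("weight8")
        with pytest.raises(ValueError, match="k'"):
            two_step_filter(s1, s2, list(low)[0], 1, low, GHParams(tau_score=0.0))

    def test_vacuous_prefilter_equals_plain_run(self, rng):
        """With tau'=1 every candidate-bearing tile (plus neighbours) is
        selected, so pass 2 keeps the same passing seed set as a plain run."""
        from geoseed import find_spaced_seeds, run_geometric_hashing

        s1, s2 = self._inputs(rng)
        high = list(load_bundled_patterns("weight19"))[0]
        low = load_bundled_patterns("weight8")
        params = GHParams(tau_score=0.0)
        passed_ts, _ = two_step_filter(s1, s2, high, 1, low, params, rng_seed=3)
        cands = find_spaced_seeds(s1, s2, low, rng_seed=3)
        lengths = {"a": len(s1[0].residues), "b": len(s2[0].residues)}
        passed_plain, _ = run_geometric_hashing(
            cands, lengths, params,
            (float(lengths["a"]), float(lengths["b"])),
        )
        # tau'=1 selects every tile with >= 1 high-weight candidate; with a
        # 3 kb identical block every such tile exists, so sets agree on the
        # planted region; all two-step output is a subset of the plain run
        assert {c.coords for c in passed_ts} <= {c.coords for c in passed_plain}
        planted = {c.coords for c in passed_plain if abs((c.i - c.j) - 15_000) < 100}
        assert planted <= {c.coords for c in passed_ts}

    def test_planted_gene_restricted_to_neighbouring_tiles(self, rng):
        s1, s2 = self._inputs(rng)
        high = list(load_bundled_patterns("weight19"))[0]
        low = load_bundled_patterns("weight8")
        params = GHParams(tau_score=0.0)
        passed, _ = two_step_filter(s1, s2, high, 3, low, params, rng_seed=2)
        assert passed  # the identical block yields plenty of candidates
        # high-weight candidates of the planted block sit at offset 15,000/F=1
        offsets = {(c.i - c.j) // params.F for c in passed}
        assert offsets <= {0, 1, 2}

    def test_select_tiles_includes_neighbours(self):
        cands = [S(25_000, 12_000)] * 3
        sel = select_tiles_by_count(cands, 10_000, tau_prime=3)
        assert sel == {("a", "b", 0), ("a", "b", 1), ("a", "b", 2)}
        assert select_tiles_by_count(cands, 10_000, 4) == set()
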