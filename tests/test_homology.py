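"""Match grids, permutation nulls, BH adjustment, microhomology length,
base composition."""

import numpy as np
import pytest
from scipy.stats import kstest

from svfootprint.breakends import FlankPair
from svfootprint.homology import (
    aggregate_grids,
    base_composition,
    bh_adjust,
    build_homology_grid,
    junction_match_grid,
    junction_spanning_bins,
    microhomology_length,
    permutation_null,
)
from svfootprint.simulate import (
    SimulationConfig,
    random_translocations,
    simulate,
    simulate_genome,
)


def _pair(left, right, w=4):
    return FlankPair(left_flank=left, right_flank=right, w=w)


class TestMatchGrid:
    def test_half_matching_flanks(self):
        g = junction_match_grid(_pair("AAAACCCC", "CCCCAAAA"))
        # brute-force double loop oracle
        L, R = "AAAACCCC", "CCCCAAAA"
        expected = [[1 if L[i] == R[j] else 0 for j in range(8)] for i in range(8)]
        assert g.tolist() == expected
        assert g.sum() == 32 and g.mean() == 0.5

    def test_all_match_and_disjoint(self):
        assert junction_match_grid(_pair("A" * 8, "A" * 8)).sum() == 64
        assert junction_match_grid(_pair("A" * 8, "G" * 8)).sum() == 0

    def test_n_never_matches(self):
        g = junction_match_grid(_pair("N" * 8, "N" * 8))
        assert g.sum() == 0

    def test_random_grids_match_double_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            L = "".join("ACGTN"[i] for i in rng.integers(0, 5, size=8))
            R = "".join("ACGTN"[i] for i in rng.integers(0, 5, size=8))
            g = junction_match_grid(_pair(L, R))
            for i in range(8):
                for j in range(8):
                    want = int(L[i] == R[j] and L[i] != "N")
                    assert g[i, j] == want


class TestAggregate:
    def test_mean_of_extremes(self):
        ones, zeros = np.ones((8, 8)), np.zeros((8, 8))
        assert (aggregate_grids([ones, zeros]) == 0.5).all()

    def test_single_grid_identity(self):
        g = np.eye(8)
        assert (aggregate_grids([g]) == g).all()

    def test_random_average(self):
        rng = np.random.default_rng(0)
        grids = [rng.integers(0, 2, size=(8, 8)) for _ in range(100)]
        assert np.allclose(
            aggregate_grids(grids), np.mean(np.stack(grids), axis=0)
        )

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            aggregate_grids([])


def bh_oracle(p):
    """Hand-applied step-up: q_(i) = min over j>=i of p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_example(self):
        q = bh_adjust(np.array([0.001, 0.02, 0.03, 0.05]))
        assert np.allclose(q, [0.004, 0.04, 0.04, 0.05])

    def test_all_ones(self):
        assert (bh_adjust(np.ones(64)) == 1).all()

    def test_against_stepup_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            p = rng.uniform(1e-6, 1, size=64)
            assert np.allclose(bh_adjust(p), bh_oracle(p))

    def test_q_at_least_p_and_shape_kept(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0.001, 1, size=(8, 8))
        q = bh_adjust(p)
        assert q.shape == (8, 8) and (q >= p - 1e-12).all() and (q <= 1).all()


def mh_oracle(left, right, w):
    """Brute-force run scan over both junction-shift directions."""
    best = 0
    for direction in (1, 2):
        k = 0
        for i in range(w):
            if direction == 1:
                a, b = left[w - 1 - i], right[w - 1 - i]
            else:
                a, b = left[w + i], right[w + i]
            if a != b or a == "N":
                break
            k += 1
        best = max(best, k)
    return best


class TestMicrohomologyLength:
    def test_single_base_run(self):
        # A:0 == B:-1 but A:+1 != B:-2  ->  length 1
        left = "ACGT" + "TTTT"  # labels +3+2+1 0 | -1-2-3-4
        right = "AAAT" + "GGGG"  # labels -4-3-2-1 | 0+1+2+3
        assert left[3] == right[3] and left[2] != right[2]
        assert microhomology_length(_pair(left, right)) == 1

    def test_no_match_either_direction(self):
        assert microhomology_length(_pair("AAAAAAAA", "GGGGGGGG")) == 0

    def test_oracle_agreement_random(self):
        rng = np.random.default_rng(21)
        for _ in range(500):
            L = "".join("ACGTN"[i] for i in rng.integers(0, 5, size=8))
            R = "".join("ACGTN"[i] for i in rng.integers(0, 5, size=8))
            assert microhomology_length(_pair(L, R)) == mh_oracle(L, R, 4)

    @pytest.mark.parametrize("m", [0, 1, 2, 3, 4])
    def test_planted_length_recovered(self, m):
        from svfootprint.breakends import extract_flanks
        from svfootprint.filtering import run_filter_cascade

        cfg = SimulationConfig(
            seed=100 + m,
            contig_lengths={"chrI": 200_000},
            n_translocations=200,
            n_deletions=0,
            n_inherited_background_svs=0,
            nonpass_rate=0.0,
            mh_length_dist={m: 1.0},
            templated_insert_rate=0.0,
            misc_insert_rate=0.0,
        )
        ds = simulate(cfg)
        tl, _, _ = run_filter_cascade(ds.samples["F1"][0], [], [], ds.repeats)
        assert len(tl) == 200
        lengths = {
            microhomology_length(extract_flanks(t, ds.genome, 4)) for t in tl
        }
        assert lengths == {m}


class TestPermutationNull:
    def test_p_value_formula_extremes(self):
        # planted certain signal: observed diagonal frequency 1.0 can be
        # reached by a random placement only by chance, so p == (r+1)/(n+1)
        cfg = SimulationConfig(
            seed=6, contig_lengths={"chrI": 100_000}, n_translocations=40,
            n_deletions=0, n_inherited_background_svs=0, nonpass_rate=0.0,
            mh_length_dist={3: 1.0}, templated_insert_rate=0.0,
            misc_insert_rate=0.0,
        )
        ds = simulate(cfg)
        from svfootprint.filtering import run_filter_cascade

        tl, _, _ = run_filter_cascade(ds.samples["F1"][0], [], [], ds.repeats)
        grid = build_homology_grid(tl, ds.genome, 4)
        grid = permutation_null(grid, tl, ds.genome, n_perm=999, seed=0)
        for i, j in junction_spanning_bins(4, 3):
            assert grid.matrix[i, j] == 1.0
            assert grid.p_values[i, j] == pytest.approx(1 / 1000)
        assert (grid.p_values > 0).all() and (grid.p_values <= 1).all()
        assert (grid.q_values >= grid.p_values - 1e-12).all()

    def test_determinism_and_seed_sensitivity(self):
        genome = simulate_genome(
            SimulationConfig(seed=1, contig_lengths={"chrI": 50_000})
        )
        tls = random_translocations(genome, 30, rng=4)
        grid = build_homology_grid(tls, genome, 4)
        g1 = permutation_null(grid, tls, genome, n_perm=500, seed=9)
        g2 = permutation_null(grid, tls, genome, n_perm=500, seed=9)
        g3 = permutation_null(grid, tls, genome, n_perm=500, seed=10)
        assert (g1.p_values == g2.p_values).all()
        assert not (g1.p_values == g3.p_values).all()

    def test_null_calibration_uniform_p(self):
        genome = simulate_genome(
            SimulationConfig(seed=0, contig_lengths={"chrI": 100_000})
        )
        tls = random_translocations(genome, 64, rng=1)
        grid = build_homology_grid(tls, genome, 4)
        grid = permutation_null(grid, tls, genome, n_perm=1999, seed=2)
        frac = (grid.p_values < 0.05).mean()
        assert abs(frac - 0.05) <= 0.03
        assert kstest(grid.p_values.ravel(), "uniform").pvalue > 0.01


class TestBaseComposition:
    def test_uniform_background_near_25(self):
        cfg = SimulationConfig(seed=3, contig_lengths={"chrI": 100_000})
        genome = simulate_genome(cfg)
        tls = random_translocations(genome, 50, rng=3)
        bc = base_composition(tls, genome, w=4, n_perm=2000, seed=0)
        for base in "ACGT":
            assert np.allclose(bc.background[base], 25.0, atol=1.0)

    def test_percentages_sum_to_100(self):
        cfg = SimulationConfig(seed=3, contig_lengths={"chrI": 50_000})
        genome = simulate_genome(cfg)
        tls = random_translocations(genome, 20, rng=5)
        bc = base_composition(tls, genome, w=4, n_perm=200, seed=0)
        total = sum(bc.observed[b] for b in "ACGT")
        assert np.allclose(total, 100.0)

    def test_empty_sites_error(self):
        cfg = SimulationConfig(seed=3, contig_lengths={"chrI": 50_000})
        genome = simulate_genome(cfg)
        with pytest.raises(ValueError):
            base_composition([], genome)
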