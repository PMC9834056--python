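"""Deletion junction homology, categorization schemes and binomial tests."""

from math import comb

import numpy as np
import pytest

from svfootprint.deletions import (
    SCHEMES,
    build_deletion_junctions,
    categorize,
    chance_category_probs,
    deletion_homology_length,
    deletion_to_translocation,
    filter_same_class_repeats,
    footprint_test,
    size_filter,
    stratify_by_origin,
    trio_denovo_filter,
)
from svfootprint.homology import build_homology_grid, microhomology_length
from svfootprint.breakends import extract_flanks
from svfootprint.io import Genome, IndelRecord, RepeatTrack
from svfootprint.simulate import SimulationConfig, simulate


def _del(contig, start, end, rid="", passed=True):
    return IndelRecord("deletion", contig, start, end, filter_pass=passed,
                       record_id=rid)


class TestSizeFilter:
    def test_inclusive_bounds(self):
        recs = [_del("c", 1, n) for n in (7, 8, 200, 201)]
        kept = size_filter(recs)
        assert sorted(r.length for r in kept) == [8, 200]

    def test_empty_and_idempotent(self):
        assert size_filter([]) == []
        recs = [_del("c", 1, 50)]
        assert size_filter(size_filter(recs)) == size_filter(recs)


class TestHomologyLength:
    def _genome_with(self, prefix, deleted, suffix):
        return Genome({"c": prefix + deleted + suffix}), len(prefix)

    def test_two_base_prefix_match(self):
        # deleted TTAA followed by TTGG...: longest common prefix 2
        g, s0 = self._genome_with("CAGCG", "TTAA", "TTGGCAGCA")
        d = _del("c", s0 + 1, s0 + 4)
        assert d.fetch_deleted_seq(g) == "TTAA"
        assert deletion_homology_length(d, g) == 2

    def test_no_match(self):
        g, s0 = self._genome_with("CAGTG", "CCCC", "AAAATTTT")
        assert deletion_homology_length(_del("c", s0 + 1, s0 + 4), g) == 0

    def test_left_alignment_normalizes(self):
        # in CCGAGAGTTT, deleting "AG" at 1-based 6..7 is the same allele
        # as the left-aligned deletion at 3..4; homology must agree
        g = Genome({"c": "CCGAGAGTTT"})
        d_right = _del("c", 6, 7)
        d_left = _del("c", 3, 4)
        h1 = deletion_homology_length(d_right, g)
        h2 = deletion_homology_length(d_left, g)
        assert h1 == h2 == 2

    def test_planted_homology_recovered(self):
        cfg = SimulationConfig(
            seed=31,
            contig_lengths={"chrI": 400_000},
            n_translocations=0,
            n_deletions=400,
            n_inherited_background_svs=0,
            nonpass_rate=0.0,
            deletion_homology_dist={h: 1 / 8 for h in range(8)},
        )
        ds = simulate(cfg)
        truth = ds.truth.set_index(["contig_a", "pos_b"])
        for d in ds.samples["F1"][1]:
            h = deletion_homology_length(d, ds.genome)
            assert h == int(truth.loc[(d.contig, d.end0)].del_homology)


class TestCategorize:
    @pytest.mark.parametrize(
        "h, scheme, expected",
        [
            (0, "celegans_1bp", "non"),
            (1, "celegans_1bp", "micro"),
            (2, "celegans_1bp", "macro"),
            (0, "human_2to6bp", "non"),
            (1, "human_2to6bp", "non"),
            (2, "human_2to6bp", "micro"),
            (4, "human_2to6bp", "micro"),
            (6, "human_2to6bp", "micro"),
            (7, "human_2to6bp", "macro"),
        ],
    )
    def test_schemes(self, h, scheme, expected):
        assert categorize(h, scheme) == expected

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            categorize(1, "mouse")


def _junctions(homologies):
    from svfootprint.deletions import DeletionJunction

    return [
        DeletionJunction(_del("c", 1, 10), "A" * 10, h) for h in homologies
    ]


class TestFootprintTest:
    def test_zero_micro_p_is_one(self):
        res = footprint_test(_junctions([0] * 10), "celegans_1bp")
        assert res.binom_p == pytest.approx(1.0)

    def test_all_micro_closed_form(self):
        res = footprint_test(_junctions([1] * 10), "celegans_1bp")
        assert res.binom_p == pytest.approx(SCHEMES["celegans_1bp"]["micro"] ** 10)

    def test_half_micro_tail_sum(self):
        p0 = SCHEMES["celegans_1bp"]["micro"]
        expected = sum(
            comb(10, i) * p0**i * (1 - p0) ** (10 - i) for i in range(5, 11)
        )
        res = footprint_test(_junctions([1] * 5 + [0] * 5), "celegans_1bp")
        assert res.binom_p == pytest.approx(expected)

    def test_counts_and_n_zero(self):
        res = footprint_test([], "human_2to6bp")
        assert res.n == 0 and res.binom_p is None
        assert sum(res.counts.values()) == 0


class TestTrioAndOrigin:
    def test_overlap_removed(self):
        kept = trio_denovo_filter(
            [_del("c", 100, 150)], [_del("c", 140, 400)], []
        )
        assert kept == []

    def test_disjoint_trio_identity(self):
        child = [_del("c", 100, 150)]
        kept = trio_denovo_filter(child, [_del("c", 500, 600)],
                                  [_del("c", 700, 800)])
        assert kept == child

    def test_labeled_inherited_exactly_removed(self, small_dataset):
        ds = small_dataset
        child = [d for d in ds.samples["F1"][1] if d.filter_pass]
        father = ds.samples["P0_a"][1]
        mother = ds.samples["P0_b"][1]
        kept = trio_denovo_filter(child, father, mother)
        truth = ds.truth[ds.truth.kind == "deletion"]
        want = truth[(truth.status == "denovo") & truth.filter_pass]
        assert {(d.contig, d.start0) for d in kept} == {
            (r.contig_a, r.del_start0) for r in want.itertuples()
        }

    def test_stratify(self):
        dels = [_del("c", 1, 10, "a"), _del("c", 20, 30, "b"),
                _del("c", 40, 50, "x")]
        f, m = stratify_by_origin(
            dels, {"a": "father", "b": "mother", "x": "unknown"}
        )
        assert [d.record_id for d in f] == ["a"]
        assert [d.record_id for d in m] == ["b"]

    def test_all_unknown(self):
        f, m = stratify_by_origin([_del("c", 1, 10, "a")], {})
        assert f == [] and m == []

    def test_planted_paternal_enrichment(self):
        """Father-origin micro enrichment yields the smaller binomial p."""
        base = dict(
            contig_lengths={"chrI": 400_000},
            n_translocations=0,
            n_inherited_background_svs=0,
            nonpass_rate=0.0,
            n_deletions=500,
        )
        enriched = SimulationConfig(
            seed=51,
            deletion_homology_dist={0: 0.50, 1: 0.4166, 2: 0.0834},
            **base,
        )
        null = SimulationConfig(seed=52, **base)
        p_vals = {}
        for name, cfg in (("father", enriched), ("mother", null)):
            ds = simulate(cfg)
            j = build_deletion_junctions(ds.samples["F1"][1], ds.genome)
            p_vals[name] = footprint_test(j, "celegans_1bp").binom_p
        assert p_vals["father"] < p_vals["mother"]


class TestRepeatRule:
    def test_same_class_both_sites_removed(self):
        track = RepeatTrack([("c", 90, 110, "LTR"), ("c", 190, 210, "LTR")])
        d = _del("c", 101, 200)  # breaks at pos0 99 and 200
        assert filter_same_class_repeats([d], track) == []

    def test_different_class_kept(self):
        track = RepeatTrack([("c", 90, 110, "LTR"), ("c", 190, 210, "DNA")])
        d = _del("c", 101, 200)
        assert filter_same_class_repeats([d], track) == [d]


class TestDeletionGrid:
    def test_grid_code_path_shared_with_translocations(self):
        """16x16 deletion grid reuses flank machinery: run length from the
        grid view equals the deletion homology length."""
        cfg = SimulationConfig(
            seed=61,
            contig_lengths={"chrI": 300_000},
            n_translocations=0,
            n_deletions=200,
            n_inherited_background_svs=0,
            nonpass_rate=0.0,
            deletion_homology_dist={h: 1 / 8 for h in range(8)},
        )
        ds = simulate(cfg)
        dels_ = ds.samples["F1"][1]
        for d in dels_[:50]:
            t = deletion_to_translocation(d)
            pair = extract_flanks(t, ds.genome, 8)
            assert microhomology_length(pair) == deletion_homology_length(
                d, ds.genome
            )
        grid = build_homology_grid(
            [deletion_to_translocation(d) for d in dels_], ds.genome, 8
        )
        assert grid.matrix.shape == (16, 16)
        assert grid.n == len(dels_)


class TestChanceModel:
    def test_non_homology_chance_is_75_percent(self):
        probs = chance_category_probs()
        assert probs["non"] * 100 == pytest.approx(75.0)

    def test_geometric_masses_normalize(self):
        for scheme in SCHEMES:
            full = chance_category_probs(scheme=scheme)
            assert 0.99 < sum(full.values()) <= 1.0 + 1e-9
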