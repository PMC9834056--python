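"""Generator determinism, configured rates, and closed-loop exactness."""

import numpy as np
import pytest

from svfootprint.io import read_fasta, read_sv_vcf
from svfootprint.simulate import SimulationConfig, simulate, simulate_genome


class TestGenome:
    def test_uniform_base_frequencies(self):
        cfg = SimulationConfig(seed=1, contig_lengths={"chrI": 100_000})
        g = simulate_genome(cfg)
        seq = g["chrI"]
        for b in "ACGT":
            assert abs(seq.count(b) / len(seq) - 0.25) < 0.01

    def test_gc_skew_honored(self):
        cfg = SimulationConfig(
            seed=1,
            contig_lengths={"chrI": 100_000},
            base_freqs=(0.325, 0.175, 0.175, 0.325),
        )
        seq = simulate_genome(cfg)["chrI"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.35) < 0.01

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=5, contig_lengths={"chrI": 20_000})
        assert simulate_genome(cfg).contigs == simulate_genome(cfg).contigs


class TestDeterminism:
    def test_outputs_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(
            seed=9,
            contig_lengths={"chrI": 80_000},
            n_translocations=20,
            n_deletions=20,
            n_inherited_background_svs=4,
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = simulate(cfg).write(d1)
        p2 = simulate(cfg).write(d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key


class TestConfigValidation:
    def test_unnormalized_distribution_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, type_mix={1: 0.5, 2: 0.2})

    def test_infeasible_microhomology_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SimulationConfig(seed=1, mh_length_dist={9: 1.0})

    def test_rates_bounded(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, templated_insert_rate=0.8,
                             misc_insert_rate=0.5)


class TestConfiguredRates:
    def test_type_mix_fractions(self):
        cfg = SimulationConfig(
            seed=13,
            contig_lengths={"chrI": 400_000, "chrII": 300_000},
            n_translocations=400,
            n_deletions=0,
            n_inherited_background_svs=0,
            type_mix={1: 0.5, 2: 0.25, 4: 0.25},
        )
        ds = simulate(cfg)
        frac = ds.truth.ttype.value_counts(normalize=True)
        assert abs(frac[1] - 0.5) <= 0.07
        assert abs(frac[2] - 0.25) <= 0.07
        assert abs(frac[4] - 0.25) <= 0.07

    def test_null_configuration(self):
        """Degenerate config: no microhomology, no inserts anywhere."""
        from svfootprint.filtering import run_filter_cascade
        from svfootprint.insertions import classify_insertion
        from svfootprint.breakends import extract_flanks
        from svfootprint.homology import microhomology_length

        cfg = SimulationConfig(
            seed=17,
            contig_lengths={"chrI": 150_000},
            n_translocations=60,
            n_deletions=0,
            n_inherited_background_svs=0,
            nonpass_rate=0.0,
            mh_length_dist={0: 1.0},
            templated_insert_rate=0.0,
            misc_insert_rate=0.0,
        )
        ds = simulate(cfg)
        tl, _, _ = run_filter_cascade(ds.samples["F1"][0], [], [], ds.repeats)
        assert len(tl) == 60
        for t in tl:
            assert classify_insertion(t, ds.genome).category == "no_insertion"
            assert microhomology_length(extract_flanks(t, ds.genome, 4)) == 0

    def test_all_templated(self):
        from svfootprint.filtering import run_filter_cascade
        from svfootprint.insertions import classify_insertion

        cfg = SimulationConfig(
            seed=19,
            contig_lengths={"chrI": 200_000},
            n_translocations=80,
            n_deletions=0,
            n_inherited_background_svs=0,
            nonpass_rate=0.0,
            templated_insert_rate=1.0,
            misc_insert_rate=0.0,
        )
        ds = simulate(cfg)
        tl, _, _ = run_filter_cascade(ds.samples["F1"][0], [], [], ds.repeats)
        assert len(tl) == 80
        for t in tl:
            assert classify_insertion(t, ds.genome).category == "templated"

    def test_deletion_sizes_within_range_pass_size_filter(self):
        from svfootprint.deletions import size_filter

        cfg = SimulationConfig(
            seed=23, contig_lengths={"chrI": 200_000}, n_translocations=0,
            n_deletions=150, n_inherited_background_svs=0,
        )
        ds = simulate(cfg)
        dels = ds.samples["F1"][1]
        assert len(size_filter(dels)) == len(dels)

    def test_deletion_category_fractions_near_null(self):
        from svfootprint.deletions import (
            build_deletion_junctions, footprint_test,
        )

        cfg = SimulationConfig(
            seed=29, contig_lengths={"chrI": 300_000}, n_translocations=0,
            n_deletions=500, n_inherited_background_svs=0, nonpass_rate=0.0,
        )
        ds = simulate(cfg)
        j = build_deletion_junctions(ds.samples["F1"][1], ds.genome)
        res = footprint_test(j, "celegans_1bp")
        for cat, p in res.null_probs.items():
            se = np.sqrt(p * (1 - p) / 500)
            assert abs(res.counts[cat] / 500 - p) <= 3 * se


class TestRepeatTrack:
    def test_zero_density_empty(self):
        cfg = SimulationConfig(
            seed=2, contig_lengths={"chrI": 50_000}, repeat_density=0.0,
            n_translocations=5, n_deletions=5, n_inherited_background_svs=0,
        )
        assert simulate(cfg).repeats.intervals == []

    def test_planted_events_never_swallowed(self, small_dataset):
        """Repeats avoid event neighborhoods so the closed loop stays exact."""
        ds = small_dataset
        truth = ds.truth[ds.truth.kind == "translocation"]
        for r in truth.itertuples():
            assert not ds.repeats.classes_at(r.contig_a, r.pos_a)
            assert not ds.repeats.classes_at(r.contig_b, r.pos_b)


class TestRoundTripThroughFiles:
    def test_vcf_and_fasta_round_trip(self, tmp_path, small_dataset):
        paths = small_dataset.write(tmp_path)
        g = read_fasta(paths["genome"])
        assert g.contigs == small_dataset.genome.contigs
        bnds, indels = read_sv_vcf(paths["F1"])
        orig_b, orig_i = small_dataset.samples["F1"]
        key = lambda r: r.record_id
        for a, b in zip(sorted(orig_b, key=key), sorted(bnds, key=key)):
            assert (a.contig, a.pos, a.alt, a.mate_id, a.filter_pass) == (
                b.contig, b.pos, b.alt, b.mate_id, b.filter_pass)
        for a, b in zip(sorted(orig_i, key=key), sorted(indels, key=key)):
            assert (a.contig, a.start, a.end, a.deleted_seq) == (
                b.contig, b.start, b.end, b.deleted_seq)
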