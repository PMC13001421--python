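"""Synthetic-data generator: genome, lineage, emission, truth invariants."""

import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import small_config
from somaclock.channels import SBS96_INDEX
from somaclock.spectra import Spectrum, cosine
from somaclock.synthetic import (
    SimConfig,
    SimConfigError,
    emit_calls,
    simulate_genome,
    simulate_lineage,
    synthetic_id_catalog,
    synthetic_sbs_catalog,
)


class TestConfigValidation:
    def test_bad_gc_names_field(self):
        with pytest.raises(SimConfigError, match="gc_fraction"):
            SimConfig(gc_fraction=1.5)

    def test_mix_must_sum_to_one(self):
        with pytest.raises(SimConfigError, match="aging_signature_mix"):
            SimConfig(aging_signature_mix={"SBS1": 0.5, "SBS5": 0.4})

    def test_nonincreasing_schedule_rejected(self):
        with pytest.raises(SimConfigError, match="strictly increasing"):
            SimConfig(division_schedule=((0.5, 2), (0.2, 2)))

    def test_sensitivity_range(self):
        with pytest.raises(SimConfigError, match="detect_sensitivity"):
            SimConfig(detect_sensitivity={"30X": 0.0})


class TestSyntheticCatalogs:
    def test_columns_are_distributions(self):
        for cat in (synthetic_sbs_catalog(), synthetic_id_catalog()):
            sums = cat.matrix.sum(axis=0)
            assert np.allclose(sums, 1.0)
            assert (cat.matrix.to_numpy() >= 0).all()

    def test_clock_signature_is_cpg_concentrated(self):
        cat = synthetic_sbs_catalog()
        cpg = [i for i, ch in enumerate(cat.matrix.index)
               if "[C>T]" in ch and ch.endswith("G")]
        assert cat.column("SBS1")[cpg].sum() > 0.8


class TestSimulateGenome:
    def test_length_and_gc(self):
        cfg = SimConfig(seed=1, genome_length=100_000, gc_fraction=0.5)
        syn = simulate_genome(cfg)
        assert syn.genome.length == 100_000
        gc = sum(s.count("G") + s.count("C") for s in syn.genome.sequences.values())
        assert 0.49 <= gc / 100_000 <= 0.51

    def test_seeded_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=9, genome_length=100_000)
        a, b = tmp_path / "a.fa", tmp_path / "b.fa"
        simulate_genome(cfg).genome.to_fasta(a)
        simulate_genome(cfg).genome.to_fasta(b)
        assert a.read_bytes() == b.read_bytes()

    def test_minimum_length_enforced(self):
        with pytest.raises(SimConfigError, match="genome_length"):
            simulate_genome(SimConfig(genome_length=50_000))

    def test_trinucleotide_frequencies_match_iid_model(self):
        """Observed trinucleotide counts agree with the closed-form i.i.d.
        expectation within 3 SD (multinomial oracle)."""
        cfg = SimConfig(seed=3, genome_length=1_000_000, gc_fraction=0.41,
                        n_chromosomes=1)
        g = simulate_genome(cfg).genome
        seq = g.sequences["chr1"]
        p = {"A": 0.295, "C": 0.205, "G": 0.205, "T": 0.295}
        counts = {}
        for i in range(len(seq) - 2):
            tri = seq[i : i + 3]
            counts[tri] = counts.get(tri, 0) + 1
        n = len(seq) - 2
        for tri, obs in counts.items():
            # neighbouring windows overlap, inflating the variance ~3x;
            # use a conservative 3-SD band on 3x multinomial variance
            exp = n * p[tri[0]] * p[tri[1]] * p[tri[2]]
            sd = np.sqrt(3 * exp * (1 - exp / n))
            assert abs(obs - exp) <= 3 * sd, tri

    def test_partition_tracks_tile_genome(self):
        cfg = SimConfig(seed=4, genome_length=200_000)
        syn = simulate_genome(cfg)
        for name in ("genic", "genic_detail"):
            covered = (
                syn.tracks[name].intervals["end"]
                - syn.tracks[name].intervals["start"]
            ).sum()
            assert covered == syn.genome.length


class TestSimulateLineage:
    def test_degenerate_rates_give_private_only(self, genome):
        cfg = small_config(clonal_mu=0.0, clonal_indel_mu=0.0, aging_rate=0.0,
                           aging_intercept=5.0, aging_indel_rate=0.0,
                           aging_indel_intercept=0.0)
        truth = simulate_lineage(cfg, 0, genome)
        assert (truth.variants["origin"] == "private").all()
        counts = list(truth.true_private_counts.values())
        # Poisson(5) draws: mean in a sane band
        assert 2 < np.mean(counts) < 9

    def test_region_mixing_zero_keeps_clades_pure(self, genome):
        cfg = small_config(region_mixing=0.0)
        truth = simulate_lineage(cfg, 0, genome)
        for clade in truth.tree.root.children:
            regions = {truth.region_labels[c] for c in clade.cells}
            assert len(regions) == 1

    def test_terminal_time_beyond_age_rejected(self, genome):
        cfg = small_config(subject_ages=(1.0,), division_schedule=((0.1, 2),),
                           terminal_times=0.5, aging_intercept=0.0)
        bad = small_config(subject_ages=(1.0,), division_schedule=((0.1, 2),),
                           terminal_times=2.0, aging_intercept=0.0)
        simulate_lineage(cfg, 0, genome)  # fine
        with pytest.raises(SimConfigError, match="terminal time"):
            simulate_lineage(bad, 0, genome)

    def test_slope_recovery_against_ols_oracle(self, genome):
        """Regressing true private counts on age recovers the configured
        accumulation rate within the OLS 95% CI."""
        ages = (20.0, 40.0, 60.0, 80.0)
        cfg = small_config(
            n_subjects=4, subject_ages=ages, cells_per_subject=20,
            division_schedule=((0.05, 4), (0.1, 5)), terminal_times=0.2,
            clonal_mu=0.0, clonal_indel_mu=0.0,
            aging_rate=27.0, aging_intercept=100.0, aging_indel_rate=0.0,
            aging_indel_intercept=0.0,
        )
        xs, ys = [], []
        for s in range(4):
            truth = simulate_lineage(cfg, s, genome)
            for cell, n in truth.true_private_counts.items():
                xs.append(ages[s])
                ys.append(n)
        res = stats.linregress(xs, ys)
        half = 1.96 * res.stderr
        assert res.slope - half <= 27.0 <= res.slope + half

    def test_subject_substreams_are_order_independent(self, genome):
        cfg = small_config(n_subjects=2, subject_ages=(50.0, 70.0))
        t1 = simulate_lineage(cfg, 1, genome)
        _ = simulate_lineage(cfg, 0, genome)
        t1_again = simulate_lineage(cfg, 1, genome)
        assert t1.variants.equals(t1_again.variants)

    def test_variant_uniqueness_across_branches_and_cells(self, genome):
        truth = simulate_lineage(small_config(), 0, genome)
        keys = truth.variants[["chrom", "pos", "ref", "alt"]]
        assert not keys.duplicated().any()


class TestEmitCalls:
    def test_full_sensitivity_round_trip(self, genome):
        """At sensitivity 1 (and callable fraction 1) emitted per-cell calls
        equal the truth variant sets exactly."""
        cfg = small_config()
        truth = simulate_lineage(cfg, 0, genome)
        emitted = emit_calls(truth, cfg, genome=genome)
        got = emitted.cell_variant_keys()
        carriers = truth.carriers()
        for cell in truth.cells:
            want = {k for k, cs in carriers.items() if cell in cs}
            assert set(got[cell]) == want

    def test_binomial_thinning(self, genome):
        cfg = small_config(detect_sensitivity={"30X": 0.5},
                           aging_intercept=600.0, aging_rate=0.0)
        truth = simulate_lineage(cfg, 0, genome)
        emitted = emit_calls(truth, cfg)
        # per-(cell,variant) Bernoulli(0.5): total inside binomial 99% bounds
        n_pairs = sum(
            len(n.cells) * len(n.variants) for n in truth.tree.nodes()
        )
        kept = len(emitted.calls)
        lo, hi = stats.binom.interval(0.99, n_pairs, 0.5)
        assert lo <= kept <= hi

    def test_shared_variant_in_both_cells_and_bulk(self, genome):
        cfg = small_config()
        truth = simulate_lineage(cfg, 0, genome)
        emitted = emit_calls(truth, cfg)
        got = emitted.cell_variant_keys()
        shared = truth.variants[truth.variants["origin"] == "shared"]
        assert len(shared) > 0
        bulk_keys = set(map(tuple, emitted.bulk.itertuples(index=False)))
        carriers = truth.carriers()
        for row in itertools.islice(shared.itertuples(), 50):
            key = (row.chrom, int(row.pos), row.ref, row.alt)
            for cell in carriers[key]:
                assert key in set(got[cell])
            assert key in bulk_keys

    def test_depth_classes_thin_differently(self, genome):
        cfg = small_config(
            depth_class_fractions={"30X": 0.5, "10X": 0.5},
            detect_sensitivity={"30X": 1.0, "10X": 0.4},
            callable_fraction={"30X": 1.0, "10X": 1.0},
            aging_intercept=400.0, aging_rate=0.0,
        )
        truth = simulate_lineage(cfg, 0, genome)
        emitted = emit_calls(truth, cfg)
        per_cell = emitted.calls.groupby("cell_id").size()
        meta = emitted.metadata.set_index("cell_id")
        deep = per_cell[meta["depth_class"] == "30X"].mean()
        shallow = per_cell[meta["depth_class"] == "10X"].mean()
        assert shallow < 0.6 * deep


class TestSpectrumConvergence:
    def test_private_spectrum_converges_to_aging_mix(self, genome):
        """With >=20k private mutations the emitted SBS spectrum matches
        aging_signature_mix x catalog at cosine >= 0.98."""
        cfg = small_config(cells_per_subject=32, aging_intercept=700.0,
                           aging_rate=0.0, clonal_mu=0.0, clonal_indel_mu=0.0,
                           aging_indel_rate=0.0, aging_indel_intercept=0.0)
        truth = simulate_lineage(cfg, 0, genome)
        priv = truth.variants[
            (truth.variants["origin"] == "private")
            & (truth.variants["kind"] == "SNV")
        ]
        assert len(priv) >= 20_000
        counts = np.zeros(96)
        for ch, n in priv["channel"].value_counts().items():
            counts[SBS96_INDEX[ch]] = n
        cat = cfg.sbs_catalog()
        expected = sum(w * cat.column(s) for s, w in cfg.aging_signature_mix.items())
        assert cosine(counts, expected) >= 0.98
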