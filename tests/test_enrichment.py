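"""Permutation enrichment, trend tests and impact summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somaclock.enrichment import (
    AnnotationTrack,
    enrich,
    enrichment_frame,
    impact_summary,
    permute_positions,
    record_contexts,
    trend,
)
from somaclock.spectra import MutationRecord
from somaclock.synthetic import sample_positions, track_position_weights


@pytest.fixture(scope="module")
def genic(syn_genome):
    return syn_genome.tracks["genic"]


class TestAnnotationTrack:
    def test_overlap_rejected(self, genome):
        df = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 50], "end": [100, 150],
             "label": ["a", "b"]}
        )
        with pytest.raises(ValueError, match="overlapping"):
            AnnotationTrack("bad", df).validate(genome)

    def test_partition_must_tile(self, genome):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100], "label": ["a"]}
        )
        with pytest.raises(ValueError, match="tile"):
            AnnotationTrack("bad", df, layer="partition").validate(genome)

    def test_out_of_bounds_rejected(self, genome):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10**9], "label": ["a"]}
        )
        with pytest.raises(ValueError, match="outside"):
            AnnotationTrack("bad", df).validate(genome)

    def test_bed_convention_one_interval(self, genome):
        """BED 'chr1 0 100 x' covers 1-based positions 1..100."""
        df = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100], "label": ["x"]}
        )
        track = AnnotationTrack("t", df, layer="quantile")
        codes, labels = track.label_codes(genome)
        assert codes[genome.to_global("chr1", 1)] == 0
        assert codes[genome.to_global("chr1", 100)] == 0
        assert codes[genome.to_global("chr1", 101)] == -1


class TestPermutePositions:
    def test_count_conserved_and_inside_callable(self, genome, rng):
        mask = np.zeros(genome.length, dtype=bool)
        mask[1000:50_000] = True
        pos = sample_positions(genome, 100, rng)
        out = permute_positions(pos, genome, rng, "uniform", callable_mask=mask)
        assert len(out) == 100
        assert mask[out].all()

    def test_context_matched_destinations(self, genome, rng):
        recs = []
        pool = genome.positions_by_context()["ACA"]
        for gp in pool[:50]:
            chrom, p = genome.from_global(int(gp))
            recs.append(MutationRecord("c", chrom, p, genome.base(chrom, p), "T"))
        contexts = record_contexts(recs, genome)
        pos = np.array([genome.to_global(r.chrom, r.pos) for r in recs])
        out = permute_positions(
            pos, genome, rng, "context-matched", contexts=contexts
        )
        for gp in out:
            chrom, p = genome.from_global(int(gp))
            assert genome.pyrimidine_context(chrom, p) == "ACA"

    def test_uniform_class_hits_match_binomial(self, genome, genic, rng):
        frac = genic.class_fractions(genome)["genic"]
        pos = sample_positions(genome, 500, rng)
        codes, labels = genic.label_codes(genome)
        gi = labels.index("genic")
        hits = [
            (codes[permute_positions(pos, genome, rng, "uniform")] == gi).sum()
            for _ in range(300)
        ]
        lo, hi = stats.binom.interval(0.9999, 500, frac)
        assert lo <= np.mean(hits) <= hi


class TestEnrich:
    def test_forced_concentration_ratio(self, genome, syn_genome, rng):
        """All mutations inside a class covering fraction f give ratio 1/f."""
        detail = syn_genome.tracks["genic_detail"]
        w = track_position_weights(
            genome, detail,
            {"exon": 1.0, "intron": 0, "utr5": 0, "utr3": 0, "intergenic": 0},
        )
        pos = sample_positions(genome, 4000, rng, weights=w)
        res = {r.label: r for r in enrich(pos, detail, genome,
                                          n_permutations=400, seed=1)}
        f = detail.class_fractions(genome)["exon"]
        assert res["exon"].ratio == pytest.approx(1 / f, rel=0.05)
        assert res["exon"].p_value < 0.01
        assert res["intron"].observed == 0

    def test_null_ratios_near_one(self, genome, genic, rng):
        pos = sample_positions(genome, 10_000, rng)
        res = enrich(pos, genic, genome, n_permutations=400, seed=2)
        for r in res:
            assert 0.9 <= r.ratio <= 1.1

    def test_seeded_determinism(self, genome, genic, rng):
        pos = sample_positions(genome, 500, rng)
        a = enrich(pos, genic, genome, n_permutations=100, seed=7)
        b = enrich(pos, genic, genome, n_permutations=100, seed=7)
        assert [(r.ratio, r.p_value) for r in a] == [
            (r.ratio, r.p_value) for r in b
        ]

    def test_bh_column_present(self, genome, genic, rng):
        pos = sample_positions(genome, 200, rng)
        df = enrichment_frame(enrich(pos, genic, genome, n_permutations=50))
        assert "q_bh" in df and (df["q_bh"] >= df["p_value"] - 1e-12).all()


class TestTrend:
    def test_monotone_bins_give_negative_r(self, genome):
        """Hand-constructed decreasing per-bin ratios yield r < 0."""
        df = pd.DataFrame(
            {"chrom": "chr1",
             "start": [0, 1000, 2000], "end": [1000, 2000, 3000],
             "label": ["b1", "b2", "b3"]}
        )
        track = AnnotationTrack("toy", df, layer="quantile",
                                bins=("b1", "b2", "b3"))
        rng = np.random.default_rng(0)
        pos = np.concatenate([
            rng.integers(0, 1000, 400),      # ratio ~2
            rng.integers(1000, 2000, 200),   # ratio ~1
            rng.integers(2000, 3000, 100),   # ratio ~0.5
        ])
        mask = np.zeros(genome.length, dtype=bool)
        mask[:3000] = True
        _, r, p = trend(pos, track, genome, n_permutations=200, seed=1,
                        callable_mask=mask)
        assert r < 0

    def test_linear_expression_bias_detected(self, genome, syn_genome, rng):
        track = syn_genome.tracks["expression"]
        mult = {f"dec{i+1:02d}": 1.0 - 0.09 * i for i in range(10)}
        w = track_position_weights(genome, track, mult)
        pos = sample_positions(genome, 8000, rng, weights=np.where(w > 0, w, 0.2))
        _, r, p = trend(pos, track, genome, n_permutations=300, seed=2)
        assert r < 0 and p < 0.05

    def test_flat_placement_is_null(self, genome, syn_genome):
        track = syn_genome.tracks["expression"]
        hits = 0
        for rep in range(30):
            rng = np.random.default_rng(900 + rep)
            pos = sample_positions(genome, 3000, rng)
            _, r, p = trend(pos, track, genome, n_permutations=120, seed=rep)
            hits += p < 0.05
        assert hits / 30 <= 0.2

    def test_too_few_bins_rejected(self, genome):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100], "label": ["a"]}
        )
        track = AnnotationTrack("t", df, layer="quantile", bins=("a",))
        with pytest.raises(ValueError, match=">=3"):
            trend(np.array([5]), track, genome)


class TestImpactSummary:
    def _records(self, spec):
        recs = []
        for cell, labels in spec.items():
            for i, lab in enumerate(labels):
                rec = MutationRecord(cell, "chr1", i + 10, "C", "T")
                if lab:
                    rec.annotations["impact"] = lab
                recs.append(rec)
        return recs

    def test_degenerate_all_low(self):
        recs = self._records({"c0": ["low"] * 5, "c1": ["low"] * 5})
        meta = pd.DataFrame(
            {"cell_id": ["c0", "c1"], "celltype": ["GN", "OL"]}
        ).set_index("cell_id", drop=False)
        frac, tests = impact_summary(recs, meta)
        assert (frac["frac_high"] == 0).all()

    def test_identical_distributions_null(self):
        spec = {f"g{i}": ["high", "low", "low", "moderate"] for i in range(6)}
        spec.update({f"o{i}": ["high", "low", "low", "moderate"]
                     for i in range(6)})
        recs = self._records(spec)
        meta = pd.DataFrame(
            {"cell_id": list(spec), "celltype": ["GN"] * 6 + ["OL"] * 6}
        ).set_index("cell_id", drop=False)
        _, tests = impact_summary(recs, meta)
        assert (tests["p"] > 0.9).all()

    def test_doubled_high_rate_detected(self):
        rng = np.random.default_rng(4)
        spec = {}
        for i in range(50):
            n_high = rng.binomial(20, 0.10)
            spec[f"g{i}"] = ["high"] * n_high + ["low"] * (20 - n_high)
        for i in range(50):
            n_high = rng.binomial(20, 0.05)
            spec[f"o{i}"] = ["high"] * n_high + ["low"] * (20 - n_high)
        recs = self._records(spec)
        meta = pd.DataFrame(
            {"cell_id": list(spec),
             "celltype": ["GN"] * 50 + ["OL"] * 50}
        ).set_index("cell_id", drop=False)
        _, tests = impact_summary(recs, meta)
        p = tests.loc[tests["impact"] == "high", "p"].iloc[0]
        assert p < 0.05

    def test_missing_labels_excluded(self):
        recs = self._records({"c0": ["low", None, "high"]})
        meta = pd.DataFrame(
            {"cell_id": ["c0"], "celltype": ["GN"]}
        ).set_index("cell_id", drop=False)
        frac, _ = impact_summary(recs, meta)
        assert frac.iloc[0]["total"] == 2
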