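"""Lineage reconstruction, MRCA dating and region sharing."""

import numpy as np
import pytest

from conftest import small_config
from somaclock.burden import RateFit
from somaclock.lineage import (
    build_tree,
    date_mrca,
    date_tree,
    region_sharing,
)
from somaclock.synthetic import emit_calls, simulate_lineage


def key(i):
    return ("chr1", i, "A", "T")


def make_fit(slope=27.0, intercept=0.0, se_slope=0.0, se_intercept=0.0):
    return RateFit(
        slope=slope, intercept=intercept,
        ci95_slope=(slope - 1.96 * se_slope, slope + 1.96 * se_slope),
        ci95_intercept=(intercept - 1.96 * se_intercept,
                        intercept + 1.96 * se_intercept),
        se_slope=se_slope, se_intercept=se_intercept,
        residual_sd=0.0, n_cells=100, n_subjects=4,
    )


class TestBuildTree:
    def test_hand_checkable_nesting(self):
        cv = {
            "c1": [key(0), key(1), key(2)],
            "c2": [key(0), key(1), key(2)],
            "c3": [key(0)],
        }
        tree = build_tree(cv, min_support=2)
        assert tree.clade_family() == {frozenset({"c1", "c2"})}
        clade = next(tree.internal_nodes())
        assert clade.branch_length == 2  # key(1), key(2)
        assert tree.root.variants == [key(0)]

    def test_conflict_resolved_by_support(self):
        cv = {
            "c1": [key(0), key(1), key(2)],
            "c2": [key(0), key(1), key(2), key(3)],
            "c3": [key(3), key(4), key(5)],
        }
        # {c1,c2} has 3 supporting variants, {c2,c3} only 1 -> discarded
        tree = build_tree(cv, min_support=1)
        assert frozenset({"c1", "c2"}) in tree.clade_family()
        assert frozenset({"c2", "c3"}) not in tree.clade_family()

    def test_star_tree_on_no_sharing(self):
        cv = {"c1": [key(0)], "c2": [key(1)], "c3": [key(2)]}
        with pytest.warns(UserWarning, match="star tree"):
            tree = build_tree(cv)
        assert tree.clade_family() == set()
        assert all(len(l.variants) == 1 for l in tree.leaves())

    def test_disjoint_path_invariant_asserted(self, genome):
        cfg = small_config(cells_per_subject=24)
        truth = simulate_lineage(cfg, 0, genome)
        emitted = emit_calls(truth, cfg)
        tree = build_tree(emitted.cell_variant_keys())
        # _assert_disjoint_paths runs inside build_tree; re-check counts:
        total_assigned = sum(len(n.variants) for n in tree.nodes())
        assert total_assigned == len(
            {tuple(k) for v in emitted.cell_variant_keys().values() for k in v}
        )

    def test_exact_recovery_at_full_sensitivity(self, genome):
        cfg = small_config(
            cells_per_subject=32,
            division_schedule=((0.05, 2), (0.1, 2), (0.2, 2), (0.3, 2)),
            terminal_times=0.5, clonal_mu=40.0,
        )
        truth = simulate_lineage(cfg, 0, genome)
        emitted = emit_calls(truth, cfg)
        bulk = set(map(tuple, emitted.bulk.itertuples(index=False)))
        tree = build_tree(emitted.cell_variant_keys(), bulk)
        assert tree.clade_family() == truth.tree.clade_family()

    def test_conservation_of_burden(self, genome):
        """Sum of path branch lengths + private count equals each cell's
        total variant count at sensitivity 1."""
        cfg = small_config(cells_per_subject=16)
        truth = simulate_lineage(cfg, 0, genome)
        emitted = emit_calls(truth, cfg)
        cv = emitted.cell_variant_keys()
        tree = build_tree(cv)
        depth = tree.depths()
        for leaf in tree.leaves():
            cell = next(iter(leaf.cells))
            assert depth[leaf.id] == len(cv[cell])


class TestDateMRCA:
    def _node(self, cells):
        from somaclock.lineage import CladeNode

        return CladeNode(id="n1", cells=frozenset(cells))

    def test_dating_arithmetic(self):
        node = self._node(["a", "b"])
        fit = make_fit(slope=27.0, intercept=0.0)
        est = date_mrca(node, fit, 82.7, {"a": 2160.0, "b": 2160.0}, offset=0.0)
        assert est.t_mrca == pytest.approx(82.7 - 80.0, abs=1e-9)

    def test_zygote_boundary(self):
        node = self._node(["a", "b"])
        fit = make_fit(slope=27.0, intercept=0.0)
        burden = 27.0 * 82.7
        est = date_mrca(node, fit, 82.7, {"a": burden, "b": burden}, offset=0.0)
        assert est.t_mrca == pytest.approx(0.0, abs=1e-9)

    def test_default_offset_is_intercept(self):
        node = self._node(["a", "b"])
        fit = make_fit(slope=10.0, intercept=100.0)
        est = date_mrca(node, fit, 50.0, {"a": 200.0, "b": 200.0})
        assert est.t_mrca == pytest.approx(50.0 - 10.0)

    def test_future_estimate_clipped_and_flagged(self):
        # burden below the intercept would date past the donor's death
        node = self._node(["a", "b"])
        fit = make_fit(slope=10.0, intercept=100.0)
        est = date_mrca(node, fit, 50.0, {"a": 10.0, "b": 10.0})
        assert est.clipped and est.t_mrca == 50.0

    def test_nonpositive_slope_rejected(self):
        node = self._node(["a", "b"])
        with pytest.raises(ValueError, match="positive"):
            date_mrca(node, make_fit(slope=0.0), 50.0, {"a": 1.0, "b": 1.0})

    def test_thinning_cells_shifts_within_ci(self, genome):
        """Dating from a random half of a clade's cells stays inside the
        full-clade CI (estimate robust to cell subsampling)."""
        rng = np.random.default_rng(3)
        burdens = {f"c{i}": 2000 + rng.normal(0, 60) for i in range(24)}
        fit = make_fit(slope=27.0, intercept=100.0, se_slope=0.5,
                       se_intercept=30.0)
        node = self._node(list(burdens))
        full = date_mrca(node, fit, 82.7, burdens)
        half_cells = rng.choice(sorted(burdens), 12, replace=False)
        half = date_mrca(self._node(list(half_cells)), fit, 82.7, burdens)
        assert full.ci95[0] <= half.t_mrca <= full.ci95[1]

    def test_simulated_terminal_times_recovered(self, genome):
        """Clades stopping division at .5/1/2 years date near those times."""
        cfg = small_config(
            subject_ages=(82.7,), cells_per_subject=24,
            division_schedule=((0.05, 3),), terminal_times=(0.5, 1.0, 2.0),
            clonal_mu=60.0, aging_rate=27.0, aging_intercept=100.0,
        )
        truth = simulate_lineage(cfg, 0, genome)
        emitted = emit_calls(truth, cfg)
        tree = build_tree(emitted.cell_variant_keys())
        fit = make_fit(slope=27.0, intercept=100.0, se_slope=0.5,
                       se_intercept=20.0)
        # the clock divides private sSNVs by the sSNV rate: exclude indels
        burdens = {
            next(iter(l.cells)): sum(
                1 for k in l.variants if len(k[2]) == 1 and len(k[3]) == 1
            )
            for l in tree.leaves()
        }
        ests = date_tree(tree, fit, 82.7, burdens)
        covered = 0
        for est in ests:
            node = tree.node_by_id(est.node_id)
            t_true = truth.true_mrca_time(truth.tree.node_by_id(
                _match_truth_node(truth, node)))
            covered += est.ci95[0] <= t_true <= est.ci95[1]
        assert covered >= 0.9 * len(ests)


def _match_truth_node(truth, node):
    for tn in truth.tree.nodes():
        if tn.cells == node.cells:
            return tn.id
    raise AssertionError("no matching truth clade")


class TestRobinsonFoulds:
    def test_clade_symdiff_matches_dendropy(self, genome, tmp_path):
        """Our clade-family symmetric difference equals dendropy's
        Robinson-Foulds distance on the same tree pair."""
        import dendropy

        from somaclock.io import write_newick

        cfg_a = small_config(seed=21, cells_per_subject=16,
                             division_schedule=((0.05, 2), (0.2, 2), (0.3, 2)),
                             terminal_times=0.4)
        truth = simulate_lineage(cfg_a, 0, genome)
        thinned = small_config(
            seed=21, cells_per_subject=16,
            division_schedule=((0.05, 2), (0.2, 2), (0.3, 2)),
            terminal_times=0.4, detect_sensitivity={"30X": 0.85},
        )
        emitted = emit_calls(truth, thinned)
        tree_b = build_tree(emitted.cell_variant_keys())

        ours = len(truth.tree.clade_family() ^ tree_b.clade_family())

        pa, pb = tmp_path / "a.nwk", tmp_path / "b.nwk"
        write_newick(truth.tree, pa)
        write_newick(tree_b, pb)
        tns = dendropy.TaxonNamespace()
        da = dendropy.Tree.get(path=str(pa), schema="newick",
                               taxon_namespace=tns)
        db = dendropy.Tree.get(path=str(pb), schema="newick",
                               taxon_namespace=tns)
        da.encode_bipartitions()
        db.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(da, db)
        assert ours == rf


class TestRegionSharing:
    def test_definitional_fractions(self):
        cv = {
            "c1": [key(0), key(1)],
            "c2": [key(0), key(1)],
            "c3": [key(2), key(3)],
            "c4": [key(2), key(3)],
        }
        tree = build_tree(cv)
        carriers = {key(i): {"c1", "c2"} if i < 2 else {"c3", "c4"}
                    for i in range(4)}
        # clade {c1,c2} spans both regions -> all its variants common
        labels = {"c1": "CH", "c2": "V", "c3": "CH", "c4": "CH"}
        df = region_sharing(tree, labels, carriers).set_index("clade")
        mixed = df.loc[df["n_cells"].index[df["common_fraction"] == 1.0][0]]
        assert mixed["n_common"] == 2
        pure = df[df["common_fraction"] == 0.0].iloc[0]
        assert pure["n_specific"] == 2
        assert pure["note"] == "single-region clade"

    def test_mixing_monotonicity(self, genome):
        """Higher region_mixing raises the common-variant fraction."""
        fracs = {}
        for mixing in (0.05, 0.8):
            vals = []
            for seed in range(6):
                cfg = small_config(
                    seed=seed, cells_per_subject=16, region_mixing=mixing,
                    division_schedule=((0.05, 2), (0.2, 2), (0.4, 2)),
                    terminal_times=0.5,
                )
                truth = simulate_lineage(cfg, 0, genome)
                df = region_sharing(
                    truth.tree, truth.region_labels, truth.carriers()
                )
                vals.append(df["common_fraction"].mean())
            fracs[mixing] = np.mean(vals)
        assert fracs[0.8] > fracs[0.05]


class TestNewick:
    def test_round_trip_topology_and_lengths(self, genome, tmp_path):
        from somaclock.io import read_newick, write_newick

        cfg = small_config(cells_per_subject=16)
        truth = simulate_lineage(cfg, 0, genome)
        path = tmp_path / "tree.nwk"
        write_newick(truth.tree, path)
        back = read_newick(path)
        assert back.clade_family() == truth.tree.clade_family()
        orig = {frozenset(n.cells): n.branch_length
                for n in truth.tree.nodes()}
        new = {frozenset(n.cells): n.branch_length for n in back.nodes()}
        assert orig == new
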