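"""End-to-end parameter-recovery experiments on synthetic cohorts.

Each function simulates data with known generative parameters, runs the
relevant analysis stage(s) through their public interfaces, and reports how
well the truth is recovered.  These experiments back the package's
validation suite and the reproduction script; problem sizes are chosen so
the full battery runs in minutes on one core (the methods note records the
sizes used).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .burden import CellProfile, fit_rate
from .channels import BASES, COMPLEMENT, revcomp, sbs_channel
from .enrichment import AnnotationTrack, enrich
from .genome import Genome
from .intermixing import test_deviation_index, test_neighbor_match
from .lineage import build_tree, date_tree
from .signatures import stepwise_select
from .spectra import MutationRecord, Spectrum, classify_id, classify_sbs
from .synthetic import (
    SimConfig,
    emit_calls,
    sample_positions,
    simulate_genome,
    simulate_lineage,
    synthetic_sbs_catalog,
)

#: design shared by the burden experiments: one donor per age, as in
#: cross-sectional single-cell studies
COHORT_AGES = (20.0, 42.0, 59.0, 83.0)


def _shared_genome(seed: int, length: int = 1_000_000) -> Genome:
    return simulate_genome(SimConfig(seed=seed, genome_length=length)).genome


def _is_snv(key) -> bool:
    return len(key[2]) == 1 and len(key[3]) == 1


def _profiles_from_emission(truth, emitted) -> list[CellProfile]:
    kinds = truth.variants.set_index(["chrom", "pos", "ref", "alt"])["kind"]
    counts: dict[str, list[int]] = {c: [0, 0] for c in truth.cells}
    for row in emitted.calls.itertuples():
        snv = _is_snv((row.chrom, row.pos, row.ref, row.alt))
        counts[row.cell_id][0 if snv else 1] += 1
    out = []
    for row in emitted.metadata.itertuples():
        out.append(
            CellProfile(
                cell_id=row.cell_id,
                subject_id=row.subject_id,
                age=float(row.age_years),
                region=row.region,
                depth_class=row.depth_class,
                callable_fraction=float(row.callable_fraction),
                n_calls_snv=counts[row.cell_id][0],
                n_calls_indel=counts[row.cell_id][1],
            )
        )
    return out


# ---------------------------------------------------------------------------
# 1. age-rate recovery
# ---------------------------------------------------------------------------

def rate_recovery(
    seed: int,
    n_replicates: int = 100,
    cells_per_subject: int = 25,
    genome: Genome | None = None,
) -> dict:
    """Slope recovery and CI coverage for the sSNV ageing rate.

    Four donors at ages 20/42/59/83, Poisson-noise burdens accumulating at
    27/yr over an intercept of 100 (and 1.86 indels/yr), detection at full
    sensitivity over an 80%-callable genome.  Reports CI coverage of the
    true rate across replicates and the pooled rate estimates.
    """
    genome = genome or _shared_genome(seed)
    covered = 0
    slopes, islopes = [], []
    intercepts = []
    for rep in range(n_replicates):
        cfg = SimConfig(
            seed=seed + 1000 * rep,
            genome_length=genome.length,
            n_subjects=4,
            subject_ages=COHORT_AGES,
            cells_per_subject=cells_per_subject,
            division_schedule=((0.05, 5), (0.1, 5)),
            terminal_times=0.2,
            clonal_mu=0.0,
            clonal_indel_mu=0.0,
            aging_rate=27.0,
            aging_intercept=100.0,
            detect_sensitivity={"30X": 1.0},
            callable_fraction={"30X": 0.8},
        )
        profiles = []
        for s in range(4):
            truth = simulate_lineage(cfg, s, genome)
            profiles += _profiles_from_emission(truth, emit_calls(truth, cfg))
        fit = fit_rate(profiles)
        covered += fit.ci95_slope[0] <= 27.0 <= fit.ci95_slope[1]
        slopes.append(fit.slope)
        intercepts.append(fit.intercept)
        if rep < 10:  # the indel fit is cheap but only needs a few replicates
            islopes.append(fit_rate(profiles, response="indel").slope)
    return {
        "coverage_pct": 100.0 * covered / n_replicates,
        "snv_rate": float(np.mean(slopes)),
        "snv_intercept": float(np.mean(intercepts)),
        "indel_rate": float(np.mean(islopes)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# 2. stepwise signature recovery
# ---------------------------------------------------------------------------

def signature_recovery(seed: int, n_mutations: int = 50_000) -> dict:
    """Stepwise refitting of a 60/25/15 three-signature mixture."""
    catalog = synthetic_sbs_catalog()
    mix = {"SBS5": 0.60, "SBS1": 0.25, "SBS18": 0.15}
    rng = np.random.default_rng(seed)
    p = sum(w * catalog.column(s) for s, w in mix.items())
    spectrum = Spectrum(
        rng.multinomial(n_mutations, p).astype(float), "SBS96", "mixture"
    )
    expo = stepwise_select(spectrum, catalog, threshold=0.01)
    fr = expo.fractions()
    max_err = max(abs(fr.get(s, 0.0) - w) for s, w in mix.items())
    return {
        "selected_exactly": float(set(expo.selected) == set(mix)),
        "max_fraction_error_pts": 100.0 * float(max_err),
        "reconstruction_cosine": expo.reconstruction_cosine,
        "n_mutations": n_mutations,
    }


# ---------------------------------------------------------------------------
# 3. clonal vs private mixture split
# ---------------------------------------------------------------------------

def clonal_private_split(seed: int, genome: Genome | None = None) -> dict:
    """Recover the developmental and ageing signature mixes from the
    shared/private split of one simulated lineage.

    The developmental mix is SBS1-heavy and the ageing mix SBS5-heavy;
    exposures are refitted separately on ancestral-branch and terminal-
    branch spectra of the reconstructed tree.
    """
    genome = genome or _shared_genome(seed)
    dev_mix = {"SBS1": 0.7, "SBS5": 0.3}
    aging_mix = {"SBS1": 0.10, "SBS5": 0.75, "SBS18": 0.15}
    cfg = SimConfig(
        seed=seed,
        genome_length=genome.length,
        subject_ages=(60.0,),
        cells_per_subject=32,
        division_schedule=((0.05, 2), (0.2, 2), (0.4, 2)),
        terminal_times=0.6,
        clonal_mu=300.0,
        clonal_indel_mu=0.0,
        aging_indel_rate=0.0,
        aging_indel_intercept=0.0,
        dev_signature_mix=dev_mix,
        aging_signature_mix=aging_mix,
        detect_sensitivity={"30X": 1.0},
        callable_fraction={"30X": 1.0},
    )
    truth = simulate_lineage(cfg, 0, genome)
    emitted = emit_calls(truth, cfg)
    bulk = set(map(tuple, emitted.bulk.itertuples(index=False)))
    tree = build_tree(emitted.cell_variant_keys(), bulk)

    catalog = cfg.sbs_catalog()
    spectra = {}
    for origin, keys in (
        ("shared", [k for n in tree.internal_nodes() for k in n.variants]
         + list(tree.root.variants)),
        ("private", [k for l in tree.leaves() for k in l.variants]),
    ):
        counts = np.zeros(96)
        for key in keys:
            if not _is_snv(key):
                continue
            rec = MutationRecord("x", key[0], key[1], key[2], key[3])
            ch = classify_sbs(rec, genome)
            counts[list(catalog.matrix.index).index(ch)] += 1
        spectra[origin] = Spectrum(counts, "SBS96", origin)

    out = {}
    for origin, mix in (("shared", dev_mix), ("private", aging_mix)):
        expo = stepwise_select(spectra[origin], catalog, threshold=0.01)
        fr = expo.fractions()
        out[f"{origin}_max_error_pts"] = 100.0 * float(
            max(abs(fr.get(s, 0.0) - w) for s, w in mix.items())
        )
        out[f"{origin}_n"] = spectra[origin].total
    return out


# ---------------------------------------------------------------------------
# 4. lineage fidelity
# ---------------------------------------------------------------------------

def lineage_fidelity(seed: int, genome: Genome | None = None) -> dict:
    """Clade-family recovery of a 64-cell lineage at full and 0.9 sensitivity."""
    genome = genome or _shared_genome(seed)
    base = dict(
        seed=seed,
        genome_length=genome.length,
        subject_ages=(82.7,),
        cells_per_subject=64,
        division_schedule=(
            (0.05, 2), (0.1, 2), (0.2, 2), (0.3, 2), (0.45, 2),
        ),
        terminal_times=0.6,
        clonal_mu=60.0,
        aging_rate=27.0,
        aging_intercept=100.0,
        callable_fraction={"30X": 1.0},
    )
    truth = simulate_lineage(
        SimConfig(**base, detect_sensitivity={"30X": 1.0}), 0, genome
    )
    true_family = truth.tree.clade_family()

    results = {}
    for label, sens in (("full", 1.0), ("thinned", 0.9)):
        cfg = SimConfig(**base, detect_sensitivity={"30X": sens})
        emitted = emit_calls(truth, cfg)
        bulk = set(map(tuple, emitted.bulk.itertuples(index=False)))
        tree = build_tree(emitted.cell_variant_keys(), bulk)
        family = tree.clade_family()
        sym = len(true_family ^ family)
        results[label] = {
            "exact": float(family == true_family),
            "rf": sym,
            "rf_fraction": sym / (len(true_family) + len(family)),
        }
    return {
        "exact_recovery_at_full_sensitivity": results["full"]["exact"],
        "rf_fraction_at_0.9": results["thinned"]["rf_fraction"],
        "n_true_clades": len(true_family),
    }


# ---------------------------------------------------------------------------
# 5. MRCA dating coverage
# ---------------------------------------------------------------------------

def mrca_dating(
    seed: int,
    n_replicates: int = 50,
    genome: Genome | None = None,
) -> dict:
    """CI coverage of true post-mitotic times for dated clades.

    Each replicate fits the ageing trend on a fresh 4-donor cohort, then
    dates the clades of an aged donor whose three lineages became
    post-mitotic at 0.5, 1.0 and 2.0 years.
    """
    genome = genome or _shared_genome(seed)
    covered = total = 0
    estimates_late = []
    for rep in range(n_replicates):
        cohort = SimConfig(
            seed=seed + 7919 * rep,
            genome_length=genome.length,
            n_subjects=4,
            subject_ages=COHORT_AGES,
            cells_per_subject=8,
            division_schedule=((0.05, 4), (0.1, 2)),
            terminal_times=0.2,
            clonal_mu=0.0,
            clonal_indel_mu=0.0,
            aging_indel_rate=0.0,
            aging_indel_intercept=0.0,
            aging_rate=27.0,
            aging_intercept=100.0,
            detect_sensitivity={"30X": 1.0},
            callable_fraction={"30X": 0.8},
        )
        profiles = []
        for s in range(4):
            tr = simulate_lineage(cohort, s, genome)
            profiles += _profiles_from_emission(tr, emit_calls(tr, cohort))
        fit = fit_rate(profiles)

        aged = SimConfig(
            seed=seed + 7919 * rep + 1,
            genome_length=genome.length,
            subject_ages=(82.7,),
            cells_per_subject=24,
            division_schedule=((0.05, 3),),
            terminal_times=(0.5, 1.0, 2.0),
            clonal_mu=60.0,
            clonal_indel_mu=0.0,
            aging_indel_rate=0.0,
            aging_indel_intercept=0.0,
            aging_rate=27.0,
            aging_intercept=100.0,
            detect_sensitivity={"30X": 1.0},
            callable_fraction={"30X": 0.8},
        )
        truth = simulate_lineage(aged, 0, genome)
        emitted = emit_calls(truth, aged)
        tree = build_tree(emitted.cell_variant_keys())
        cf = dict(
            zip(emitted.metadata["cell_id"], emitted.metadata["callable_fraction"])
        )
        burdens = {
            next(iter(l.cells)): sum(1 for k in l.variants if _is_snv(k))
            / cf[next(iter(l.cells))]
            for l in tree.leaves()
        }
        truth_cells = {
            frozenset(n.cells): truth.true_mrca_time(n)
            for n in truth.tree.nodes()
        }
        for est in date_tree(tree, fit, 82.7, burdens):
            node = tree.node_by_id(est.node_id)
            t_true = truth_cells.get(node.cells)
            if t_true is None:
                # spurious clade from callable thinning: compare against the
                # mean terminal time of its cells (the quantity estimated)
                t_true = float(
                    np.mean([truth.terminal_times[c] for c in node.cells])
                )
            total += 1
            covered += est.ci95[0] <= t_true <= est.ci95[1]
            if abs(t_true - 2.0) < 1e-9:
                estimates_late.append(est.t_mrca)
    return {
        "coverage_pct": 100.0 * covered / total,
        "n_dated_nodes": total,
        "latest_clade_mean_t": float(np.mean(estimates_late)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# 6. enrichment calibration
# ---------------------------------------------------------------------------

def _window_track(genome: Genome, n_classes: int, name: str) -> AnnotationTrack:
    rows = []
    for chrom in genome.contigs:
        L = genome.contig_length(chrom)
        bounds = np.linspace(0, L, n_classes + 1).astype(int)
        for i in range(n_classes):
            rows.append((chrom, int(bounds[i]), int(bounds[i + 1]), f"w{i:03d}"))
    return AnnotationTrack(
        name, pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    )


def enrichment_calibration(
    seed: int,
    n_permutations: int = 1000,
    n_mutations: int = 10_000,
    genome: Genome | None = None,
) -> dict:
    """Null calibration and a forced 10x concentration.

    Under uniform placement every obs/exp ratio on coarse tracks should sit
    near 1 and the empirical p-values over 200 window classes should be
    uniform; forcing all mutations into a class covering 10% of the genome
    should give a ratio of ~10.
    """
    cfg = SimConfig(seed=seed, genome_length=1_000_000)
    syn = simulate_genome(cfg)
    genome = syn.genome
    rng = np.random.default_rng(seed + 1)

    pos = sample_positions(genome, n_mutations, rng)
    ratios = []
    worst_dev = 0.0
    for track in (syn.tracks["genic"], syn.tracks["replication_timing"],
                  syn.tracks["accessibility"]):
        for r in enrich(pos, track, genome, n_permutations=n_permutations,
                        seed=seed + 2, mode="uniform"):
            ratios.append(r.ratio)
            worst_dev = max(worst_dev, abs(r.ratio - 1.0))

    null_track = _window_track(genome, 200, "windows200")
    pvals = [
        r.p_value
        for r in enrich(pos, null_track, genome,
                        n_permutations=n_permutations, seed=seed + 3)
    ]
    ks_p = float(stats.kstest(pvals, "uniform").pvalue)

    # forced concentration: class X = first 10% of each contig
    rows = []
    for chrom in genome.contigs:
        L = genome.contig_length(chrom)
        cut = L // 10
        rows.append((chrom, 0, cut, "X"))
        rows.append((chrom, cut, L, "bg"))
    forced_track = AnnotationTrack(
        "forced", pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    )
    codes, labels = forced_track.label_codes(genome)
    x_pool = np.flatnonzero(codes == labels.index("X"))
    forced_pos = x_pool[rng.integers(0, len(x_pool), size=5000)]
    forced = {
        r.label: r
        for r in enrich(forced_pos, forced_track, genome,
                        n_permutations=n_permutations, seed=seed + 4)
    }
    return {
        "max_null_ratio_deviation": float(worst_dev),
        "p_uniformity_ks_p": ks_p,
        "forced_ratio": float(forced["X"].ratio),
        "forced_expected": float(
            1.0 / forced_track.class_fractions(genome)["X"]
        ),
        "n_permutations": n_permutations,
    }


# ---------------------------------------------------------------------------
# 7. intermixing power and size
# ---------------------------------------------------------------------------

def intermixing_performance(
    seed: int,
    n_replicates: int = 100,
    n_permutations: int = 199,
    genome: Genome | None = None,
) -> dict:
    """Rejection rates of both intermixing tests at the two extremes.

    region_mixing 0 (clades perfectly segregated between CH and V) should be
    rejected nearly always; region_mixing 1 (i.i.d. labels) at most at the
    nominal rate.  Donors are young (age 20) to keep lineage simulation
    light; the statistics only see tree distances and labels.
    """
    genome = genome or _shared_genome(seed)
    out = {}
    for label, mixing in (("power", 0.0), ("size", 1.0)):
        rej_dev = rej_nm = 0
        for rep in range(n_replicates):
            cfg = SimConfig(
                seed=seed + 104729 * rep + int(mixing),
                genome_length=genome.length,
                subject_ages=(20.0,),
                cells_per_subject=64,
                division_schedule=((0.1, 2), (0.3, 2), (0.5, 2)),
                terminal_times=0.6,
                clonal_mu=60.0,
                clonal_indel_mu=0.0,
                aging_indel_rate=0.0,
                aging_indel_intercept=0.0,
                region_mixing=mixing,
                detect_sensitivity={"30X": 1.0},
                callable_fraction={"30X": 1.0},
            )
            truth = simulate_lineage(cfg, 0, genome)
            emitted = emit_calls(truth, cfg)
            tree = build_tree(emitted.cell_variant_keys())
            dev = test_deviation_index(
                tree.root, truth.region_labels,
                n_permutations=n_permutations, seed=seed + rep,
            )
            nm = test_neighbor_match(
                tree, truth.region_labels, k=3,
                n_permutations=n_permutations, seed=seed + rep,
            )
            rej_dev += dev.p_value < 0.05
            rej_nm += nm.p_value < 0.05
        out[f"deviation_{label}_pct"] = 100.0 * rej_dev / n_replicates
        out[f"neighbor_{label}_pct"] = 100.0 * rej_nm / n_replicates
    out["n_replicates"] = n_replicates
    return out


# ---------------------------------------------------------------------------
# 8. classification consistency
# ---------------------------------------------------------------------------

ID_GOLDEN = (
    ("GGATTTTAGG", 4, "T", "TT", "1:Ins:T:4"),
    ("GGAGAGAGGG", 3, "A", "AT", "1:Ins:T:0"),
    ("GGACAGGGGG", 3, "AC", "A", "1:Del:C:0"),
    ("TTAGGGATTT", 3, "AG", "A", "1:Del:C:2"),
    ("TGCAAAAAGT", 3, "CA", "C", "1:Del:T:4"),
    ("GGCTATAGGC", 3, "CTA", "C", "2:Del:R:1"),
    ("GGCTAGGGCC", 3, "C", "CTA", "2:Ins:R:1"),
    ("ACTAGTACCC", 2, "CTAG", "C", "3:Del:M:2"),
    ("GACTGAGGGC", 2, "ACTG", "A", "3:Del:R:0"),
    ("TTACGTCACGTCAGG", 2, "TACGTC", "T", "5:Del:R:1"),
)


def classification_consistency(seed: int = 0) -> dict:
    """Exhaustive SBS96 strand-collapse check and the ID83 golden set."""
    n_ok = 0
    n_total = 0
    for five, mid, three in itertools.product(BASES, repeat=3):
        tri = five + mid + three
        for alt in BASES:
            if alt == mid:
                continue
            n_total += 1
            if sbs_channel(tri, alt) == sbs_channel(revcomp(tri), COMPLEMENT[alt]):
                n_ok += 1
    id_ok = 0
    for seq, pos, ref, alt, expected in ID_GOLDEN:
        g = Genome({"chr1": seq})
        rec = MutationRecord("c", "chr1", pos, ref, alt)
        id_ok += classify_id(rec, g) == expected
    return {
        "sbs_consistent": n_ok,
        "sbs_total": n_total,
        "id_golden_correct": id_ok,
        "id_golden_total": len(ID_GOLDEN),
    }
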