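"""Truth-tagged synthetic data for the whole pipeline.

The generator emulates the statistical structure the downstream analyses
assume, with known parameters so every stage has a parameter-recovery test:

* an i.i.d.-base reference genome at a configurable GC fraction, with layered
  annotation tracks (genic structure, expression deciles, replication-timing
  and accessibility bins);
* a timed developmental lineage per subject: internal branches carry
  Poisson-distributed clonal mutations drawn from a developmental signature
  mixture, and each post-mitotic cell accumulates private mutations linearly
  in time from a distinct ageing mixture (clock-like accumulation);
* anatomical region labels (CH/V) assigned per clade with tunable
  intermixing; and
* detection thinning by depth class, mirroring deep (30X) and shallow (10X)
  single-cell genomes with different sensitivities and callable fractions.

Mutations are placed at genome positions whose trinucleotide (or homopolymer)
context is compatible with the drawn signature channel, so spectrum and
enrichment analyses see realistic context structure.  All randomness flows
from a single seed with per-subject substreams, making subject simulations
order-independent.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .channels import (
    BASES,
    COMPLEMENT,
    ID83_CHANNELS,
    SBS96_CHANNELS,
    channel_alt,
    channel_context,
    encode_bases,
)
from .enrichment import AnnotationTrack
from .genome import Genome
from .lineage import CladeNode, LineageTree
from .signatures import SignatureCatalog


class SimConfigError(ValueError):
    """A SimConfig field violates its invariant."""


# ---------------------------------------------------------------------------
# synthetic signature catalogs
# ---------------------------------------------------------------------------

_CATALOG_SEED = 714025  # fixed: catalogs are deterministic constants


def synthetic_sbs_catalog() -> SignatureCatalog:
    """Synthetic stand-in for a COSMIC-style SBS catalog.

    Signature ids follow the familiar naming so mixtures read naturally, but
    the columns are constructed here, not measured: ``SBS1`` concentrates on
    CpG C>T channels (deamination clock), ``SBS5`` is a flat ageing
    signature with a mild T>C tilt, and the remaining columns are seeded
    Dirichlet draws tilted toward one substitution class each.
    """
    rng = np.random.default_rng(_CATALOG_SEED)
    channels = list(SBS96_CHANNELS)
    cols = {}

    sbs1 = np.full(96, 0.15 / 92)
    for i, ch in enumerate(channels):
        if "[C>T]" in ch and ch.endswith("G"):
            sbs1[i] = 0.85 / 4
    cols["SBS1"] = sbs1

    sbs5 = np.array([2.0 if "[T>C]" in ch else 1.0 for ch in channels])
    cols["SBS5"] = sbs5 / sbs5.sum()

    tilts = {
        "SBS8": "[C>A]",
        "SBS16": "[T>C]",
        "SBS18": "[C>A]",
        "SBS19": "[C>T]",
        "SBS32": "[C>T]",
        "SBS40": "[T>A]",
        "SBS89": "[C>G]",
        "SBS94": "[T>G]",
    }
    for sig, cls in tilts.items():
        alpha = np.array([3.0 if cls in ch else 0.15 for ch in channels])
        cols[sig] = rng.dirichlet(alpha)

    mat = pd.DataFrame(cols, index=channels)
    return SignatureCatalog(mat / mat.sum(axis=0), "SBS96")


def synthetic_id_catalog() -> SignatureCatalog:
    """Synthetic ID83 catalog over the 1-bp homopolymer channels.

    ``ID1``: T insertions at long runs; ``ID2``: T deletions at long runs;
    ``ID5``: flat 1-bp background; ``ID9``: C deletions.  Mass is confined
    to channels the simulator can place on an i.i.d. genome.
    """
    channels = list(ID83_CHANNELS)
    idx = {c: i for i, c in enumerate(channels)}

    def col(weights: dict[str, float]) -> np.ndarray:
        v = np.zeros(83)
        for ch, w in weights.items():
            v[idx[ch]] = w
        return v / v.sum()

    cols = {
        "ID1": col({f"1:Ins:T:{k}": w for k, w in zip(range(6), (3, 6, 8, 5, 2, 1))}),
        "ID2": col({f"1:Del:T:{k}": w for k, w in zip(range(6), (3, 6, 8, 5, 2, 1))}),
        "ID5": col(
            {
                f"1:{kind}:{b}:{k}": 1.0
                for kind in ("Del", "Ins")
                for b in "CT"
                for k in range(4)
            }
        ),
        "ID9": col({f"1:Del:C:{k}": w for k, w in zip(range(5), (4, 6, 5, 3, 1))}),
    }
    return SignatureCatalog(pd.DataFrame(cols, index=channels), "ID83")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Generative parameters; defaults emulate the aged-cerebellum study design
    (granule-neuron rate ~27 sSNV/yr and ~1.9 sIndel/yr, postnatal clonal
    expansion, 30X/10X depth classes)."""

    seed: int = 0
    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.41
    n_subjects: int = 1
    subject_ages: tuple[float, ...] = (82.7,)
    cells_per_subject: int = 64
    #: (time_years, branching_factor) developmental divisions, zygote at t=0
    division_schedule: tuple[tuple[float, int], ...] = (
        (0.1, 3),
        (0.5, 2),
        (1.0, 2),
    )
    #: per-tip post-mitotic times; None = last division time, scalar = common,
    #: sequence = cycled over tips in order
    terminal_times: float | tuple[float, ...] | None = None
    clonal_mu: float = 60.0
    aging_rate: float = 27.0
    aging_intercept: float = 100.0
    dev_signature_mix: dict[str, float] = field(
        default_factory=lambda: {"SBS1": 0.7, "SBS5": 0.3}
    )
    aging_signature_mix: dict[str, float] = field(
        default_factory=lambda: {"SBS1": 0.10, "SBS5": 0.75, "SBS18": 0.15}
    )
    #: 0 = clades perfectly segregated CH vs V, 1 = labels i.i.d.
    region_mixing: float = 1.0
    detect_sensitivity: dict[str, float] = field(
        default_factory=lambda: {"30X": 0.95, "10X": 0.5}
    )
    callable_fraction: dict[str, float] = field(
        default_factory=lambda: {"30X": 0.8, "10X": 0.5}
    )
    depth_class_fractions: dict[str, float] = field(
        default_factory=lambda: {"30X": 1.0}
    )
    catalog: SignatureCatalog | None = None
    id_catalog: SignatureCatalog | None = None
    clonal_indel_mu: float = 4.0
    aging_indel_rate: float = 1.86
    aging_indel_intercept: float = 10.0
    dev_id_mix: dict[str, float] = field(
        default_factory=lambda: {"ID1": 0.5, "ID2": 0.5}
    )
    aging_id_mix: dict[str, float] = field(
        default_factory=lambda: {"ID2": 0.35, "ID5": 0.40, "ID9": 0.25}
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.gc_fraction < 1):
            raise SimConfigError(f"gc_fraction must be in (0,1), got {self.gc_fraction}")
        for name in ("dev_signature_mix", "aging_signature_mix", "dev_id_mix", "aging_id_mix"):
            mix = getattr(self, name)
            if mix and abs(sum(mix.values()) - 1) > 1e-9:
                raise SimConfigError(f"{name} must sum to 1")
            if mix and min(mix.values()) < 0:
                raise SimConfigError(f"{name} has negative entries")
        if len(self.subject_ages) != self.n_subjects:
            raise SimConfigError("subject_ages length must equal n_subjects")
        times = [t for t, _ in self.division_schedule]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise SimConfigError("division_schedule times must be strictly increasing")
        if times and (min(times) < 0 or max(times) > min(self.subject_ages)):
            raise SimConfigError("division times must be in [0, subject age]")
        for name in ("detect_sensitivity",):
            for k, v in getattr(self, name).items():
                if not (0 < v <= 1):
                    raise SimConfigError(f"{name}[{k}] must be in (0,1], got {v}")
        for k, v in self.callable_fraction.items():
            if not (0 < v <= 1):
                raise SimConfigError(f"callable_fraction[{k}] must be in (0,1], got {v}")
        if not (0 <= self.region_mixing <= 1):
            raise SimConfigError("region_mixing must be in [0,1]")

    def sbs_catalog(self) -> SignatureCatalog:
        return self.catalog if self.catalog is not None else synthetic_sbs_catalog()

    def indel_catalog(self) -> SignatureCatalog:
        return self.id_catalog if self.id_catalog is not None else synthetic_id_catalog()

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d.pop("catalog", None)
        d.pop("id_catalog", None)
        return d


# ---------------------------------------------------------------------------
# genome + tracks
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    genome: Genome
    tracks: dict[str, AnnotationTrack]
    genes: pd.DataFrame  # chrom, start, end, gene_id, expression


def simulate_genome(config: SimConfig) -> SyntheticGenome:
    """Random i.i.d.-base genome at the configured GC plus annotation layers.

    Layers: ``genic`` (genic/intergenic partition), ``genic_detail``
    (utr5/exon/intron/utr3/intergenic partition), ``expression`` (gene
    deciles), ``replication_timing`` and ``accessibility`` (window quantile
    bins tiling the genome).
    """
    if config.genome_length < 1e5:
        raise SimConfigError("genome_length must be >= 1e5")
    rng = np.random.default_rng([config.seed, 1])
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    per = config.genome_length // config.n_chromosomes
    lengths = [per] * config.n_chromosomes
    lengths[-1] += config.genome_length - per * config.n_chromosomes
    seqs = {}
    for i, L in enumerate(lengths):
        codes = rng.choice(4, size=L, p=p)
        seqs[f"chr{i + 1}"] = "".join(np.array(list(BASES))[codes])
    genome = Genome(seqs)

    genic_rows, detail_rows, gene_rows = [], [], []
    gid = 0
    for chrom, L in zip(genome.contigs, lengths):
        pos = 0
        while pos < L:
            gap = int(rng.integers(2000, 8001))
            end_gap = min(pos + gap, L)
            genic_rows.append((chrom, pos, end_gap, "intergenic"))
            detail_rows.append((chrom, pos, end_gap, "intergenic"))
            pos = end_gap
            if pos >= L:
                break
            glen = int(rng.integers(3000, 12001))
            gend = min(pos + glen, L)
            genic_rows.append((chrom, pos, gend, "genic"))
            gene_rows.append(
                {
                    "chrom": chrom,
                    "start": pos,
                    "end": gend,
                    "gene_id": f"G{gid:04d}",
                    "expression": float(rng.lognormal(0.0, 1.0)),
                }
            )
            gid += 1
            # internal gene structure: utr5 / alternating exon-intron / utr3
            q = pos
            u5 = min(q + 200, gend)
            detail_rows.append((chrom, q, u5, "utr5"))
            q = u5
            exon = True
            while q < max(gend - 300, q):
                step = 300 if exon else int(rng.integers(500, 2001))
                nxt = min(q + step, gend - 300)
                if nxt <= q:
                    break
                detail_rows.append((chrom, q, nxt, "exon" if exon else "intron"))
                exon = not exon
                q = nxt
            if q < gend:
                detail_rows.append((chrom, q, gend, "utr3"))
            pos = gend

    tracks = {
        "genic": AnnotationTrack(
            "genic", pd.DataFrame(genic_rows, columns=["chrom", "start", "end", "label"])
        ),
        "genic_detail": AnnotationTrack(
            "genic_detail",
            pd.DataFrame(detail_rows, columns=["chrom", "start", "end", "label"]),
        ),
    }
    genes = pd.DataFrame(gene_rows)
    if len(genes) >= 10:
        deciles = pd.qcut(genes["expression"], 10, labels=False, duplicates="drop")
        rows = [
            (g.chrom, g.start, g.end, f"dec{int(d) + 1:02d}")
            for g, d in zip(genes.itertuples(), deciles)
        ]
        tracks["expression"] = AnnotationTrack(
            "expression",
            pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]),
            layer="quantile",
            bins=tuple(f"dec{i + 1:02d}" for i in range(int(deciles.max()) + 1)),
        )

    for name, window, nbins, smooth in (
        ("replication_timing", 20_000, 5, True),
        ("accessibility", 10_000, 5, False),
    ):
        rows, vals = [], []
        for chrom, L in zip(genome.contigs, lengths):
            starts = np.arange(0, L, window)
            v = rng.normal(size=len(starts))
            if smooth:
                v = np.convolve(v, np.ones(5) / 5, mode="same")
            for s, x in zip(starts, v):
                rows.append((chrom, int(s), int(min(s + window, L))))
                vals.append(x)
        q = pd.qcut(pd.Series(vals), nbins, labels=False, duplicates="drop")
        bins = tuple(f"q{i + 1}" for i in range(int(q.max()) + 1))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["label"] = [bins[int(i)] for i in q]
        tracks[name] = AnnotationTrack(name, df, layer="quantile", bins=bins)

    for t in tracks.values():
        t.validate(genome)
    return SyntheticGenome(genome=genome, tracks=tracks, genes=genes)


# ---------------------------------------------------------------------------
# signature-aware placement
# ---------------------------------------------------------------------------

def _base_codes_global(genome: Genome) -> np.ndarray:
    cache = getattr(genome, "_somaclock_base_codes", None)
    if cache is None:
        cache = np.concatenate(
            [encode_bases(genome.sequences[c]) for c in genome.contigs]
        )
        genome._somaclock_base_codes = cache
    return cache


def _place_snvs(channels: np.ndarray, genome: Genome, rng: np.random.Generator):
    """Sample one distinct genome site per draw, context-compatible per channel."""
    pools = genome.positions_by_context()
    codes = _base_codes_global(genome)
    n = len(channels)
    gpos = np.empty(n, dtype=np.int64)
    refs = np.empty(n, dtype=object)
    alts = np.empty(n, dtype=object)
    for ch in np.unique(channels):
        idx = np.flatnonzero(channels == ch)
        ctx, alt_py = channel_context(ch), channel_alt(ch)
        pool = pools[ctx]
        if len(idx) > len(pool):
            raise RuntimeError(
                f"genome has only {len(pool)} sites with context {ctx}; "
                f"{len(idx)} requested — increase genome_length"
            )
        take = pool[rng.choice(len(pool), size=len(idx), replace=False)]
        gpos[idx] = take
        purine = np.isin(codes[take], (0, 2))  # A or G reference base
        refs[idx] = np.where(purine, COMPLEMENT[ctx[1]], ctx[1])
        alts[idx] = np.where(purine, COMPLEMENT[alt_py], alt_py)
    chroms, pos = genome.from_global(gpos)
    return chroms, pos, refs, alts


def _homopolymer_pools(genome: Genome) -> dict[str, list[tuple[int, str]]]:
    """Candidate events per 1-bp ID83 channel: (0-based anchor gpos, event base).

    Deletions remove the base after the anchor (the first base of a run);
    insertions add the event base after the anchor.  The ``...:0`` insertion
    channels anchor inside a run of a *different* base, so the inserted base
    has no like neighbour.
    """
    cache = getattr(genome, "_somaclock_hp_pools", None)
    if cache is not None:
        return cache
    pools: dict[str, list] = {c: [] for c in ID83_CHANNELS if c.startswith("1:")}
    for chrom in genome.contigs:
        seq = genome.sequences[chrom]
        codes = encode_bases(seq)
        off = genome.to_global(chrom, 1)
        change = np.flatnonzero(np.diff(codes)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(seq)]])
        for s, e in zip(starts, ends):
            s, e = int(s), int(e)
            if s == 0 or e >= len(seq):
                continue
            base = seq[s]
            motif = base if base in "CT" else COMPLEMENT[base]
            rl = e - s
            pools[f"1:Del:{motif}:{min(rl - 1, 5)}"].append((off + s - 1, base))
            if rl >= 1:
                pools[f"1:Ins:{motif}:{min(rl, 5)}"].append((off + s - 1, base))
            if rl >= 2:
                # anchor at the run's first base: both neighbours == base
                for m in ("C", "T"):
                    if m != base:
                        pools[f"1:Ins:{m}:0"].append((off + s, m))
    genome._somaclock_hp_pools = pools
    return pools


def _place_indels(channels: np.ndarray, genome: Genome, rng: np.random.Generator):
    """Place 1-bp homopolymer indel channels; returns chrom/pos/ref/alt arrays."""
    pools = _homopolymer_pools(genome)
    n = len(channels)
    gpos = np.empty(n, dtype=np.int64)
    refs = np.empty(n, dtype=object)
    alts = np.empty(n, dtype=object)
    for ch in np.unique(channels):
        idx = np.flatnonzero(channels == ch)
        pool = pools.get(ch)
        if not pool:
            raise RuntimeError(f"no placement pool for indel channel {ch}")
        if len(idx) > len(pool):
            raise RuntimeError(
                f"only {len(pool)} sites support channel {ch}; {len(idx)} requested"
            )
        picks = rng.choice(len(pool), size=len(idx), replace=False)
        _, kind, _, _ = ch.split(":")
        for i, pk in zip(idx, picks):
            anchor_gpos, base = pool[pk]
            chrom, pos = genome.from_global(anchor_gpos)
            anchor = genome.base(chrom, pos)
            gpos[i] = anchor_gpos
            if kind == "Del":
                refs[i] = anchor + base
                alts[i] = anchor
            else:
                refs[i] = anchor
                alts[i] = anchor + base
    chroms, pos = genome.from_global(gpos)
    return chroms, pos, refs, alts


def _draw_channels(
    n: int,
    mix: dict[str, float],
    catalog: SignatureCatalog,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (signature, channel) pairs from a signature mixture."""
    sigs = sorted(mix)
    probs = np.array([mix[s] for s in sigs])
    sig_idx = rng.choice(len(sigs), size=n, p=probs)
    channels = np.empty(n, dtype=object)
    signatures = np.empty(n, dtype=object)
    chan_names = np.array(catalog.matrix.index, dtype=object)
    for i, s in enumerate(sigs):
        sel = np.flatnonzero(sig_idx == i)
        if len(sel):
            col = catalog.column(s)
            channels[sel] = chan_names[rng.choice(len(col), size=len(sel), p=col)]
            signatures[sel] = s
    return signatures, channels


# ---------------------------------------------------------------------------
# lineage simulation
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    """Ground truth for one subject's simulated lineage."""

    subject: str
    age: float
    tree: LineageTree  # node.time = years from zygote; leaves carry private keys
    variants: pd.DataFrame  # chrom,pos,ref,alt,kind,channel,signature,node_id,origin,cell_id
    region_labels: dict[str, str]
    terminal_times: dict[str, float]  # per cell
    config: SimConfig

    @property
    def cells(self) -> list[str]:
        return sorted(self.region_labels)

    @property
    def true_private_counts(self) -> dict[str, int]:
        priv = self.variants[self.variants["origin"] == "private"]
        counts = priv.groupby("cell_id").size().to_dict()
        return {c: int(counts.get(c, 0)) for c in self.cells}

    def carriers(self) -> dict[tuple, frozenset]:
        """Variant key -> carrying cells (from the truth tree)."""
        node_cells = {n.id: n.cells for n in self.tree.nodes()}
        out = {}
        for row in self.variants.itertuples():
            key = (row.chrom, int(row.pos), row.ref, row.alt)
            out[key] = frozenset(node_cells[row.node_id])
        return out

    def cell_variant_keys(self, cell: str) -> list[tuple]:
        car = self.carriers()
        return [k for k, cs in car.items() if cell in cs]

    def true_mrca_time(self, node: CladeNode) -> float:
        """Mean post-mitotic time of the node's cells — the quantity the
        private-burden clock estimates."""
        return float(np.mean([self.terminal_times[c] for c in sorted(node.cells)]))


def simulate_lineage(
    config: SimConfig, subject: int = 0, genome: Genome | None = None
) -> TruthSet:
    """Simulate one subject's lineage, mutations and region labels.

    Randomness uses a substream keyed by (seed, subject), so subjects are
    independent and order-invariant.  ``genome`` defaults to
    ``simulate_genome(config).genome``.
    """
    if genome is None:
        genome = simulate_genome(config).genome
    age = config.subject_ages[subject]
    rng = np.random.default_rng([config.seed, 100 + subject])
    subj_id = f"s{subject}"

    # -- topology ----------------------------------------------------------
    counter = [0]

    def new_node(cells=frozenset(), time=None):
        counter[0] += 1
        return CladeNode(id=f"{subj_id}_n{counter[0]}", cells=cells, time=time)

    root = new_node(time=0.0)
    tips = [root]
    for t, k in config.division_schedule:
        new_tips = []
        for tip in tips:
            for _ in range(int(k)):
                child = new_node(time=float(t))
                tip.children.append(child)
                new_tips.append(child)
        tips = new_tips
    if len(tips) > config.cells_per_subject:
        raise SimConfigError(
            "division_schedule produces more tips than cells_per_subject"
        )

    cells = [f"{subj_id}_c{i:03d}" for i in range(config.cells_per_subject)]
    tip_of_cell = {c: tips[i % len(tips)] for i, c in enumerate(cells)}

    last_div = config.division_schedule[-1][0] if config.division_schedule else 0.0
    tt = config.terminal_times
    if tt is None:
        tip_terminal = {id(t): last_div for t in tips}
    elif np.isscalar(tt):
        tip_terminal = {id(t): float(tt) for t in tips}
    else:
        tip_terminal = {id(t): float(tt[i % len(tt)]) for i, t in enumerate(tips)}
    for t in tips:
        if tip_terminal[id(t)] < (t.time or 0.0):
            raise SimConfigError("terminal_times must be >= the tip's division time")

    leaves_of = {}
    terminal_times: dict[str, float] = {}
    for cell in cells:
        tip = tip_of_cell[cell]
        term = tip_terminal[id(tip)]
        if config.aging_intercept + config.aging_rate * (age - term) < 0:
            raise SimConfigError(
                f"terminal time {term} exceeds subject age {age} "
                "(negative expected private count)"
            )
        leaf = CladeNode(id=f"leaf_{cell}", cells=frozenset([cell]), time=term)
        tip.children.append(leaf)
        leaves_of[cell] = leaf
        terminal_times[cell] = term

    def fill_cells(node: CladeNode) -> frozenset:
        if node.is_leaf:
            return node.cells
        got = frozenset().union(*(fill_cells(c) for c in node.children))
        node.cells = got
        return got

    fill_cells(root)
    # prune tips that received no cells
    def prune(node: CladeNode) -> None:
        node.children = [c for c in node.children if c.cells]
        for c in node.children:
            prune(c)

    prune(root)
    tree = LineageTree(root)

    # -- region labels -----------------------------------------------------
    labels: dict[str, str] = {}
    top = root.children if root.children else [root]
    for i, clade in enumerate(top):
        base = "CH" if i % 2 == 0 else "V"
        for cell in clade.cells:
            labels[cell] = base
    flip = rng.random(len(cells)) < config.region_mixing / 2
    for cell, fl in zip(cells, flip):
        if fl:
            labels[cell] = "V" if labels[cell] == "CH" else "CH"

    # -- mutation counts ---------------------------------------------------
    sbs_cat, id_cat = config.sbs_catalog(), config.indel_catalog()
    draws = []  # (node_id, origin, cell_id, kind, n, mix, catalog)
    for node in tree.nodes():
        if node is root or node.is_leaf:
            continue
        draws.append((node.id, "shared", "", "SNV", rng.poisson(config.clonal_mu)))
        draws.append(
            (node.id, "shared", "", "ID", rng.poisson(config.clonal_indel_mu))
        )
    for cell in cells:
        dt = age - terminal_times[cell]
        lam = config.aging_intercept + config.aging_rate * dt
        draws.append((f"leaf_{cell}", "private", cell, "SNV", rng.poisson(lam)))
        lam_id = config.aging_indel_intercept + config.aging_indel_rate * dt
        if lam_id > 0:
            draws.append(
                (f"leaf_{cell}", "private", cell, "ID", rng.poisson(max(lam_id, 0)))
            )

    frames = []
    for kind in ("SNV", "ID"):
        rows_meta = []
        for node_id, origin, cell_id, k, n in draws:
            if k != kind or n == 0:
                continue
            mix = (
                (config.dev_signature_mix if kind == "SNV" else config.dev_id_mix)
                if origin == "shared"
                else (config.aging_signature_mix if kind == "SNV" else config.aging_id_mix)
            )
            rows_meta.append((node_id, origin, cell_id, n, frozenset(mix.items())))
        if not rows_meta:
            continue
        # draw channels per distinct mixture, then place everything at once
        sig_all = np.empty(sum(r[3] for r in rows_meta), dtype=object)
        chan_all = np.empty_like(sig_all)
        offset = 0
        catalog = sbs_cat if kind == "SNV" else id_cat
        spans = []
        for node_id, origin, cell_id, n, mix_items in rows_meta:
            mix = dict(mix_items)
            if not mix:
                raise SimConfigError("empty signature mixture with nonzero counts")
            s, c = _draw_channels(n, mix, catalog, rng)
            sig_all[offset : offset + n] = s
            chan_all[offset : offset + n] = c
            spans.append((node_id, origin, cell_id, offset, n))
            offset += n
        if kind == "SNV":
            chroms, pos, refs, alts = _place_snvs(chan_all, genome, rng)
        else:
            chroms, pos, refs, alts = _place_indels(chan_all, genome, rng)
        df = pd.DataFrame(
            {
                "chrom": chroms,
                "pos": pos.astype(int),
                "ref": refs,
                "alt": alts,
                "kind": np.where(
                    [len(r) > len(a) for r, a in zip(refs, alts)], "DEL", "INS"
                )
                if kind == "ID"
                else "SNV",
                "channel": chan_all,
                "signature": sig_all,
            }
        )
        df["node_id"] = ""
        df["origin"] = ""
        df["cell_id"] = ""
        for node_id, origin, cell_id, off, n in spans:
            df.loc[off : off + n - 1, ["node_id", "origin", "cell_id"]] = (
                node_id,
                origin,
                cell_id,
            )
        frames.append(df)

    variants = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns="chrom pos ref alt kind channel signature node_id origin cell_id".split()
        )
    )

    # record branch variant keys on the tree
    by_node = variants.groupby("node_id")
    node_index = {n.id: n for n in tree.nodes()}
    for node_id, sub in by_node:
        if node_id in node_index:
            node_index[node_id].variants = list(
                zip(sub["chrom"], sub["pos"], sub["ref"], sub["alt"])
            )

    return TruthSet(
        subject=subj_id,
        age=age,
        tree=tree,
        variants=variants,
        region_labels=labels,
        terminal_times=terminal_times,
        config=copy.deepcopy(config),
    )


# ---------------------------------------------------------------------------
# call emission
# ---------------------------------------------------------------------------

@dataclass
class EmittedCalls:
    """Detection-thinned per-cell calls plus metadata and bulk tables."""

    calls: pd.DataFrame  # cell_id + variant columns (one row per surviving call)
    metadata: pd.DataFrame  # cell_id, subject_id, age_years, region, depth_class, callable_fraction
    bulk: pd.DataFrame  # clonal variants carried by >=2 surviving cells

    def cell_variant_keys(self) -> dict[str, list[tuple]]:
        out: dict[str, list[tuple]] = {
            c: [] for c in self.metadata["cell_id"]
        }
        for row in self.calls.itertuples():
            out[row.cell_id].append((row.chrom, int(row.pos), row.ref, row.alt))
        return out


def emit_calls(
    truth: TruthSet, config: SimConfig | None = None, genome: Genome | None = None
) -> EmittedCalls:
    """Thin the truth by depth-dependent detection and build output tables.

    Each cell's variants survive independently with probability
    ``detect_sensitivity[depth] × callable_fraction[depth]``; dividing the
    surviving count by the callable fraction therefore recovers the true
    burden (in expectation) at sensitivity 1.  The bulk clonal table holds
    every ancestral-branch variant still carried by >= 2 surviving cells.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 200, int(truth.subject[1:])])
    cells = truth.cells
    if genome is not None:
        _check_refs(truth.variants, genome)

    # depth classes: deterministic proportional assignment in cell order
    classes = list(config.depth_class_fractions)
    fracs = np.array([config.depth_class_fractions[c] for c in classes])
    bounds = np.floor(np.cumsum(fracs) * len(cells)).astype(int)
    depth_of = {}
    j = 0
    for i, cell in enumerate(cells):
        while j < len(classes) - 1 and i >= bounds[j]:
            j += 1
        depth_of[cell] = classes[j]

    # expand truth to (cell, variant) pairs via the tree, then thin per cell
    node_cells = {n.id: sorted(n.cells) for n in truth.tree.nodes()}
    keys_by_cell: dict[str, list[tuple]] = {c: [] for c in cells}
    for row in truth.variants.itertuples():
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        for cell in node_cells[row.node_id]:
            keys_by_cell[cell].append(key)
    rows = []
    for cell in cells:
        dc = depth_of[cell]
        p_keep = config.detect_sensitivity[dc] * config.callable_fraction[dc]
        keys = keys_by_cell[cell]
        keep = rng.random(len(keys)) <= p_keep
        for key, kp in zip(keys, keep):
            if kp:
                rows.append((cell, *key))
    calls = pd.DataFrame(rows, columns=["cell_id", "chrom", "pos", "ref", "alt"])

    meta = pd.DataFrame(
        {
            "cell_id": cells,
            "subject_id": truth.subject,
            "age_years": truth.age,
            "region": [truth.region_labels[c] for c in cells],
            "depth_class": [depth_of[c] for c in cells],
            "callable_fraction": [
                config.callable_fraction[depth_of[c]] for c in cells
            ],
        }
    )

    shared_keys = {
        (r.chrom, int(r.pos), r.ref, r.alt)
        for r in truth.variants[truth.variants["origin"] == "shared"].itertuples()
    }
    if len(calls):
        counts = calls.groupby(["chrom", "pos", "ref", "alt"]).size()
        bulk_keys = [
            k for k in shared_keys if counts.get(k, 0) >= 2
        ]
    else:
        bulk_keys = []
    bulk = pd.DataFrame(
        sorted(bulk_keys), columns=["chrom", "pos", "ref", "alt"]
    )
    return EmittedCalls(calls=calls, metadata=meta, bulk=bulk)


def _check_refs(variants: pd.DataFrame, genome: Genome) -> None:
    for row in variants.itertuples():
        got = genome.fetch(row.chrom, int(row.pos), int(row.pos) + len(row.ref) - 1)
        if got != row.ref:
            raise AssertionError(
                f"simulated REF mismatches genome at {row.chrom}:{row.pos} "
                f"({row.ref!r} vs {got!r})"
            )


# ---------------------------------------------------------------------------
# biased placement helper (for enrichment power/null experiments)
# ---------------------------------------------------------------------------

def track_position_weights(
    genome: Genome, track: AnnotationTrack, multipliers: dict[str, float]
) -> np.ndarray:
    """Per-global-position placement weight from class multipliers."""
    codes, labels = track.label_codes(genome)
    mult = np.array([multipliers.get(l, 1.0) for l in labels])
    w = np.where(codes >= 0, mult[np.clip(codes, 0, None)], 0.0)
    return w


def sample_positions(
    genome: Genome,
    n: int,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Sample n global positions, optionally with per-position weights."""
    if weights is None:
        return rng.integers(0, genome.length, size=n)
    p = weights / weights.sum()
    return rng.choice(genome.length, size=n, replace=False, p=p)
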