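"""Readers and writers for the external formats.

Variants travel as VCF v4.2 (1-based, one file per cell), annotations as BED
(0-based half-open) or bedGraph, metadata as TSV, trees as Newick.  All
coordinate conversions happen here: internally variants are 1-based and
intervals 0-based half-open.  Run manifests record versions, seeds,
parameters and input checksums for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .burden import CellProfile
from .enrichment import AnnotationTrack
from .genome import Genome
from .lineage import CladeNode, LineageTree
from .spectra import MutationRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _match_contig(chrom: str, genome: Genome | None) -> str:
    """Normalise 'chr' prefixes against the reference's contig names."""
    if genome is None:
        return chrom
    if chrom in genome.sequences:
        return chrom
    alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
    if alt in genome.sequences:
        return alt
    return chrom


def read_cell_vcf(
    path,
    cell_id: str | None = None,
    genome: Genome | None = None,
    pass_only: bool = True,
) -> list[MutationRecord]:
    """Read one cell's somatic calls into MutationRecords.

    Multi-allelic records are split; records failing FILTER (unless
    ``pass_only=False``) and records whose REF contradicts the supplied
    reference are excluded with a logged count.
    """
    path = str(path)
    cell = cell_id or Path(path).stem.replace(".vcf", "")
    records: list[MutationRecord] = []
    n_filtered = n_ref_mismatch = 0
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            filters = list(rec.filter.keys())
            if pass_only and filters and filters != ["PASS"]:
                n_filtered += 1
                continue
            chrom = _match_contig(rec.chrom, genome)
            for alt in rec.alts or ():
                if alt is None or set(rec.ref + alt) - set("ACGTN"):
                    continue
                if genome is not None:
                    got = genome.fetch(chrom, rec.pos, rec.pos + len(rec.ref) - 1)
                    if got != rec.ref:
                        n_ref_mismatch += 1
                        logger.warning(
                            "REF mismatch at %s:%d (%s vs genome %s); excluded",
                            chrom, rec.pos, rec.ref, got,
                        )
                        continue
                records.append(
                    MutationRecord(
                        cell_id=cell, chrom=chrom, pos=rec.pos, ref=rec.ref, alt=alt
                    )
                )
    if n_filtered or n_ref_mismatch:
        logger.info(
            "%s: %d non-PASS and %d REF-mismatch records excluded",
            path, n_filtered, n_ref_mismatch,
        )
    return records


def write_cell_vcf(path, calls: pd.DataFrame, genome: Genome, sample: str) -> None:
    """Write one cell's calls (chrom/pos/ref/alt frame) as VCF v4.2."""
    header = pysam.VariantHeader()
    for contig in genome.contigs:
        header.contigs.add(contig, length=genome.contig_length(contig))
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    calls = calls.sort_values(["chrom", "pos"])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in calls.itertuples():
            rec = out.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                alleles=(row.ref, row.alt),
                filter="PASS",
            )
            rec.samples[sample]["GT"] = (0, 1)
            out.write(rec)


# ---------------------------------------------------------------------------
# BED / bedGraph tracks
# ---------------------------------------------------------------------------

def read_bed_track(
    path, name: str | None = None, layer: str = "partition",
    bins: tuple[str, ...] | None = None, genome: Genome | None = None,
) -> AnnotationTrack:
    """4-column BED (chrom, start, end, label), 0-based half-open."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "label"],
        dtype={"chrom": str, "start": int, "end": int, "label": str},
    )
    track = AnnotationTrack(
        name or Path(str(path)).stem, df, layer=layer, bins=bins
    )
    if genome is not None:
        track.validate(genome)
    return track


def read_bedgraph_quantiles(
    path, name: str, n_bins: int = 5, genome: Genome | None = None
) -> AnnotationTrack:
    """Bin a bedGraph's values into ordered quantile classes on load."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    q = pd.qcut(df["value"], n_bins, labels=False, duplicates="drop")
    bins = tuple(f"q{i + 1}" for i in range(int(q.max()) + 1))
    df["label"] = [bins[int(i)] for i in q]
    track = AnnotationTrack(
        name, df[["chrom", "start", "end", "label"]], layer="quantile", bins=bins
    )
    if genome is not None:
        track.validate(genome)
    return track


def write_track_bed(track: AnnotationTrack, path) -> None:
    track.intervals.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Cell metadata TSV indexed by cell_id."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "subject_id": str})
    required = {"cell_id", "subject_id", "age_years"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    return df.set_index("cell_id", drop=False)


def profiles_from_metadata(
    meta: pd.DataFrame,
    snv_counts: dict[str, int],
    indel_counts: dict[str, int] | None = None,
) -> list[CellProfile]:
    profiles = []
    for row in meta.itertuples():
        profiles.append(
            CellProfile(
                cell_id=row.cell_id,
                subject_id=row.subject_id,
                age=float(row.age_years),
                celltype=getattr(row, "celltype", "GN"),
                region=getattr(row, "region", "other"),
                depth_class=getattr(row, "depth_class", "30X"),
                callable_fraction=float(getattr(row, "callable_fraction", 1.0)),
                n_calls_snv=int(snv_counts.get(row.cell_id, 0)),
                n_calls_indel=int((indel_counts or {}).get(row.cell_id, 0)),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def write_newick(tree: LineageTree, path, annotate: bool = False) -> None:
    Path(path).write_text(tree.newick(annotate=annotate) + "\n")


def read_newick(path) -> LineageTree:
    """Rebuild a LineageTree (topology + integer branch lengths) from Newick."""
    import dendropy

    dtree = dendropy.Tree.get(path=str(path), schema="newick")
    counter = [0]

    def convert(dnode) -> CladeNode:
        if dnode.is_leaf():
            cell = dnode.taxon.label.replace(" ", "_")
            node = CladeNode(id=f"leaf_{cell}", cells=frozenset([cell]))
        else:
            counter[0] += 1
            node = CladeNode(id=dnode.label or f"n{counter[0]}", cells=frozenset())
            for ch in dnode.child_nodes():
                node.children.append(convert(ch))
            node.cells = frozenset().union(*(c.cells for c in node.children))
        length = int(round(dnode.edge.length or 0))
        node.variants = [("branch", node.id, i, "") for i in range(length)]
        return node

    return LineageTree(convert(dtree.seed_node))


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path, stage: str, params: dict, seeds: dict | None = None,
    inputs: list | None = None, counters: dict | None = None,
) -> dict:
    """JSON run manifest: versions, seeds, parameters, input checksums."""
    from . import __version__

    from datetime import datetime, timezone

    manifest = {
        "created": datetime.now(timezone.utc).isoformat(),
        "stage": stage,
        "somaclock_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "params": params,
        "seeds": seeds or {},
        "inputs": {str(p): file_checksum(p) for p in (inputs or [])},
        "counters": counters or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
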