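"""Mutation records, SBS96/ID83 classification and spectrum arithmetic.

Somatic single-nucleotide variants are classified into the 96 pyrimidine-
centred trinucleotide channels; somatic insertions/deletions into the 83
COSMIC indel channels (1-bp events by homopolymer context, longer events by
tandem-repeat count, deletions additionally by flanking microhomology).
Spectra are plain count vectors in the canonical channel orders defined in
:mod:`somaclock.channels`; similarity between spectra is the cosine of the
count vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import (
    COMPLEMENT,
    ID83_CHANNELS,
    ID83_INDEX,
    SBS96_CHANNELS,
    SBS96_INDEX,
    sbs_channel,
)
from .genome import Genome

UNCLASSIFIABLE = "unclassifiable"

_VALID = set("ACGT")


@dataclass
class MutationRecord:
    """A single somatic variant call in one cell.

    Positions are 1-based; ``kind`` is derived from the alleles.  ``channel``
    is filled by classification, ``annotations`` by the enrichment module and
    ``origin`` (shared vs private) by the lineage module.
    """

    cell_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    channel: str | None = None
    annotations: dict = field(default_factory=dict)
    origin: str = "unassigned"

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def key(self) -> tuple:
        """Variant identity: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class Spectrum:
    """Channel-count vector for one sample or group."""

    counts: np.ndarray
    kind: str  # "SBS96" | "ID83"
    label: str = ""

    def __post_init__(self) -> None:
        channels = self.channels
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(channels),):
            raise ValueError(
                f"{self.kind} spectrum needs {len(channels)} channels, "
                f"got shape {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative channel counts")

    @property
    def channels(self) -> tuple[str, ...]:
        if self.kind == "SBS96":
            return SBS96_CHANNELS
        if self.kind == "ID83":
            return ID83_CHANNELS
        raise ValueError(f"unknown spectrum kind {self.kind!r}")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalise an empty spectrum")
        return self.counts / self.total

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(self.channels), name=self.label)

    def __add__(self, other: "Spectrum") -> "Spectrum":
        if other.kind != self.kind:
            raise ValueError("cannot add spectra of different kinds")
        return Spectrum(self.counts + other.counts, self.kind, self.label)


# ---------------------------------------------------------------------------
# SBS classification
# ---------------------------------------------------------------------------

def classify_sbs(record: MutationRecord, genome: Genome) -> str:
    """SBS96 channel of an SNV, collapsing purine references to the pyrimidine strand."""
    if record.kind != "SNV":
        raise ValueError(f"{record.key} is not an SNV")
    tri = genome.context(record.chrom, record.pos)  # raises at contig boundary
    if tri[1] != record.ref:
        raise ValueError(
            f"REF mismatch at {record.chrom}:{record.pos}: "
            f"record {record.ref}, genome {tri[1]}"
        )
    channel = sbs_channel(tri, record.alt)
    record.channel = channel
    return channel


# ---------------------------------------------------------------------------
# indel normalisation and ID83 classification
# ---------------------------------------------------------------------------

def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return pos, ref, alt


def normalize_indel(
    record: MutationRecord, genome: Genome
) -> tuple[int, str, str] | None:
    """Parsimonious, left-aligned representation (pos, ref, alt) of an indel.

    Returns ``None`` for complex events that are neither a pure insertion nor
    a pure deletion after trimming.
    """
    pos, ref, alt = _trim(record.pos, record.ref, record.alt)
    if not (set(ref) <= _VALID and set(alt) <= _VALID):
        return None
    if len(ref) > 1 and len(alt) > 1:
        return None  # complex substitution
    if len(ref) == len(alt):
        return None  # SNV slipped through
    seq = genome.sequences[record.chrom]
    if len(ref) > 1:  # deletion; event starts at 0-based s
        if ref[0] != alt[0]:
            return None
        s, dele = pos, ref[1:]  # 0-based: anchor at pos-1, event at pos..pos+L-1
        L = len(dele)
        if seq[s : s + L] != dele:
            raise ValueError(
                f"REF mismatch for deletion at {record.chrom}:{record.pos}"
            )
        while s > 1 and seq[s - 1] == seq[s + L - 1]:
            s -= 1
        new_pos = s  # 1-based anchor position = s (0-based s-1)
        ref_n = seq[s - 1 : s + L]
        return new_pos, ref_n, ref_n[0]
    else:  # insertion
        if ref[0] != alt[0]:
            return None
        ins = alt[1:]
        s = pos  # inserted before 0-based position s
        while s > 1 and ins[-1] == seq[s - 1]:
            ins = seq[s - 1] + ins[:-1]
            s -= 1
        return s, seq[s - 1], seq[s - 1] + ins


def _run_length(seq: str, start: int, base: str) -> int:
    n = 0
    while start + n < len(seq) and seq[start + n] == base:
        n += 1
    return n


def _repeat_count(seq: str, start: int, unit: str) -> int:
    L, n = len(unit), 0
    while seq[start + n * L : start + (n + 1) * L] == unit:
        n += 1
    return n


def classify_id(record: MutationRecord, genome: Genome) -> str:
    """ID83 channel of an insertion/deletion.

    The record is internally trimmed and left-aligned first, so VCF dialect
    differences in anchor placement do not change the channel.  Complex
    events return the ``"unclassifiable"`` sentinel.
    """
    norm = normalize_indel(record, genome)
    if norm is None:
        record.channel = UNCLASSIFIABLE
        return UNCLASSIFIABLE
    pos, ref, alt = norm
    seq = genome.sequences[record.chrom]
    s = pos  # 0-based start of the event (first deleted base / insertion point)
    if len(ref) > len(alt):  # deletion
        dele = ref[1:]
        L = len(dele)
        if L == 1:
            base = dele
            run = _run_length(seq, s, base)
            motif = base if base in "CT" else COMPLEMENT[base]
            return _set(record, f"1:Del:{motif}:{min(run - 1, 5)}")
        rep = _repeat_count(seq, s + L, dele)
        if rep >= 1:
            return _set(record, f"{min(L, 5)}:Del:R:{min(rep, 5)}")
        # microhomology between the deleted sequence and its flanks
        mh = 0
        for k in range(min(L - 1, 5), 0, -1):
            if seq[s + L : s + L + k] == dele[:k]:
                mh = k
                break
        if mh == 0:
            for k in range(min(L - 1, 5), 0, -1):
                if s - k >= 0 and seq[s - k : s] == dele[L - k :]:
                    mh = k
                    break
        if mh >= 1:
            return _set(record, f"{min(L, 5)}:Del:M:{mh}")
        return _set(record, f"{min(L, 5)}:Del:R:0")
    else:  # insertion
        ins = alt[1:]
        L = len(ins)
        if L == 1:
            base = ins
            run = _run_length(seq, s, base)
            motif = base if base in "CT" else COMPLEMENT[base]
            return _set(record, f"1:Ins:{motif}:{min(run, 5)}")
        rep = _repeat_count(seq, s, ins)
        return _set(record, f"{min(L, 5)}:Ins:R:{min(rep, 5)}")


def _set(record: MutationRecord, channel: str) -> str:
    record.channel = channel
    return channel


def classify_records(records: list[MutationRecord], genome: Genome) -> int:
    """Classify every record in place; returns the number left unclassifiable."""
    n_bad = 0
    for rec in records:
        if rec.kind == "SNV":
            classify_sbs(rec, genome)
        else:
            if classify_id(rec, genome) == UNCLASSIFIABLE:
                n_bad += 1
    return n_bad


# ---------------------------------------------------------------------------
# aggregation and comparison
# ---------------------------------------------------------------------------

def aggregate(
    records: list[MutationRecord],
    by: str = "cell",
    kind: str = "SBS96",
    meta: pd.DataFrame | None = None,
) -> dict[str, Spectrum]:
    """Aggregate classified records into one spectrum per group.

    ``by`` is one of ``cell``, ``subject``, ``celltype`` or ``origin``;
    subject/celltype grouping requires a metadata frame indexed by cell id
    with the matching column (``subject_id`` / ``celltype``).  Unclassifiable
    indels are excluded from spectra (they still count toward burdens).
    """
    channels = SBS96_CHANNELS if kind == "SBS96" else ID83_CHANNELS
    index = SBS96_INDEX if kind == "SBS96" else ID83_INDEX
    want = "SNV" if kind == "SBS96" else ("INS", "DEL")

    def group_of(rec: MutationRecord) -> str:
        if by == "cell":
            return rec.cell_id
        if by == "origin":
            return rec.origin
        if by in ("subject", "celltype"):
            if meta is None:
                raise ValueError(f"grouping by {by} requires a metadata frame")
            col = "subject_id" if by == "subject" else "celltype"
            return str(meta.loc[rec.cell_id, col])
        raise ValueError(f"unknown grouping {by!r}")

    out: dict[str, np.ndarray] = {}
    for rec in records:
        if (rec.kind != want) if kind == "SBS96" else (rec.kind not in want):
            continue
        if rec.channel is None:
            raise ValueError(f"record {rec.key} is unclassified")
        if rec.channel == UNCLASSIFIABLE:
            continue
        g = group_of(rec)
        if g not in out:
            out[g] = np.zeros(len(channels))
        out[g][index[rec.channel]] += 1
    return {g: Spectrum(v, kind, label=g) for g, v in sorted(out.items())}


def spectra_frame(spectra: dict[str, Spectrum]) -> pd.DataFrame:
    """Channels × samples matrix in canonical channel order."""
    return pd.DataFrame({g: s.to_series() for g, s in spectra.items()})


def cosine(a: Spectrum | np.ndarray, b: Spectrum | np.ndarray) -> float:
    """Cosine similarity of two spectra (scale-invariant, in [0, 1])."""
    va = a.counts if isinstance(a, Spectrum) else np.asarray(a, dtype=float)
    vb = b.counts if isinstance(b, Spectrum) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("spectra have different channel counts")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero spectrum")
    return float(np.dot(va, vb) / (na * nb))
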