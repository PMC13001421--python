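"""Reference-genome container with trinucleotide bookkeeping.

The analyses here only ever need random access to bases and flanking context,
plus fast sampling of positions with a given pyrimidine-centred trinucleotide
context (for signature-aware mutation placement and context-matched
permutations).  Sequences are held in memory as plain strings — genomes in
this package are at the megabase scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import CONTEXT_CODE_TABLE, CONTEXTS32, collapse_context, encode_bases


@dataclass
class Genome:
    """In-memory reference: ordered mapping of contig name -> sequence."""

    sequences: dict[str, str]
    _offsets: dict[str, int] = field(init=False, repr=False)
    _order: list[str] = field(init=False, repr=False)
    _ctx_cache: dict[str, np.ndarray] | None = field(
        default=None, init=False, repr=False
    )

    def __post_init__(self) -> None:
        self._order = list(self.sequences)
        off, self._offsets = 0, {}
        for name in self._order:
            self._offsets[name] = off
            off += len(self.sequences[name])

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def contigs(self) -> list[str]:
        return list(self._order)

    def contig_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    # -- coordinates (variants are 1-based internally) ----------------------
    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos - 1]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice, clipped to the contig."""
        seq = self.sequences[chrom]
        return seq[max(start - 1, 0) : min(end, len(seq))]

    def context(self, chrom: str, pos: int) -> str:
        """Raw trinucleotide centred on ``pos`` (1-based)."""
        seq = self.sequences[chrom]
        if pos < 2 or pos > len(seq) - 1:
            raise ValueError(f"position {chrom}:{pos} has no flanking bases")
        return seq[pos - 2 : pos + 1]

    def pyrimidine_context(self, chrom: str, pos: int) -> str:
        return collapse_context(self.context(chrom, pos))

    def to_global(self, chrom: str, pos: int) -> int:
        """(chrom, 1-based pos) -> 0-based global coordinate."""
        return self._offsets[chrom] + pos - 1

    def from_global(self, gpos: int | np.ndarray):
        """0-based global coordinate(s) -> (chrom, 1-based pos) pairs."""
        if np.isscalar(gpos) or isinstance(gpos, (int, np.integer)):
            for name in reversed(self._order):
                if gpos >= self._offsets[name]:
                    return name, int(gpos - self._offsets[name] + 1)
            raise ValueError("negative coordinate")
        gpos = np.asarray(gpos)
        bounds = np.array([self._offsets[n] for n in self._order])
        idx = np.searchsorted(bounds, gpos, side="right") - 1
        chroms = np.array(self._order, dtype=object)[idx]
        pos = gpos - bounds[idx] + 1
        return chroms, pos

    # -- trinucleotide index ------------------------------------------------
    def context_codes(self) -> np.ndarray:
        """Per-position context index into CONTEXTS32 (-1 where undefined).

        Positions are global 0-based; contig-boundary positions and positions
        with non-ACGT neighbours are -1.
        """
        out = np.full(self.length, -1, dtype=np.int8)
        for name in self._order:
            seq = self.sequences[name]
            if len(seq) < 3:
                continue
            codes = encode_bases(seq)
            valid = codes >= 0
            tri_ok = valid[:-2] & valid[1:-1] & valid[2:]
            raw = 16 * codes[:-2] + 4 * codes[1:-1] + codes[2:]
            ctx = np.full(len(seq), -1, dtype=np.int8)
            ctx[1:-1][tri_ok] = CONTEXT_CODE_TABLE[raw[tri_ok]]
            off = self._offsets[name]
            out[off : off + len(seq)] = ctx
        return out

    def positions_by_context(self) -> dict[str, np.ndarray]:
        """Global 0-based positions for each of the 32 collapsed contexts."""
        if self._ctx_cache is None:
            codes = self.context_codes()
            order = np.argsort(codes, kind="stable")
            sorted_codes = codes[order]
            self._ctx_cache = {}
            for i, ctx in enumerate(CONTEXTS32):
                lo = np.searchsorted(sorted_codes, i, side="left")
                hi = np.searchsorted(sorted_codes, i, side="right")
                self._ctx_cache[ctx] = order[lo:hi]
        return self._ctx_cache

    # -- FASTA --------------------------------------------------------------
    def to_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name in self._order:
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")})
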