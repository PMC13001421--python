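"""Canonical mutation-channel definitions.

Single-base substitutions use the 96-channel convention: six pyrimidine-centred
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 16
possible 5'/3' flanking-base combinations, written ``A[C>T]G``.  Insertions and
deletions use the 83-channel COSMIC indel convention: 1-bp events split by the
deleted/inserted pyrimidine and homopolymer length, longer events by size and
tandem-repeat count, and deletions at non-repetitive sites by flanking
microhomology length.

The channel orders defined here are the single source of truth for every
spectrum and catalog in the package; matrices are validated against them on
load.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
PYRIMIDINES = ("C", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: SBS96 channels in canonical (COSMIC/SigProfiler) order.
SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)
SBS96_INDEX = {c: i for i, c in enumerate(SBS96_CHANNELS)}


def _id83_channels() -> tuple[str, ...]:
    out = []
    # 1bp deletions / insertions in homopolymers; the final field is the
    # number of *additional* repeat units for deletions (run length - 1) and
    # the pre-existing run length for insertions, saturated at 5.
    for kind in ("Del", "Ins"):
        for base in ("C", "T"):
            for n in range(6):
                out.append(f"1:{kind}:{base}:{n}")
    # >=2bp events at tandem repeats, by size (5 == 5+) and repeat count.
    for kind in ("Del", "Ins"):
        for size in (2, 3, 4, 5):
            for n in range(6):
                out.append(f"{size}:{kind}:R:{n}")
    # deletions with flanking microhomology, by size and homology length;
    # size 5 means 5+, so homology runs to 5 there.
    for size in (2, 3, 4, 5):
        mh_max = size - 1 if size < 5 else 5
        for mh in range(1, mh_max + 1):
            out.append(f"{size}:Del:M:{mh}")
    return tuple(out)


#: ID83 channels in canonical (COSMIC/SigProfiler) order.
ID83_CHANNELS: tuple[str, ...] = _id83_channels()
ID83_INDEX = {c: i for i, c in enumerate(ID83_CHANNELS)}

assert len(SBS96_CHANNELS) == 96
assert len(ID83_CHANNELS) == 83

#: The 32 pyrimidine-centred trinucleotide contexts, in SBS96 context order.
CONTEXTS32: tuple[str, ...] = tuple(
    f"{five}{mid}{three}" for mid in PYRIMIDINES for five in BASES for three in BASES
)
CONTEXT32_INDEX = {c: i for i, c in enumerate(CONTEXTS32)}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def collapse_context(trinuc: str) -> str:
    """Map a raw trinucleotide to its pyrimidine-centred representative."""
    if trinuc[1] in PYRIMIDINES:
        return trinuc
    return revcomp(trinuc)


def sbs_channel(trinuc: str, alt: str) -> str:
    """SBS96 channel for a substitution ``trinuc[1] -> alt`` in context ``trinuc``.

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand first.
    """
    ref = trinuc[1]
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref})")
    if ref not in PYRIMIDINES:
        trinuc = revcomp(trinuc)
        alt = COMPLEMENT[alt]
        ref = trinuc[1]
    return f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}"


def channel_context(channel: str) -> str:
    """Pyrimidine-centred trinucleotide context of an SBS96 channel."""
    return channel[0] + channel[2] + channel[6]


def channel_alt(channel: str) -> str:
    """Alternate base (pyrimidine strand) of an SBS96 channel."""
    return channel[4]


# integer encodings used by vectorised genome scans
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode_bases(seq: str) -> np.ndarray:
    """Encode an ACGT string as int8 codes A=0 C=1 G=2 T=3 (-1 elsewhere)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _context_code_table() -> np.ndarray:
    """Map raw trinucleotide code (16*l + 4*m + r) -> index into CONTEXTS32."""
    table = np.empty(64, dtype=np.int8)
    for l in range(4):
        for m in range(4):
            for r in range(4):
                tri = BASES[l] + BASES[m] + BASES[r]
                table[16 * l + 4 * m + r] = CONTEXT32_INDEX[collapse_context(tri)]
    return table


CONTEXT_CODE_TABLE = _context_code_table()
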