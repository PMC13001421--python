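"""Permutation-based genomic enrichment of somatic mutations.

Observed mutation counts per annotation class are compared with expected
counts obtained by relocating every mutation to a random callable position —
either uniformly or constrained to the same pyrimidine-collapsed
trinucleotide context (trinucleotide composition confounds genic/intergenic
comparisons, so context-matched is the default for substitutions).  The
enrichment ratio is observed over mean permuted count, with a two-sided
empirical p-value; ordered (quantile) tracks additionally get a linear trend
test (Pearson correlation of the per-bin ratio against bin rank).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .channels import CONTEXT32_INDEX, channel_context
from .genome import Genome

logger = logging.getLogger(__name__)


@dataclass
class AnnotationTrack:
    """Interval annotation: 0-based half-open intervals with class labels."""

    name: str
    intervals: pd.DataFrame  # columns: chrom, start, end, label
    layer: str = "partition"  # partition | quantile
    bins: tuple[str, ...] | None = None  # ordered labels for quantile layers
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def labels(self) -> tuple[str, ...]:
        if self.bins is not None:
            return tuple(self.bins)
        return tuple(sorted(self.intervals["label"].unique()))

    def validate(self, genome: Genome) -> None:
        for chrom, sub in self.intervals.groupby("chrom"):
            clen = genome.contig_length(chrom)
            if (sub["start"] < 0).any() or (sub["end"] > clen).any():
                raise ValueError(f"track {self.name}: intervals outside {chrom}")
            sub = sub.sort_values("start")
            overlaps = sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]
            if overlaps.any():
                raise ValueError(f"track {self.name}: overlapping intervals on {chrom}")
            if self.layer == "partition":
                covered = (sub["end"] - sub["start"]).sum()
                if covered != clen:
                    raise ValueError(
                        f"partition track {self.name} does not tile {chrom}"
                    )

    def label_codes(self, genome: Genome) -> tuple[np.ndarray, list[str]]:
        """Per-global-position class code (-1 = unannotated) and label list."""
        if "codes" not in self._cache:
            labels = list(self.labels)
            lab_idx = {l: i for i, l in enumerate(labels)}
            codes = np.full(genome.length, -1, dtype=np.int16)
            for chrom, sub in self.intervals.groupby("chrom"):
                off = genome.to_global(chrom, 1)
                for start, end, label in zip(sub["start"], sub["end"], sub["label"]):
                    codes[off + start : off + end] = lab_idx[label]
            self._cache["codes"] = (codes, labels)
        return self._cache["codes"]

    def class_fractions(self, genome: Genome) -> pd.Series:
        codes, labels = self.label_codes(genome)
        counts = np.bincount(codes[codes >= 0], minlength=len(labels))
        return pd.Series(counts / counts.sum(), index=labels)


@dataclass
class EnrichmentResult:
    track: str
    label: str
    observed: int
    expected_mean: float
    expected_sd: float
    ratio: float
    p_value: float
    n_permutations: int
    unreliable: bool = False


# ---------------------------------------------------------------------------
# position machinery
# ---------------------------------------------------------------------------

def records_to_global(records, genome: Genome) -> np.ndarray:
    """Global 0-based coordinates of a list of MutationRecords."""
    return np.array([genome.to_global(r.chrom, r.pos) for r in records], dtype=np.int64)


def annotate_records(records, track: AnnotationTrack, genome: Genome) -> None:
    """Store each record's class label under ``annotations[track.name]``."""
    codes, labels = track.label_codes(genome)
    for rec in records:
        c = codes[genome.to_global(rec.chrom, rec.pos)]
        rec.annotations[track.name] = labels[c] if c >= 0 else None


def _callable_positions(genome: Genome, callable_mask: np.ndarray | None) -> np.ndarray:
    if callable_mask is None:
        return np.arange(genome.length, dtype=np.int64)
    return np.flatnonzero(callable_mask).astype(np.int64)


def permute_positions(
    positions: np.ndarray,
    genome: Genome,
    rng: np.random.Generator,
    mode: str = "uniform",
    callable_mask: np.ndarray | None = None,
    contexts: np.ndarray | None = None,
) -> np.ndarray:
    """Relocate each position to a random callable position (one permutation).

    In ``context-matched`` mode the destination's collapsed trinucleotide
    equals the source context (``contexts``: per-record index into the 32
    contexts); records whose context has no callable position fall back to
    uniform placement (counted in the log).
    """
    pool = _callable_positions(genome, callable_mask)
    if len(pool) == 0:
        raise ValueError("callable region is empty")
    n = len(positions)
    if mode == "uniform":
        return pool[rng.integers(0, len(pool), size=n)]
    if mode != "context-matched":
        raise ValueError(f"unknown permutation mode {mode!r}")
    if contexts is None:
        raise ValueError("context-matched mode requires per-record contexts")
    codes = genome.context_codes()
    if callable_mask is not None:
        codes = np.where(callable_mask, codes, -1)
    out = np.empty(n, dtype=np.int64)
    n_fallback = 0
    order = np.argsort(contexts, kind="stable")
    sorted_ctx = contexts[order]
    ctx_pools = {}
    for ctx in np.unique(sorted_ctx):
        ctx_pools[ctx] = np.flatnonzero(codes == ctx)
    for ctx in ctx_pools:
        idx = order[np.searchsorted(sorted_ctx, ctx, "left"): np.searchsorted(sorted_ctx, ctx, "right")]
        p = ctx_pools[ctx]
        if len(p) == 0:
            out[idx] = pool[rng.integers(0, len(pool), size=len(idx))]
            n_fallback += len(idx)
        else:
            out[idx] = p[rng.integers(0, len(p), size=len(idx))]
    if n_fallback:
        logger.info("%d records fell back to uniform placement", n_fallback)
    return out


def record_contexts(records, genome: Genome) -> np.ndarray:
    """Collapsed-context indices for SNV records (from channel or genome)."""
    out = np.empty(len(records), dtype=np.int16)
    for i, rec in enumerate(records):
        if rec.channel and "[" in rec.channel:
            out[i] = CONTEXT32_INDEX[channel_context(rec.channel)]
        else:
            out[i] = CONTEXT32_INDEX[genome.pyrimidine_context(rec.chrom, rec.pos)]
    return out


# ---------------------------------------------------------------------------
# enrichment and trend
# ---------------------------------------------------------------------------

def _permuted_counts(
    positions: np.ndarray,
    codes: np.ndarray,
    n_labels: int,
    genome: Genome,
    n: int,
    mode: str,
    seed,
    callable_mask,
    contexts,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    perm = np.empty((n, n_labels), dtype=np.int64)
    for i in range(n):
        newpos = permute_positions(
            positions, genome, rng, mode=mode,
            callable_mask=callable_mask, contexts=contexts,
        )
        c = codes[newpos]
        perm[i] = np.bincount(c[c >= 0], minlength=n_labels)
    return perm


def enrich(
    positions: np.ndarray,
    track: AnnotationTrack,
    genome: Genome,
    n_permutations: int = 1000,
    mode: str = "uniform",
    seed: int | None = 0,
    callable_mask: np.ndarray | None = None,
    contexts: np.ndarray | None = None,
) -> list[EnrichmentResult]:
    """Observed/expected enrichment per annotation class.

    ``positions`` are global 0-based coordinates (see ``records_to_global``).
    The empirical two-sided p is ``(1 + #{|perm - mean| >= |obs - mean|}) /
    (n + 1)``; classes never hit by any permutation are flagged unreliable.
    """
    codes, labels = track.label_codes(genome)
    obs_codes = codes[positions]
    observed = np.bincount(obs_codes[obs_codes >= 0], minlength=len(labels))
    perm = _permuted_counts(
        positions, codes, len(labels), genome, n_permutations, mode, seed,
        callable_mask, contexts,
    )
    mean = perm.mean(axis=0)
    sd = perm.std(axis=0, ddof=1)
    results = []
    for j, label in enumerate(labels):
        dev = np.abs(perm[:, j] - mean[j])
        p = (1 + np.sum(dev >= abs(observed[j] - mean[j]) - 1e-12)) / (
            n_permutations + 1
        )
        results.append(
            EnrichmentResult(
                track=track.name,
                label=label,
                observed=int(observed[j]),
                expected_mean=float(mean[j]),
                expected_sd=float(sd[j]),
                ratio=float(observed[j] / mean[j]) if mean[j] > 0 else np.nan,
                p_value=float(p),
                n_permutations=n_permutations,
                unreliable=bool(mean[j] == 0),
            )
        )
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    if len(df):
        df["q_bh"] = stats.false_discovery_control(df["p_value"], method="bh")
    return df


def trend(
    positions: np.ndarray,
    track: AnnotationTrack,
    genome: Genome,
    subjects: np.ndarray | None = None,
    n_permutations: int = 1000,
    mode: str = "uniform",
    seed: int | None = 0,
    callable_mask: np.ndarray | None = None,
    contexts: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Per-bin obs/exp ratios and the linear trend across ordered bins.

    With ``subjects`` (per-record subject ids) ratios are computed per
    subject and averaged per bin, as in cross-subject enrichment plots; the
    trend is the Pearson correlation of the mean ratio against bin rank.
    """
    if track.bins is None or len(track.bins) < 3:
        raise ValueError("trend requires a quantile track with >=3 ordered bins")
    codes, labels = track.label_codes(genome)
    nl = len(labels)
    perm = _permuted_counts(
        positions, codes, nl, genome, n_permutations, mode, seed,
        callable_mask, contexts,
    )
    exp_frac = perm.mean(axis=0) / max(perm.sum(axis=1).mean(), 1)
    if subjects is None:
        subjects = np.zeros(len(positions), dtype=int)
    subjects = np.asarray(subjects)
    rows = []
    for subj in pd.unique(subjects):
        sel = positions[subjects == subj]
        oc = codes[sel]
        oc = oc[oc >= 0]
        obs = np.bincount(oc, minlength=nl)
        frac = obs / max(obs.sum(), 1)
        for j, label in enumerate(labels):
            rows.append(
                {
                    "subject": subj,
                    "bin": label,
                    "rank": j,
                    "observed": int(obs[j]),
                    "ratio": frac[j] / exp_frac[j] if exp_frac[j] > 0 else np.nan,
                }
            )
    per_bin = pd.DataFrame(rows)
    mean_ratio = per_bin.groupby("rank")["ratio"].mean()
    r, p = stats.pearsonr(mean_ratio.index.to_numpy(), mean_ratio.to_numpy())
    return per_bin, float(r), float(p)


# ---------------------------------------------------------------------------
# impact summaries (labels consumed, not computed)
# ---------------------------------------------------------------------------

def impact_summary(
    records,
    meta: pd.DataFrame,
    classes: tuple[str, ...] = ("high", "moderate", "low"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell impact-class fractions and cross-celltype rank tests.

    Impact labels are read from ``record.annotations['impact']``; records
    without a label are excluded (count logged).  Returns the per-cell
    fraction table and a pairwise two-tailed Mann-Whitney table per class.
    """
    counts: dict[str, dict[str, int]] = {}
    n_missing = 0
    for rec in records:
        label = rec.annotations.get("impact")
        if label is None:
            n_missing += 1
            continue
        counts.setdefault(rec.cell_id, {c: 0 for c in classes})
        if label in classes:
            counts[rec.cell_id][label] += 1
    if n_missing:
        logger.info("%d records had no impact label; excluded", n_missing)
    rows = []
    for cell, cc in counts.items():
        total = sum(cc.values())
        rows.append(
            {
                "cell_id": cell,
                "celltype": meta.loc[cell, "celltype"],
                "total": total,
                **{f"frac_{c}": cc[c] / total if total else np.nan for c in classes},
            }
        )
    frac = pd.DataFrame(rows)
    tests = []
    types = sorted(frac["celltype"].unique())
    for a, b in itertools.combinations(types, 2):
        for c in classes:
            xa = frac.loc[frac["celltype"] == a, f"frac_{c}"].dropna()
            xb = frac.loc[frac["celltype"] == b, f"frac_{c}"].dropna()
            if len(xa) and len(xb):
                stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
                tests.append(
                    {"type_a": a, "type_b": b, "impact": c, "u": stat, "p": p}
                )
    return frac, pd.DataFrame(tests)


def subject_ratios(
    positions: np.ndarray,
    subjects: np.ndarray,
    track: AnnotationTrack,
    genome: Genome,
    expected_fracs: pd.Series,
) -> pd.DataFrame:
    """Per-subject obs/exp ratios per class plus a Wilcoxon test against 1."""
    codes, labels = track.label_codes(genome)
    rows = []
    for subj in pd.unique(subjects):
        sel = positions[np.asarray(subjects) == subj]
        oc = codes[sel]
        oc = oc[oc >= 0]
        obs = np.bincount(oc, minlength=len(labels))
        frac = obs / max(obs.sum(), 1)
        for j, label in enumerate(labels):
            rows.append(
                {"subject": subj, "label": label, "ratio": frac[j] / expected_fracs[label]}
            )
    df = pd.DataFrame(rows)
    tests = []
    for label, sub in df.groupby("label"):
        vals = sub["ratio"].dropna()
        if len(vals) >= 2 and (vals != 1).any():
            stat, p = stats.wilcoxon(vals - 1)
        else:
            stat, p = np.nan, np.nan
        tests.append({"label": label, "wilcoxon_p": p})
    return df.merge(pd.DataFrame(tests), on="label")
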