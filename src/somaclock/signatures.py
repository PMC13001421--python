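"""Reference-signature refitting with stepwise selection.

A mutational spectrum is decomposed onto a catalog of reference signatures
(columns summing to 1 over the canonical channel order) by non-negative least
squares, so exposures come out directly in mutation counts.  Signature
selection is forward-stepwise on reconstruction-cosine gain starting from a
clock-like base set, followed by a backward prune of signatures whose removal
barely changes the fit — the standard refitting recipe for sparse somatic
data, where unconstrained NNLS over a full catalog overfits.

Per-signature ageing rates reuse the burden-model regression on per-cell
exposures, and individual mutations are attributed to signatures by the
channel-wise posterior ``P(sig | channel) ∝ exposure_sig · catalog[channel, sig]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .burden import CellProfile, RateFit, compare_rates, fit_rate
from .channels import ID83_CHANNELS, SBS96_CHANNELS
from .spectra import MutationRecord, Spectrum, cosine


@dataclass
class SignatureCatalog:
    """Channels × signatures matrix with unit-sum columns."""

    matrix: pd.DataFrame
    kind: str = "SBS96"

    def __post_init__(self) -> None:
        channels = SBS96_CHANNELS if self.kind == "SBS96" else ID83_CHANNELS
        if list(self.matrix.index) != list(channels):
            raise ValueError(
                f"catalog channel order does not match the canonical {self.kind} order"
            )
        vals = self.matrix.to_numpy()
        if (vals < 0).any():
            raise ValueError("catalog entries must be non-negative")
        sums = vals.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = self.matrix.columns[np.abs(sums - 1) > 1e-6]
            raise ValueError(f"catalog columns must sum to 1: {list(bad)}")

    @property
    def signatures(self) -> list[str]:
        return list(self.matrix.columns)

    def column(self, sig: str) -> np.ndarray:
        return self.matrix[sig].to_numpy()

    def subset(self, sigs) -> "SignatureCatalog":
        return SignatureCatalog(self.matrix[list(sigs)], self.kind)

    @classmethod
    def from_tsv(cls, path, kind: str = "SBS96") -> "SignatureCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        channels = SBS96_CHANNELS if kind == "SBS96" else ID83_CHANNELS
        df = df.reindex(list(channels))
        if df.isna().any().any():
            raise ValueError(f"catalog {path} is missing canonical {kind} channels")
        return cls(df, kind)

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="channel")


@dataclass
class SignatureExposure:
    """Per-sample signature exposures in mutation counts."""

    sample: str
    exposures: pd.Series  # indexed by every catalog signature; unselected are 0
    reconstruction_cosine: float
    selected: tuple[str, ...]

    @property
    def total(self) -> float:
        return float(self.exposures.sum())

    def fractions(self) -> pd.Series:
        return self.exposures / self.total if self.total > 0 else self.exposures


def refit(
    spectrum: Spectrum, catalog: SignatureCatalog, active
) -> SignatureExposure:
    """Non-negative least-squares fit of a spectrum onto the active signatures."""
    active = sorted(active)
    if not active:
        raise ValueError("empty active signature set")
    if spectrum.total == 0:
        raise ValueError("cannot refit an empty spectrum")
    A = catalog.matrix[active].to_numpy()
    x, _ = nnls(A, spectrum.counts)
    recon = A @ x
    cos = cosine(spectrum.counts, recon) if recon.sum() > 0 else 0.0
    exposures = pd.Series(0.0, index=catalog.signatures)
    exposures[active] = x
    return SignatureExposure(
        sample=spectrum.label,
        exposures=exposures,
        reconstruction_cosine=float(cos),
        selected=tuple(active),
    )


def stepwise_select(
    spectrum: Spectrum,
    catalog: SignatureCatalog,
    base=("SBS1", "SBS5"),
    threshold: float = 0.01,
) -> SignatureExposure:
    """Forward selection on cosine gain, then backward pruning.

    Starting from the base set (clock-like signatures for SNVs, empty for
    indels), repeatedly add the catalog signature that most improves the
    reconstruction cosine while the gain is at least ``threshold``; then
    remove any signature whose removal costs less than ``threshold / 2``.
    Deterministic: ties are broken by signature id order.
    """
    if not (0 < threshold <= 0.2):
        raise ValueError("threshold must be in (0, 0.2]")
    selected = sorted(set(base) & set(catalog.signatures))
    current = refit(spectrum, catalog, selected) if selected else None
    current_cos = current.reconstruction_cosine if current else 0.0

    remaining = sorted(set(catalog.signatures) - set(selected))
    while remaining:
        best_sig, best_cos = None, current_cos
        for sig in remaining:
            cand = refit(spectrum, catalog, selected + [sig])
            if cand.reconstruction_cosine > best_cos + 1e-12:
                best_sig, best_cos = sig, cand.reconstruction_cosine
        if best_sig is None or best_cos - current_cos < threshold:
            break
        selected = sorted(selected + [best_sig])
        remaining.remove(best_sig)
        current_cos = best_cos

    if not selected:  # nothing gained enough; keep the single best signature
        best = max(
            catalog.signatures,
            key=lambda s: (refit(spectrum, catalog, [s]).reconstruction_cosine, s),
        )
        selected = [best]
        current_cos = refit(spectrum, catalog, selected).reconstruction_cosine

    # backward prune, iterating to a fixed point
    changed = True
    while changed and len(selected) > 1:
        changed = False
        for sig in sorted(selected):
            rest = [s for s in selected if s != sig]
            cand = refit(spectrum, catalog, rest)
            if current_cos - cand.reconstruction_cosine < threshold / 2:
                selected = rest
                current_cos = cand.reconstruction_cosine
                changed = True
                break
    return refit(spectrum, catalog, selected)


def exposures_frame(exposures: dict[str, SignatureExposure]) -> pd.DataFrame:
    """Signatures × samples exposure matrix."""
    return pd.DataFrame({s: e.exposures for s, e in exposures.items()})


def signature_rates(
    exposures: dict[str, SignatureExposure],
    profiles: list[CellProfile],
) -> tuple[dict[str, dict[str, RateFit]], pd.DataFrame | None]:
    """Per-signature ageing rates and cross-celltype Tukey contrasts.

    ``exposures`` maps cell id -> per-cell exposure (fitted with a common
    selected set per cell type).  Returns ``fits[signature][celltype]`` and a
    contrast table (None when only one cell type is present).  Rates are
    fitted on callable-fraction-extrapolated exposures, reusing the burden
    regression machinery.
    """
    prof_by_cell = {p.cell_id: p for p in profiles}
    sigs = sorted(
        {s for e in exposures.values() for s in e.selected}
    )
    fits: dict[str, dict[str, RateFit]] = {}
    contrast_rows = []
    celltypes = sorted({prof_by_cell[c].celltype for c in exposures})
    for sig in sigs:
        fits[sig] = {}
        pseudo = []
        for cell, expo in exposures.items():
            p = prof_by_cell[cell]
            pseudo.append(
                CellProfile(
                    cell_id=cell,
                    subject_id=p.subject_id,
                    age=p.age,
                    celltype=p.celltype,
                    region=p.region,
                    depth_class=p.depth_class,
                    callable_fraction=p.callable_fraction,
                    n_calls_snv=float(expo.exposures.get(sig, 0.0)),
                )
            )
        for ct in celltypes:
            sub = [q for q in pseudo if q.celltype == ct]
            if sub and pd.Series([q.age for q in sub]).nunique() >= 2:
                fits[sig][ct] = fit_rate(sub, response="snv")
        if len(fits[sig]) >= 2:
            tab = compare_rates(
                [q for q in pseudo if q.celltype in fits[sig]], response="snv"
            )
            tab.insert(0, "signature", sig)
            contrast_rows.append(tab)
    contrasts = pd.concat(contrast_rows, ignore_index=True) if contrast_rows else None
    return fits, contrasts


def attribute_mutations(
    records: list[MutationRecord],
    exposures: dict[str, SignatureExposure],
    catalog: SignatureCatalog,
) -> pd.DataFrame:
    """Per-record signature posterior and MAP label.

    ``P(sig | channel) ∝ exposure_sig × catalog[channel, sig]`` over the
    sample's selected signatures; channels with zero mass under every active
    signature are labelled ``"unattributed"``.  The MAP label is stored in
    ``record.annotations["signature"]``; ties go to the first signature in id
    order.  Returns a frame of posteriors (records × signatures).
    """
    rows = []
    for rec in records:
        expo = exposures[rec.cell_id]
        sigs = list(expo.selected)
        if rec.channel is None:
            raise ValueError(f"record {rec.key} is unclassified")
        weights = np.array(
            [expo.exposures[s] * catalog.matrix.loc[rec.channel, s] for s in sigs]
        )
        total = weights.sum()
        if total <= 0:
            rec.annotations["signature"] = "unattributed"
            rows.append({s: 0.0 for s in sigs})
            continue
        post = weights / total
        rec.annotations["signature"] = sigs[int(np.argmax(post))]
        rows.append(dict(zip(sigs, post)))
    return pd.DataFrame(rows).fillna(0.0)
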