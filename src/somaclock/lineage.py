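"""Shared-variant lineage reconstruction and MRCA dating.

Somatic variants shared by two or more cells mark clonal ancestry: the set of
cells carrying a variant defines a candidate clade.  Candidate clades that
violate laminarity (neither disjoint nor nested) are resolved greedily in
favour of the clade with more supporting variants, and the survivors are
nested into a rooted tree whose branch lengths are variant counts.  Because
private variants accumulate linearly with age, the mean extrapolated private
burden of a clade's cells converts into the time its cells became
post-mitotic — the dated most recent common ancestor (MRCA) — via the fitted
annual accumulation rate.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .burden import RateFit

logger = logging.getLogger(__name__)

#: fertilisation precedes birth by ~0.75 years; the internal time axis has
#: the zygote at 0, so "postnatal" means t > FERTILIZATION_OFFSET.
FERTILIZATION_OFFSET = 0.75


@dataclass
class CladeNode:
    """One node of the lineage tree.

    ``variants`` are the variant keys assigned to the branch *above* this
    node; leaves hold one cell and its private variants.
    """

    id: str
    cells: frozenset
    children: list["CladeNode"] = field(default_factory=list)
    variants: list[tuple] = field(default_factory=list)
    time: float | None = None  # truth-only: years from zygote

    @property
    def branch_length(self) -> int:
        return len(self.variants)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class LineageTree:
    root: CladeNode

    def nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> list[CladeNode]:
        return [n for n in self.nodes() if n.is_leaf]

    @property
    def n_cells(self) -> int:
        return len(self.root.cells)

    def internal_nodes(self, nontrivial: bool = True):
        for n in self.nodes():
            if n.is_leaf or n is self.root:
                continue
            if nontrivial and len(n.cells) < 2:
                continue
            yield n

    def clade_family(self) -> set[frozenset]:
        """Cell sets of the non-root, non-singleton clades (laminar family)."""
        return {n.cells for n in self.internal_nodes()}

    def cell_fraction(self, node: CladeNode) -> float:
        return len(node.cells) / self.n_cells

    def private_sets(self) -> dict[str, list[tuple]]:
        return {next(iter(n.cells)): list(n.variants) for n in self.leaves()}

    def node_by_id(self, node_id: str) -> CladeNode:
        for n in self.nodes():
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def depths(self) -> dict[str, float]:
        """Sum of branch lengths from root to each node (root depth 0)."""
        out = {self.root.id: 0.0}
        stack = [self.root]
        while stack:
            node = stack.pop()
            for ch in node.children:
                out[ch.id] = out[node.id] + ch.branch_length
                stack.append(ch)
        return out

    def leaf_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Pairwise leaf distance = non-shared branch variants on the path."""
        leaves = sorted(self.leaves(), key=lambda n: next(iter(n.cells)))
        names = [next(iter(n.cells)) for n in leaves]
        depth = self.depths()
        # ancestors (node ids) with cumulative depth for each leaf
        paths = {}
        parent = {}
        for n in self.nodes():
            for ch in n.children:
                parent[ch.id] = n.id
        for leaf in leaves:
            chain = [leaf.id]
            while chain[-1] in parent:
                chain.append(parent[chain[-1]])
            paths[leaf.id] = chain
        D = np.zeros((len(leaves), len(leaves)))
        for i, a in enumerate(leaves):
            seen = set(paths[a.id])
            for j in range(i + 1, len(leaves)):
                b = leaves[j]
                lca = next(nid for nid in paths[b.id] if nid in seen)
                d = depth[a.id] + depth[b.id] - 2 * depth[lca]
                D[i, j] = D[j, i] = d
        return names, D

    def newick(self, annotate: bool = False) -> str:
        def fmt(node: CladeNode) -> str:
            if node.is_leaf:
                label = next(iter(node.cells))
                return f"{label}:{node.branch_length}"
            inner = ",".join(fmt(c) for c in node.children)
            note = f"[&&NHX:cells={len(node.cells)}]" if annotate else ""
            return f"({inner}){node.id}{note}:{node.branch_length}"

        return fmt(self.root) + ";"


@dataclass
class MRCAEstimate:
    node_id: str
    mean_private_burden: float
    t_mrca: float
    ci95: tuple[float, float]
    n_descendants: int
    clipped: bool = False


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def build_tree(
    cell_variants: dict[str, list],
    bulk_clonal: set | None = None,
    min_cells: int = 2,
    min_support: int = 2,
) -> LineageTree:
    """Reconstruct the clonal tree from per-cell variant sets.

    Variant identity is the (chrom, pos, ref, alt) key.  A variant is a
    shared marker when carried by >= ``min_cells`` cells or present in the
    bulk clonal table (and carried by >= 2 cells).  Candidate clades are the
    distinct carrier sets with >= ``min_support`` markers; laminarity
    conflicts are resolved by keeping the clade with more support (ties:
    more cells, then lexicographic).  Every shared variant is then assigned
    to the smallest surviving clade containing all of its carriers.
    """
    bulk_clonal = bulk_clonal or set()
    cells = sorted(cell_variants)
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to build a tree")

    carriers: dict[tuple, set] = {}
    for cell, variants in cell_variants.items():
        for key in variants:
            carriers.setdefault(tuple(key), set()).add(cell)

    shared = {
        k: frozenset(c)
        for k, c in carriers.items()
        if len(c) >= 2 and (len(c) >= min_cells or k in bulk_clonal)
    }
    if not shared:
        warnings.warn("no shared variants; returning a star tree")

    support: dict[frozenset, int] = {}
    for cset in shared.values():
        support[cset] = support.get(cset, 0) + 1

    all_cells = frozenset(cells)
    candidates = [
        cset
        for cset, sup in support.items()
        if sup >= min_support and cset != all_cells
    ]
    candidates.sort(
        key=lambda c: (-support[c], -len(c), tuple(sorted(c)))
    )
    accepted: list[frozenset] = []
    for cand in candidates:
        ok = True
        for acc in accepted:
            inter = cand & acc
            if inter and not (cand <= acc or acc <= cand):
                logger.info(
                    "discarding clade of %d cells (support %d): conflicts with "
                    "accepted clade of %d cells",
                    len(cand), support[cand], len(acc),
                )
                ok = False
                break
        if ok:
            accepted.append(cand)

    # nest accepted clades (largest first) under root, then attach leaves
    node_count = itertools.count()
    root = CladeNode(id=f"n{next(node_count)}", cells=all_cells)
    internals = [root]
    for cset in sorted(accepted, key=lambda c: (-len(c), tuple(sorted(c)))):
        node = CladeNode(id=f"n{next(node_count)}", cells=cset)
        parent = min(
            (p for p in internals if cset < p.cells), key=lambda p: len(p.cells)
        )
        parent.children.append(node)
        internals.append(node)
    smallest_first = sorted(internals, key=lambda n: len(n.cells))
    leaf_by_cell = {}
    for cell in cells:
        parent = next(n for n in smallest_first if cell in n.cells)
        leaf = CladeNode(id=f"leaf_{cell}", cells=frozenset([cell]))
        parent.children.append(leaf)
        leaf_by_cell[cell] = leaf

    # assign every variant to the smallest node containing all carriers
    for key, cset in carriers.items():
        if len(cset) == 1:
            (cell,) = cset
            leaf_by_cell[cell].variants.append(key)
        else:
            # shared (>=2 carriers); below-threshold carrier sets still nest
            target = next(n for n in smallest_first if cset <= n.cells)
            target.variants.append(key)

    tree = LineageTree(root)
    _assert_disjoint_paths(tree)
    return tree


def _assert_disjoint_paths(tree: LineageTree) -> None:
    """Variant sets along any root-to-leaf path must be disjoint."""
    def walk(node, seen):
        overlap = seen & set(map(tuple, node.variants))
        if overlap:
            raise AssertionError(
                f"variant assigned to two branches on one path: {sorted(overlap)[:3]}"
            )
        seen = seen | set(map(tuple, node.variants))
        for ch in node.children:
            walk(ch, seen)

    walk(tree.root, set())


# ---------------------------------------------------------------------------
# MRCA dating
# ---------------------------------------------------------------------------

def date_mrca(
    node: CladeNode,
    rate_fit: RateFit,
    donor_age: float,
    private_burdens: dict[str, float],
    offset: float | None = None,
    method: str = "mean",
) -> MRCAEstimate:
    """Date a clade's MRCA from its descendants' private burdens.

    ``t = donor_age - (mean_private_burden - offset) / slope`` with the
    offset defaulting to the fitted intercept (mutations not attributable to
    post-MRCA ageing).  The 95% CI propagates the standard error of the
    burden mean and the slope CI by the delta method.  Estimates past the
    donor age are clipped and flagged.
    """
    if rate_fit.slope <= 0:
        raise ValueError("MRCA dating requires a positive accumulation rate")
    burdens = np.array([private_burdens[c] for c in sorted(node.cells)])
    if len(burdens) == 0:
        raise ValueError("node has no descendant cells with burdens")
    if offset is None:
        offset = rate_fit.intercept
    center = float(np.median(burdens) if method == "median" else np.mean(burdens))
    t = donor_age - (center - offset) / rate_fit.slope

    se_mean = float(np.std(burdens, ddof=1) / np.sqrt(len(burdens))) if len(burdens) > 1 else 0.0
    var_t = (se_mean**2 + rate_fit.se_intercept**2) / rate_fit.slope**2 + (
        (center - offset) ** 2 * rate_fit.se_slope**2
    ) / rate_fit.slope**4
    half = stats.norm.ppf(0.975) * np.sqrt(var_t)
    lo, hi = t - half, t + half
    clipped = False
    if t > donor_age:
        t, clipped = donor_age, True
    return MRCAEstimate(
        node_id=node.id,
        mean_private_burden=center,
        t_mrca=float(t),
        ci95=(float(lo), float(min(hi, donor_age))),
        n_descendants=len(burdens),
        clipped=clipped,
    )


def date_tree(
    tree: LineageTree,
    rate_fit: RateFit,
    donor_age: float,
    private_burdens: dict[str, float],
    offset: float | None = None,
    method: str = "mean",
) -> list[MRCAEstimate]:
    """Date every non-root internal clade of the tree."""
    return [
        date_mrca(n, rate_fit, donor_age, private_burdens, offset, method)
        for n in tree.internal_nodes()
    ]


# ---------------------------------------------------------------------------
# region sharing
# ---------------------------------------------------------------------------

def region_sharing(
    tree: LineageTree,
    region_labels: dict[str, str],
    carriers: dict[tuple, set] | None = None,
):
    """Common vs region-specific shared variants per top-level clade.

    A shared variant is *common* when its carriers span both regions and
    *region-specific* when they are confined to one.  Considers every shared
    variant assigned inside each top-level clade, including the clade's own
    branch.  ``carriers`` (variant key -> carrying cells) refines the carrier
    sets; without it the assigned clade's cell set is used.
    """
    import pandas as pd

    rows = []
    for clade in tree.root.children:
        if len(clade.cells) < 2:
            continue
        n_common = n_specific = 0
        specific_by_region: dict[str, int] = {}
        stack = [clade]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                continue
            for key in node.variants:
                carrying = (
                    carriers.get(tuple(key), node.cells) if carriers else node.cells
                )
                regions = {region_labels[c] for c in carrying}
                if len(regions) > 1:
                    n_common += 1
                else:
                    n_specific += 1
                    (r,) = regions
                    specific_by_region[r] = specific_by_region.get(r, 0) + 1
            stack.extend(node.children)
        total = n_common + n_specific
        regions_present = {region_labels[c] for c in clade.cells}
        note = "" if len(regions_present) > 1 else "single-region clade"
        rows.append(
            {
                "clade": clade.id,
                "n_cells": len(clade.cells),
                "n_shared": total,
                "n_common": n_common,
                "n_specific": n_specific,
                "common_fraction": n_common / total if total else np.nan,
                **{f"specific_{r}": v for r, v in sorted(specific_by_region.items())},
                "note": note,
            }
        )
    return pd.DataFrame(rows)
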