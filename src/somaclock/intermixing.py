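"""Permutation tests of anatomical clonal intermixing.

Two statistics quantify how strongly a lineage tree's anatomical labels
(cerebellar hemisphere vs vermis) segregate with clonal structure:

* the **region-mixing deviation index** of a clade — the size-weighted mean
  absolute deviation of each subcluster's CH fraction from the clade's
  overall CH fraction (0 when every subcluster mirrors the clade ratio); and
* the **nearest-neighbour region-match probability** — the mean, over cells,
  of the fraction of a cell's k nearest tree neighbours (tree distance =
  non-shared branch variants) sharing its region.

Both increase with segregation, so their permutation tests are one-sided
against null distributions from uniform random relabellings that preserve
the marginal label counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lineage import CladeNode, LineageTree


@dataclass
class IntermixResult:
    clade_id: str
    statistic: str  # deviation_index | neighbor_match
    observed: float
    null_mean: float
    null_sd: float
    null_quantiles: dict[str, float]
    p_value: float
    n_permutations: int
    seed: int | None
    degenerate: bool = False

    @property
    def null_summary(self) -> dict:
        return {
            "mean": self.null_mean,
            "sd": self.null_sd,
            **self.null_quantiles,
        }


def _ch_fraction(cells, labels: dict[str, str]) -> float:
    vals = [labels[c] for c in cells]
    return sum(v == "CH" for v in vals) / len(vals)


def deviation_index(
    subclusters: list[frozenset] | list[set], labels: dict[str, str]
) -> float:
    """Size-weighted mean |subcluster CH fraction − clade CH fraction|.

    ``subclusters`` partition the clade's cells (immediate child clades,
    with unclustered leaves as singletons).  A single subcluster gives 0
    (untestable).
    """
    allcells = [c for s in subclusters for c in s]
    if len(subclusters) <= 1:
        return 0.0
    f_clade = _ch_fraction(allcells, labels)
    N = len(allcells)
    return float(
        sum(
            len(s) / N * abs(_ch_fraction(s, labels) - f_clade)
            for s in subclusters
        )
    )


def clade_subclusters(clade: CladeNode) -> list[frozenset]:
    """Immediate children of the clade root (leaves grouped as singletons)."""
    return [ch.cells for ch in clade.children]


def nearest_neighbor_index(names: list[str], D: np.ndarray, k: int) -> np.ndarray:
    """(n, k) indices of each cell's k nearest neighbours.

    Ties broken by cell-id order (``names`` are sorted); self excluded.
    Neighbour identity does not depend on labels, so permutation tests reuse
    this index across relabellings.
    """
    n = len(names)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    order_idx = np.arange(n)
    nn = np.empty((n, k), dtype=int)
    for i in range(n):
        key = np.lexsort((order_idx, D[i]))
        nn[i] = [j for j in key if j != i][:k]
    return nn


def neighbor_match(
    tree: LineageTree, labels: dict[str, str], k: int = 3
) -> float:
    """Mean fraction of each cell's k nearest tree neighbours sharing its region.

    Distance between two cells is the number of branch variants not shared
    by both (tree path length, private variants included).  Ties are broken
    by cell-id order.
    """
    names, D = tree.leaf_distance_matrix()
    nn = nearest_neighbor_index(names, D, k)
    lab = np.array([labels[c] for c in names])
    return float(np.mean(lab[nn] == lab[:, None]))


def permutation_test(
    statistic_fn,
    cells: list[str],
    labels: dict[str, str],
    n_permutations: int = 1000,
    seed: int | None = 0,
    clade_id: str = "",
    statistic_name: str = "",
) -> IntermixResult:
    """One-sided permutation test (null >= observed) for a label statistic.

    ``statistic_fn`` maps a labels dict (for ``cells``) to a float; labels
    are shuffled uniformly among ``cells``, preserving marginal counts.
    Degenerate label sets (a single region) return p = 1 with a flag.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    cells = sorted(cells)
    values = np.array([labels[c] for c in cells])
    observed = float(statistic_fn({c: l for c, l in zip(cells, values)}))
    degenerate = len(set(values)) < 2
    null = np.empty(n_permutations)
    if degenerate:
        null[:] = observed
    else:
        for i in range(n_permutations):
            perm = rng.permutation(values)
            null[i] = statistic_fn({c: l for c, l in zip(cells, perm)})
    p = (1 + np.sum(null >= observed - 1e-12)) / (n_permutations + 1)
    qs = np.quantile(null, [0.025, 0.5, 0.975])
    return IntermixResult(
        clade_id=clade_id,
        statistic=statistic_name,
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_permutations > 1 else 0.0,
        null_quantiles={"q2.5": float(qs[0]), "median": float(qs[1]), "q97.5": float(qs[2])},
        p_value=float(1.0 if degenerate else p),
        n_permutations=n_permutations,
        seed=seed,
        degenerate=degenerate,
    )


def test_deviation_index(
    clade: CladeNode,
    labels: dict[str, str],
    n_permutations: int = 1000,
    seed: int | None = 0,
) -> IntermixResult:
    """Deviation-index permutation test, labels shuffled within the clade."""
    subs = clade_subclusters(clade)

    def stat(lab):
        return deviation_index(subs, lab)

    return permutation_test(
        stat,
        sorted(clade.cells),
        labels,
        n_permutations,
        seed,
        clade_id=clade.id,
        statistic_name="deviation_index",
    )


def test_neighbor_match(
    tree: LineageTree,
    labels: dict[str, str],
    k: int = 3,
    n_permutations: int = 1000,
    seed: int | None = 0,
) -> IntermixResult:
    """Neighbour-match permutation test, labels shuffled tree-wide."""
    names, D = tree.leaf_distance_matrix()
    nn = nearest_neighbor_index(names, D, k)

    def stat(lab):
        arr = np.array([lab[c] for c in names])
        return float(np.mean(arr[nn] == arr[:, None]))

    return permutation_test(
        stat,
        names,
        labels,
        n_permutations,
        seed,
        clade_id=tree.root.id,
        statistic_name="neighbor_match",
    )
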