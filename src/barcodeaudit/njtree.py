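"""Neighbor-joining trees, bootstrap support, monophyly and problem clades.

The tree is built by canonical Saitou-Nei agglomeration on the K2P
distance matrix and kept unrooted (represented with a trifurcating
root).  Monophyly is therefore a bipartition property: a set of leaves
is monophyletic iff some edge separates exactly that set from the rest
— no outgroup is assumed.

Bootstrap support of a bipartition is the percentage of
column-resampled replicates whose NJ tree contains it.  Each replicate
draws from an independent RNG stream derived from (seed, replicate), so
replicates are order-independent.

Problem clades group the species flagged by the Max-WSD >= Min-BSD
diagnostic into connected components of mutual proximity and locate the
smallest tree clade containing each component — the tree-level view of
clusters of species that barcodes fail to discriminate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from barcodeaudit.dataio import BarcodeAlignment, Dataset
from barcodeaudit.distances import (
    DEFAULT_MIN_OVERLAP,
    DistanceMatrix,
    k2p_from_counts_arrays,
)


class Node:
    """Tree node; leaves carry a name, internal nodes may carry support."""

    __slots__ = ("name", "children", "length", "support")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.children: list[Node] = []
        self.length = length
        self.support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted leaf-labelled tree stored with a trifurcating root.

    Bipartitions are canonicalised as the side *not* containing the
    lexicographically smallest leaf, so each internal edge maps to one
    frozenset regardless of orientation.
    """

    root: Node
    n_clamped: int = 0  # negative NJ branch estimates clamped to zero

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                out.append(node.name)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def _leafset_below(self) -> dict[int, frozenset[str]]:
        below: dict[int, frozenset[str]] = {}

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                s = frozenset([node.name])
            else:
                s = frozenset().union(*(walk(c) for c in node.children))
            below[id(node)] = s
            return s

        walk(self.root)
        return below

    def canonical(self, leafset: Iterable[str]) -> frozenset[str]:
        """Canonical form of a bipartition side (side without the min leaf)."""
        all_leaves = frozenset(self.leaves())
        side = frozenset(leafset)
        return all_leaves - side if min(all_leaves) in side else side

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (each side has >= 2 leaves), canonical."""
        all_leaves = frozenset(self.leaves())
        n = len(all_leaves)
        out: set[frozenset[str]] = set()
        below = self._leafset_below()

        def walk(node: Node) -> None:
            s = below[id(node)]
            if 2 <= len(s) <= n - 2:
                out.add(self.canonical(s))
            for c in node.children:
                walk(c)

        for c in self.root.children:
            walk(c)
        return out

    def bipartition_nodes(self) -> dict[frozenset[str], Node]:
        """Canonical non-trivial bipartition -> subtending node (root side)."""
        all_leaves = frozenset(self.leaves())
        n = len(all_leaves)
        out: dict[frozenset[str], Node] = {}
        below = self._leafset_below()

        def walk(node: Node) -> None:
            s = below[id(node)]
            if 2 <= len(s) <= n - 2:
                out[self.canonical(s)] = node
            for c in node.children:
                walk(c)

        for c in self.root.children:
            walk(c)
        return out

    def newick(self, with_supports: bool = True, decimals: int = 8) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.{decimals}f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_supports and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.{decimals}f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def path_length_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path lengths (sorted leaf order)."""
        names = sorted(self.leaves())
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        dist = np.zeros((n, n))

        def walk(node: Node) -> dict[int, float]:
            if node.is_leaf:
                return {idx[node.name]: 0.0}
            merged: dict[int, float] = {}
            child_maps = []
            for c in node.children:
                m = {k: v + c.length for k, v in walk(c).items()}
                child_maps.append(m)
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for i, di in child_maps[a].items():
                        for j, dj in child_maps[b].items():
                            dist[i, j] = dist[j, i] = di + dj
            for m in child_maps:
                merged.update(m)
            return merged

        walk(self.root)
        return names, dist


def neighbor_joining(matrix: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Requires all off-diagonal entries defined and n >= 3.  Among pairs
    minimising the Q criterion, the pair whose sorted cluster keys
    (smallest leaf name per cluster) are lexicographically smallest is
    joined, so results are bit-reproducible.  Negative branch-length
    estimates are clamped to zero with the deficit moved to the sister
    branch (sum preserved); clamps are counted on the returned tree.
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    off_diag = ~np.eye(n, dtype=bool)
    if not matrix.defined[off_diag].all():
        bad = np.argwhere(~matrix.defined & off_diag)
        i, j = bad[0]
        raise ValueError(
            f"undefined distance between {matrix.ids[i]!r} and {matrix.ids[j]!r}; "
            "remove the specimens or impute before tree building"
        )
    D = matrix.values.copy()
    nodes: list[Node] = [Node(name=sid) for sid in matrix.ids]
    keys: list[str] = list(matrix.ids)  # smallest leaf name in each cluster
    active = list(range(n))
    n_clamped = 0

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        # sums[a]+sums[b] is commutative, so Q is bitwise symmetric and the
        # tie scan over a < b always sees the minimum
        Q = (r - 2) * sub - (sums[:, None] + sums[None, :])
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        best = min(
            (tuple(sorted((keys[active[a]], keys[active[b]]))), a, b)
            for a, b in ties
            if a < b
        )
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = D[i, j]
        li = dij / 2 + (sums[ai] - sums[bi]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij  # deficit moved to the sister branch, sum kept
            n_clamped += 1
        elif lj < 0:
            li, lj = dij, 0.0
            n_clamped += 1
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.children = [nodes[i], nodes[j]]
        # distances from the new cluster to all other active clusters
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    # join the final three clusters at the trifurcating root
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    lengths = [la, lb, lc]
    for k in range(3):
        if lengths[k] < 0:
            n_clamped += 1
            lengths[k] = 0.0
    root = Node()
    for node_idx, length in zip((a, b, c), lengths):
        nodes[node_idx].length = length
        root.children.append(nodes[node_idx])
    return Tree(root, n_clamped=n_clamped)


@dataclass
class BootstrapResult:
    """Reference tree with supports attached, plus replicate bookkeeping."""

    tree: Tree
    supports: dict[frozenset[str], float]
    n_replicates: int
    n_retained: int
    n_dropped: int


def _matrix_from_codes(
    ids: Sequence[str], codes: np.ndarray, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceMatrix:
    """K2P matrix straight from an encoded (uint8) alignment matrix."""
    n = len(ids)
    values = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    n_compared = np.zeros((n, n), dtype=np.int64)
    n_sat = n_nov = 0
    np.fill_diagonal(n_compared, (codes != 255).sum(axis=1))
    for i in range(n - 1):
        block = codes[i + 1:]
        row = codes[i]
        valid = (block != 255) & (row != 255)
        diffm = (block != row) & valid
        tsm = diffm & ((block & 1) == (row & 1))
        comp = valid.sum(axis=1)
        ts = tsm.sum(axis=1)
        tv = (diffm & ~tsm).sum(axis=1)
        d, dmask, sat = k2p_from_counts_arrays(comp, ts, tv)
        n_sat += int(sat.sum())
        n_nov += int((comp == 0).sum())
        values[i, i + 1:] = d
        values[i + 1:, i] = d
        defined[i, i + 1:] = dmask
        defined[i + 1:, i] = dmask
        n_compared[i, i + 1:] = comp
        n_compared[i + 1:, i] = comp
    low_conf = (n_compared < min_overlap) & ~np.eye(n, dtype=bool)
    return DistanceMatrix(
        list(ids), values, defined, n_compared, low_conf,
        n_saturated=n_sat, n_no_overlap=n_nov,
    )


def bootstrap_support(
    alignment: BarcodeAlignment,
    n_reps: int = 500,
    seed: int = 0,
    reference_tree: Tree | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> BootstrapResult:
    """Nonparametric bootstrap of NJ node support.

    Columns are resampled with replacement; the K2P matrix and NJ tree
    are recomputed per replicate and each reference bipartition's
    support is the percentage of retained replicates containing it.
    Replicates yielding undefined distances are dropped and counted.
    Replicate r draws from RNG stream (seed, r).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if reference_tree is None:
        reference_tree = neighbor_joining(
            _matrix_from_codes(alignment.ids, alignment.codes, min_overlap)
        )
    ref_bips = reference_tree.bipartitions()
    counts = {b: 0 for b in ref_bips}
    n_cols = alignment.columns
    retained = 0
    dropped = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, n_cols, size=n_cols)
        codes = alignment.codes[:, cols]
        m = _matrix_from_codes(alignment.ids, codes, min_overlap)
        off = ~np.eye(len(m.ids), dtype=bool)
        if not m.defined[off].all():
            dropped += 1
            continue
        retained += 1
        rep_bips = neighbor_joining(m).bipartitions()
        for b in ref_bips:
            if b in rep_bips:
                counts[b] += 1
    supports = {
        b: (100.0 * c / retained if retained else math.nan)
        for b, c in counts.items()
    }
    for bip, node in reference_tree.bipartition_nodes().items():
        node.support = supports[bip]
    return BootstrapResult(
        tree=reference_tree,
        supports=supports,
        n_replicates=n_reps,
        n_retained=retained,
        n_dropped=dropped,
    )


def is_monophyletic(tree: Tree, specimen_set: Iterable[str]) -> bool:
    """True iff some edge of the unrooted tree splits off exactly this set.

    Singletons and the full leaf set are monophyletic by convention.
    """
    leaves = set(tree.leaves())
    target = set(specimen_set)
    unknown = target - leaves
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    if len(target) <= 1 or len(target) >= len(leaves) - 1:
        # singleton, full set, or complement-of-a-leaf: a pendant edge
        # always induces the split
        return True
    return tree.canonical(target) in tree.bipartitions()


@dataclass
class MonophylyCensus:
    """Species-level monophyly verdicts over multi-specimen species."""

    percent_monophyletic: float  # nan when no multi-specimen species exist
    verdicts: dict[str, bool]
    supports: dict[str, float | None]  # subtending-edge support where monophyletic

    @property
    def n_multi(self) -> int:
        return len(self.verdicts)


def monophyly_census(tree: Tree, dataset: Dataset) -> MonophylyCensus:
    """Monophyly verdict for every species with >= 2 specimens.

    For monophyletic species the support of the subtending bipartition
    is reported when bootstrap supports were attached to the tree
    (None for a two-leaf tree side whose edge is trivial or when no
    supports were computed).
    """
    by_species: dict[str, list[str]] = {}
    for r in dataset.records:
        by_species.setdefault(r.species, []).append(r.specimen_id)
    bip_nodes = tree.bipartition_nodes()
    verdicts: dict[str, bool] = {}
    supports: dict[str, float | None] = {}
    for sp, ids in sorted(by_species.items()):
        if len(ids) < 2:
            continue
        mono = is_monophyletic(tree, ids)
        verdicts[sp] = mono
        if mono:
            node = bip_nodes.get(tree.canonical(ids))
            supports[sp] = node.support if node is not None else None
    n_multi = len(verdicts)
    pct = 100.0 * sum(verdicts.values()) / n_multi if n_multi else math.nan
    return MonophylyCensus(pct, verdicts, supports)


@dataclass
class CladeReport:
    """One cluster of species poorly discriminated by barcodes."""

    clade_id: str
    species_counts: dict[str, int]      # all species inside the tree clade
    component_species: list[str]        # the flagged species that seeded it
    min_bsd_range: tuple[float, float]  # within-clade per-species Min-BSD
    min_bsd_mean: float
    support: float | None               # bootstrap support of the clade
    min_bsd_to_closest: float           # distance to nearest outside species
    clade_leaves: frozenset[str] = field(default_factory=frozenset, repr=False)


def _species_pair_min(
    dataset: Dataset, matrix: DistanceMatrix, sp_a: str, sp_b: str
) -> float:
    order = {sid: i for i, sid in enumerate(matrix.ids)}
    ia = [order[r.specimen_id] for r in dataset.records if r.species == sp_a]
    ib = [order[r.specimen_id] for r in dataset.records if r.species == sp_b]
    sub = matrix.values[np.ix_(ia, ib)]
    subdef = matrix.defined[np.ix_(ia, ib)]
    vals = sub[subdef]
    return float(vals.min()) if vals.size else math.nan


def problem_clades(
    tree: Tree,
    diagnostics,
    dataset: Dataset,
    matrix: DistanceMatrix,
    threshold: float = 0.015,
) -> list[CladeReport]:
    """Group flagged species into clusters and locate their tree clades.

    Flagged species are joined into connected components when the
    minimum between-species distance of a pair falls below
    ``threshold`` (default 1.5%, the conventional cutoff for
    exceptionally low interspecific divergence).  For each component
    the smallest clade of the unrooted tree containing all member
    specimens is located; the report covers every species inside that
    clade (nested unflagged species included), the within-clade
    per-species Min-BSD statistics, the clade's bootstrap support and
    its distance to the nearest outside species.
    """
    flagged = sorted(d.species for d in diagnostics if d.failure_flag)
    if not flagged:
        return []
    missing = set(flagged) - {r.species for r in dataset.records}
    if missing:
        raise ValueError(f"flagged species absent from dataset: {sorted(missing)}")
    leaf_set = set(tree.leaves())
    for r in dataset.records:
        if r.specimen_id not in leaf_set:
            raise ValueError(f"specimen {r.specimen_id!r} absent from tree")

    # connected components under "species-pair min distance < threshold"
    parent = {sp: sp for sp in flagged}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(flagged):
        for b in flagged[i + 1:]:
            if _species_pair_min(dataset, matrix, a, b) < threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    components: dict[str, list[str]] = {}
    for sp in flagged:
        components.setdefault(find(sp), []).append(sp)

    # candidate clades: every bipartition side plus the full leaf set
    sides: list[frozenset[str]] = []
    for bip in tree.bipartitions():
        sides.append(bip)
        sides.append(frozenset(leaf_set) - bip)
    sides.append(frozenset(leaf_set))
    bip_nodes = tree.bipartition_nodes()

    specimens_of: dict[str, list[str]] = {}
    species_of_specimen: dict[str, str] = {}
    for r in dataset.records:
        specimens_of.setdefault(r.species, []).append(r.specimen_id)
        species_of_specimen[r.specimen_id] = r.species

    order = {sid: i for i, sid in enumerate(matrix.ids)}
    reports: list[CladeReport] = []
    for comp in sorted(components.values(), key=lambda c: min(c)):
        need = set()
        for sp in comp:
            need.update(specimens_of[sp])
        containing = [s for s in sides if need <= s]
        clade = min(containing, key=lambda s: (len(s), tuple(sorted(s))))
        clade_species = sorted({species_of_specimen[sid] for sid in clade})
        # per-species min distance to another clade species
        per_species_min: list[float] = []
        for sp in clade_species:
            vals = [
                _species_pair_min(dataset, matrix, sp, other)
                for other in clade_species
                if other != sp
            ]
            vals = [v for v in vals if not math.isnan(v)]
            if vals:
                per_species_min.append(min(vals))
        if per_species_min:
            rng_lo, rng_hi = min(per_species_min), max(per_species_min)
            mean = sum(per_species_min) / len(per_species_min)
        else:
            rng_lo = rng_hi = mean = math.nan
        # support of the clade's bipartition (either orientation)
        node = bip_nodes.get(tree.canonical(clade))
        support = node.support if node is not None and clade != leaf_set else None
        # nearest outside species
        inside_idx = [order[sid] for sid in clade]
        outside_idx = [order[sid] for sid in leaf_set - clade]
        if outside_idx:
            sub = matrix.values[np.ix_(inside_idx, outside_idx)]
            subdef = matrix.defined[np.ix_(inside_idx, outside_idx)]
            outvals = sub[subdef]
            closest = float(outvals.min()) if outvals.size else math.nan
        else:
            closest = math.nan
        reports.append(
            CladeReport(
                clade_id="",  # assigned below in sorted order
                species_counts={
                    sp: len([s for s in specimens_of[sp] if s in clade])
                    for sp in clade_species
                },
                component_species=sorted(comp),
                min_bsd_range=(rng_lo, rng_hi),
                min_bsd_mean=mean,
                support=support,
                min_bsd_to_closest=closest,
                clade_leaves=frozenset(clade),
            )
        )
    for i, rep in enumerate(reports):
        rep.clade_id = chr(ord("A") + i) if i < 26 else f"Z{i - 25}"
    return reports
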