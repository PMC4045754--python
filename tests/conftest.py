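"""Shared fixtures: toy datasets built in memory and simulated libraries."""

from __future__ import annotations

import numpy as np
import pytest

from barcodeaudit.dataio import BarcodeAlignment, Dataset, SpecimenRecord
from barcodeaudit.synthetic_data import SimConfig, simulate


_TRANSITION = str.maketrans("AGCT", "GATC")


def transition_flip(seq: str, positions: list[int]) -> str:
    """Swap A<->G / C<->T at the given positions (keeps K2P unsaturated)."""
    chars = list(seq)
    for p in positions:
        chars[p] = chars[p].translate(_TRANSITION)
    return "".join(chars)


def make_dataset(rows) -> Dataset:
    """Build a Dataset from (id, species[, genus], sequence) tuples.

    With 3-tuples the genus is the first token of the species binomial.
    """
    norm = []
    for r in rows:
        if len(r) == 3:
            sid, sp, seq = r
            norm.append((sid, sp, sp.split()[0], seq))
        else:
            norm.append(tuple(r))
    alignment = BarcodeAlignment([r[0] for r in norm], [r[3] for r in norm])
    records = [SpecimenRecord(r[0], r[1], r[2]) for r in norm]
    return Dataset(alignment, records)


@pytest.fixture(scope="session")
def toy_dataset() -> Dataset:
    """Two genera, three species, five specimens, 40 columns."""
    base = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
    mut1 = transition_flip(base, [39])                  # ~2.5% from base
    sib = transition_flip(base, [0, 20])                # congeneric species
    far = transition_flip(base, [0, 5, 10, 15, 20, 25, 30, 35])  # ~20%
    far2 = transition_flip(far, [38])
    return make_dataset(
        [
            ("s1", "Alpha one", "Alpha", base),
            ("s2", "Alpha one", "Alpha", mut1),
            ("s3", "Alpha two", "Alpha", sib),
            ("s4", "Beta one", "Beta", far),
            ("s5", "Beta one", "Beta", far2),
        ]
    )


@pytest.fixture(scope="session")
def sim_clean():
    """Default 5x4x4 simulation, no engineered sharing."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_shared():
    """Simulation with engineered haplotype sharing (p_share = 0.2)."""
    return simulate(SimConfig(seed=11, p_share=0.2))


def random_additive_tree(
    rng: np.random.Generator, n_leaves: int
) -> tuple[list[str], np.ndarray, set[frozenset[str]]]:
    """Random unrooted binary tree with positive branch lengths.

    Built independently of the package: leaves are attached one at a
    time to a random edge of a networkx graph; the path-length matrix
    and the canonical bipartition set are read off the graph.  Serves
    as the oracle for neighbor-joining recovery tests.
    """
    import networkx as nx

    names = [f"t{i:02d}" for i in range(n_leaves)]
    g = nx.Graph()

    def blen() -> float:
        return float(rng.uniform(0.05, 1.0))

    g.add_edge(names[0], names[1], length=blen())
    internal = 0
    for name in names[2:]:
        u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
        length = g[u][v]["length"]
        g.remove_edge(u, v)
        mid = f"x{internal}"
        internal += 1
        split = float(rng.uniform(0.25, 0.75))
        g.add_edge(u, mid, length=length * split)
        g.add_edge(mid, v, length=length * (1 - split))
        g.add_edge(mid, name, length=blen())
    dist = np.zeros((n_leaves, n_leaves))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            dist[i, j] = paths[a][b]
    dist = (dist + dist.T) / 2  # exact symmetry despite summation order
    # bipartitions: remove each internal edge, read the leaf split
    bips: set[frozenset[str]] = set()
    leafset = set(names)
    for u, v in list(g.edges()):
        if u in leafset or v in leafset:
            continue
        h = g.copy()
        h.remove_edge(u, v)
        import networkx as nx2

        comp = nx2.node_connected_component(h, u)
        side = frozenset(comp & leafset)
        if 2 <= len(side) <= n_leaves - 2:
            canon = side if min(leafset) not in side else frozenset(leafset) - side
            bips.add(canon)
    return names, dist, bips
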