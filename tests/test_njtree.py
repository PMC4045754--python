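"""Neighbor joining, bootstrap supports, monophyly, problem clades."""

import math

import numpy as np
import pytest

from barcodeaudit.dataio import BarcodeAlignment
from barcodeaudit.distances import DistanceMatrix, pairwise_matrix
from barcodeaudit.divergence import species_diagnostics
from barcodeaudit.njtree import (
    bootstrap_support,
    is_monophyletic,
    monophyly_census,
    neighbor_joining,
    problem_clades,
)
from conftest import make_dataset, random_additive_tree


def _dm(ids, values):
    values = np.asarray(values, dtype=float)
    n = len(ids)
    return DistanceMatrix(
        list(ids), values, np.ones((n, n), bool),
        np.full((n, n), 1000), np.zeros((n, n), bool),
    )


def test_four_taxon_additive_recovery():
    """Matrix from ((A:1,B:2):1,(C:3,D:4)): split AB|CD, exact lengths."""
    ids = ["A", "B", "C", "D"]
    D = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
    tree = neighbor_joining(_dm(ids, D))
    assert tree.bipartitions() == {frozenset({"C", "D"})}
    names, P = tree.path_length_matrix()
    assert names == ids
    assert np.allclose(P, D, atol=1e-12)


def test_three_taxon_closed_form():
    ids = ["a", "b", "c"]
    D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
    tree = neighbor_joining(_dm(ids, D))
    lengths = {c.name: c.length for c in tree.root.children}
    assert lengths["a"] == pytest.approx((2 + 3 - 5) / 2)
    assert lengths["b"] == pytest.approx((2 + 5 - 3) / 2)
    assert lengths["c"] == pytest.approx((3 + 5 - 2) / 2)


def test_equidistant_matrix_deterministic_tie_break():
    ids = ["d", "b", "c", "a"]
    D = np.ones((4, 4)) - np.eye(4)
    t1 = neighbor_joining(_dm(ids, D))
    t2 = neighbor_joining(_dm(ids, D))
    assert t1.newick() == t2.newick()
    # the tie rule joins the lexicographically smallest pair (a, b) first,
    # leaving the c|d side as the single internal split
    assert t1.bipartitions() == {frozenset({"c", "d"})}


def test_undefined_entries_rejected():
    ids = ["a", "b", "c"]
    D = np.zeros((3, 3))
    m = _dm(ids, D)
    m.defined[0, 1] = m.defined[1, 0] = False
    with pytest.raises(ValueError, match="undefined"):
        neighbor_joining(m)


@pytest.mark.parametrize("n_leaves", [4, 6, 8, 12])
def test_random_additive_trees_recovered_exactly(n_leaves):
    """NJ is consistent on additive matrices: topology and path lengths."""
    rng = np.random.default_rng(100 + n_leaves)
    for rep in range(25):
        names, D, true_bips = random_additive_tree(rng, n_leaves)
        tree = neighbor_joining(_dm(names, D))
        assert tree.bipartitions() == true_bips
        got_names, P = tree.path_length_matrix()
        assert got_names == sorted(names)
        order = [names.index(n) for n in got_names]
        assert np.abs(P - D[np.ix_(order, order)]).max() < 1e-9


def test_nj_matches_external_implementation():
    """Cross-check topology against scikit-bio's neighbor joining."""
    import skbio

    rng = np.random.default_rng(5)
    names, D, _ = random_additive_tree(rng, 9)
    ours = neighbor_joining(_dm(names, D)).bipartitions()
    sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids=names))
    theirs = set()
    total = frozenset(names)
    for node in sk_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(names) - 2:
            canon = side if min(total) not in side else total - side
            theirs.add(canon)
    assert ours == theirs


def test_monophyly_matches_rooted_mrca_oracle():
    """Random 16-leaf trees: bipartition test vs dendropy MRCA after rooting."""
    import dendropy

    rng = np.random.default_rng(77)
    for rep in range(10):
        names, D, _ = random_additive_tree(rng, 16)
        tree = neighbor_joining(_dm(names, D))
        newick = tree.newick(with_supports=False)
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        for _ in range(12):
            k = int(rng.integers(2, 9))
            target = sorted(rng.choice(names, size=k, replace=False).tolist())
            outside = [n for n in names if n not in target]
            # oracle: root at an outgroup leaf, compare MRCA leaf set
            dtree2 = dtree.clone(depth=1)
            og = dtree2.find_node_with_taxon_label(outside[0])
            dtree2.reroot_at_edge(og.edge, update_bipartitions=True)
            mrca = dtree2.mrca(taxon_labels=target)
            mrca_leaves = {lf.taxon.label for lf in mrca.leaf_iter()}
            expected = mrca_leaves == set(target)
            assert is_monophyletic(tree, target) == expected


def test_monophyly_conventions(toy_dataset):
    m = pairwise_matrix(toy_dataset.alignment, min_overlap=5)
    tree = neighbor_joining(m)
    leaves = tree.leaves()
    assert is_monophyletic(tree, [leaves[0]])          # singleton
    assert is_monophyletic(tree, leaves)               # full set
    with pytest.raises(ValueError):
        is_monophyletic(tree, ["nope"])


def test_monophyly_census_toy(toy_dataset):
    m = pairwise_matrix(toy_dataset.alignment, min_overlap=5)
    tree = neighbor_joining(m)
    census = monophyly_census(tree, toy_dataset)
    # Alpha one {s1,s2} and Beta one {s4,s5} are the multi-specimen species
    assert set(census.verdicts) == {"Alpha one", "Beta one"}
    assert census.verdicts["Beta one"] is True


def test_monophyly_census_singleton_only_dataset():
    from conftest import transition_flip

    base = "ACGTACGTACGTACGT"
    ds = make_dataset(
        [
            ("s1", "A a", base),
            ("s2", "A b", transition_flip(base, [0])),
            ("s3", "B c", transition_flip(base, [0, 4, 8, 12])),
        ]
    )
    m = pairwise_matrix(ds.alignment, min_overlap=4)
    census = monophyly_census(neighbor_joining(m), ds)
    assert census.n_multi == 0 and math.isnan(census.percent_monophyletic)


def test_bootstrap_unanimous_support_and_determinism():
    """Every variable column supports the same split -> support 100."""
    rows = {
        "a1": "A" * 60 + "CCCCC",
        "a2": "A" * 60 + "CCCCC",
        "b1": "A" * 60 + "TTTTT",
        "b2": "A" * 60 + "TTTTT",
    }
    aln = BarcodeAlignment(list(rows), list(rows.values()))
    r1 = bootstrap_support(aln, n_reps=30, seed=4, min_overlap=5)
    r2 = bootstrap_support(aln, n_reps=30, seed=4, min_overlap=5)
    split = frozenset({"b1", "b2"})
    assert r1.supports[split] == 100.0
    assert r1.supports == r2.supports
    assert r1.n_dropped == 0


def test_bootstrap_support_invariant_to_leaf_order():
    from conftest import transition_flip

    rng = np.random.default_rng(8)
    base = "".join(rng.choice(list("ACGT"), 120))
    # each taxon mutated at a few distinct positions: related, unsaturated
    rows = [
        transition_flip(base, rng.choice(120, size=3 * (i + 1), replace=False).tolist())
        for i in range(6)
    ]
    ids = [f"t{i}" for i in range(6)]
    aln1 = BarcodeAlignment(ids, rows)
    perm = [3, 0, 5, 1, 4, 2]
    aln2 = BarcodeAlignment([ids[i] for i in perm], [rows[i] for i in perm])
    r1 = bootstrap_support(aln1, n_reps=25, seed=2, min_overlap=10)
    r2 = bootstrap_support(aln2, n_reps=25, seed=2, min_overlap=10)
    assert r1.supports == r2.supports


def test_problem_clades_shared_haplotype_pair():
    from conftest import transition_flip

    seq = "ACGTACGTACGTACGTACGT"
    far = transition_flip(seq, [0, 4, 8, 12, 16])  # 25% transitions, unsaturated
    ds = make_dataset(
        [
            ("s1", "A a", seq),
            ("s2", "A a", seq),
            ("s3", "A b", seq),        # shares haplotype with A a
            ("s4", "A b", seq),
            ("s5", "A c", far),
            ("s6", "A c", far),
        ]
    )
    m = pairwise_matrix(ds.alignment, min_overlap=5)
    tree = neighbor_joining(m)
    diags = species_diagnostics(ds, m)
    clades = problem_clades(tree, diags, ds, m, threshold=0.015)
    assert len(clades) == 1
    c = clades[0]
    assert c.component_species == ["A a", "A b"]
    assert c.min_bsd_mean == pytest.approx(0.0)
    assert c.min_bsd_to_closest > 0.015


def test_problem_clades_component_grouping_matches_brute_force():
    """Three mutually close species + one distant: one 3-species component."""
    from conftest import transition_flip

    s = "ACGTACGTACGTACGTACGTACGTACGTACGT"
    near1 = transition_flip(s, [31])
    near2 = transition_flip(s, [30, 31])
    far = transition_flip(s, [0, 4, 8, 12, 16, 20, 24, 28])
    ds = make_dataset(
        [
            ("s1", "A a", s), ("s2", "A a", s),
            ("s3", "A b", near1), ("s4", "A b", s),      # shares with A a
            ("s5", "A c", near2), ("s6", "A c", near1),  # close to A b
            ("s7", "A d", far), ("s8", "A d", far[:-1] + "C"),
        ]
    )
    m = pairwise_matrix(ds.alignment, min_overlap=5)
    tree = neighbor_joining(m)
    diags = species_diagnostics(ds, m)
    flagged = sorted(d.species for d in diags if d.failure_flag)
    assert "A d" not in flagged
    clades = problem_clades(tree, diags, ds, m, threshold=0.015)
    assert len(clades) == 1
    assert clades[0].component_species == flagged


def test_problem_clades_empty_without_flags(sim_clean):
    ds, _ = sim_clean
    m = pairwise_matrix(ds.alignment)
    tree = neighbor_joining(m)
    diags = species_diagnostics(ds, m)
    assert problem_clades(tree, diags, ds, m) == []
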