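"""Identity matrix, neighbor joining, and bootstrap support."""

import numpy as np
import pytest

from orscout.phylo import (
    IdentityMatrix,
    bootstrap_support,
    build_nj_tree,
    nj_tree_from_identity,
    pairwise_identity_matrix,
)
from orscout.seq import ProtSeq
from orscout.synthetic import (
    random_additive_tree_distances,
    simulate_protein_family,
    simulate_two_clade_family,
)


def test_identical_sequences_identity_100():
    m = pairwise_identity_matrix([ProtSeq("a", "MAYDRY"), ProtSeq("b", "MAYDRY")])
    assert m.values[0, 1] == pytest.approx(100.0)


def test_single_substitution_identity():
    m = pairwise_identity_matrix([ProtSeq("a", "ACDEFGHIK"), ProtSeq("b", "ACDEFGHIR")])
    assert m.values[0, 1] == pytest.approx(100 * 8 / 9, abs=0.01)


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError):
        pairwise_identity_matrix([ProtSeq("a", "MAY"), ProtSeq("a", "MAY")])


def test_matrix_symmetric_diagonal_100():
    prots = simulate_protein_family(6, 150, 0.3, seed=3)
    m = pairwise_identity_matrix(prots)
    assert np.allclose(m.values, m.values.T)
    assert np.allclose(np.diag(m.values), 100.0)
    assert ((m.values >= 0) & (m.values <= 100)).all()


def test_star_family_identity_matches_closed_form():
    """Leaves of a star phylogeny at per-site substitution rate r agree in a
    site with probability (1-r)^2 + r^2/19; pairwise identity should track
    that expectation."""
    rate = 0.2
    expected = 100 * ((1 - rate) ** 2 + rate**2 / 19)
    prots = simulate_protein_family(10, 310, rate, seed=12)
    m = pairwise_identity_matrix(prots, mode="from_msa")
    off = m.values[~np.eye(10, dtype=bool)]
    assert abs(off.mean() - expected) < 2.0
    # per-pair spread: ~4.4 site-sampling SDs at 310 sites
    assert (np.abs(off - expected) < 12.0).all()


def test_from_msa_ignores_shared_gap_columns():
    m = pairwise_identity_matrix(
        [ProtSeq("a", "MA-YD"), ProtSeq("b", "MA-YE")], mode="from_msa"
    )
    assert m.values[0, 1] == pytest.approx(75.0)  # 3 of 4 scored columns


def test_three_taxa_closed_form_branch_lengths():
    d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
    tree = build_nj_tree(d, ["a", "b", "c"])
    lengths = {c.name: c.length for c in tree.root.children}
    assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
    assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
    assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))


def test_clear_quartet_signal():
    labels = ["A", "B", "C", "D"]
    d = np.full((4, 4), 0.5)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 0.1
    d[2, 3] = d[3, 2] = 0.1
    tree = build_nj_tree(d, labels)
    splits = tree.bipartitions()
    assert frozenset({"C", "D"}) in splits or frozenset({"A", "B"}) in splits


def test_asymmetric_matrix_rejected():
    d = np.array([[0, 1.0], [0.5, 0]])
    with pytest.raises(ValueError):
        build_nj_tree(d, ["a", "b"])


def test_nj_recovers_additive_topologies_exactly():
    """On additive distances from random 6-12-taxon trees, NJ must recover
    the generating topology (Robinson-Foulds distance 0, dendropy oracle)
    and reproduce the distances as tree path lengths."""
    import dendropy
    from dendropy.calculate import treecompare

    rng = np.random.default_rng(77)
    for rep in range(60):
        n = int(rng.integers(6, 13))
        d, labels, true_newick, true_splits = random_additive_tree_distances(
            n, seed=1000 + rep
        )
        tree = build_nj_tree(d, labels)
        assert tree.bipartitions() == true_splits
        tns = dendropy.TaxonNamespace()
        t_true = dendropy.Tree.get(data=true_newick, schema="newick", taxon_namespace=tns)
        t_nj = dendropy.Tree.get(
            data=tree.to_newick(with_support=False), schema="newick", taxon_namespace=tns
        )
        t_true.encode_bipartitions()
        t_nj.encode_bipartitions()
        assert treecompare.symmetric_difference(t_true, t_nj) == 0


def test_nj_matches_independent_implementation():
    """Cross-check topology against scikit-bio's neighbor joining."""
    import dendropy
    from dendropy.calculate import treecompare
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    prots = simulate_protein_family(8, 200, 0.25, seed=5)
    m = pairwise_identity_matrix(prots, mode="from_msa")
    tree = nj_tree_from_identity(m)
    sk = skbio_nj(DistanceMatrix(m.to_distances(), ids=m.labels))
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=tree.to_newick(with_support=False), schema="newick",
                           taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=str(sk).strip(), schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    assert treecompare.symmetric_difference(t1, t2) == 0


def test_negative_branch_lengths_clamped_with_raw_retained():
    d = np.array(
        [[0, 0.1, 0.4, 0.4], [0.1, 0, 0.4, 0.4], [0.4, 0.4, 0, 0.02], [0.4, 0.4, 0.02, 0]]
    )
    tree = build_nj_tree(d, list("abcd"))

    def walk(node):
        assert node.length >= 0.0
        for c in node.children:
            walk(c)

    walk(tree.root)


def test_single_replicate_bootstrap_supports_are_0_or_100():
    prots = simulate_protein_family(6, 120, 0.2, seed=9)
    tree = bootstrap_support(prots, n_reps=1, seed=4)
    supports = [n.support for _, n in tree.internal_nodes()]
    assert supports and all(s in (0.0, 100.0) for s in supports)


def test_two_separated_clades_get_high_support():
    seqs, true_splits = simulate_two_clade_family(seed=21)
    tree = bootstrap_support(seqs, n_reps=100, seed=2)
    found = {key: n.support for key, n in tree.internal_nodes()}
    ref = tree.labels[0]
    full = set(tree.labels)
    for split in true_splits:
        key = frozenset(full - split) if ref in split else split
        assert key in found
        assert found[key] >= 95.0


def test_bootstrap_reproducible_for_fixed_seed():
    prots = simulate_protein_family(5, 100, 0.2, seed=1)
    t1 = bootstrap_support(prots, n_reps=20, seed=3).to_newick()
    t2 = bootstrap_support(prots, n_reps=20, seed=3).to_newick()
    assert t1 == t2


def test_identity_matrix_extremes_on_planted_divergence():
    """Min/max of the matrix match the generator's planted extremes: one
    identical duplicate pair (max 100) and one heavily diverged pair."""
    base = simulate_protein_family(1, 200, 0.0, seed=30)[0]
    twin = ProtSeq("twin", base.residues)
    far = simulate_protein_family(1, 200, 0.9, seed=31, prefix="far")[0]
    m = pairwise_identity_matrix([base, twin, far], mode="from_msa")
    lo, hi = m.off_diagonal_range
    assert hi == pytest.approx(100.0)
    assert lo == m.to_dataframe().loc[base.id, "far0"]
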