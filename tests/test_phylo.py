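"""Global alignment vs brute-force enumeration; NJ vs additive matrices;
Newick round-trips through an independent reader (dendropy)."""

import functools

import dendropy
import numpy as np
import pytest

import neuromine as nm
from neuromine.errors import ContractError, SequenceAlphabetError
from neuromine.phylo import AlignScoring, DistanceMatrix, tree_to_newick

SCORING = AlignScoring()

# ------------------------------------------------------------ alignment ----


def oracle_best_score(a, b):
    """Enumerate every global alignment recursively; max score."""

    @functools.lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            best = max(best, SCORING.score(a[i], b[j]) + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, SCORING.gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, SCORING.gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def test_identical_sequences_align_perfectly():
    res = nm.global_align("ACDEFGHIKL", "ACDEFGHIKL")
    assert res.identity_fraction == 1.0
    assert "-" not in res.aligned_a + res.aligned_b


def test_single_substitution_column():
    res = nm.global_align("A", "G")
    assert (res.aligned_a, res.aligned_b) == ("A", "G")


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        nm.global_align("A", "")


def test_bad_character_rejected():
    with pytest.raises(SequenceAlphabetError):
        nm.global_align("AC1", "ACD")


def test_gap_removal_recovers_inputs():
    rng = np.random.default_rng(9)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(20):
        a = "".join(rng.choice(aa, rng.integers(1, 30)))
        b = "".join(rng.choice(aa, rng.integers(1, 30)))
        res = nm.global_align(a, b)
        assert res.aligned_a.replace("-", "") == a
        assert res.aligned_b.replace("-", "") == b
        assert len(res.aligned_a) == len(res.aligned_b)
        assert nm.global_align(b, a).score == res.score


def test_score_equals_bruteforce_enumeration():
    """All pairs of short random sequences (length <= 6): DP score equals
    exhaustive enumeration over every alignment."""
    rng = np.random.default_rng(19)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    seqs = ["".join(rng.choice(aa, rng.integers(1, 7))) for _ in range(14)]
    for i in range(len(seqs)):
        for j in range(i, len(seqs)):
            got = nm.global_align(seqs[i], seqs[j]).score
            assert got == pytest.approx(oracle_best_score(seqs[i], seqs[j]))


def test_self_score_dominates():
    rng = np.random.default_rng(10)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    seqs = ["".join(rng.choice(aa, 12)) for _ in range(8)]
    for s in seqs:
        self_score = nm.global_align(s, s).score
        assert all(
            self_score >= nm.global_align(s, t).score for t in seqs
        )


# ------------------------------------------------------------ distances ----


def test_distance_examples():
    mat = nm.pairwise_distance_matrix([("a", "PFCNAFTGC"), ("b", "PFCNAFTGC")])
    assert mat.values[0, 1] == 0.0
    mat = nm.pairwise_distance_matrix([("a", "AAAA"), ("b", "AAAC")])
    assert mat.values[0, 1] == pytest.approx(0.25)


def test_distance_matrix_invariants():
    rng = np.random.default_rng(12)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    peps = [(f"p{i}", "".join(rng.choice(aa, 15))) for i in range(10)]
    mat = nm.pairwise_distance_matrix(peps)
    assert np.allclose(mat.values, mat.values.T)
    assert np.allclose(np.diag(mat.values), 0.0)
    assert (mat.values >= 0).all()


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="x"):
        nm.pairwise_distance_matrix([("x", "AA"), ("x", "AC")])


# --------------------------------------------------------------- NJ -------


def test_three_taxon_closed_form():
    mat = DistanceMatrix(["A", "B", "C"], [[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
    tree = nm.neighbor_joining(mat)
    lengths = {
        child.label: length for child, length in tree.root.children
    }
    assert lengths["A"] == pytest.approx(0.1)
    assert lengths["B"] == pytest.approx(0.2)
    assert lengths["C"] == pytest.approx(0.3)


def _random_additive(rng, n):
    """Build a random binary tree over n taxa via successive joins; return
    (newick string, additive distance matrix)."""
    labels = [f"t{i}" for i in range(n)]
    nodes = {lab: lab for lab in labels}
    dist = {lab: {lab2: 0.0 for lab2 in labels} for lab in labels}
    # distances via random leaf depths on a random topology: simulate with
    # dendropy for independence
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n,
        rng=rng,
    )
    for leaf, lab in zip(tree.leaf_node_iter(), labels):
        leaf.taxon.label = lab
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    taxa = {t.label: t for t in tree.taxon_namespace}
    values = np.array(
        [[pdm.distance(taxa[a], taxa[b]) for b in labels] for a in labels]
    )
    return tree, DistanceMatrix(labels, values)


def _topology(newick):
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    tree.encode_bipartitions()
    return tns, tree


def test_additive_matrix_recovers_topology():
    """NJ on an exactly additive matrix reproduces the generating tree
    (random trees, 5..8 taxa)."""
    import random as pyrandom

    rng = pyrandom.Random(23)
    for n in (5, 6, 7, 8):
        src_tree, mat = _random_additive(rng, n)
        nj = nm.neighbor_joining(mat)
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(
            data=src_tree.as_string(schema="newick"),
            schema="newick",
            taxon_namespace=tns,
        )
        t2 = dendropy.Tree.get(
            data=tree_to_newick(nj), schema="newick", taxon_namespace=tns
        )
        for t in (t1, t2):  # compare as unrooted trees
            t.is_rooted = False
            t.update_bipartitions()
        dist = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert dist == 0
        assert sorted(nj.leaf_labels()) == sorted(mat.labels)


def test_asymmetric_matrix_rejected():
    mat = DistanceMatrix(["A", "B", "C"], [[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
    with pytest.raises(ContractError):
        nm.neighbor_joining(mat)


def test_negative_branch_clamped_with_warning():
    mat = DistanceMatrix(
        ["A", "B", "C"], [[0, 1.0, 1.0], [1.0, 0, 2.5], [1.0, 2.5, 0]]
    )
    with pytest.warns(UserWarning, match="clamped"):
        tree = nm.neighbor_joining(mat)
    assert all(length >= 0 for _, length in tree.root.children)


# -------------------------------------------------------------- Newick ----


def test_newick_three_taxon_shape(tmp_path):
    mat = DistanceMatrix(["A", "B", "C"], [[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
    path = tmp_path / "t.nwk"
    nm.write_newick(nm.neighbor_joining(mat), path)
    text = path.read_text().strip()
    assert text.startswith("(") and text.endswith(";")
    assert text.count(":") == 3


def test_newick_round_trip_via_dendropy(tmp_path):
    import random as pyrandom

    src, mat = _random_additive(pyrandom.Random(31), 7)
    nj = nm.neighbor_joining(mat)
    path = tmp_path / "t.nwk"
    nm.write_newick(nj, path)
    parsed = dendropy.Tree.get(path=str(path), schema="newick")
    assert sorted(t.label for t in parsed.taxon_namespace) == sorted(mat.labels)
    # lengths preserved to 1e-6
    direct = {}

    def walk(node):
        for child, length in node.children:
            if not child.children:
                direct[child.label] = length
            walk(child)

    walk(nj.root)
    for leaf in parsed.leaf_node_iter():
        assert leaf.edge.length == pytest.approx(
            direct[leaf.taxon.label], abs=1e-6
        )


def test_labels_with_spaces_are_quoted():
    mat = DistanceMatrix(
        ["tax one", "B", "C"], [[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]]
    )
    text = tree_to_newick(nm.neighbor_joining(mat))
    assert "'tax one'" in text
    parsed = dendropy.Tree.get(data=text, schema="newick")
    assert "tax one" in {t.label for t in parsed.taxon_namespace}
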