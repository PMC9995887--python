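"""Distances, neighbor joining, bootstrap and monophyly."""

import io
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode

from pa2c.core import ProteinRecord
from pa2c.phylo import (
    GAP_EXTEND,
    GAP_OPEN,
    MAX_POISSON,
    PhyloError,
    alignment_score,
    bipartitions,
    bootstrap_support,
    clade_monophyly,
    clade_split_supports,
    distance_matrix,
    nj_tree,
    pairwise_distance,
    tree_placement_clade,
)
from pa2c.simulate import GeneratorConfig, make_family, make_protein


def _rec(name, seq):
    return ProteinRecord(id=name, sequence=seq)


# ---------------------------------------------------------------- distances


def _enumerate_alignments(a, b):
    if not a and not b:
        yield [], []
        return
    if a and b:
        for ra, rb in _enumerate_alignments(a[1:], b[1:]):
            yield [a[0]] + ra, [b[0]] + rb
    if a:
        for ra, rb in _enumerate_alignments(a[1:], b):
            yield [a[0]] + ra, ["-"] + rb
    if b:
        for ra, rb in _enumerate_alignments(a, b[1:]):
            yield ["-"] + ra, [b[0]] + rb


def _affine_score(row_a, row_b, matrix):
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(row_a, row_b):
        if ca == "-":
            score += GAP_EXTEND if in_gap_a else GAP_OPEN
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score += GAP_EXTEND if in_gap_b else GAP_OPEN
            in_gap_b, in_gap_a = True, False
        else:
            score += matrix[ca, cb]
            in_gap_a = in_gap_b = False
    return score


def test_alignment_score_matches_exhaustive_enumeration():
    blosum = substitution_matrices.load("BLOSUM62")
    for a, b in [("ACDE", "ACDF"), ("ACD", "AD"), ("WW", "WAW")]:
        oracle = max(
            _affine_score(ra, rb, blosum) for ra, rb in _enumerate_alignments(a, b)
        )
        assert alignment_score(a, b) == pytest.approx(oracle)


def test_pairwise_distance_examples():
    assert pairwise_distance(_rec("a", "MKV"), _rec("b", "MKV")) == 0.0
    # optimal alignment of ACDE/ACDF is gap-free (verified by enumeration
    # above), so p is one mismatch over four columns
    assert pairwise_distance(_rec("a", "ACDE"), _rec("b", "ACDF")) == 0.25
    d = pairwise_distance(_rec("a", "ACDE"), _rec("b", "ACDF"), model="poisson")
    assert d == pytest.approx(-math.log(0.75))


def test_distance_symmetry_on_random_pairs(rng):
    letters = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(5):
        a = "".join(letters[i] for i in rng.integers(0, 20, size=30))
        b = "".join(letters[i] for i in rng.integers(0, 20, size=25))
        assert pairwise_distance(_rec("a", a), _rec("b", b)) == pairwise_distance(
            _rec("b", b), _rec("a", a)
        )


def test_poisson_cap():
    # maximally dissimilar single residues: p = 1 -> capped correction
    d = pairwise_distance(_rec("a", "W" * 10), _rec("b", "P" * 10), model="poisson")
    assert d == MAX_POISSON


# ----------------------------------------------------------------------- NJ


def _four_point_split(dm):
    """Brute-force oracle: the additive split minimizes the pair-sum."""
    a, b, c, d = dm.ids
    sums = {
        frozenset([frozenset([a, b])]): dm[a, b] + dm[c, d],
        frozenset([frozenset([a, c])]): dm[a, c] + dm[b, d],
        frozenset([frozenset([a, d])]): dm[a, d] + dm[b, c],
    }
    return min(sums, key=sums.get)


def test_nj_recovers_four_taxon_additive_topology():
    dm = DistanceMatrix(
        [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], ids=list("ABCD")
    )
    assert _four_point_split(dm) == frozenset([frozenset(["A", "B"])])
    tree = nj_tree(dm)
    assert frozenset(["C", "D"]) in bipartitions(tree, internal_only=True) or frozenset(
        ["A", "B"]
    ) in bipartitions(tree, internal_only=True)


def test_nj_three_taxa_and_minimum_size():
    dm = DistanceMatrix([[0, 2, 3], [2, 0, 4], [3, 4, 0]], ids=list("ABC"))
    tree = nj_tree(dm)
    assert {t.name for t in tree.tips()} == {"A", "B", "C"}
    with pytest.raises(PhyloError):
        nj_tree(DistanceMatrix([[0, 1], [1, 0]], ids=list("AB")))


def _random_additive_tree(rng, n):
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 1.0))) for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(
            children=[nodes[i], nodes[j]], length=float(rng.uniform(0.1, 1.0))
        )
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [merged]
    return TreeNode(children=nodes)


def test_nj_recovers_random_additive_topologies(rng):
    """NJ on an additive matrix reproduces the generating topology exactly."""
    for n in (4, 5, 6, 8):
        for _ in range(3):
            true_tree = _random_additive_tree(rng, n)
            dm = true_tree.tip_tip_distances()
            recovered = nj_tree(DistanceMatrix(dm.data, ids=list(dm.ids)))
            assert bipartitions(recovered, internal_only=True) == bipartitions(
                true_tree, internal_only=True
            )


def test_nj_matches_skbio_reference_on_random_matrices(rng):
    import skbio.tree

    for n in (5, 7):
        base = rng.uniform(0.2, 1.0, size=(n, n))
        data = (base + base.T) / 2
        np.fill_diagonal(data, 0.0)
        dm = DistanceMatrix(data, ids=[f"t{i}" for i in range(n)])
        mine = nj_tree(dm)
        ref = skbio.tree.nj(dm)
        assert bipartitions(mine, internal_only=True) == bipartitions(
            ref, internal_only=True
        )


def test_nj_invariant_to_label_order():
    data = np.array(
        [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], dtype=float
    )
    dm1 = DistanceMatrix(data, ids=list("ABCD"))
    perm = [2, 0, 3, 1]
    dm2 = DistanceMatrix(data[np.ix_(perm, perm)], ids=[list("ABCD")[i] for i in perm])
    assert bipartitions(nj_tree(dm1)) == bipartitions(nj_tree(dm2))


# ---------------------------------------------------------------- bootstrap


def test_bootstrap_determinism_and_single_rep(default_family):
    aln = default_family.alignment
    _, s1 = bootstrap_support(aln, n_reps=10, seed=9)
    _, s2 = bootstrap_support(aln, n_reps=10, seed=9)
    assert s1 == s2
    _, s_one = bootstrap_support(aln, n_reps=1, seed=9)
    assert set(s_one.values()) <= {0.0, 100.0}
    with pytest.raises(PhyloError):
        bootstrap_support(aln, n_reps=0, seed=9)


def test_clean_family_between_clade_supports(default_family):
    tree, supports = bootstrap_support(default_family.alignment, n_reps=100, seed=1)
    split_supports = clade_split_supports(supports, default_family.labels)
    assert set(split_supports) == {"alpha", "beta", "pla2like"}
    assert all(s >= 90 for s in split_supports.values())


# ---------------------------------------------------------------- monophyly


def test_monophyly_simple_and_interleaved():
    tree = TreeNode.read(io.StringIO("((a1,a2),(b1,b2));"))
    count, detail = clade_monophyly(tree, {"a1": "a", "a2": "a", "b1": "b", "b2": "b"})
    assert count == 2 and all(detail.values())

    caterpillar = TreeNode.read(io.StringIO("(x1,(y1,(x2,(y2,(x3,y3)))));"))
    labels = {"x1": "x", "x2": "x", "x3": "x", "y1": "y", "y2": "y", "y3": "y"}
    count, detail = clade_monophyly(caterpillar, labels)
    assert count < 2  # interleaving breaks both groups


def test_monophyly_invariant_under_rerooting(default_family):
    tree = nj_tree(distance_matrix(default_family.records))
    count, _ = clade_monophyly(tree, default_family.labels)
    rerooted = tree.root_at(next(tree.tips()))
    count2, _ = clade_monophyly(rerooted, default_family.labels)
    assert count == count2 == 3


def test_monophyly_requires_labels():
    tree = TreeNode.read(io.StringIO("((a1,a2),(b1,b2));"))
    with pytest.raises(PhyloError):
        clade_monophyly(tree, {"a1": "a"})


# ----------------------------------------------------------- tree placement


def test_tree_placement_recovers_reference_copy(default_family):
    refs = default_family.records
    alpha_ref = next(r for r in refs if r.true_clade == "alpha")
    query = ProteinRecord(id="query", sequence=alpha_ref.sequence)
    clade = tree_placement_clade(query, refs, default_family.labels)
    assert clade == "alpha"


def test_tree_placement_beta_queries():
    cfg = GeneratorConfig(seed=21, n_per_clade=3)
    fam = make_family(cfg)
    rng = np.random.default_rng(22)
    hits = 0
    trials = 20
    for k in range(trials):
        query = make_protein("beta", cfg, rng, record_id=f"q{k}")
        if tree_placement_clade(query, fam.records, fam.labels) == "beta":
            hits += 1
    assert hits / trials >= 0.95


def test_tree_placement_panel_too_small(default_family):
    query = make_protein("alpha", record_id="q")
    # one reference per clade is below the required panel size
    thin_panel = [default_family.records[0], default_family.records[8]]
    with pytest.raises(PhyloError):
        tree_placement_clade(query, thin_panel, default_family.labels)


# ------------------------------------------------------------------- newick


def test_newick_round_trip_preserves_topology_and_supports(default_family, tmp_path):
    tree, _ = bootstrap_support(default_family.alignment, n_reps=20, seed=4)
    path = tmp_path / "tree.nwk"
    tree.write(str(path))
    back = TreeNode.read(str(path))
    assert bipartitions(back, internal_only=True) == bipartitions(
        tree, internal_only=True
    )
    assert {n.name for n in back.non_tips()} == {n.name for n in tree.non_tips()}
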