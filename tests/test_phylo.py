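"""Distance phylogenetics: oracles, additive recovery, bootstrap, lineages."""

import dendropy
import numpy as np
import pytest

from rosaslocus.phylo import (Alignment, DistanceMatrix, LINEAGE_NONE, assign_lineage,
                              bootstrap_support, neighbor_joining, p_distance_matrix,
                              read_newick, write_newick)


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

def naive_p_distance(row_a, row_b, alphabet="nucleotide"):
    valid = "ACGT" if alphabet in ("nucleotide", "codon") else None
    diffs = eff = 0
    for x, y in zip(row_a, row_b):
        if valid is not None:
            if x not in valid or y not in valid:
                continue
        else:
            if x in "-X*.?" or y in "-X*.?":
                continue
        eff += 1
        if x != y:
            diffs += 1
    return diffs / eff, eff


def test_p_distance_simple_cases():
    m = p_distance_matrix(Alignment(["x", "y"], ["ATCG", "ATTA"]))
    assert m.matrix[0, 1] == pytest.approx(0.5)
    m = p_distance_matrix(Alignment(["x", "y"], ["A-CG", "AACG"]))
    assert m.matrix[0, 1] == 0.0
    assert m.effective_sites[0, 1] == 3


def test_p_distance_matches_double_loop_oracle(rng):
    n, length = 20, 500
    rows = ["".join(rng.choice(list("ACGT-N"), size=length, p=[.22, .22, .22, .22, .06, .06]))
            for _ in range(n)]
    aln = Alignment([f"s{i}" for i in range(n)], rows)
    m = p_distance_matrix(aln)
    for i in range(n):
        for j in range(i + 1, n):
            d, eff = naive_p_distance(rows[i], rows[j])
            assert m.matrix[i, j] == pytest.approx(d)
            assert m.effective_sites[i, j] == eff
    # symmetry and row-order invariance
    assert np.allclose(m.matrix, m.matrix.T)
    perm = list(rng.permutation(n))
    m2 = p_distance_matrix(Alignment([aln.ids[i] for i in perm],
                                     [rows[i] for i in perm]))
    for a in range(n):
        for b in range(n):
            assert m2.matrix[a, b] == pytest.approx(m.matrix[perm[a], perm[b]])


def test_zero_effective_sites_pair_is_an_error():
    with pytest.raises(ValueError, match="zero effective sites"):
        p_distance_matrix(Alignment(["x", "y"], ["AA--", "--AA"]))


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def tip_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            out[(a.label, b.label)] = pdm.distance(a, b)
    return out


def test_three_taxon_exact_solution():
    d = DistanceMatrix(["A", "B", "C"],
                       np.array([[0, .2, .3], [.2, 0, .4], [.3, .4, 0]]),
                       np.ones((3, 3)))
    tree = neighbor_joining(d)
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lengths["A"] == pytest.approx(0.05)
    assert lengths["B"] == pytest.approx(0.15)
    assert lengths["C"] == pytest.approx(0.25)


@pytest.mark.parametrize("n_taxa", range(4, 13))
def test_additive_matrix_recovers_generating_tree(n_taxa):
    """NJ is exact on additive distances: round-trip random trees."""
    from rosaslocus.synthetic import random_tree

    tree = random_tree(n_taxa, seed=n_taxa * 17)
    truth = tip_distances(tree)
    ids = sorted({a for a, _ in truth} | {b for _, b in truth})
    m = np.zeros((len(ids), len(ids)))
    for (a, b), v in truth.items():
        i, j = ids.index(a), ids.index(b)
        m[i, j] = m[j, i] = v
    recovered = neighbor_joining(DistanceMatrix(ids, m, np.ones_like(m)))
    got = tip_distances(recovered)
    for pair, v in truth.items():
        assert got[pair] == pytest.approx(v, abs=1e-9)


def test_duplicate_taxon_joined_with_zero_branches():
    d = np.array([[0, 0, .5, .6],
                  [0, 0, .5, .6],
                  [.5, .5, 0, .7],
                  [.6, .6, .7, 0]])
    tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], d, np.ones_like(d)))
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lengths["A"] == pytest.approx(0.0)
    assert lengths["B"] == pytest.approx(0.0)


def test_agrees_with_skbio_reference_nj():
    """Independent cross-check against scikit-bio on a random matrix."""
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(3)
    from rosaslocus.synthetic import random_tree
    tree = random_tree(7, seed=9)
    truth = tip_distances(tree)
    ids = sorted({a for a, _ in truth} | {b for _, b in truth})
    m = np.zeros((7, 7))
    for (a, b), v in truth.items():
        i, j = ids.index(a), ids.index(b)
        m[i, j] = m[j, i] = v
    ours = neighbor_joining(DistanceMatrix(ids, m, np.ones_like(m)))
    theirs = skbio.tree.nj(skbio.DistanceMatrix(m, ids))
    got = tip_distances(ours)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            assert got[(a, b)] == pytest.approx(theirs.find(a).distance(theirs.find(b)),
                                                abs=1e-6)


def test_asymmetric_matrix_rejected():
    m = np.array([[0, .1, .2], [.15, 0, .3], [.2, .3, 0]])
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b", "c"], m, np.ones_like(m))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def two_clade_alignment(n_per_clade=4, length=300, n_fixed=40, seed=5):
    """Two groups separated by many fixed differences."""
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), size=length)
    clade2 = base.copy()
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    sites = rng.choice(length, size=n_fixed, replace=False)
    for s in sites:
        clade2[s] = flip[clade2[s]]
    rows, ids = [], []
    for k in range(n_per_clade):
        for name, seqbase in (("x", base), ("y", clade2)):
            row = seqbase.copy()
            for s in rng.choice(length, size=3, replace=False):
                row[s] = rng.choice(list("ACGT"))
            ids.append(f"{name}{k}")
            rows.append("".join(row))
    return Alignment(ids, rows)


def test_separated_clades_get_high_support():
    aln = two_clade_alignment()
    tree = bootstrap_support(aln, replicates=300, seed=1)
    x_tips = {t for t in (lf.taxon.label for lf in tree.leaf_node_iter())
              if t.startswith("x")}
    supports = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None or node.label is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if side == x_tips or side == (set(aln.ids) - x_tips):
            supports.append(float(node.label))
    assert supports and min(supports) >= 99.0


def test_single_replicate_supports_are_all_or_nothing():
    aln = two_clade_alignment(n_per_clade=3)
    tree = bootstrap_support(aln, replicates=1, seed=2)
    values = {float(n.label) for n in tree.preorder_node_iter()
              if n.label is not None and not n.is_leaf()}
    assert values <= {0.0, 100.0}


def test_bootstrap_deterministic_given_seed():
    aln = two_clade_alignment(n_per_clade=3)
    t1 = bootstrap_support(aln, replicates=50, seed=9)
    t2 = bootstrap_support(aln, replicates=50, seed=9)
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


# ---------------------------------------------------------------------------
# Lineage assignment
# ---------------------------------------------------------------------------

def lineage_tree():
    newick = ("((P1:0.1,(P2:0.1,cand:0.05):0.05):0.2,"
              "((M1:0.1,M2:0.1):0.2,far:0.4):0.1,OG:0.5);")
    return dendropy.Tree.get(data=newick, schema="newick")


def test_candidate_inside_reference_clade_assigned():
    tree = lineage_tree()
    refs = {"Prunus-S": {"P1", "P2"}, "Maleae-S": {"M1", "M2"}}
    out = assign_lineage(["cand", "far"], tree, refs, outgroup="OG")
    by_id = {a.candidate_id: a.lineage for a in out}
    assert by_id["cand"] == "Prunus-S"
    assert by_id["far"] == LINEAGE_NONE


def test_non_exclusive_references_yield_ambiguous():
    tree = lineage_tree()
    refs = {"Prunus-S": {"P1", "M1"}, "Maleae-S": {"M2"}}
    out = assign_lineage(["cand"], tree, refs, outgroup="OG")
    assert out[0].lineage == "ambiguous"


def test_missing_outgroup_is_an_error():
    with pytest.raises(ValueError, match="outgroup"):
        assign_lineage(["cand"], lineage_tree(), {"L": {"P1"}}, outgroup="nope")


def test_newick_round_trip(tmp_path):
    tree = lineage_tree()
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = read_newick(path)
    assert {l.taxon.label for l in back.leaf_node_iter()} == \
           {l.taxon.label for l in tree.leaf_node_iter()}
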