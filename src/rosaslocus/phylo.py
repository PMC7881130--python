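"""Distance phylogenetics: p-distance, neighbor-joining, bootstrap, lineages.

These are the low-coverage-genome analyses of the screen: evolutionary
distances are observed proportions of differing sites (p-distance) with
pairwise deletion of gapped/ambiguous positions, trees come from the
Saitou–Nei neighbor-joining agglomeration, and clade support from
nonparametric bootstrap over alignment columns (codon columns for codon
alignments).  Candidate sequences are assigned to S-RNase lineages by
their placement relative to labelled reference clades on an
outgroup-rooted tree.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .config import NUCLEOTIDES

logger = logging.getLogger(__name__)

GAP = "-"

LINEAGE_NONE = "non-S-RNase-lineage"
LINEAGE_AMBIGUOUS = "ambiguous"


@dataclass
class Alignment:
    """A multiple alignment: equal-length rows over a declared alphabet."""

    ids: list[str]
    rows: list[str]
    alphabet: str = "nucleotide"        # nucleotide | amino-acid | codon

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]
        if self.alphabet == "codon":
            if self.length % 3 != 0:
                raise ValueError("codon alignment length not divisible by 3")
            for rid, row in zip(self.ids, self.rows):
                for i in range(0, len(row), 3):
                    codon = row[i:i + 3]
                    if GAP in codon and codon != GAP * 3:
                        raise ValueError(
                            f"row {rid!r}: gap not in whole-codon units at column {i}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: list[str]) -> "Alignment":
        index = {rid: row for rid, row in zip(self.ids, self.rows)}
        return Alignment(list(ids), [index[i] for i in ids], self.alphabet)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray                   # symmetric, zero diagonal
    effective_sites: np.ndarray          # per-pair site counts after deletion

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix is not symmetric")


def _valid_mask(row: str, alphabet: str) -> np.ndarray:
    arr = np.frombuffer(row.encode(), dtype="S1")
    if alphabet in ("nucleotide", "codon"):
        valid = np.isin(arr, [b.encode() for b in NUCLEOTIDES])
    else:
        # amino acid: gaps, X and non-standard symbols are excluded
        invalid = np.isin(arr, [b"-", b"X", b"*", b".", b"?"])
        valid = ~invalid
    return valid


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Observed proportion of differing sites, with pairwise deletion.

    For each pair, sites where either row carries a gap or an ambiguity
    symbol are excluded; the distance is differences over the remaining
    (effective) sites.  A pair with no effective sites is an error.
    """
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(aln)
    chars = np.array([np.frombuffer(r.encode(), dtype="S1") for r in aln.rows])
    valid = np.array([_valid_mask(r, aln.alphabet) for r in aln.rows])
    dist = np.zeros((n, n))
    eff = np.zeros((n, n), dtype=int)
    for i in range(n):
        eff[i, i] = int(valid[i].sum())
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"pair ({aln.ids[i]!r}, {aln.ids[j]!r}) has zero effective sites")
            diffs = int(np.count_nonzero(chars[i][both] != chars[j][both]))
            dist[i, j] = dist[j, i] = diffs / m
            eff[i, j] = eff[j, i] = m
    return DistanceMatrix(list(aln.ids), dist, eff)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Ties in the Q criterion are broken by the lowest (i, j) index pair;
    negative branch lengths are clamped to zero with the deficit logged.
    The returned tree is unrooted (trifurcating seed node).
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(d.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes: list[dendropy.Node] = []
    for label in d.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    dist = d.matrix.astype(float).copy()
    active = list(range(n))

    def clamp(value: float) -> float:
        if value < 0.0:
            logger.debug("clamping negative branch length %.6g to 0", value)
            return 0.0
        return value

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie break: scan in (i, j) order
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or q[a, b] < best[0] - 1e-15:
                    best = (q[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        vi = clamp(0.5 * sub[a, b] + (r[a] - r[b]) / (2.0 * (m - 2)))
        vj = clamp(sub[a, b] - (0.5 * sub[a, b] + (r[a] - r[b]) / (2.0 * (m - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = vi
        parent.add_child(nodes[j])
        nodes[j].edge.length = vj
        # distances from the new node
        new_index = len(nodes)
        nodes.append(parent)
        grow = np.zeros((len(nodes), len(nodes)))
        grow[:-1, :-1] = dist
        for c in active:
            if c in (i, j):
                continue
            duk = 0.5 * (dist[i, c] + dist[j, c] - dist[i, j])
            grow[new_index, c] = grow[c, new_index] = max(duk, 0.0)
        dist = grow
        active = [c for c in active if c not in (i, j)] + [new_index]

    # join the last three nodes on a central (unrooted) vertex
    a, b, c = active
    va = clamp(0.5 * (dist[a, b] + dist[a, c] - dist[b, c]))
    vb = clamp(0.5 * (dist[a, b] + dist[b, c] - dist[a, c]))
    vc = clamp(0.5 * (dist[a, c] + dist[b, c] - dist[a, b]))
    center = dendropy.Node()
    for node, v in ((nodes[a], va), (nodes[b], vb), (nodes[c], vc)):
        center.add_child(node)
        node.edge.length = v
    tree.seed_node = center
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _resample_columns(aln: Alignment, rng: np.random.Generator) -> Alignment:
    if aln.alphabet == "codon":
        n_units = aln.length // 3
        picks = rng.integers(0, n_units, size=n_units)
        rows = ["".join(row[3 * k: 3 * k + 3] for k in picks) for row in aln.rows]
    else:
        picks = rng.integers(0, aln.length, size=aln.length)
        rows = ["".join(row[k] for k in picks) for row in aln.rows]
    return Alignment(list(aln.ids), rows, aln.alphabet)


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits as frozensets of tip labels (smaller side)."""
    all_tips = frozenset(t.label for t in tree.taxon_namespace)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_tips - side
        if len(side) <= 1 or len(other) <= 1:
            continue
        splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def bootstrap_support(aln: Alignment, replicates: int, seed: int) -> dendropy.Tree:
    """NJ tree of the full alignment with bootstrap supports (0–100).

    Columns (codon columns for the codon alphabet) are resampled with
    replacement; each internal edge's support is the percentage of
    replicate NJ trees containing its bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = neighbor_joining(p_distance_matrix(aln))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(replicates):
        rep = _resample_columns(aln, rng)
        try:
            rep_tree = neighbor_joining(p_distance_matrix(rep))
        except ValueError:
            continue        # a replicate may delete all shared sites of a pair
        for split in _bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    all_tips = frozenset(t.label for t in tree.taxon_namespace)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_tips - side
        if len(side) <= 1 or len(other) <= 1:
            continue
        key = min(side, other, key=lambda s: (len(s), sorted(s)))
        node.label = f"{100.0 * counts.get(key, 0) / replicates:g}"
    return tree


# ---------------------------------------------------------------------------
# Lineage assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineageAssignment:
    candidate_id: str
    lineage: str
    support: float | None = None


def assign_lineage(
    candidate_ids: list[str],
    tree: dendropy.Tree,
    reference_labels: dict[str, set[str]],
    outgroup: str,
) -> list[LineageAssignment]:
    """Place candidates into reference lineages on an outgroup-rooted tree.

    A candidate is assigned to a lineage iff it lies inside the smallest
    rooted clade containing all of that lineage's references and none of
    any other lineage's.  A lineage whose defining clade captures foreign
    references yields ``ambiguous`` assignments for candidates inside it;
    candidates outside every valid clade are ``non-S-RNase-lineage``.
    """
    work = tree.clone(depth=1)
    labels = {t.label for t in work.taxon_namespace}
    if outgroup not in labels:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    for lineage, refs in reference_labels.items():
        missing = set(refs) - labels
        if missing:
            raise ValueError(f"lineage {lineage!r} references missing from tree: {sorted(missing)}")
    og_node = work.find_node_with_taxon_label(outgroup)
    work.reroot_at_edge(og_node.edge, update_bipartitions=False)
    work.is_rooted = True

    all_refs = {rid: lin for lin, refs in reference_labels.items() for rid in refs}
    clades: dict[str, tuple[set[str], float | None, bool]] = {}
    for lineage, refs in reference_labels.items():
        mrca = work.mrca(taxon_labels=sorted(refs))
        leaves = {lf.taxon.label for lf in mrca.leaf_iter()}
        foreign = {l for l in leaves if l in all_refs and all_refs[l] != lineage}
        support = None
        if mrca.label is not None:
            try:
                support = float(mrca.label)
            except ValueError:
                support = None
        clades[lineage] = (leaves, support, bool(foreign))
        if foreign:
            logger.warning("lineage %s references are not exclusive: clade also holds %s",
                           lineage, sorted(foreign))

    out: list[LineageAssignment] = []
    for cid in candidate_ids:
        if cid not in labels:
            raise ValueError(f"candidate {cid!r} not in tree")
        assigned = None
        for lineage, (leaves, support, tainted) in clades.items():
            if cid in leaves:
                if tainted:
                    assigned = LineageAssignment(cid, LINEAGE_AMBIGUOUS, support)
                else:
                    assigned = LineageAssignment(cid, lineage, support)
                break
        out.append(assigned or LineageAssignment(cid, LINEAGE_NONE))
    return out


# ---------------------------------------------------------------------------
# Codon-aware alignment (peptide alignment back-mapped to codons)
# ---------------------------------------------------------------------------

def align_codon_sequences(cds: dict[str, str]) -> Alignment:
    """Codon-aware multiple alignment of in-frame coding sequences.

    Sequences are translated, the peptides aligned with mafft, and the
    peptide alignment back-mapped to codons, so gaps always appear in
    whole-codon units.  Alignment fidelity is not a contribution of this
    package; an externally produced alignment can be supplied anywhere an
    Alignment is accepted.
    """
    from .candidates import translate_cds

    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH")
    peptides = {}
    for rid, seq in cds.items():
        if len(seq) % 3 != 0:
            raise ValueError(f"{rid!r}: CDS length not divisible by 3")
        pep, pseudo = translate_cds(seq)
        if pseudo:
            raise ValueError(f"{rid!r}: internal stop codon")
        peptides[rid] = pep
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fa"
        with open(infile, "w") as fh:
            for rid, pep in peptides.items():
                fh.write(f">{rid}\n{pep}\n")
        res = subprocess.run(
            ["mafft", "--quiet", "--auto", str(infile)],
            capture_output=True, text=True, check=True,
        )
    aligned: dict[str, str] = {}
    current = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            current = line[1:].split()[0]
            aligned[current] = ""
        elif current:
            aligned[current] += line.strip()
    rows = []
    for rid in cds:
        codons = [cds[rid][i:i + 3] for i in range(0, len(cds[rid]), 3)]
        row, k = [], 0
        for aa in aligned[rid].upper():
            if aa == GAP:
                row.append(GAP * 3)
            else:
                row.append(codons[k])
                k += 1
        # trailing stop codon (translated away) is dropped
        rows.append("".join(row))
    return Alignment(list(cds.keys()), rows, "codon")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
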