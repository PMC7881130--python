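"""Synthetic genomes, codon alignments and count matrices with known truth.

Every downstream stage of the screen is testable without a download:
the generator plants S-RNase-like genes with controlled isoelectric
point, motif content, intron structure and strand into random background
sequence, simulates codon alignments under site models with known omega
classes, and draws per-tissue count matrices from archetypal expression
profiles.  All outputs are pure functions of (spec, seed).

Planted genes are flanked by in-frame stop codons so the stop-to-stop
ORF of the correct frame is exactly the planted CDS, and their peptides
are derived from the bundle's reference peptide so the similarity screen
can recover them at a calibrated threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .config import CODON_TABLE, DEFAULT_PATTERN1, DEFAULT_PATTERN2, reverse_complement
from .expression import TISSUES
from .isoelectric import isoelectric_point
from .motifs import ABSENT, RELAXED_Y, STRICT, ProsofilePattern, match_pattern, parse_pattern
from .seqio import NucleotideSequence

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

MOTIF1_CHOICES = ("present_strict", "present_relaxed_Y", "absent")
MOTIF2_CHOICES = ("present", "absent")

MAX_PI_ATTEMPTS = 10_000

#: archetypal tissue profiles in FPKM units
EXPRESSION_ARCHETYPES: dict[str, dict[str, float]] = {
    "pistil_ovary_high": {"pistil_ovary": 200.0, "stamen": 2.0,
                          "leaf": 0.1, "stem": 0.1, "root": 0.1},
    "stamen_only": {"pistil_ovary": 0.1, "stamen": 100.0,
                    "leaf": 0.1, "stem": 0.1, "root": 0.1},
    "broad": {"pistil_ovary": 50.0, "stamen": 50.0,
              "leaf": 50.0, "stem": 50.0, "root": 50.0},
    "not_expressed": {t: 0.0 for t in TISSUES},
}


@dataclass(frozen=True)
class PlantedGeneSpec:
    """Ground-truth description of one gene to plant."""

    gene_id: str
    target_pi_band: tuple[float, float] = (8.0, 10.0)
    motif1: str = "present_strict"
    motif2: str = "present"
    intron_count: int = 0
    cds_length_nt: int = 600
    strand: str = "+"
    divergence_from_reference: float = 0.25
    expression_class: str = "pistil_ovary_high"

    def __post_init__(self) -> None:
        if self.cds_length_nt < 120 or self.cds_length_nt % 3 != 0:
            raise ValueError("cds_length_nt must be >= 120 and divisible by 3")
        lo, hi = self.target_pi_band
        if not lo < hi:
            raise ValueError("target_pi_band min must be < max")
        if self.motif1 not in MOTIF1_CHOICES:
            raise ValueError(f"motif1 must be one of {MOTIF1_CHOICES}")
        if self.motif2 not in MOTIF2_CHOICES:
            raise ValueError(f"motif2 must be one of {MOTIF2_CHOICES}")
        if self.intron_count < 0:
            raise ValueError("intron_count must be >= 0")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.expression_class not in EXPRESSION_ARCHETYPES:
            raise ValueError(f"unknown expression_class {self.expression_class!r}")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length_nt: int = 100_000
    gc_content: float = 0.42
    noise_model: str = "poisson"          # poisson | negative_binomial
    nb_dispersion: float = 0.2            # var = mu + dispersion * mu^2

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ValueError("noise_model must be poisson or negative_binomial")


@dataclass(frozen=True)
class PlantedGeneTruth:
    gene_id: str
    contig: str
    start: int                  # 0-based half-open gene span (introns included)
    end: int
    strand: str
    spliced_cds: str
    peptide: str
    expected_pi: float
    motif1_status: str
    motif2_status: str
    intron_count: int
    expression_class: str


@dataclass
class SyntheticBundle:
    contigs: dict[str, str]
    truth: list[PlantedGeneTruth]
    reference_peptides: dict[str, str]
    count_matrix: pd.DataFrame = field(default_factory=pd.DataFrame)
    library_sizes: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def contig_records(self) -> list[NucleotideSequence]:
        return [NucleotideSequence(cid, seq) for cid, seq in self.contigs.items()]


class PiBandError(RuntimeError):
    """Raised when no peptide satisfying the requested pI band was found."""


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _realize_pattern(pattern: ProsofilePattern, rng: np.random.Generator,
                     first_override: str | None = None) -> str:
    """A concrete peptide string matching the pattern (minimal repeats)."""
    out = []
    for k, elem in enumerate(pattern.elements):
        for _ in range(elem.min_rep):
            if k == 0 and first_override is not None:
                out.append(first_override)
                continue
            if elem.allowed is None:
                out.append(rng.choice(list(AMINO_ACIDS)))
            elif elem.negated:
                pool = sorted(set(AMINO_ACIDS) - elem.allowed)
                out.append(rng.choice(pool))
            else:
                out.append(rng.choice(sorted(elem.allowed)))
    return "".join(out)


def _back_translate(peptide: str, rng: np.random.Generator) -> str:
    by_aa: dict[str, list[str]] = {}
    for codon, aa in CODON_TABLE.items():
        by_aa.setdefault(aa, []).append(codon)
    return "".join(rng.choice(sorted(by_aa[aa])) for aa in peptide)


def _build_peptide(spec: PlantedGeneSpec, reference: str, rng: np.random.Generator,
                   pattern1: ProsofilePattern, pattern2: ProsofilePattern) -> str:
    """Peptide satisfying the spec's pI band and motif statuses.

    Starts from the bundle reference (so the similarity screen finds it),
    plants or removes motif instances, then rejection-samples basic (K/R)
    or acidic (D/E) substitutions at unprotected positions until the pI
    lands in the band; bounded at 10,000 attempts.
    """
    n_aa = spec.cds_length_nt // 3
    base = list((reference * (n_aa // len(reference) + 1))[:n_aa])
    n_mut = int(round(spec.divergence_from_reference * n_aa))
    for pos in rng.choice(n_aa, size=n_mut, replace=False):
        base[pos] = rng.choice(list(AMINO_ACIDS))

    protected: set[int] = set()
    m1_instance = None
    if spec.motif1 == "present_strict":
        m1_instance = _realize_pattern(pattern1, rng)
    elif spec.motif1 == "present_relaxed_Y":
        m1_instance = _realize_pattern(pattern1, rng, first_override="Y")
    m2_instance = _realize_pattern(pattern2, rng) if spec.motif2 == "present" else None
    if m1_instance:
        off1 = n_aa // 4
        base[off1:off1 + len(m1_instance)] = list(m1_instance)
        protected |= set(range(off1, off1 + len(m1_instance)))
    if m2_instance:
        off2 = (2 * n_aa) // 3
        base[off2:off2 + len(m2_instance)] = list(m2_instance)
        protected |= set(range(off2, off2 + len(m2_instance)))

    free = [i for i in range(n_aa) if i not in protected]
    lo, hi = spec.target_pi_band
    target1 = {"present_strict": STRICT, "present_relaxed_Y": RELAXED_Y,
               "absent": ABSENT}[spec.motif1]
    target2 = spec.motif2 == "present"

    def break_match(pattern: ProsofilePattern, relax: bool) -> None:
        """Mutate one free residue inside an unwanted pattern match."""
        import re

        from .motifs import _relax_first_position, pattern_to_regex

        pat = _relax_first_position(pattern) if relax else pattern
        m = re.search(pattern_to_regex(pat), "".join(base))
        span = range(m.start(), m.end()) if m else free
        pool = [i for i in span if i in set(free)] or free
        base[int(rng.choice(pool))] = rng.choice(list("GASTNQ"))

    for attempt in range(MAX_PI_ATTEMPTS):
        pep = "".join(base)
        s1 = match_pattern(pep, pattern1, relaxed_first_position=True)
        s2 = match_pattern(pep, pattern2) != ABSENT
        if s1 != target1 or s2 != target2:
            # destroy the accidental match and retry
            if s1 != target1:
                break_match(pattern1, relax=(s1 == RELAXED_Y))
            else:
                break_match(pattern2, relax=False)
            continue
        pi = isoelectric_point(pep)
        if lo < pi < hi:
            return pep
        pos = int(rng.choice(free))
        base[pos] = rng.choice(["K", "R"]) if pi <= lo else rng.choice(["D", "E"])
    raise PiBandError(
        f"gene {spec.gene_id!r}: no peptide with pI in ({lo}, {hi}) "
        f"after {MAX_PI_ATTEMPTS} attempts")


def _insert_introns(cds: str, n_introns: int, rng: np.random.Generator) -> str:
    """Insert GT..AG introns (>= 20 nt) at distinct codon boundaries."""
    if n_introns == 0:
        return cds
    n_codons = len(cds) // 3
    boundaries = rng.choice(np.arange(1, n_codons), size=n_introns, replace=False)
    pieces = []
    prev = 0
    for b in sorted(boundaries):
        pieces.append(cds[3 * prev: 3 * b])
        inner = _random_sequence(rng, int(rng.integers(16, 60)), 0.4)
        pieces.append("GT" + inner + "AG")
        prev = b
    pieces.append(cds[3 * prev:])
    return "".join(pieces)


def generate_genome(specs: list[PlantedGeneSpec], cfg: SimulationConfig) -> SyntheticBundle:
    """Plant the specified genes into one random contig.

    Each planted cassette is TAA + gene + TAA on its coding strand, so
    stop-to-stop ORF extraction recovers exactly the planted CDS (for
    intronless genes).  The truth table records coordinates (0-based
    half-open), strand, spliced CDS, recomputed pI and motif statuses.
    """
    if not specs:
        raise ValueError("need at least one PlantedGeneSpec")
    if len({s.gene_id for s in specs}) != len(specs):
        raise ValueError("duplicate gene ids")
    rng = np.random.default_rng(cfg.seed)
    pattern1 = parse_pattern(DEFAULT_PATTERN1, "pattern1")
    pattern2 = parse_pattern(DEFAULT_PATTERN2, "pattern2")

    reference = "".join(rng.choice(list(AMINO_ACIDS), size=220))
    # the reference itself should look like an S-RNase: give it both motifs
    m1 = _realize_pattern(pattern1, rng)
    m2 = _realize_pattern(pattern2, rng)
    reference = reference[:50] + m1 + reference[50 + len(m1):]
    reference = reference[:150] + m2 + reference[150 + len(m2):]

    cassettes = []
    truths = []
    for spec in specs:
        pep = _build_peptide(spec, reference, rng, pattern1, pattern2)
        cds = _back_translate(pep, rng)
        gene_seq = _insert_introns(cds, spec.intron_count, rng)
        cassette = "TAA" + gene_seq + "TAA"
        if spec.strand == "-":
            cassette = reverse_complement(cassette)
        cassettes.append((spec, pep, cds, gene_seq, cassette))

    total = sum(len(c[-1]) for c in cassettes)
    if total >= cfg.genome_length_nt:
        raise ValueError("planted genes exceed the genome length")

    n_gaps = len(cassettes) + 1
    slack = cfg.genome_length_nt - total
    cuts = np.sort(rng.choice(np.arange(1, slack), size=n_gaps - 1, replace=False))
    gap_lengths = np.diff(np.concatenate([[0], cuts, [slack]]))

    contig_id = "contig_1"
    parts = []
    pos = 0
    for k, (spec, pep, cds, gene_seq, cassette) in enumerate(cassettes):
        background = _random_sequence(rng, int(gap_lengths[k]), cfg.gc_content)
        parts.append(background)
        pos += len(background)
        gene_start = pos + 3          # skip the leading TAA
        gene_end = gene_start + len(gene_seq)
        if spec.strand == "-":
            # cassette was reverse complemented: the trailing TAA leads now
            gene_start = pos + 3
            gene_end = gene_start + len(gene_seq)
        parts.append(cassette)
        pos += len(cassette)
        truths.append(PlantedGeneTruth(
            gene_id=spec.gene_id, contig=contig_id,
            start=gene_start, end=gene_end, strand=spec.strand,
            spliced_cds=cds, peptide=pep,
            expected_pi=isoelectric_point(pep),
            motif1_status=match_pattern(pep, pattern1, relaxed_first_position=True),
            motif2_status="present" if match_pattern(pep, pattern2) != ABSENT else "absent",
            intron_count=spec.intron_count,
            expression_class=spec.expression_class,
        ))
    parts.append(_random_sequence(rng, int(gap_lengths[-1]), cfg.gc_content))
    contig = "".join(parts)

    bundle = SyntheticBundle(
        contigs={contig_id: contig},
        truth=truths,
        reference_peptides={"REF_SRNASE": reference},
    )
    profiles = {
        spec.gene_id: EXPRESSION_ARCHETYPES[spec.expression_class] for spec in specs
    }
    lengths = {spec.gene_id: spec.cds_length_nt for spec in specs}
    bundle.count_matrix, bundle.library_sizes = generate_counts(
        profiles, cfg, lengths=lengths)
    return bundle


def generate_counts(
    profiles: dict[str, dict[str, float]],
    cfg: SimulationConfig,
    lengths: dict[str, int] | None = None,
    library_size: float = 2e7,
) -> tuple[pd.DataFrame, pd.Series]:
    """Integer count matrix from per-tissue FPKM-scale mean profiles.

    Mean counts are FPKM * library_size * length / 1e9 (20 M fragments
    per tissue library by default, a typical RNA-seq depth — deep enough
    that single stray counts cannot cross FPKM thresholds); noise is Poisson
    or negative binomial per the config.  Returns (counts, library sizes).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genes = list(profiles)
    for g in genes:
        missing = [t for t in TISSUES if t not in profiles[g]]
        if missing:
            raise ValueError(f"gene {g!r}: missing tissues {missing}")
        if any(v < 0 for v in profiles[g].values()):
            raise ValueError(f"gene {g!r}: negative mean")
    lengths = lengths or {}
    mat = np.zeros((len(genes), len(TISSUES)), dtype=int)
    for i, g in enumerate(genes):
        length = lengths.get(g, 1000)
        for j, t in enumerate(TISSUES):
            mu = profiles[g][t] * library_size * length / 1e9
            if mu == 0:
                mat[i, j] = 0
            elif cfg.noise_model == "poisson":
                mat[i, j] = rng.poisson(mu)
            else:
                # NB with var = mu + d * mu^2
                d = cfg.nb_dispersion
                r = 1.0 / d
                p = r / (r + mu)
                mat[i, j] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(mat, index=genes, columns=list(TISSUES))
    lib = pd.Series(library_size, index=list(TISSUES), name="library_size")
    return counts, lib


def power_study_tree() -> dendropy.Tree:
    """The fixed 6-taxon tree of the selection power study.

    Balanced, all branches 0.3 substitutions/codon (tree length 2.7) —
    the scale used in codon-model power simulations.
    """
    newick = "((t1:0.3,t2:0.3):0.3,(t3:0.3,t4:0.3):0.3,(t5:0.3,t6:0.3):0.3);"
    return dendropy.Tree.get(data=newick, schema="newick")


#: the positive-selection alternative of the power study: one fifth of
#: sites under omega=5, the rest split between purifying and neutral
def power_study_alternative():
    from .codonmodels import SiteModelParams

    return SiteModelParams(model="M2a", p0=0.5, p1=0.3, omega0=0.1, omega2=5.0,
                           kappa=2.0)


def power_study_null():
    from .codonmodels import SiteModelParams

    return SiteModelParams(model="M1a", p0=0.5, omega0=0.1, kappa=2.0)


def synthetic_assay_template(seed: int = 0, product_length: int = 353,
                             flank: int = 150) -> NucleotideSequence:
    """SYNTHETIC stand-in for the genotyping-assay amplicon template.

    A random linear template carrying exact binding sites for the RA-F /
    RA-R primer pair spaced so the primer-inclusive product is
    ``product_length`` nt (the assay's expected size), with one DdeI and
    one HinfI site inside the amplicon.  This is generated data, not the
    deposited accession: it exercises the assay logic (degenerate
    matching, product-size arithmetic, restriction patterns) with the
    real primer sequences.
    """
    from .config import PRIMER_RA_F, PRIMER_RA_R

    rng = np.random.default_rng(seed)

    def concrete(primer: str) -> str:
        from .config import IUPAC_SETS
        return "".join(rng.choice(sorted(IUPAC_SETS[s])) for s in primer)

    fwd_site = concrete(PRIMER_RA_F)
    rev_site = reverse_complement(concrete(PRIMER_RA_R))
    inner_len = product_length - len(fwd_site) - len(rev_site)
    if inner_len < 20:
        raise ValueError("product too short for the primer pair")
    inner = list(_random_sequence(rng, inner_len, 0.42))
    # plant one DdeI (CTNAG) and one HinfI (GANTC) site inside the product
    inner[40:45] = list("CTTAG")
    inner[120:125] = list("GACTC")
    inner = "".join(inner)
    template = (_random_sequence(rng, flank, 0.42) + fwd_site + inner
                + rev_site + _random_sequence(rng, flank, 0.42))
    return NucleotideSequence("synthetic_assay_template", template)


def random_tree(n_tips: int, seed: int, min_branch: float = 0.05,
                max_branch: float = 0.3) -> dendropy.Tree:
    """A random binary tree with uniform branch lengths (for simulations)."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_tips)]
    taxa = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for n in (nodes[i], nodes[j]):
            parent.add_child(n)
            n.edge.length = float(rng.uniform(min_branch, max_branch))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for n in nodes:
        root.add_child(n)
        n.edge.length = float(rng.uniform(min_branch, max_branch))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree
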