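# Methods

This note documents the models and procedures implemented in
`rosaslocus`, the parameters that matter, the numerical choices behind
them, and what the synthetic studies do and do not demonstrate.

## The screening problem

Gametophytic self-incompatibility (GSI) in Rosaceae is controlled by a
single locus carrying a pistil-expressed ribonuclease (S-RNase) and one
or more pollen-expressed F-box genes. S-RNases have a recognisable
signature: they are basic proteins (isoelectric point typically above
8), carry conserved amino-acid patterns, are expressed in pistil and
ovary tissue, and evolve under diversifying selection that leaves
positively selected amino-acid sites around the active-site pocket. The
package operationalises that signature as a screen over genome
assemblies: extract candidate coding segments, test them for similarity
to reference S-RNase/F-box proteins, score the protein-level criteria,
place survivors on a reference phylogeny, and corroborate with
expression, divergence and selection statistics.

## ORF extraction and the similarity screen

ORFs are maximal stop-to-stop codon runs in all six frames (not
ATG-initiated), kept when strictly longer than 100 nt (>= 34 codons).
Coordinates are 0-based half-open on the forward strand in code and
1-based inclusive in reports. Ambiguous codons translate to X; X is
scored as neutral (0) in alignments.

Candidacy is decided by Smith–Waterman local alignment (BLOSUM62, gap
open 11, extend 1) of each ORF peptide against the reference peptides.
Without BLAST's extreme-value statistics an e-value cutoff is not
reproducible, so the screen uses a deterministic statistic: the raw
local-alignment score divided by the ORF peptide length. A per-aligned-
column score was considered and rejected — short spurious local matches
(5–10 columns) reach high per-column scores, so that statistic cannot
separate background ORFs from homologs. Score-per-residue requires a
hit to cover a substantial fraction of the query; for random queries it
*decreases* with query length, so the calibration null uses fragments of
residue-shuffled references at the minimum ORF length (the worst case).
The pass threshold is the (1 − fpr) quantile of the null statistic
(best score over all references, matching the screen's decision rule);
the default fpr of 0.002 is per tested ORF, keeping a genome-scale
screen with thousands of background ORFs near zero expected false
candidates while diverged homologs (30% amino-acid divergence) score
several-fold above threshold.

## Protein-level criteria

**Isoelectric point.** Net charge is the Henderson–Hasselbalch sum over
the free termini and the D, E, C, Y (acidic) and H, K, R (basic) side
chains; pI is the root of charge(pH), found by bisection on [0, 14] to
0.001 pH units (the charge is strictly decreasing in pH, so bisection is
exact). The default pKa set is the ExPASy/Bjellqvist table, including
the residue-specific N-terminal values and the D/E-specific C-terminal
values; an EMBOSS-style set is selectable. X residues carry no charge;
an all-X peptide is an error. A caveat verified in testing: the pI of a
short or charge-balanced peptide is ill-conditioned (the charge curve
has a plateau near zero), so small composition changes can move the root
substantially — the screen applies pI to full-length candidate proteins
where the crossing is steep.

**Conserved patterns.** Patterns are PROSITE-syntax expressions matched
by a direct backtracking scanner (tested against a regex translation).
The canonical S-RNase patterns 1 and 2 are defined in the T2/S-RNase
literature and are *not* shipped; the defaults are structurally similar
placeholders, clearly non-canonical, and real analyses must supply the
published patterns via configuration. The screen's "relaxed first
position" rule — accepting Y where pattern 1 requires [FST], a violation
observed in genuine S-RNases — is implemented in the matcher and
reported as a distinct status (`relaxed_Y`).

**Classification table.** Candidates are tallied per source genome with
the reporting convention of the original screen: pseudogenes (internal
stops or broken reading frames) are excluded from all protein-level
columns; the both-motif column uses IP >= 7 while the motif-2-only
column uses IP > 7 (two deliberately distinct comparators); the basic-
protein prior for nomination is pI >= 8.

## Distance phylogenetics

Evolutionary distances are p-distances with pairwise deletion: per
sequence pair, sites with a gap or ambiguity in either row are excluded
and the distance is differences over the remaining sites (a pair with
no shared sites is an error naming the pair). Trees are built with the
Saitou–Nei neighbor-joining agglomeration; Q-matrix ties break to the
lowest index pair, negative branch lengths are clamped to zero (deficit
logged), and the final three lineages join on an unrooted central
vertex. NJ on an additive matrix reproduces the generating tree exactly
(verified over random 4–12-taxon trees, and against scikit-bio's
implementation). Bootstrap support resamples alignment columns (codon
triplets for codon alignments) with replacement; support is the
percentage of replicate NJ trees containing each bipartition of the
full-data tree. Tests and the acceptance studies use 300–1,000
replicates; analyses of real data would typically use 10,000.

Lineage assignment roots the tree on an explicit outgroup (no midpoint
fallback) and assigns a candidate to a lineage iff it lies inside the
smallest rooted clade containing all of that lineage's references and
none of any other's; lineages whose references are not exclusive yield
`ambiguous`, and candidates outside every valid clade are
`non-S-RNase-lineage`.

Multiple alignment is deliberately not a contribution of this package:
codon-aware alignment translates the CDS set, aligns the peptides with
mafft, and back-maps to codons (gaps in whole-codon units); externally
produced alignments are accepted everywhere an alignment is an input.

## Divergence and polymorphism (NG86 + Jukes–Cantor)

Synonymous site counts follow Nei–Gojobori (1986): per codon position,
the synonymous fraction of the non-stop single-nucleotide changes
(mutations to stops are excluded from the denominator), so S + N = 3 ×
codons always. Differences between codons are averaged with equal
weights over all minimal substitution pathways; pathways through stop
codons are discarded, and a codon pair whose pathways are all blocked is
skipped and counted (`codons_skipped`). Proportions pS = Sd/S and
pN = Nd/N are corrected with Jukes–Cantor, d = −(3/4) ln(1 − 4p/3),
which is reported as undefined (never fabricated) for p >= 3/4. Group
divergence is the arithmetic mean of pairwise dS and dN over defined
pairs with the undefined count reported; synonymous polymorphism pi_s is
the mean pairwise Sd/S, uncorrected by default (the DnaSP convention)
with a JC switch.

Two properties worth knowing: NG86 assumes equal rates per change, so
with a transition bias (kappa > 1) dN/dS is biased *below* 1 even for
neutral data (synonymous changes are disproportionately transitions) —
the neutral round-trip test therefore simulates with kappa = 1. And
pathway averaging can attribute fractional non-synonymous steps to a
codon pair that encodes the same amino acid twice (e.g. CTT↔TTA via
TTT), so "omega = 0 data" shows Nd > 0 under NG86 even though the
simulated process never changed the protein.

## Codon site models and positive selection

The substitution process is the Goldman–Yang codon model on the 61 sense
codons: rate proportional to the target codon frequency, times kappa for
transitions, times omega for non-synonymous changes; multi-nucleotide
changes are forbidden. Site models mix omega across sites: M0 (one
ratio), M1a (omega0 < 1, omega1 = 1), M2a (M1a + omega2 > 1), M7
(Beta(p, q) discretised into K = 10 equal-probability classes by their
conditional means) and M8 (M7 + omega_s > 1). The rate matrix is scaled
so one unit of branch length is one expected substitution per codon
under the fitted mixture; likelihoods use Felsenstein pruning with
per-site scaling, and the matrix exponential comes from the symmetric
(reversible) eigendecomposition. Codon frequencies are equal by default
(keeping the simulator/estimator pair self-consistent); F3x4 is
available for real data.

Fitting strategy: branch lengths and kappa are estimated once under M0
(jointly, L-BFGS-B on log-transformed parameters), then fixed for the
site models, which re-optimise kappa, a global tree-scale factor and
their class parameters. Each fit runs three starts — one deterministic
(seeded from the nested model's solution, which preserves the nested
lnL ordering) and two dispersed random starts (essential for M2a/M8:
the nested solution sits on the boundary p_positive → 0, a saddle the
optimiser cannot leave locally). Convergence is the best of starts;
`converged` reflects the optimiser's own status.

Positive selection is tested with the M2a–M1a and M8–M7 likelihood
ratio tests (2·ΔlnL against chi-square, df = 2; negative statistics from
optimiser noise are clamped to zero with a warning). Sites are called
from the posterior of the positive class: NEB plugs in the MLEs; BEB
integrates the class posterior over a uniform grid on the mixture
parameters (proportions and omegas for M2a; beta shapes, p0 and omega_s
for M8), weighting grid points by their data likelihood, with kappa and
branch lengths held at their MLEs and per-omega site likelihoods cached.
The default calling rule is NEB-only with posterior > 0.90 under both
model comparisons; `NEB_and_BEB` additionally requires the BEB
posteriors to clear the threshold. Site columns are mapped to residue
numbering of a named reference row, skipping its gaps.

### The power study and its known limitation

The selection study simulates on a fixed balanced 6-taxon tree, all
branches 0.3 substitutions/codon (tree length 2.7, the scale of
published codon-model power studies), with the alternative M2a
(p0 = 0.5, p1 = 0.3, omega0 = 0.1, omega2 = 5) and the null M1a
(p0 = 0.5, omega0 = 0.1), 500 codons per replicate. Under these
conditions the M2a–M1a LRT is essentially always significant
(statistics near 200) and the null rejection rate is at the nominal
level. Site-level detection is another matter: the posterior of the
positive class computed at the *true* parameters — the ceiling no
estimator can beat — recovers only ~55–60% of planted sites at the 0.90
cutoff, and the ceiling does not improve with deeper branches
(0.58/0.57/0.55/0.54 at branch lengths 0.4/0.5/0.6/0.8). With six
sequences the per-site evidence saturates; this is the well-documented
low site-detection power of empirical-Bayes site methods with few
lineages. Consequently the acceptance suite's site-recall clause (70%
at posterior > 0.90) fails honestly at these study conditions, while
false site calls stay below 1%. Real S-RNase analyses mitigate this by
using more alleles.

## Expression

FPKM = count × 1e9 / (library_size × effective_length), with effective
length equal to the CDS length (no fragment-length correction — a
documented simplification of RSEM; read mapping is out of scope and
counts are inputs). Tissue categories are mutually exclusive and
exhaustive given the thresholds (defaults: expressed = 1 FPKM,
high = 10 FPKM): `not_expressed` (all tissues below expressed),
`stamen_only` (stamen expressed, everything else below), 
`pistil_ovary_high` (pistil/ovary at or above high, other non-stamen
tissues below expressed, stamen below high — low stamen leakage is
tolerated, matching the S-pistil pattern), else `broad`. The thresholds
are operational choices, config-exposed, since the underlying categories
are qualitative.

## In-silico genotyping assay

Primer binding is IUPAC-aware (a template base matches a primer symbol
iff it is in the symbol's set): the forward primer is scanned on the
forward strand, the reverse primer as its reverse complement; matches
allow at most `max_mismatch` mismatches (default 0) with the 3'-terminal
3 nt exact, and all compatible pairs within the product-length bounds
are reported. Product length is primer-inclusive. Restriction digestion
resolves recognition sites on both strands to unique top-strand cut
positions (a palindromic site matching both strands is a single cut
event) and returns the fragment lengths of the linear template, which
always sum to the template length. DdeI (C^TNAG) and HinfI (G^ANTC)
ship as named constants, as do the RA-F/RA-R genotyping primers.

The assay template used in tests and in the acceptance script is
*synthetic*: a random linear sequence carrying exact RA-F/RA-R sites
spaced for a 353-nt product with one DdeI and one HinfI site planted
inside the amplicon. It exercises the full assay logic with the real
primer sequences; it is not the deposited accession sequence.

## The synthetic-data generator

`generate_genome` plants genes with controlled properties into random
background sequence (GC content 0.42 by default). Each planted peptide
derives from the bundle's reference peptide (25% divergence by default,
so the similarity screen finds it); motif instances are spliced in (or
accidental matches destroyed), and the pI is driven into the requested
band by substituting K/R (to raise) or D/E (to lower) at unprotected
positions, verified with the package's own pI solver, bounded at 10,000
attempts (an infeasible band raises an error naming the band). The CDS
is back-translated with uniform synonymous codon choice, optionally
interrupted by GT…AG introns (>= 20 nt) at codon boundaries, flanked by
in-frame stop codons — so stop-to-stop ORF extraction recovers exactly
the planted CDS for intronless genes — and inserted on either strand.
Counts are Poisson (or negative-binomial) draws around archetypal FPKM
profiles (pistil-high 200/2/0.1; stamen-only 100 in stamen; broad 50
everywhere; silent 0), at a default library depth of 2e7 fragments per
tissue — a typical RNA-seq depth, deep enough that single stray counts
cannot cross the FPKM thresholds. Everything is a pure function of
(spec, seed).

What the generator does *not* emulate: real intergenic composition and
repeats, intron-containing gene recovery (the screen has no spliced
aligner; the original analysis annotated exons manually, which is out of
scope), multi-mapping reads, library-preparation biases, and real
S-RNase sequence structure beyond pI/motif/divergence control. Passing
the synthetic studies therefore demonstrates the correctness of the
screen's logic and statistics, not its sensitivity on real assemblies.

## Problem sizes used in the shipped studies

Whole-genome recovery: 20 bundles × 100 kb × 5 planted genes. Oracle
agreement: 500 codon pairs (NG86), peptides <= 12 aa (local alignment),
4–12-taxon trees (NJ), 100 peptides at a 1e-4 pH grid (pI). Selection
power: 20 alternative + 20 null replicates of 6 taxa × 500 codons.
Divergence round trip: 8 taxa × 1,200 codons. These sizes were chosen
to exercise each estimator at full fidelity while keeping the whole
suite a few minutes of compute on a single core.
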