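# Methods

`aldhkit` re-implements a complete gene-family census workflow of the
kind used for plant ALDH (aldehyde dehydrogenase) superfamilies:
candidate identification, threshold-based nomenclature, phylogeny,
exon–intron structure and splice-variant analysis, duplication and
synteny analysis, and a microarray-style differential-expression
screen. This note records the models, parameter choices and numerical
conventions, what the synthetic generator does and does not emulate,
and the design decisions taken where the workflow was genuinely open.

## Identification

Candidates are flagged by two OR-combined evidence channels: a match to
at least one PROSITE-syntax motif, or a best global-alignment identity
to a curated panel at or above a floor (default 0.40). OR was chosen
because the classification stage re-screens every candidate against the
same identity thresholds, so a permissive search stage costs nothing in
final precision; the combination rule is recorded on each hit. Pattern
content is configuration — the packaged `aldh_patterns.txt` ships
representative ALDH active-site signatures and can be replaced without
code changes. The scanner reports all leftmost-anchored matches,
including overlaps and multiple end points of variable-length repeats,
as 1-based inclusive intervals; it is a set-propagation matcher, linear
in sequence length per start position, and is property-tested against a
brute-force expansion oracle. Profile-HMM search is out of scope: motif
plus identity evidence stands in for it.

## Classification (the nomenclature rule)

Family and subfamily membership follow the AGNC percent-identity
convention with *strict* thresholds: identity > 0.40 to a named
sequence joins its family, > 0.60 its subfamily, and a query at or
below 0.40 to every named sequence founds a new family. The boundary
cases (exactly 0.40 → new family; exactly 0.60 → same family, new
subfamily) follow the "more than 40% / more than 60%" reading and are
unit-tested at the exact values.

Pairwise alignment is true global (end gaps penalized) under BLOSUM62
with affine gaps: 10 to open (charged on a gap's first residue), 0.5
per additional residue. These values are a conventional protein-search
default; they are recorded in the census metadata. Among co-optimal
alignments the engine's first reported alignment is used, which is
deterministic for a fixed Biopython version. Alignment optimality is
verified against an exhaustive affine-gap recursion on short sequences.

Percent identity uses matched columns divided by the number of
alignment columns excluding terminal gap columns (robust to length
differences); a `shorter`-sequence denominator is available because
nomenclature practice is not uniform on this point.

The whole-proteome census canonicalizes naming by processing queries in
order of a sequence digest, so family membership is invariant to input
order. Queries that anchor to the panel inherit its family; mutually
novel queries are grouped by single linkage at the family threshold
(and, within a family, at the subfamily threshold), then numbered after
the highest existing family/member numbers. Historical member numbers
(why a grape family-2 gene is "B4" rather than "B1") are inherited from
prior literature and cannot be reproduced algorithmically; the census
numbers members densely instead.

## Phylogeny

Distances are p-distances with pairwise deletion: mismatched columns
over columns where both rows hold residues. The tree builder is
standard neighbor joining on the Q-criterion; ties are broken by the
lexicographically smallest taxon pair (a merged node is keyed by the
smallest leaf beneath it) for reproducibility, and negative branch
lengths are clamped to zero with a count kept on the tree. NJ is exact
on additive matrices; the tests verify 100% topology recovery on random
6-taxon additive matrices against a least-squares fit enumerated over
all 105 topologies, and cross-check against scikit-bio's NJ.

The progressive aligner mirrors the classic ClustalW recipe: an NJ
guide tree on pairwise global-alignment p-distances, then
profile–profile merging up the tree using mean substitution scores
(gap characters excluded from the mean) with a linear gap penalty of 8.
Two sequences reduce exactly to the pairwise global aligner. This is a
deliberate simplification of ClustalW's position-specific gap machinery;
it is adequate for the within-superfamily alignments the census needs.

Bootstrap support follows the full-data-tree convention (as in MEGA):
columns are resampled with replacement, a replicate NJ tree is built
per resample, and each internal edge of the full-data tree is annotated
with the percentage of replicates containing its bipartition. The
default is 1000 replicates; tests and examples use 20–200 to keep the
suite fast. A consensus-tree alternative is not implemented. Trees are
scikit-bio `TreeNode` objects; Newick round trips preserve topology,
lengths (|Δ| < 1e-9) and supports (written as internal node labels).

## Gene structure and splice variants

Gene models are ordered coding exons in 1-based inclusive genomic
coordinates; minus-strand models store exons in transcription order;
CDS coordinates include the stop codon. Structures are inferred by a
spliced alignment DP over (CDS position, genomic position): exon bases
align column by column (match +1, mismatch −3), an intron is a free-
length genomic gap of at least 20 bp costing −6, refunded +2 at each
canonical boundary (GT donor, AG acceptor), and genomic flanks are
free. The per-row intron transition is computed with a running-maximum
trick, so the DP is O(n·m) and fully vectorized. Because the intended
inputs guarantee the CDS is the exact concatenation of exon substrings,
the implementation requires the reconstruction to equal the CDS and
raises otherwise — mismatch scoring exists for tie-breaking, not for
approximate matching.

Splice events between a variant and a reference at the same locus are
classified minimally: intron retention (a variant exon spans a
reference intron; the retained length is reported), alternative 3′
acceptor / 5′ donor (one intron boundary moves; donor and acceptor are
transcriptional, so the genomic sides swap on the minus strand), and
exon skipping (two reference introns fuse across an exon). `location`
is the affected intron/exon index in transcription order and
`length_delta` the bases the variant transcript gains (+) or loses (−).

ORF calling takes the longest ATG-initiated, stop-terminated reading
frame (default minimum 50 aa), not the first ATG: a frameshifting
retained intron can move the usable start codon downstream, and the
longest-ORF policy recovers that reading. The translation-length law
(protein = cds/3 − 1) is asserted across the whole packaged catalog.

## Duplication and synteny

Tandem duplicates are maximal same-chromosome runs of same-family genes
in which successive members have at most `max_intervening` annotated
loci between them (default 1). Intervening loci of *any* kind count —
the rule is about gene count, not identity. The implementation is
property-tested against an exhaustive window scan and is monotone in
the cap.

Synteny blocks are consumed from file (the workflow downloads them; it
does not compute collinearity de novo). A block is a pair of
chromosomal intervals in a declared dialect — `rank` (gene-order
indices, used by the packaged fixtures) or `coordinate` — and genes are
assigned to every block containing them, with genes outside all blocks
flagged rather than dropped. Same-family genes on opposite sides of a
block become syntenic pairs, classified `unambiguous` (1:1) or
`ambiguous` (1:many, as for the duplicated family-2 and family-18
correspondences); a side whose family has no partner on the opposite
side is reported `counterpart_lost`.

The packaged grape layout is a documented fixture assumption: the
catalog does not print chromosome assignments, so loci are ordered by
numeric locus id on one proxy chromosome, with background loci filling
the id gaps (capped at 2 — enough to exercise the ≤1-intervening rule).
The within-genome block fixture encodes six block pairs over 11 genes
from five families; family 2 contributes two of the three possible
pairs among its three block-resident genes (the source material lists
the trio without naming the pairing; either choice gives the same gene
and block counts).

## Expression screen

The screen consumes summarized probe-set log2 intensities with P/M/A
detection calls; probe-level background correction is upstream of this
data model, and quantile normalization (columns forced onto the mean
empirical distribution, ties receiving interpolated reference
quantiles) stands in for the normalization half of that pipeline.
Probes absent or marginal on *every* array are removed — marginal-only
probes are treated as uninformative, the stricter of the two possible
readings — and the drop log is returned. MAS5-style calls are inputs or
simulated, never computed: the call algorithm needs probe-pair data
that summarized matrices no longer carry.

Differential expression uses the moderated t: per-probe pooled
within-group variance with d = n₁+n₂−2 df, shrunk toward a prior
variance s₀² with prior df d₀ estimated by the method of moments on
log sample variances (matching limma's `fitFDist`: the excess variance
of log s² over trigamma(d/2) identifies d₀ through a trigamma
inversion solved by Newton's method; non-positive excess ⇒ d₀ = ∞,
full pooling, in which case p-values use the normal tail). The
statistic is the fold change over the shrunk standard error, with
d + d₀ degrees of freedom. With d₀ = 0 the ordinary equal-variance
t-test is recovered (unit-tested); the full path is cross-checked
against Bioconductor limma to machine precision on a small matrix.
BH adjustment is the standard step-up (via statsmodels), verified
against a brute-force oracle; the DE call is adjusted p < 0.05.

Gene-level responsiveness aggregates probes by "any probe DE" (the
matching "all probes" mode is available), reports signed direction from
the most significant probe, distinguishes `not_assayed` (no surviving
probes) from `not_de`, and orders the gene × contrast log2-FC matrix by
average-linkage hierarchical clustering under correlation distance.
Reordering never changes stored values.

A note on power: with σ = 1 and n = 3 arrays per group the standard
error of a fold change is σ·√(2/3) ≈ 0.82, so a 2-unit log2 shift puts
the moderated statistic near 2.45 while the self-consistent BH
threshold in a 2000-probe, 200-effect experiment sits near z ≈ 3.1.
Recovery of planted effects at these settings is therefore partial by
construction (the FDR guarantee, by contrast, is unconditional for
independent probes, and the acceptance run measures it below 0.05);
near-complete recovery at this effect size needs on the order of nine
or ten arrays per group.

## Synthetic data

The generator emulates the statistical structure each stage assumes,
not the biology of any real genome. One seeded NumPy generator drives
every draw, so a seed determines the output byte for byte.

- **Families.** Identity is controlled by uniform random substitutions
  at sampled positions, no indels (an analytically controllable model;
  mutating a fraction 1−t of positions gives identity ≈ t).
  `within_family_identity` (default 0.7) and `between_family_identity`
  (default 0.3) are targets for *pairwise* identity among members:
  members are mutated from a family founder at √w, founders from a
  common ancestor at √b, so member–member identity ≈ w within a family
  and ≈ w·b across families. The generator accepts within-family
  targets anywhere above the 0.40 family threshold, so recovery can be
  exercised at stringent settings (e.g. 0.45 within / 0.35 between).
  Proteins begin with a fixed, never-mutated methionine so every CDS is
  ATG-initiated and translates back to its protein exactly.
- **Gene models.** Each protein is reverse-translated codon-uniformly
  (stop appended), split into 3–9 exons (configurable; tests plant up
  to 20) with canonical GT..AG introns of 30–90 bp and random flanks.
- **Layout.** Planted tandem arrays are placed with their requested
  intervening counts; all other genes are separated by at least two
  background loci, so the only clusters under the ≤1-intervening rule
  are the planted ones. The background budget is sized automatically
  unless given.
- **Expression.** Probe baselines are N(8, 1.5²) log2 units; noise is
  i.i.d. N(0, σ²) per cell; planted probes (default 200 of 2000) gain
  `log2fc` (default 2) in the treatment group; a configurable fraction
  (default 0.1) of probes — disjoint from the planted set, so planted
  truth stays recoverable — is flagged absent on every array, with
  scattered marginal/absent calls elsewhere that never trigger the
  all-absent filter.

What passing tests on this generator do **not** show: robustness to
indels or domain rearrangements in real proteins, non-canonical splice
sites, correlated probe noise or array batch effects, probe-level
hybridization artefacts, or real chromosome-scale gene order. The
fixtures transcribed from the published tables anchor the counts the
pipeline must reproduce; everything sequence-shaped around them is
synthetic.

## Degenerate inputs and tie-breaks (summary)

- Empty classification panel: the query founds family 1, with a warning.
- Identity denominator of zero (no comparable columns): error naming
  the pair (p-distance) or the condition (percent identity).
- NJ on < 3 taxa, asymmetric matrices: rejected.
- Bootstrap replicates in which some pair has no comparable columns
  support nothing but still count in the denominator (deterministic).
- `mutate_to_identity` with target 0 requires a residue alphabet
  disjoint from the seed's; if the seed uses all 20 residues the target
  is unreachable and a parameter error is raised.
- A condition with a single array cannot support a variance estimate;
  the screen refuses it and advises descriptive fold changes only.

## Problem sizes used by the packaged checks

The acceptance script and test suite run at desk scale: 5-family
proteomes of 15–25 proteins (planted-family recovery over 20 seeds),
6-taxon trees for the NJ oracle (50 matrices), 200 simulated
2000-probe experiments for the FDR measurement, and sequences of a few
hundred residues throughout. These sizes were chosen so each check
isolates one claim and the whole suite stays interactive; the
algorithms themselves carry no such limits.
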