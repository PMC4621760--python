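# Methods

This note records the models, conventions and design choices behind each
operator, the parameters that matter, and what the synthetic fixtures do
and do not establish about real data.

## Coordinates and formats

All internal coordinates are 1-based inclusive (GFF3 convention).  BED
input is converted on read (`start+1`, `end`).  The first coding base of a
gene (`cds_start`) is the minimum CDS coordinate on the + strand and the
maximum on the − strand; "upstream of the start codon" is interpreted
relative to this base, not the transcription start, so promoters are the
1,000 bp immediately 5' of the coding sequence.  Gene order within a
chromosome is the rank by start coordinate, ties broken by gene id; this
order index is what collinearity chaining and the tandem rule consume.

## Family identification

Membership is a deterministic motif rule, not a profile-HMM search: a
protein is a family member when at least two of motifs {II, III, IV}
match (configurable).  Requiring the dimerisation blocks but not the
degron keeps non-canonical (degron-less) members in-family, which a rule
anchored on motif II would lose.  Motif patterns are degenerate strings
(fixed residues, `x` wildcards, bracketed classes); the packaged
motif III/IV consensus strings are package conventions — the community
describes these blocks structurally (βαα region, acidic region) without a
canonical sequence — and can be replaced via the motif TSV.  Whether
GWPPI counts as an intact degron is unsettled; the default pattern
`GWPP[VI]` accepts both.

Physicochemical profiles use average residue masses (MW = Σ residues +
one water) and a bisection solver for pI on the Henderson–Hasselbalch net
charge over N-/C-termini and K, R, H, D, E, C, Y.  The default pKa table
is the EMBOSS-style set (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5,
D 3.9, E 4.1, C 8.5, Y 10.1); it is an input so other constant sets can
be substituted.  Net charge is strictly decreasing in pH, so the root is
unique; bisection stops at |charge| &lt; 1e-4, which locates the pH to a
few hundredths of a unit for typical proteins (flatter titration curves,
e.g. diglycine, are resolved proportionally less tightly).

## Genome organisation

The tandem rule — consecutive family members with at most 1 intervening
gene **and** at most 100 kb separation — is a package convention chosen
to be permissive enough for classic tandem arrays while excluding genes
that merely share a chromosome arm; published surveys report clusters
without stating a rule.  Both parameters are exposed.

## Phylogeny

Pairwise distances are 1 − fractional identity from global
Needleman–Wunsch alignments under BLOSUM62 with affine gaps (open −10,
extend −1; a gap of length k costs 10 + (k − 1)).  Identity rather than
similarity keeps the distance a metric-like quantity in [0, 1];
similarity (identities + positive-scoring pairs) is still reported.
UPGMA uses the classic size-weighted mean update with node height = d/2;
ties are broken by the lexicographically smallest pair of cluster labels
(a cluster is labelled by its smallest leaf), making trees deterministic.
The progressive MSA merges profiles in guide-tree post-order with
profile–profile global alignment (column score = mean pairwise
substitution score); it exists to support column bootstrapping, not to
compete with MAFFT.  Bootstrap support resamples MSA columns with
replacement, rebuilds a p-distance matrix and UPGMA tree per replicate,
and reports the fraction of replicates containing each clade of the
full-data tree (no consensus tree is built).  1,000 replicates is the
default; at that depth two seeds agree to within ~0.05.

## Duplication and dating

Collinear blocks are maximal monotone chains over supplied homolog
anchors (the package does not implement an all-vs-all search): per
chromosome pair, dynamic programming finds the longest chain with
strictly monotone order indices in both genomes (either direction), index
gaps ≤ 25, and ≥ 5 anchors; chains are extracted greedily and each anchor
serves one block.

Duplication modes are assigned per gene by precedence: anchored in a
block → WGD/segmental; else in a tandem cluster → tandem; else, if the
gene has a family homolog elsewhere and carries a transposable element
within 10 kb on *both* flanks → transposed; otherwise dispersed.  The
two-sided TE requirement reflects the "located among two transposable
elements" diagnostic; the window is configurable.

Ka/Ks follows Nei–Gojobori (1986).  Site counts renormalise per position
over non-stop single-base changes, so s + n = 3 exactly per codon.
Multi-site codon differences are averaged over all orderings of
single-base steps, excluding pathways through stop codons; when every
pathway is blocked the average runs over all pathways with stop steps
counted as nonsynonymous, and the result is flagged.  Proportions are
Jukes–Cantor corrected (d = −¾ ln(1 − 4p/3)); p ≥ ¾ raises a saturation
error rather than returning a number, and the pipeline records such pairs
as saturated.  Divergence time is T = Ks/(2 × 6.1e-9) × 1e-6 Mya; Ks
bins at 0.3 and 1.3 assign pairs to the *Glycine* WGD, legume WGD and
gamma WGT eras, with both boundaries assigned to the legume bin (the
source phrasing "between 0.3 and 1.3" does not specify openness).

## Promoters

Scanning is exact IUPAC set-membership matching; every match start is
reported, overlapping matches included.  Minus-strand hits are positions
where the reverse complement of the pattern matches the forward sequence,
reported at the forward match start, which makes the scan symmetric under
reverse-complementing the input.  The packaged element library carries
PLACE-nomenclature ids and patterns (AuxRE/ARFAT TGTCTC, DRE/CRT core
RCCGAC, ABRE ACGTG, E-box CANNTG, MYB/MYC drought- and salt-response
motifs, seed/endosperm elements); it is a convenience import of public
nomenclature, not a claim about any particular study's supplementary
tables, and a full user library can be substituted.

## Expression

RPKM is the naive `count × 1e9 / (library_size × length_bp)`; isoform
resolution is out of scope.  The DE rule is the classic screen: DE iff
fold ≥ 2 (either direction) **and** two-sided t-test P ≤ 0.05, Welch by
default (a pooled-variance flag exists), with no multiple-testing
correction — deliberately matching the original screen rather than
"fixing" it.  Fold changes use a pseudo-count of 1 only when a group mean
is zero, so the ordinary ratio is reported whenever it is defined.
Paralog expression divergence is the Pearson correlation of the two
genes' log2(RPKM+1) profiles across tissues; conserved iff r ≥ 0.8.  The
threshold is a package convention (published verdicts come without a
statistic); zero-variance profiles leave r undefined and the pair is
called diverged with a flag.  Tissue-specificity descriptors (max-tissue
share, tau) are reported as descriptive aids only.

## Synthetic data

The packaged catalogs transcribe the published family inventories:
per-chromosome counts (22 chickpea genes on 8 linkage groups; 63 soybean
genes on 16 of 20 chromosomes), tandem clusters, non-canonical member
lists, duplication-mode labels (57 WGD/segmental, GmIAA6/7 tandem) and
the 16 conserved + 8 diverged paralog pairs.  Ids are assigned
sequentially along chromosomes, which is exactly consistent with the
printed per-chromosome counts and cluster memberships.  Labels not fully
determined by the published main text are catalog conventions: the three
synthetic pairings among otherwise unpaired WGD genes, the specific
transposed/dispersed assignments (GmIAA4/31/42 transposed, GmIAA57
dispersed), and all chickpea mode labels.

The generators build one consistent dataset per catalog:

* **Coding sequences.**  Genes connected by pairing or cluster adjacency
  share an ancestral CDS; each member is evolved independently by random
  substitutions that never create stops, accepting synonymous changes
  until the branch reaches its synonymous-event target (branch dS drawn
  from [0.05, 0.2]) and nonsynonymous changes with probability ω = 0.2.
  Motif blocks are re-imposed afterwards (motif II knocked out for
  non-canonical members), editing codons synonymously where possible.
* **Genome.**  Genes are placed in catalog order with dedicated decoy
  genes flanking each family gene; cluster members are adjacent, other
  family genes are separated by ≥ 4 decoys (≈ 17 kb).  Each WGD-labelled
  gene is embedded in a 5-anchor chain with its partner's neighbourhood
  (orientation inverted per chromosome pair when the catalog pairing runs
  antiparallel, so chains stay monotone); a WGD gene without a WGD
  partner is anchored against a decoy-only region.  Transposed genes get
  TEs planted 2.5–3 kb away on both flanks; no other TEs fall within the
  10 kb window of family genes.  Promoters carry planted cis-element
  instances recorded in a manifest; because short degenerate patterns
  also match random background (CANNTG matches a random position with
  probability 1/256), round-trip tests assert that every manifest entry
  is recovered at its exact position and strand, not that the presence
  table equals the planting spec.
* **Expression.**  19 samples (soybean) / 17 (chickpea), per the tissue
  panels the surveys used.  Each gene has a latent log2 profile (baseline
  uniform in [4, 9] log2 RPKM, tissue effects N(0, 2.5²)); conserved
  pairs share profiles at latent correlation 0.95, diverged pairs at 0.2,
  unlabelled genes are independent.  Counts are gamma-Poisson with gamma
  shape 50 (CV ≈ 0.14, a realistic tissue-panel dispersion at gene
  level); library sizes are uniform in [15, 25] million.  A separate
  3 + 3 replicate stress matrix plants 4-fold responses in alternating
  genes for the DE operator.
* Every generator is a deterministic function of (config, seed), and the
  build self-checks at construction time that the pipeline operators
  recover every catalog label.

**What passing on these fixtures shows** is that the operators implement
their contracts exactly — coordinate arithmetic, counting rules,
estimator formulas, classification precedence — and that the whole chain
composes.  It does not show robustness to the messiness of real
annotations: fragmented gene models, nested/overlapping genes, repetitive
background sequence that breaks anchor uniqueness, motif divergence
beyond the configured patterns, isoform-level expression, or
batch-structured libraries.  Real surveys also rest on HMM-based domain
calls and genuine synteny pipelines, which this package deliberately
replaces with transparent local operators.

## Problem sizes and numerics

Default desk-scale sizes, chosen so the full survey runs in well under
two minutes on one core: 63-protein soybean panel (~1,950 pairwise
alignments), 1,000 bootstrap replicates on the resulting MSA, 500-codon
sequences and 50 pairs for selection-recovery simulations.  Numerical
conventions worth knowing: UPGMA and merge tie-breaks are lexicographic;
bisection runs at most 200 halvings; Jukes–Cantor saturation raises
rather than truncates; zero-variance rows map to all-zero Z-scores; and
all randomness flows from numpy `default_rng` seeded per substream, so
reruns are byte-identical.
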