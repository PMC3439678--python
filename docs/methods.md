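# Methods

## The transfer model

The package implements homology transfer of metal-coordination annotation:
a residue-level feature observed in a structure (this residue coordinates
an Mg²⁺ ion) is carried to every sequence similar enough to share the
template's fold.  The central assumption is that cluster membership —
being in the same connected component of a stringent similarity graph —
is sufficient evidence of structural equivalence, so that an alignment to
the cluster's template fixes the coordinates of the transferred feature.
Two supporting assumptions: depositor LINK/SITE annotation is trusted as
the definition of a coordination sphere (no geometric re-derivation), and
an ion whose annotated sphere contains no protein residue carries no
sequence-level signal and is set aside.

## Site extraction

Parsing is strictly column-driven against the PDB 3.x fixed-column layout;
records are never whitespace-split, so padding inside a field cannot
change the parse.  LINK contacts and SITE membership are merged per metal
instance (union of protein residues, with the evidence source recorded).
LINK records carry the partner atom name, which drives the
backbone/side-chain split: only the carbonyl/terminal oxygens `O`/`OXT`
count as backbone, since magnesium coordinates through oxygen; any other
atom of a standard residue is side-chain; SITE-only positions have no atom
evidence and are excluded from that split.  Waters (HOH/DOD/WAT) are
dropped from coordination lists; a metal with protein *and* water partners
remains protein-coordinated; a metal with only water partners is flagged
`water_only` and never transferred.  Only MODEL 1 and altloc ' '/'A' atoms
are read.  LINK distances outside (0, 10) Å are rejected as implausible;
no tighter distance cut is applied by default because the depositor's
annotation is taken at face value (a configurable cut exists).

Template acceptance: coverage = resolved reference positions ∩ mature
positions / mature length, where the mature sequence excludes an annotated
signal peptide; the bound (default ≥ 0.70, inclusive) filters fragments
and chimeras.  Resolution is recorded but never used as a filter.
Multiple structures of one accession contribute the union of their site
positions, with per-position provenance.

## Similarity clustering

Edges require identity ≥ 40 % and coverage ≥ 90 % (inclusive), computed
from a local BLOSUM62 alignment with affine gaps (open 11, extend 1, a
length-k gap costing open + k·extend).  Identity is identical pairs over
aligned columns (gaps in the denominator); coverage is the fraction of the
*longer* sequence inside the aligned region, chosen so a fragment cannot
claim high overlap against a full-length chain.  The aligner is a
hand-written Gotoh DP with a fixed tie-break (diagonal, then up, then
left) and a canonical argument order, making results symmetric and
bit-reproducible; a brute-force DP oracle in the tests pins its optima.
Clusters are exactly the connected components (no further splitting);
singletons inherit nothing.  Fragment-flagged records are excluded before
clustering; the flag is an input column, never inferred.

## Cluster profile HMM

The cluster alignment is a star alignment around the anchor template (the
longest template when there are several; the rest are aligned as members).
Match states are the anchor's residues — a structure-anchored match rule,
chosen over gap-fraction rules because the model exists to carry
structural positions, so every observed residue must own a match state.
Emissions are estimated as (counts + w·background)/(total + w) with
weight w = 1 and a uniform 1/20 background (the smallest defensible
smoother); transitions get Laplace add-one over the allowed successors.
Decoding is global Viterbi (cluster membership already guarantees ≥ 90 %
coverage, so local decoding would only lose signal), scored in bits
against the uniform background, with ties preferring match over delete
over insert.  Scores are reported but not used for filtering: once a
sequence is in the cluster, it is annotated.  Models serialise to a
documented plain-text format.

## Transfer and term validation

A template site position maps through its MSA row to a match column and
through the target's Viterbi path to a target coordinate; positions
deleted in the target, or sitting on insert columns of a non-anchor
template, are reported as untransferred with a reason rather than silently
dropped.  Multiple templates contribute the union of positions (duplicate
coordinates merged, provenance concatenated).  Substitutions are classed
with BLOSUM62: identical; similar when the score between distinct residues
is strictly positive (the standard convention; cutoff configurable);
different otherwise, with X always different.  Templates whose metal has
no documented role are still transferred but carry their role label
(functional / structural / undetermined — an input column) into the
output.

Term inheritance uses the hypergeometric upper tail P(X ≥ k) for k
carriers in a cluster of n against K carriers among N background
sequences, Bonferroni-corrected by the number of distinct terms tested in
the cluster (a global multiplier is selectable), validated when the
corrected p < 0.01.  The background is the run's own sequence universe:
self-contained at desk scale, and documented so users supplying a larger
background get resource-scale behaviour.  A permutation bootstrap
(term multiset preserved, assignments shuffled, ≥ 100 replicates, seeded)
returns the 1st percentile of per-cluster minimum corrected p-values as an
empirical threshold; the fixed 0.01 remains the default decision rule,
with the bootstrap exposed separately.  The most specific annotation per
sequence is the validated term(s) of maximal *longest-path* distance from
the ontology root — longest rather than shortest because specificity in an
ontology corresponds to maximal depth; ties are all returned.

## Structural summaries

Kabsch superposition: SVD of the cross-covariance with the determinant
sign correction, giving the least-squares rigid motion; RMSD uses CA atoms
of HMM-shared match columns (atom choice is a package decision; the
all-atom option is off by default).  Cluster summaries report mean ±
*population* SD over template pairs; pairs sharing fewer than 3 CA atoms
are skipped with a warning.  Binding-mode labels (Mg alone / with ions /
with ligands / both) come from the structure's non-water hetero content
against a fixed ion-code list.  Frequency tables count one incidence per
site residue (not unique residues), normalised within each split;
target-side tables count residue type only.

## Synthetic data

The generator emulates the pipeline's real inputs at desk scale.  Families
derive from a root sequence by i.i.d. substitutions (uniform over the 19
alternatives) and indels (per-site rate, geometric(0.5) lengths,
insertion/deletion equiprobable), with a truth table tracking every
planted position into every member.  Planted sites draw from
oxygen-bearing residues weighted toward Asp/Glu, matching observed Mg
coordination chemistry.  Toy structures are CA-trace helices with
coordinating oxygens placed 2.1 Å from their ion and column-correct
LINK/SITE/REMARK 800 records; optional extras are a water-only ion, an
author-numbering offset (exercising the mapping layer), and seeded
Gaussian coordinate jitter (giving distinct, superposable copies of one
fold for RMSD studies).  A divergent-chain preset produces a target below
30 % identity to the root that stays linked through intermediates.

What the fixtures do *not* emulate: realistic side-chain geometry,
phylogenetic (non-i.i.d.) evolution, alternate conformations, chimeras,
and the scale and annotation noise of real archives.  Passing tests
therefore demonstrate correctness of the machinery under the stated model,
not performance on present-day UniProt/PDB snapshots.

## Study conditions and measured quantities

Validation studies (`mgsite.validation`, driven by the test suite and
`scripts/acceptance.py`) use sizes chosen once for desk-scale runtime:
root length 90, family size 6, substitution rate 0.15 and indel rate 0.01
for recovery (100 independent seeds); three families of 5 at substitution
rate 0.05 for partition exactness; 1000 permutation replicates for type-I
control; 100 random rigid motions for superposition invariance; model and
target lengths ≤ 6 for exhaustive Viterbi enumeration; 200 random graphs
(n ≤ 50) against a BFS oracle; all hypergeometric parameter combinations
with N ≤ 12 against draw enumeration.

Recovery is measured over *transfer targets*: members of the annotating
cluster, excluding the rare member whose sampled indels push it below the
90 % coverage edge threshold (such a member is a singleton by
construction and receives no annotation at all — a sensitivity property of
the clustering stage, which the partition study measures separately).  A
hit requires the predicted coordinate to equal the generator's truth
coordinate exactly.  The residual miss rate (≈ 0.5 %) comes from planted
positions adjacent to indels inside homopolymer-like runs, where the
optimal alignment is genuinely ambiguous.

## Numerical and degenerate-input choices

Distributions are validated to 1e-9; rigid-motion invariance to 1e-8;
alignment and Viterbi ties are broken by fixed state preference, so equal
inputs give byte-equal outputs.  Empty coordinate files, empty sequences,
mature length 0, non-injective residue maps, impossible count
configurations, cyclic ontologies and out-of-range rates raise typed
errors; malformed LINK lines and unmapped residues degrade gracefully
(collected errors / warnings, parse continues).  Unknown residues emit at
background in the HMM and class as "different" in substitution scoring.

## Known limitations

PDB format only (no mmCIF); single-chain reasoning per template (sites are
reported per chain; cross-chain deduplication is not attempted); no
forward/posterior decoding or E-values; no HMMER file compatibility; the
enrichment background is the run's universe, not a proteome-scale
database; the component-splitting refinement used by large annotation
resources is deliberately not guessed at — clusters are plain connected
components.
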