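# Methods

This note documents the models, rules and numerical choices behind
`noxevo`, and what the synthetic families its tests run on do and do not
establish about real data.

## Sequence curation

Pairwise identity and similarity are computed from the raw alignment.
Published identity servers differ in their denominator, so it is explicit
and configurable: the default scores every column where at least one of the
two rows is non-gap (gap-gap columns excluded); an `ungapped_pair`
alternative restricts to columns where both rows have residues. `X` never
counts as a match. Similarity adds pairs falling in one of the groups
{D,E}, {K,R,H}, {S,T}, {I,L,V,M}, {F,Y,W}, {N,Q}, {A,G}; the grouping is a
parameter.

Curation removes a sequence only when its identity to *every* canonical
reference is below the threshold (default 0.20); references are never
removed. Trimming drops columns whose gap fraction exceeds a ceiling —
0.5 by default for tree building, with a "conservative" 0.9 preset used
before ancestral reconstruction so that lineage-specific domains
(EF-hands, the DUOX N-terminal extension) survive into the ancestor
inference. The kept-column map translates trimmed coordinates back to raw
columns. All user-facing coordinates are 1-based inclusive; everything
internal is 0-based half-open.

## Motif annotation

**TM helices.** Sliding-window Kyte-Doolittle hydropathy (window 19,
threshold 1.6, both configurable). Seed residues whose centred window mean
clears the threshold are grown into maximal runs, extended outward over
hydrophobic residues, bridging dips of at most one hydrophilic residue —
the heme-coordinating histidines (KD −3.2) sit *inside* TM helices III and
V and would otherwise truncate them. Runs closer than 3 residues merge;
runs longer than 30 are split at their hydropathy minimum (two helices can
fuse across a short loop that drifted hydrophobic), and runs shorter than
15 are discarded.

**Core fingerprint.** Heme histidine pairs are sought on helices III and V
with an intra-helix spacing of 10–18 residues, first within the predicted
span, then within a ±3-residue margin (the histidines themselves depress
the hydropathy signal at helix edges). A further helix-III histidine not
assigned to a heme is the non-coordinating (ROS-site) histidine. The
(V/I/L)xGP(F/Y)G motif is the first match C-terminal of the last helix;
(T/S)G is sought in the cytosolic loops (II–III, then IV–V); E-loop
cysteines are all cysteines strictly between helices V and VI — the E-loop
span is this package's convention, since no standard definition exists. A
sequence is NOX-like when it has ≥6 helices, ≥4 heme histidines and the
dehydrogenase motif.

**EF-hands.** Classification is a weighted rule table with mandatory
anchors and scored preferences, accepted at ≥0.6 of the maximal score.
Canonical (12-residue loop): position 1 ∈ {D,N,S} (D preferred) and
position 12 ∈ {D,E} (the bidentate -Z) are mandatory; oxygen-bearing side
chains at 3, 5 and 9 and the glycine at 6 are scored. Calpain-like
(11-residue loop): position 1 ∈ {A,V}, position 4 ∈ {D,E} and E at
position 11 are mandatory; oxygen at 6 and 8 is scored. Role maps are the
fixed offsets (canonical X,Y,Z,-Y,-X,-Z at 1,3,5,7,9,12; calpain-like
X,Z,-Y,-X,-Z at 1,4,6,8,11). Overlapping candidate windows resolve by
score, then leftmost. A call must additionally sit in a helix-loop-helix
context — mean Chou-Fasman helix propensity ≥1.05 over both 8-residue
flanks. This gate is a design choice of this package: the motif is defined
structurally as helix-loop-helix, and without it long hydrophilic segments
(the DUOX N-terminal extension in particular) yield spurious loop calls;
it can be disabled (`require_helical_flanks=False`). A degraded loop that
still carries the anchors (like the weakened fourth EF-hand of RBOHs) is
reported as a low-score canonical call, not a separate kind.

**Architecture.** The decision table maps EF-hand count to subtype
(4 → NOX5-like; 2 + ≥250-residue N-terminal extension → DUOX-like; 2 →
RBOH-like; 1 → NOXC-like; 0 with E-loop cysteine →
calcium-independent-like; 0 without → unclassified-NOX-like; incomplete
core → non-NOX). Three EF-hands fall to the nearest rule (NOX5-like) with
a low-confidence flag. The extension length is the distance from the
N-terminus to the first EF-hand loop; a true peroxidase-domain profile
search is out of scope. `activation_class` is calcium-dependent exactly
when at least one EF-hand is present.

## Phylogenetics

Distances are p-distances over pairwise non-gap columns, optionally
Poisson-corrected (−ln(1−p); p ≥ 1 is an error). Neighbor joining is the
standard Saitou-Nei Q-criterion with Studier-Keppler updates; Q ties break
on the lexicographically smallest cluster pair (clusters keyed by their
smallest leaf), negative branch lengths clamp to zero with the deficit
logged. Midpoint rooting bisects the longest leaf-to-leaf path (ties: the
lexicographically smallest leaf pair) and preserves all pairwise leaf path
lengths; outgroup rooting is available as an alternative. Maximum
likelihood topology search is deliberately not implemented — it is
off-the-shelf elsewhere, and the pipeline's contribution is the supported
NJ tree plus likelihood evaluation of fixed trees. Bootstrap replicates
resample columns with replacement; replicate trees are rebuilt by NJ.

Transfer bootstrap expectation for a reference bipartition b with smaller
side p: over replicates, find the minimum Hamming distance δ between b's
leaf-membership indicator and that of any replicate branch (or its
complement; trivial branches included, which caps δ at p−1); the support is
1 − mean(δ)/(p−1). TBE ≥ the Felsenstein proportion on every branch by
construction. Supports are reported on internal branches only, rounded to
two decimals in text outputs with full precision in JSON.

The LG substitution model ships as packaged data (exchangeabilities and
equilibrium frequencies); a Poisson model is available for closed-form
checks. The rate matrix is normalised to one expected substitution per
unit branch length; transition matrices come from the symmetric
eigendecomposition of the reversibly-scaled rate matrix, with tiny
negative entries clipped and rows renormalised. Among-site rate variation
uses k equal-probability discrete gamma categories (default k=4); each
category rate is the conditional mean of Gamma(α, α) within its quantile
band, renormalised to mean exactly 1. The defaults α=1.347 (family-wide)
and α=1.294 (animals-plus-fungi subset) are the shapes estimated for the
two datasets this pipeline is designed around; α is always user-supplied,
never estimated here. Site likelihoods average the gamma categories with
equal weights; gaps and X are missing data (partial vectors of ones). At
the alignment sizes this package targets (tens of sequences) per-site
scaling is unnecessary in double precision.

## Ancestral reconstruction

Marginal (not joint) reconstruction: for each site, category and internal
node, the posterior is proportional to the product of the node's
conditional (downward) partial likelihood and its outside (upward) partial
that carries the stationary frequencies at the root; categories are
marginalised with equal prior weights (an empirical-Bayes variant that
conditions each site on its highest-evidence category is provided as
`category_weighting="map_category"`). Posteriors are renormalised per site
and verified to sum to 1 within 1e-9.

Ancestor lengths come from Fitch parsimony on the two-state
presence/absence character of every column: bottom-up set
intersection/union (the parsimony score is the number of union events)
with top-down refinement. Ambiguity at the root resolves toward
"present", so inferred ancestors err toward retaining domains — the same
conservative intent as the 0.9 re-trim. Columns absent in every leaf are
flagged and stay absent. The composed ancestor emits MAP residues at
Fitch-present columns with a per-site posterior confidence track. Target
nodes are addressed by clade leaf-set descriptors (MRCA), never by fixed
node numbers, since internal numbering is labelling-dependent.

## Synthetic families

The generator builds root sequences whose architecture is the ground
truth: a hydrophilic N-terminal region carrying 0–4 EF-hand
helix-loop-helix units, six 21-residue hydrophobic TM stretches with the
planted histidines, loops carrying (T/S)G and optionally the E-loop
cysteine block, a 280-residue N-terminal extension standing in for the
DUOX peroxidase-like domain, and a dehydrogenase tail with
(V/I/L)xGP(F/Y)G. Residue pools are chosen so the planted motifs are the
only motifs at the root (the linker pool avoids EF anchors, glycine and
cysteine); everything downstream of divergence is left to the model.

Evolution runs along a rooted tree under LG (or Poisson) with per-site
rates drawn once — continuously from Gamma(α, α) by default. Two
conservation tiers act on the rates: planted feature *spans* evolve at a
configurable fraction of their rate (default 0.05), while the
coordination- and motif-critical *anchor residues* (heme and
non-coordinating histidines, EF-loop coordinating positions, T/S-G, the
(V/I/L)xGP(F/Y)G positions, E-loop cysteines) are invariant sites. The
two-tier design reflects the biology the fingerprint is built on — those
residues are strictly conserved across the family, which is why they are
diagnostic — and keeps substitution signal in motif regions for ancestral
reconstruction. Indels are deterministic clade-wise events, not a
stochastic process: a deletion gaps a span at and below a branch, an
insertion keeps a span only at and below a branch. The default family
plants the calcium-dependent-origin scenario: a four-EF-hand root, EF-hand
losses on the branches leading to the NOXC/DUOX/RBOH clades, loss of the
whole EF region plus gain of the E-loop cysteine insertion on the
calcium-independent stem, and the extension insertion on the DUOX stem.
Loss events are placed on a *minimal covering set* of branches, so a loss
pattern that is convex on the tree becomes a single event. This matters
for testability: a pattern like EF-hand 4 (retained by the NOX5-like and
RBOH-like clades but lost twice in between) is inherently homoplastic —
no parsimony method can recover the true states on the backbone — so
tests assert exact recovery of every event's footprint (states at and
below the event branch) and full-tree exactness only for events whose
span no other event touches.

Defaults: five clades (nox5, noxc, duox, rboh, ca_independent — the
inferred divergence order), four leaves each, ultrametric tree of
root-to-tip height 0.5, α=1.347, conservation 0.05, one integer seed
driving all randomness. At height 0.5 the root MAP sequence recovers
roughly 93–96% of true root residues over root-present columns; at height
0.3 every leaf receives its intended architecture call in almost all
seeds (a leaf can still drop a TM helix through hydrophobicity drift in
the unfrozen span positions — a known, rare failure mode).

**What passing tests show, and what they do not.** The synthetic families
have true alignments (no alignment error), deterministic block indels (no
indel-model misspecification), site-independent evolution, and motif
anchors that never substitute. Passing recovery tests therefore validates
the *algorithms* — the scanner finds what the rules describe, NJ is
consistent on additive distances, the ASR machinery computes the exact
marginal posteriors, Fitch is exactly parsimonious — but does not certify
performance on real proteomes, where alignment error, rate correlation,
profile-level motif degeneracy and incomplete lineage sampling all bite.

## Numerical and interface conventions

Likelihood and posterior computations are float64 throughout;
posterior normalisation tolerance 1e-9; branch lengths serialise with six
decimals and supports parse/serialise as internal Newick node labels.
Every stochastic operation takes a single integer seed; pipeline runs are
bitwise reproducible from config plus seed. Stage artifacts are plain
FASTA/Newick/TSV/JSON with a JSON provenance record per stage.

## Known limitations

- The hydropathy predictor is a windowed heuristic: helix boundaries on
  diverged sequences are approximate, and heavily drifted helices can drop
  below threshold.
- The peroxidase-like domain is detected only as an N-terminal extension
  length; there is no profile/HMM search.
- Fitch parsimony cannot, in principle, recover non-convex (homoplastic)
  loss patterns on internal backbone nodes.
- Likelihood evaluation has no per-site rescaling, which bounds practical
  alignment depth (hundreds of sequences would underflow).
- The identity/similarity definitions are explicit conventions; they need
  not match any particular web service.
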