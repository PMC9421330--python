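# noxevo

Evolutionary analysis of the eukaryotic NADPH oxidase (NOX) family as a
tested, reusable pipeline.

NADPH oxidases are transmembrane enzymes that produce reactive oxygen
species by passing electrons from NADPH through FAD and two hemes to
molecular oxygen. The family splits into calcium-dependent members
(NOX5, DUOX, RBOH, NOXC), which are switched on by calcium binding to
N-terminal EF-hand motifs, and calcium-independent members (NOX1-4,
NOXA/B), which instead rely on protein partners and carry conserved
cysteines in the extracellular loop between transmembrane helices V and VI
(the E-loop). Reconstructing how these activation modes arose requires
annotating the catalytic-core fingerprint and EF-hand geometry across a
protein family, building a supported phylogeny, and inferring ancestral
sequences at key internal nodes. `noxevo` implements that workflow for
anyone studying NOX-like families — or any transmembrane family with a
rule-describable architecture — with a synthetic-data generator that plants
every feature as ground truth, so each stage is testable without database
downloads.

## What it computes

- **Curation** — pairwise identity/similarity from a raw MSA, removal of
  sequences below an identity threshold (default 20%) to every canonical
  reference, and per-column gap-fraction trimming with a kept-column map.
- **Annotation** — Kyte-Doolittle sliding-window prediction of the six TM
  helices; the core fingerprint (two heme histidine pairs on helices III
  and V, the non-coordinating helix-III histidine, the (T/S)G motif, the
  (V/I/L)xGP(F/Y)G dehydrogenase motif, E-loop cysteines); EF-hand
  detection and classification. A canonical EF-hand is a 12-residue loop
  coordinating Ca2+ at positions 1,3,5,7,9,12 (roles X, Y, Z, -Y, -X, -Z)
  with a bidentate acidic -Z at 12 and a flexibility glycine at 6; a
  calpain-like EF-hand (the first motif of NOX5) coordinates at 1,4,6,8,11
  (X, Z, -Y, -X, -Z) with -Z a glutamate at 11. Architecture calls follow
  the EF-hand count: four (first may be calpain-like) = NOX5-like, two plus
  a long N-terminal extension = DUOX-like, two = RBOH-like, one =
  NOXC-like, none with E-loop cysteines = calcium-independent-like.
- **Phylogenetics** — p- or Poisson-corrected distances, Saitou-Nei
  neighbor joining, midpoint (or outgroup) rooting, column bootstrap, and
  branch supports as either classical Felsenstein proportions or transfer
  bootstrap expectations: TBE(b) = 1 − E[δ(b, T*)] / (p − 1), where δ is
  the minimum transfer (Hamming) distance of bipartition b to any branch of
  a replicate tree and p is the size of b's smaller side.
- **Likelihood and ancestral reconstruction** — Felsenstein pruning under
  the LG model with k equal-probability discrete gamma rate categories
  (shape α, category rates normalised to mean 1); marginal per-site
  posterior distributions of ancestral residues at any internal node; Fitch
  parsimony on per-column residue presence/absence to set ancestor lengths
  (root ties resolve toward "present"). The composed ancestor emits the
  maximum-a-posteriori residue at every Fitch-present column.
- **Simulation** — root sequences with planted NOX architectures, evolved
  along a tree under LG+Γ with per-site rates, conserved ("frozen") motif
  spans, invariant anchor residues, and clade-wise insertion/deletion
  events, emitting the true alignment, true tree and per-node truth tables.

## Worked example

Generate a 20-leaf synthetic family (five clades: NOX5-, NOXC-, DUOX-,
RBOH- and calcium-independent-like) and annotate its sequences:

```
$ noxevo simulate --seed 7 --out demo_fixture
wrote fixture (20 leaves, 716 columns) to demo_fixture
$ noxevo annotate --fasta demo_fixture/leaves.fasta --out demo_ann.tsv
nox5_1  NOX5-like       calcium-dependent
nox5_2  NOX5-like       calcium-dependent
...
noxc_1  NOXC-like       calcium-dependent
```

Every leaf receives its planted label. The TSV lists each feature with
1-based coordinates — for `nox5_1` the six TM helices start at residue 147,
with the heme histidine pair and the extra non-coordinating histidine on
helix III (213-233):

```
id      feature_type    start  end  kind  score
nox5_1  tm_helix        147    167  tm1   3.86
nox5_1  tm_helix        213    233  tm3   2.96
```

The full pipeline chains curation, annotation, a TBE-supported
neighbor-joining tree and ancestral reconstruction:

```
$ noxevo pipeline --seed 7 --out demo_run
pipeline complete: demo_run
```

`demo_run/report.json` summarises 16 calcium-dependent and 4
calcium-independent sequences; `demo_run/tree.nwk` carries two-decimal TBE
supports (the NOX5-like cherry `(nox5_1,nox5_2)` gets 0.99); and
`demo_run/ancestor_architectures.tsv` reports the family root ancestor
(371 residues after Fitch length inference) as calcium-dependent with two
surviving EF-hands on the midpoint-rooted tree — reconstruction on the
*true* tree recovers all four (see the acceptance script below).

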