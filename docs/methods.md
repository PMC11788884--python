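# Methods

## Model and assumptions

The package infers gene birth by domain shuffling from presence/absence of
unordered Pfam domain pairs across species. The underlying evolutionary
model is "one acquisition, multiple losses": a domain pair observed on both
sides of a clade's basal split and nowhere outside the clade is parsimony-
dated to the clade's stem branch. Convergent acquisition of the same pair
in two lineages and complete secondary loss outside the focal clade are
*not* modelled; the former hides true events (the pair stops being
lineage-specific), the latter misdates events to a younger stem. Both
behaviours are deliberate properties of the design, shared with the
conservation-first inference family the package implements, and both are
exercised explicitly by the simulator tests.

Class assignment encodes the shuffling argument itself: a lineage-specific
pair whose two member domains each occur somewhere in the outgroup
(Class 2) is parsimoniously a new *combination* of old parts — shuffling —
whereas a pair with a lineage-restricted member (Class 1) may just be a
fast-evolving duplicate crossing the detection threshold, and is excluded.

## Pipeline stages and parameters

| parameter | default | unit | role |
|---|---|---|---|
| `evalue_threshold` | 1e-3 | per-domain i-Evalue | hit retention (strict `<`) |
| `relaxed_evalue` | 1e-1 | per-domain i-Evalue | Filter 3 outgroup re-scan |
| `model_cov_min` | 0.5 | fraction of Pfam model | truncation cut for Filters 4/5 |
| `cover_fraction` | 1.0 | fraction of shorter hit | containment definition for coverage removal |

The per-domain **independent E-value** is thresholded rather than the
full-sequence E-value because domain instances, not whole proteins, are the
unit of analysis. Where a gene has several translations only the longest is
kept, so isoforms cannot inflate pair support.

**Coverage removal.** Within one gene, an instance combination of a pair is
"covered" when the shorter envelope lies fully inside the longer
(`cover_fraction` relaxes this to fractional overlap of the shorter
interval; equal intervals count as mutual containment and are
removal-eligible). A pair is covered-in-gene when *every* instance
combination is covered, covered-in-species when every supporting gene is,
and removed from the matrix only when covered in *every* carrier species —
a nested annotation conserved across all carriers describes one region,
not an architecture.

**Filters 3–5** are reconstructions of a coarsely documented
"outgroup-conservation and truncation" step and are therefore shipped as
named, independently switchable predicates with explicit knobs rather than
one opaque rule. F3 re-thresholds the (unfiltered) outgroup tables at
`relaxed_evalue` and fails a candidate whose both domains co-occur on any
outgroup gene — protection against novelty that exists only by grace of the
1e-3 boundary. F4 fails a candidate whose focal-lineage support for either
domain is entirely truncated (`model_cov < model_cov_min`). F5 discounts
truncated outgroup hits when judging Class 2; a pair whose outgroup
evidence for either domain is entirely truncated reverts to Class 1.
`model_cov_min = 0.5` is the common "half the model" convention and is a
knob, not a measured value. **Filter 6** is a dependency-injected
similarity-search port (`SequenceSearchPort`); the repository ships only
mocks, and a raising or absent backend yields SKIPPED — never a silent
pass.

**Grouping.** One initial group per DSO-DP carries the pair's supporting
genes in the clade's reference species (human for vertebrate/gnathostome
groups, Arctic lamprey for cyclostome groups; configurable). Rule 1 merges
groups with *exactly equal* gene sets (union–find, transitive). Rule 2
merges groups containing "nearly identical" pairs: two pairs sharing one
accession whose differing accessions are clan-mates in the supplied Pfam
clan table (two accessions absent from the table are never clan-mates).
Rationale: clan-mate variation (Trypsin/Trypsin_2, PDZ/PDZ_2, the Ig-set
models, the EGF variants) reflects Pfam model granularity on one
architecture, not independent shuffling events. Both rules are idempotent;
ordering and serial numbering (VGG01…, prefix configurable) are fully
deterministic. The packaged clan table is a minimal subset of the public
Pfam clan assignments covering the accessions that vary within the
published groups.

**Enrichment.** One-sided hypergeometric tail (`scipy.stats.hypergeom.sf`)
per term against an *explicit* background gene set, Benjamini–Hochberg
adjustment across the tested terms (`statsmodels`), significance at
FDR < 0.05. No ontology-graph propagation is performed; annotations are
taken as given, and the background is an input rather than a service
default, so results are exactly reproducible from the annotation table.

## The simulator

`dsog.simulate` emulates per-species annotation tables produced by domain
architectures evolving on a tree. Ancestral genes (default 30, 1–3 domains
each) carry synthetic accessions unique to one gene, so every cross-gene
combination is novel by construction. A shuffling event on a branch (a
leaf, or a named clade's stem) creates a new two-domain gene inherited by
all descendants; per-branch gene loss (probability `loss_prob` per gene per
branch) and hit truncation (`truncation_prob`, emitting model coverage 0.3
versus 0.9) degrade the signal. Identical seeds give byte-identical output
tables.

The ground truth reports, besides the planted events, the *expected* calls
per clade given the losses that actually occurred — computed by direct set
arithmetic over the simulator's own state, independent of the detection
code. The recovery analysis (`analysis/03_recovery_study.py`, 20 replicates
of 4 events on the three clade stems of the 22-species tree) shows
precision = recall = 1.0 without loss and precision = 1.0 with loss up to
0.3, with recall degrading as carriers drop below the conservation minima.

What the simulator does **not** emulate: residue-level sequences and
realistic Pfam score distributions, annotation error, assembly artefacts,
isoform complexity, or rate heterogeneity across branches. Passing
recovery tests therefore demonstrate the correctness of the inference
logic under its own model, not robustness to the annotation noise of real
gene-model sets.

## Numerical and degenerate-input choices

- Pair construction canonicalises accession order; self-pairs are rejected
  (every published group pair has two distinct accessions).
- Strict inequality at every E-value threshold; a hit at exactly 1e-3 is
  discarded.
- Hits with `env_end < env_start` are rejected with a warning and the run
  continues; genuinely malformed lines abort with the line number.
- Missing coordinates make a pair "not covered" (conservative: the pair is
  kept) with a warning.
- Multifurcating clade roots split first-listed child versus the rest, with
  a warning; the reference topology is binary so this never triggers there.
- Empty inputs degrade gracefully: empty hit tables give empty matrices,
  empty call lists give empty groupings, an empty clan map makes the
  near-identical merge the identity.
- Group sizes here are tiny (≤ 63 pairs), so the quadratic merge scans are
  immaterial; the union–find keeps merging transitive regardless of scan
  order.

## Known limitations

- The published cyclostome grouping cannot be reproduced partition-exactly
  by *any* symmetric share-one-accession merge rule: one published group
  joins a (BolA, CENP-B_N) pair supported by a single gene to zinc-finger
  pairs with larger gene sets (no gene-set equality, no clan link), while
  two other published groups stay separate despite sharing an accession
  with clan-mate partners. The shipped rule reproduces the published
  *count* (17) and the vertebrate and gnathostome partitions exactly; the
  two affected cyclostome groups trade membership. The clan table and the
  merge rule are configuration inputs so alternative criteria can be
  tested without code changes.
- Whether "nearly identical" should also merge pairs differing in *both*
  members is undecidable from the published groups; the shipped rule
  requires one shared accession.
- Filter 2's outgroup domain occurrence is assessed at the standard 1e-3
  threshold (the relaxed threshold applies only to Filter 3's architecture
  check).
- Genome-scale results (tens of thousands of pairs from 22 proteomes)
  depend on the specific gene-model releases and Pfam version and are out
  of scope here; the packaged tables and the simulator are the test
  substrate. The analysis scripts use the 22-leaf reference tree with 30
  ancestral genes and 4 planted events per replicate — small enough to run
  the whole study in seconds while exercising every stage.
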