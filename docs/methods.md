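# Methods

This note documents the models, rules and numerical choices behind
`lecfam`, and what the synthetic-data tests do and do not demonstrate
about real proteomes.

## Homolog search

Pairwise alignment is exact affine-gap dynamic programming (Biopython's
`PairwiseAligner`) under BLOSUM62 with the convention that a gap of
length *k* costs `gap_open + k * gap_extend` (defaults 10 and 0.2; this
maps onto Biopython's first/subsequent-position scores as
`open = -(10 + 0.2)`, `extend = -0.2`).  Local mode is used for
threshold screening, global mode for guide-tree distances.  No
heuristic prefilters or E-values are involved: the intended proteomes
(hundreds to a few thousand candidates) are small enough for exact DP.

**Percent similarity** is defined as the number of alignment columns
whose substitution score is positive, divided by the alignment length
*including* gap columns.  Database front-ends that report "similarity"
rarely state their denominator; this choice is documented so tests can
be exact.  Two consequences are worth knowing:

* the cheap gap extension makes optimal local alignments of unrelated
  proteins long and gap-diluted, so random 400–900-residue pairs score
  ~0.22–0.30 positives — the 30 % screening threshold sits at the very
  edge of the random background.  Short subjects (< ~250 residues) can
  exceed it spuriously;
* the screen is therefore treated as a *candidate* filter: family
  membership is always confirmed by the dual-domain rule, which is why
  end-to-end counts are robust even when a background protein drifts
  over the threshold.

**Reciprocal expansion** starts from a seed query, collects every
subject at or above the threshold, then re-queries with the
highest-similarity hit not yet used as a query, until a round adds no
new hits or `max_rounds` (default 5) is exhausted.  This generalizes
the manual two-to-three-round protocol deterministically (ties broken
by id).  Isoform handling: exactly one record per isoform group
survives — the longest, ties broken by lexicographically smallest id.

## Domain filter and typing

A protein is a family member iff it has at least one lectin-role hit
and at least one kinase hit.  The accession → (role, model length)
vocabulary ships with Pfam-style defaults (`B_lectin`, `Lectin_legB`,
`Lectin_C`, `Pkinase`/`Pkinase_Tyr`, `S_locus_glycop`, `PAN_*`,
`EGF*`, `DUF3403`) and is fully overridable from YAML.  Mixed lectin
identities raise an explicit `AmbiguousTypeError` rather than being
resolved silently — no real catalogue case motivates a precedence
rule.  A hit is *truncated* when it is at least 10 residues shorter
than its domain model; the same margin is applied to kinase domains
(an extrapolation chosen for symmetry — the published rule concerns
lectins).  Truncation is reported, never used to reject a member.

## Topology classes

Input models are ordered inside/membrane/outside segments tiling the
sequence, with per-segment scores and an optional signal-peptide score
(emulating TMHMM + SignalP output).  Processing order:

1. **TM acceptance**: membrane segments scoring < 0.8 are removed and
   their span absorbed into the flanking side segments, which merge
   under the longer flank's label.  If that breaks side alternation
   across a surviving TM, the model is flagged contradictory and the
   protein reports `UNCLASSIFIED`.  Removing a protein's only TM
   yields `NO_TM`.
2. **Signal-peptide priority**: if the SP score is ≥ 0.7 and the first
   TM overlaps positions 1..`sp_end` (or starts within the first 40
   residues when the cleavage site is absent), that TM is
   reinterpreted as the signal peptide — it leaves the TM count and
   the mature chain starts extracellular.  The priority rule runs
   *before* TM counting, so a signal-anchor TM never inflates the
   count.
3. **Domain sides**: a domain is extracellular/intracellular when the
   corresponding side segments cover a strict majority (> 50 %) of its
   residues; otherwise (e.g. a TM splitting it evenly) it is
   `membrane_spanning`.
4. **Classification**: the eight observed (TM count, lectin side,
   kinase side) patterns map to classes I–VIII; zero TMs map to
   `NO_TM`; every other combination — (1, intra, intra), ≥ 4 TMs,
   membrane-spanning domains — maps to `UNCLASSIFIED`.  For fusion
   architectures with duplicated domains (class VII/VIII) the first
   lectin and first kinase by coordinate decide, with multiplicity
   recorded in the architecture string; no multi-domain voting rule is
   invented.

The **fallback TM predictor** is a Kyte–Doolittle sliding window
(width 19): runs of window means ≥ 1.5 become membrane segments (minimum
length 15), the peak mean maps to a [0, 1] score through a fixed
logistic (midpoint 1.0, slope 3 — calibrated so detected segments pass
the 0.8 acceptance threshold on the package's own fixtures), and sides
alternate starting from the positive-inside heuristic (the flank richer
in Arg+Lys is cytoplasmic).  It is a deliberately simple stand-in for
an HMM topology predictor, adequate for constructed fixtures, not for
production annotation.

## Tandem clusters

Ranks are computed against the full gene annotation per chromosome.
Two family genes are tandem-adjacent when at most `max_intervening`
(default 5) non-family genes lie between them *or* their bp gap is at
most `max_gap_bp` (default 100 kb); clusters are maximal chains, which
for this interval-monotone relation equals the full adjacency closure
(verified against a brute-force union-find oracle).  A cluster with
more than 20 members is flagged "super".  The criterion itself is a
design decision — surveys rarely define "tandem repeat" operationally —
so both knobs are configurable and echoed in all reports.
Scaffold-placed genes (chromosome id starting with `scaffold`) are kept
in the catalogue but excluded from clustering and from clustered-
fraction denominators.

## Phylogenetics

* **Progressive MSA**: guide tree by UPGMA (scipy average linkage) on
  p-distances from pairwise global alignments; profiles merged by a
  vectorized Gotoh profile aligner whose column score is the
  frequency-weighted mean substitution score (gap symbols score zero —
  gap costs live entirely in the affine penalties, which also apply to
  terminal gaps, matching the pairwise aligner).  For two sequences the
  profile aligner provably reaches the pairwise DP optimum (tested).
* **Distances**: p = mismatches / shared non-gap columns; the 20-state
  Jukes–Cantor analogue d = −(19/20)·ln(1 − (20/19)·p).  p ≥ 19/20
  saturates the correction and raises an error rather than returning
  infinity.
* **Neighbor joining**: classical Saitou–Nei Q-criterion with
  deterministic tie-breaking (lowest active index pair).  Negative
  branch-length estimates are clamped to zero; the pre-clamp value is
  retained in a node annotation and the total deficit logged.  On
  additive matrices NJ is exact — topology and pre-clamp lengths —
  which the tests verify over random 4–12-taxon trees.
* **Bootstrap**: replicates resample alignment columns with
  replacement; a replicate in which some pair shares no sampled
  non-gap column is redrawn (logged).  Support of each bipartition of
  the full-data tree is the fraction of replicate trees containing it;
  deterministic under a fixed seed.  Trees are dendropy objects
  (Newick IO, bipartition encoding); dendropy's own tree machinery is
  also the independent cross-check in the test suite, never the
  implementation.

Maximum-likelihood inference (model selection, NNI search, aLRT
supports) is deliberately out of scope: the distance path is the
implemented, validated surface.

## Expression zones

"Expressed in a tissue type" means FPKM ≥ 1 in **at least one** sample
of that type; a strict all-samples mode exists behind a flag because
published zone analyses treat a tissue type as a unit without stating
the within-type rule.  Over the four standard types (root, leaf, stem,
bud) every gene lands in exactly one category: Zone I (no type
expressed; sub-flag "undetectable" when FPKM = 0 everywhere), Zone II
(all four), Zone III (root only), Zone IV (bud only), stem-only,
leaf-only, two-tissues or three-tissues.  The specificity table
(types × categories with marginals) asserts its own row/column
consistency on every construction.  Reproductive (female/male) tissue
types use the same any-sample rule, independently of the standard
zones.  Which samples count as "standard conditions" is a
grouping-file concern, never hard-coded.

## Synthetic catalogues

The generator's defaults encode the reference study design: 231 family
members (180 G / 50 L / 1 C), the per-type orientation-class census
(classes VII/VIII only among G-type — requesting them for another type
is rejected as infeasible), tandem clusters of 21/22/23 G-type genes
(three super regions) plus an 8-gene L-type cluster, 36 scaffold-placed
genes, the per-type expression-specificity census, 12 standard samples
(2 root, 3 leaf, 2 stem, 5 bud) plus 2 female and 2 male samples, and
21/9 female- and 9/1 male-specific G/L genes.  Category quotas are
apportioned by deterministic largest-remainder allocation, so designed
counts are exact at any family size.

Construction details that matter for interpretation:

* Domain "sequences" are fixed random signature blocks, one archetype
  per domain role per seed; members of one (type, class) are identical
  before divergence.  `mutate_family` substitutes each site
  independently with probability `divergence_rate`, uniformly over the
  other 19 residues, so the expected p-distance to the seed equals the
  rate (the closed form used by the parameter-recovery tests).
* Background proteins are uniform-random sequences of 250–850 residues
  (short random subjects can spuriously clear the 30 % local-similarity
  screen) and never carry both a lectin and a kinase annotation;
  configurable fractions carry single-domain decoy hits to exercise the
  filter's negative set.
* Cluster members sit at 2 kb gaps with no intervening genes; isolated
  family genes sit behind six background/filler genes and > 140 kb on
  either side, so the default clustering criterion separates them
  cleanly.
* FPKM: designed "expressed" values are uniform on [5, 100],
  "not expressed" uniform on [0, 0.5], "undetectable" exactly 0, then
  Gaussian replicate noise (sd default 0.1, clipped at 0; designed
  zeros stay exact).  The off-state band is kept well below the
  detection cutoff so that designed states survive realistic noise;
  this is a stand-in — the real data's replicate noise structure is
  unknown — and the 0.5 ceiling is a deliberate margin between the
  off-state and the cutoff.

**What the round-trip tests show**: at zero divergence and zero noise
the full pipeline recovers every planted label (type, class, cluster,
super flag, zone) exactly, and at divergence 0.05 / noise sd 0.1
agreement stays ≥ 95 %.  What they do *not* show: performance on real
proteomes with indels, rate heterogeneity, overlapping or partial
domain hits, ambiguous topologies, or atlas-scale expression noise —
the generator models none of these.

## Pipeline and problem sizes

Stages run homology → domains → topology → tandem → phylogeny →
expression; every stage logs one structured line of input/output
counts, and the summary's provenance block (full config, SHA-256 hash,
seed) suffices to re-run bit-identically.  Cross-table marginal
consistency (per-type totals = class-column sums; specificity grand
total = catalogue size) is asserted on every run, not just in tests.

The phylogeny stage of the orchestrated pipeline builds its tree on an
evenly spaced, seeded subset of members (default cap 40 taxa) with a
configurable bootstrap count: guide-tree construction is quadratic in
pairwise global alignments, and a full-catalogue MSA adds nothing to
label-recovery checks.  Dedicated analyses can always call
`progressive_msa`/`bootstrap_support` directly on any selection.  The
acceptance script uses a 24-taxon cap with 200 replicates for the
catalogue run and the canonical 12-taxon, 300-column, 1000-replicate
setting for the bootstrap floor.
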