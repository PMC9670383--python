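# Methods

## Scope and posture

`detoxevol` implements the computational layer of a comparative analysis of
detoxification gene superfamilies (CYP, CCE, GST) in five hemipterans. The
heavy upstream tools of such an analysis — BLAST/tBLASTn searches,
InterProScan, alignment, trimming and maximum-likelihood tree building —
are established programs whose outputs (hit tables, domain tables, rooted
gene trees) are this package's *inputs*. What the package owns is
everything downstream: the curation rules, the duplication–loss
reconciliation and its per-branch accounting, the cluster rule, the
contingency statistics, and a simulator that generates data with known
answers for validating all of it.

## Species tree and branch naming

The default species tree is
`(Nlug,((Clec,Rpro)CR,(Hhal,Nvir)HN)HET)root` — *N. lugens* as the
non-heteropteran outgroup, a bed-bug/kissing-bug clade (CR), a pentatomid
clade (HN), and their heteropteran ancestor (HET). Every node label doubles
as the name of the branch above it, which is what lets duplication and loss
counts be charged to named branches, including internal ones. The tree is
user-overridable; any rooted binary newick with unique labels works
(unlabelled internal nodes are auto-named).

Gene-tree leaves carry their species as a 4-letter tag prefix
(`Hhal_CYP3_g7`); the extraction pattern is configurable, and a leaf whose
tag is not on the species tree is a hard error naming the leaf.

## Duplication–loss reconciliation

Classical LCA mapping on a rooted gene tree G and rooted species tree S:
M(leaf) is the leaf's species; M(v) = lca_S(M(left), M(right)). Node v is a
**duplication** iff M(v) equals the image of one of its children, otherwise
a **speciation**. For a gene-tree edge (v, c) whose images span the species
path M(v) = s0 → s1 → … → sk = M(c):

* a speciation contributes k − 1 losses, one charged to the sibling branch
  at each intermediate node s1 … s(k−1);
* a duplication contributes k losses, additionally charging the sibling
  branch at s0.

Charging losses to the *sibling* branch places each loss on the branch
where the lineage actually disappeared, which is what a per-branch loss row
needs. Duplications are charged to the branch above M(v); duplications
mapping to the species root predate the first split and go on a synthetic
`root` branch so that totals are preserved even though the species tree has
no branch there.

This mapping yields the most-parsimonious reconciliation: the test suite
verifies the cost against an exhaustive enumeration of *all* valid
duplication–loss reconciliations for every rooted binary gene tree of up to
six leaves over a three-species tree.

**Polytomies** are rejected by default — the expected inputs are binary ML
trees, and silently resolving would hide data problems. An opt-in mode
(`polytomies="resolve"`) resolves each multifurcation greedily, always
joining the pair of children whose species LCA is deepest (ties on the
smallest leaf name), which favours speciations over duplications. It is a
deterministic heuristic, not an exact minimum over all resolutions.

**Rooting.** For gene trees lacking an outgroup, `root_by_min_dl` tries
every branch of the unrooted topology and keeps the rooting of minimum DL
cost; ties break on the lexicographically smallest pair of minimal leaf
names flanking the root branch, so the choice is reproducible. Branch
support values are not used to collapse weak nodes; if collapsing is
wanted it belongs upstream.

**Event matrix.** Per-family results aggregate into a branch × family-group
matrix with `Duplications` and `Losses` rows per branch. Row, column and
grand totals are always recomputed as sums — the packaged fixture stores
only cells, and `fixture_discrepancies()` reports the two places where the
originally printed totals disagree with their own cells (the outgroup
duplications row total and the grand total) instead of resolving them.

## Cluster rule

Two genes cluster when they share family and scaffold and are separated by
**less than 35,000 bp**, strictly: a 34,999-bp gap clusters, a 35,000-bp
gap does not. Separation is boundary-to-boundary — the bases strictly
between the two intervals, zero when they overlap — because "separated by"
most naturally reads as intervening distance; start-to-start and midpoint
metrics are available since the convention is not forced. Clusters are
connected components of the pairwise graph (single linkage): A–B–C with
adjacent gaps under the threshold is one cluster even when A–C is not, and
an interleaved gene of another family neither joins nor breaks a chain. A
greedy complete-linkage mode exists for sensitivity checks. Genes on
different scaffolds never cluster, which on scaffold-level assemblies can
only undercount clustered genes — reports should read cluster percentages
as lower bounds.

## Contingency schemes and statistics

Expansion tests compare two species with Pearson chi-square (1 df) on 2×2
tables under three schemes: (a) detoxification genes vs the rest of the
genome (requires genome-wide gene totals, supplied by the caller), (b) one
superfamily vs the sum of the other two, (c) one clan/class vs the rest of
its superfamily. The statistic is plain Σ(O−E)²/E without continuity
correction — Yates is available as an option but off by default, matching
the ordinary reading of "chi-square test". Any expected cell below 5 sets a
flag rather than suppressing the result; a zero margin is an error because
the test is undefined. Raw and Benjamini–Hochberg-adjusted p-values are
both reported so no significance threshold is imposed.

Percentages are rounded half-away-from-zero (17/29 → 58.6%). Fold ratios
(total duplications over total losses for a group) are reported raw *and*
truncated to one decimal, because a printed "2.8-fold" corresponds to
truncation of 154/54 = 2.85…; zero losses give a flagged infinite ratio.

## The simulator

The generator realises the gene birth-and-death model the analysis assumes,
discretised per species-tree branch. Each incoming lineage on a branch
draws Poisson(dup_rate) duplications placed at ordered uniform points; each
event splits a uniformly chosen extant descendant of that lineage, so new
copies are exposed to later events on the same branch. At the bottom of the
branch every lineage is lost independently with probability loss_prob;
survivors speciate into both child branches. The expected copy number per
species is `root_copies · Π (1+dup_rate)(1−loss_prob)` over the root-to-leaf
path, which the suite checks by Monte Carlo (1,000 replicates, 3 standard
errors). Every event is logged per branch, surviving counts per species are
recorded, and extinct families keep their full truth log with an empty
tree — useful for quantifying how loss erodes the reconcilable signal.

Defaults `dup_rate = 0.3`, `loss_prob = 0.1` per branch give gene families
of realistic size for detoxification clans (a handful to a few dozen copies
across five species) with a duplication surplus, matching the qualitative
expansion regime of the empirical matrix; they are modelling choices, not
estimates — the rate regime behind the empirical counts is unknown. With
`loss_prob = 0` the reconciliation provably recovers the simulated
per-branch duplications exactly (each duplication node maps to its true
branch when no descendant is missing), and the suite confirms this over
500 families; with losses, the inferred cost is a lower bound on the true
event count, also asserted over 500 families.

The scaffold-layout generator places a configurable fraction of each
family's genes in tandem chains with gaps drawn strictly below the 35-kb
threshold and separates everything else by gaps at or above it, so the true
cluster partition is known by construction and detector recovery can be
asserted exactly. What the synthetic data does **not** emulate: sequence
evolution (no substitutions or indels — protein sequences in bundles are
random placeholders), pseudogenes, rate heterogeneity across families,
assembly artefacts, or incomplete transcriptomes. Passing tests therefore
demonstrate correctness of the inference machinery on clean data, not
robustness to annotation error.

## Numerical and procedural choices

* Filter boundaries are strict and unit-tested: a 100-aa protein passes the
  "shorter than 100" rule; an E-value of exactly 1e-4 fails "< 1e-4".
* Isoform ties (equal lengths) keep the smallest protein id.
* Proteins whose domains match two superfamilies are flagged as conflicts
  and kept with the first label, never silently assigned; missing domain
  annotations are discards with an explicit reason.
* Every filter returns a discard log and preserves
  retained + discarded = input.
* All randomness flows from explicit seeds through
  `numpy.random.default_rng`; per-family seeds are spawned from a
  `SeedSequence` so family k is reproducible independently of how many
  families are drawn. Pipeline outputs contain no timestamps; same-seed
  runs are byte-identical.
* Cluster output order is fixed (species, family, scaffold, leftmost
  start), making reports permutation-invariant in the input order.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at deliberately modest sizes:
exhaustive reconciliation checking at ≤ 6 leaves / 3 species (≈ 2,000 gene
trees), 500-family simulation recoveries, 1,000 random cluster layouts of
≤ 50 genes, 10,000 null contingency tables for type-I calibration, and a
200-family seeded round trip in the acceptance script. These sizes give
tight Monte-Carlo intervals while keeping a full run under a minute.

## Known limitations

* Reconciliation assumes the gene tree is correct; reconstruction error
  inflates inferred events. No support-based collapsing is offered.
* Parsimony under-counts: a duplication followed by loss of both copies on
  the same branch is invisible, so per-branch losses are lower bounds —
  especially for taxa represented only by transcriptomes, where absent
  genes may simply be unexpressed.
* The polytomy resolution and complete-linkage clustering modes are greedy
  heuristics, documented as such.
* Scheme (a) tests need genome-wide gene totals the package does not ship.
* The cluster rule ignores strand and intervening gene content by design;
  biological tandem arrays with large insertions are split.
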