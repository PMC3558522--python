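# Methods

## The problem and the pipeline's shape

Target enrichment of ultraconserved elements (UCEs) yields hundreds to
thousands of short loci (a conserved core with increasingly variable
flanks) across distant taxa. The downstream analysis this package
implements is the standard one for such data: assign assembled contigs to
the reference loci while guarding orthology, build complete and
partially-missing supermatrices for concatenated analyses, select
per-locus substitution models and partition by model, estimate per-locus
gene trees, summarise them into a species tree that accommodates
gene-tree discordance, and use shared indels as an independent,
low-homoplasy line of evidence for clades.

Because the interesting regime — an ancient rapid radiation — is exactly
the one where truth is unknowable from real data alone, the package is
organised around a simulator with full truth tables, and every stage is
validated against that truth or against an independent brute-force
oracle.

## Simulator

**Species tree.** Yule (pure-birth) trees with waiting times
Exp(k·birth_rate); branch lengths are produced directly in coalescent
units, since the downstream multispecies coalescent needs that scale and
no external timescale is imposed. Internal branch lengths are multiplied
by `internal_branch_scale` (default 0.1) after the draw — this is the
rapid-radiation dial: tips keep long terminal branches while internodes
shrink. A `min_internal_branch` floor supports controlled low-discordance
regimes. An outgroup can be attached as sister to everything,
`outgroup_stem` (default 5) coalescent units above the ingroup root, deep
enough that essentially no lineage sorting spans it.

**Gene trees.** One sampled lineage per species; within each species-tree
branch, lineages coalesce at rate k(k−1)/2 per coalescent unit; lineages
remaining at the root coalesce in the unbounded ancestral population.
Each locus uses an independent RNG substream derived from (seed, locus
index), so locus i's tree is invariant to the total locus count. The
implementation was checked against the closed-form quartet prediction:
for an asymmetric 4-taxon tree with internal branch t, each minor
topology appears with frequency e^(−t)/3 (no coalescence on the branch,
then a uniformly random first join), which a 3000-locus run reproduces
within Monte-Carlo error.

**Sequences.** HKY85 (default κ = 3, frequencies 0.3/0.2/0.2/0.3) via the
eigendecomposition of the normalised rate matrix; the model family is the
same one the selection stage searches, keeping closed-form checks
available. Site rates are two-tier: a central `core_fraction` (default
0.34, roughly a 120 bp probe core in a 350 bp locus) evolves at
`core_rate` (default 0.05) and the flanks at `flank_rate` (default 1.0)
times `subst_rate` (default 0.02 substitutions/site per coalescent unit).
The core/flank ratio is a structural choice, not an estimate from data.

**Indels.** Deletions only: an insertion would create columns absent from
the ancestor and make true column homology bookkeeping ambiguous, while
deletions leave the emitted alignments exactly column-homologous with the
reference, which is what the indel scanner consumes. Events per locus are
Poisson(`indel_rate`); each picks a branch with probability proportional
to its length (optionally internal branches only), a length uniform on
[`indel_len_min`, `indel_len_max`] (default 2–10 bp), and a position such
that events within a locus stay column-disjoint with at least one
non-gap column between them and never touch the alignment ends. That
placement rule is what makes every event a recoverable maximal gap run
with identical boundaries across its taxa; overlapping or terminal
events would be real-data complications the detector's "missing data"
and slop rules address, but the round-trip validation deliberately
excludes them.

**Contigs.** One ungapped contig per retained (non-dropout) taxon-locus
pair; dropout is i.i.d. Bernoulli per cell (default 0.13, the
87%-complete regime). With probability `paralog_prob` (default 0.02,
matching the few-dozen-per-sample removal counts enrichment studies
report) a taxon additionally receives a chimeric contig: the 5′ half of
its own contig at one locus joined to the 3′ half at another. Halves
guarantee high identity to two loci over ~50% of each — which is why the
paralog screen in the validation runs uses a locus-coverage threshold of
0.45, just under one half; the generic default of 0.80 is for ordinary
orthologous matching.

**What the simulator does not emulate:** read-level errors and coverage,
assembly artifacts, alignment error (emitted alignments are true
alignments; there is no realignment step), insertion indels, rate
variation beyond the two tiers, and correlated (non-i.i.d.) locus
dropout. Passing tests therefore demonstrate correctness of the
algorithms under clean inputs, not robustness to upstream noise.

## Matching and duplicate filtering

Candidate (contig, locus) pairs come from shared 15-mers (both strands);
verification is local alignment (Biopython's PairwiseAligner, match 1,
mismatch −1.5, gap open −3, extend −1 — scores checked in the tests
against an independent Smith–Waterman dynamic program). Identity is
computed over aligned columns (local alignment has no terminal
overhangs); coverage is the aligned span over the locus length. A pair is
reported when identity ≥ `min_identity` (0.80) and coverage ≥
`min_locus_fraction`. Filtering is two rules in fixed order: (a) a contig
matching more than one locus is removed entirely — a tie for best locus
does not rescue it; (b) a locus hit by more than one surviving contig of
a taxon is dropped for that taxon rather than keeping the best contig.
Rule (b) is the conservative reading; it is logged separately so the
choice is auditable.

## Supermatrices

`?` encodes whole-locus absence; `-` encodes within-alignment gaps. Both
are missing for informative-site counting, but only `?` blocks count
against completeness — indels are characters of the alignment, absent
loci are not. Completeness is cell-based (filled taxon×locus cells over
all cells), the natural reading of a "percent complete" matrix
statistic. The retention test is ≤ ("up to 50%" keeps exactly half
missing). Partition intervals are 0-based half-open internally; exports
use each format's native convention (1-based inclusive for RAxML-style
partition files and NEXUS charsets).

## Model selection

Candidates are JC69, K80, F81, HKY85 and GTR, each optionally +G4 — ten
models spanning the nesting hierarchy that model-based partitioning
relies on. (A full MrAIC-style set with +I variants would be a superset;
the partition count here is structurally capped at ten.) For each locus:
NJ topology from JC distances; for each candidate, branch lengths by
coordinate-wise line search with cached inside/outside partials (each
candidate length costs O(site patterns)), substitution parameters (κ,
GTR exchangeabilities, gamma shape) by bounded ML, then a final sweep;
two sweeps at tolerance 1e−4 on lnL, with a rollback safeguard since the
cached sweep is Gauss–Seidel-like. +G4 uses the mean-category
discretisation of a mean-1 gamma. Base frequencies are empirical counts
(with a small pseudocount) rather than ML-optimised: standard, cheap,
stable. k counts free model parameters plus branch lengths (MrAIC's
convention); AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) with n = alignment
columns, falling back to AIC with a logged notice when n ≤ k + 1. Ties
keep the simpler model. Pairwise distances have closed forms for JC69
and K80; HKY85/GTR requests fall back to JC69 with a notice; saturated
pairs are capped at `max_distance` (5.0).

## Gene trees and STAR

Neighbor-joining (Saitou–Nei Q criterion) with negative branch lengths
clamped to zero and deterministic tie-breaking by the lexicographically
smallest pair of cluster representatives, so results are independent of
input order. Taxa involved in no-shared-data pairs at a locus are pruned
from that locus (most-masked first). Gene trees are rooted at the
midpoint of the outgroup's pendant edge; loci lacking the outgroup are
excluded from rank-based analyses.

STAR assigns rank n−1 to the root of an n-tip rooted binary gene tree
and parent−1 to every other internal node; the distance between two taxa
is twice their MRCA's rank. Distances are averaged entrywise over the
gene trees in which both taxa occur — averaging over co-occurring trees
only is what lets STAR run on incomplete locus sets — and NJ on the
averaged matrix gives the species tree. Multifurcating gene trees are
rejected outright rather than guessing a rank convention for polytomies.

The multilocus bootstrap draws L loci with replacement, then columns
with replacement within each drawn locus to its original length,
re-estimates all gene trees and the STAR tree, and scores each internal
branch of the point estimate by the percentage of replicate trees
containing its unrooted bipartition (unrooted splits are robust to
per-replicate rooting failures). Replicate r uses RNG substream
(seed, r), so any replicate can be reproduced in isolation. A replicate
whose locus draw leaves a taxon pair disconnected is redrawn (bounded);
with complete matrices this never triggers. `collapse` contracts
branches below a support threshold into polytomies.

## Indel evidence

A shared indel is a maximal internal gap run of ≥ 2 columns with
identical start and end in ≥ 2 ingroup taxa; leading/trailing runs are
missing data, not indels. Identical boundaries are the strict homology
reading; a `boundary_slop` option (default 0) merges runs whose ends
differ by at most that many columns, for realigned real data. An event
validates the branch whose ingroup descendant leaf set equals the
sharing set exactly — a gap shared by a clade plus an outside taxon is
evidence against the branch, so subset matches are deliberately counted
as homoplastic. Events are counted per locus occurrence (identical
events at different loci are separate evidence).

## Problem sizes in the validation suite

The acceptance benchmarks run at: enumeration-vs-pruning on ≤ 6 tips ×
≤ 5 columns; NJ on random additive matrices of ≤ 8 taxa; bootstrap
consistency at 8 taxa × 200 loci × 1000 bp × 100 replicates × 20 seeds
(every internode ≥ 2 coalescent units — a regime where STAR is expected
to converge); paralog recall at 12 taxa × 80 loci; indel round trip at
8 taxa × 6 loci × 50 seeds in a fully concordant regime; completeness at
the full 33 × 1541 cell scale with 120 bp loci (the statistic is
per-cell, so locus length is immaterial). These sizes are the package's
own validation design: large enough for the statistical claims being
checked, small enough to run on a laptop.

## Known limitations

Gene-tree estimation is distance-based NJ, not per-locus ML: adequate
because STAR consumes topologies and ranks, and short UCE loci carry
limited per-locus signal, but a hook accepts externally estimated Newick
gene trees for hybrid runs. Concatenated Bayesian/ML tree inference is
out of scope; supermatrices, partition files and NEXUS exports serve
external tools. The likelihood engine has no +I (invariant-sites) class.
The simulator's clean-alignment assumption means indel-detector
performance on realigned real data will depend on the `boundary_slop`
setting, which has no simulated analogue here.
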