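# Methods

## Model

A genome is a master list of N protein-coding genes in rank order along
chromosomes (chromosomes natural-sorted by name unless an explicit order is
given; within a chromosome genes are ordered by start coordinate, ties broken
by end coordinate then gene id). All proximity is measured in rank
differences; base-pair coordinates are read, converted to a single internal
convention (1-based closed; BED input is converted from 0-based half-open) and
never used after indexing. Strand is preserved for reporting but ignored by
every computation. Overlapping gene models are kept as distinct ranked loci.
Unplaced scaffolds are treated as additional chromosomes.

Evidence of ancestral relatedness is normalized to a uniform term form: a
dataset maps each gene to a set of term ids, and for every term the exact
genome-wide carrier count m is tabulated. Explicit paralog pairs are converted
by taking connected components of the paralogy graph as synthetic family terms
(component term ids are canonicalized by the smallest member gene id, so the
conversion is independent of pair input order). Genes with no annotation in a
dataset keep their ranks: they can be interstitial and they are what the
coverage audit counts as dark.

## Chromosome walk and permutation null

The walk asks, for each gene and each span n in 2..`max_span` (default 100,
n = 2 meaning adjacent; the internal rank offset is d = n − 1), whether the
gene n positions downstream on the same chromosome shares at least one term.
Each forward pair is counted once. The per-gene nearest-related distance is
searched in both directions, capped at a rank difference of `max_span` − 1,
with an overflow bin for genes (including unannotated ones) with no related
neighbor within the cap.

The null model shuffles genes genome-wide into the fixed positional slots
(chromosome sizes preserved, annotations following the genes); the default of
10 permutations is a parameter because reasonable choices between 5 and 10
exist and the baseline is already smooth at either. The expected baseline is
flat up to edge effects: at offset d a chromosome of L genes offers L − d
forward slots, so the baseline declines by a factor proportional to the number
of chromosomes divided by N per unit span — the "very slight negative slope"
the acceptance suite checks.

## Chaining

Per dataset and chromosome, a forward scan opens a chain at the first
unassigned annotated gene. From the last member it looks ahead for the nearest
*unassigned* gene sharing at least one term of the chain's current common
subset; on admission the subset is intersected with the new member's terms
(the admission rule keeps it non-empty). The scan tolerates an effective run
of at most `max_gap` (default 15) consecutive non-member genes; a longer run
closes the chain at its last member, so k (span, interstitials included) is
measured member-to-member. Chains with l ≥ 2 members are emitted; every gene
joins at most one chain per dataset, first come first served, which makes the
result order-dependent in the way any greedy forward pass is. The number of
gaps per chain is uncapped by default (`max_gaps` exists purely as a runtime
control).

Gap lengths are *effective*: a maximal run of consecutive interstitial genes
that are all members of one other chain — a nested tandem array of a different
family — counts as one gap space. Chains from *all* datasets of the run are
eligible as nesting evidence. Because effective gaps depend on chains, the
pass is re-run with the previous round's chain membership until chain
boundaries reach a fixed point, capped at 5 iterations (a warning is emitted
and the last result kept if the cap is hit; in practice two or three rounds
suffice). Running the collapse as a re-run rather than post-hoc gap accounting
is this package's choice; both readings are defensible and the fixed point
makes the rule self-consistent.

## Significance

For a chain with l members over k genes and common term frequency m in a
genome of N genes, p = P(X ≥ l) for X hypergeometric(N, m, k). For N ≤ 10,000
the tail is computed with exact integer binomials (converted through a
rational to avoid rounding); above that, scipy's log-gamma survival function
is used, and the two paths are cross-checked in the tests. The expectation
correction is e = p × N exactly — the number of chain opportunities is taken
as the gene count, the approximation the method itself sanctions — rather than
p × (N − k + 1). When the common subset holds several terms, each is scored
and the largest p wins; together with e this makes the method deliberately
conservative (it underestimates clustering). Chains with e < `e_threshold`
(default 0.01) are significant; 0.05 / 0.1 / 0.15 are supported for
sensitivity sweeps, and the significant sets are nested across thresholds
because the chain set itself does not depend on the threshold.

### Residual false positives on null genomes

e = p·N corrects for *positional* opportunity but not for the multiplicity of
families tested. With a realistic family-size mixture (thousands of 2–5 member
families), the expected number of chance chains passing e < 0.01 on a
randomized 20,000-gene genome is the sum over families of
C(m,2)·2·d_max(m)/N, where d_max(m) is the largest member distance whose pair
still scores below threshold (for m = 2, k(k−1)/(N−1) < 0.01 gives d ≤ 13).
This evaluates to ≈ 3 per dataset, and measurement on ten null seeds gives
≈ 3.4 — a handful against the hundreds-to-thousands of real clusters the same
settings detect, but not literally zero. The acceptance suite contains a
stricter check (mean < 1) that this implementation does not meet under the
calibrated mixture; the test is kept as-is rather than thinning the mixture,
and this analysis documents why.

## Merging and metrics

Significant chains from different datasets are merged transitively when their
member-gene sets intersect. Member intersection, not interval overlap, is the
criterion: interval overlap would fuse nested clusters of unrelated families.
Members are the union; interstitials are recomputed over the merged span, so a
gene interstitial for one dataset but member for another becomes a member.
Cluster size is l, the paralog count, never the span. Adjacency fractions
(percent of genes with a co-cluster member at rank distance 1, or within 10)
are computed on merged clusters. The dataset overlap matrix intersects
per-dataset clustered-gene sets (the choice for off-diagonal cells when the
merged alternative was also defensible). Cross-species sharing follows the
in-paralog rule: a cluster is shared with a partner species when at least one
member has an in-paralog inside any of the partner's clusters, and
species-specific when shared with none of the supplied partners.

## Synthetic genomes

Defaults are calibrated to the annotated human genome: N = 20,000 genes over
26 chromosomes with skewed sizes including micro-chromosomes; 68.3% of genes
are singleton families; multi-member family sizes are 1 + Geometric(p = 0.5)
with probability 0.97 and 10 + Geometric(p = 0.12) with probability 0.03
(capped at 100), giving a multi-family mean near 3 and a few percent of genes
in families larger than 10. Five datasets are emulated — four term-based, one
pair-based — each dropping every gene independently with probability 0.1
(modeling incomplete annotation coverage; this is what makes merging
informative). Two prolific domains (400 and 250 carriers) are sprinkled on
dispersed genes and attached to the domain-style datasets only, to exercise
the false-negative regime of high-frequency terms and the risk of spuriously
absorbing neighbors into large clusters. Planted clusters are private
families laid contiguously or with prescribed gaps at random internal
boundaries, optionally nested inside another cluster's gap; non-planted genes
are shuffled uniformly into the remaining slots. Coordinates are synthetic
(2 kb spacing with jitter); no sequence-level realism is attempted, so passing
tests demonstrate the positional statistics and bookkeeping, not robustness to
annotation noise beyond independent per-gene dropout, nor to correlated errors
real pipelines produce.

The ledger records families, planted layouts, prolific-domain carriers and
per-dataset dropped genes exactly as emitted, so tests compare computed
quantities against ground truth rather than frozen copies of outputs.

## Numerical and determinism choices

All randomness flows through `numpy.random.default_rng` seeds carried in
configs; identical config and seed give byte-identical report files (the
provenance record carries parameters and input SHA-256 checksums, no
timestamps, and omits the output directory). Tie-breaks are explicit
everywhere order could leak in: gene sort ties by end then id, scoring ties by
term id, chain ids by dataset/chromosome/start rank, cluster ids by start
rank. Thresholds compare strictly (e < t). Degenerate inputs — empty datasets,
unannotated genes, single-gene chromosomes, l = 0 or l > m tails — take the
defined trivial values rather than erroring.

## Problem sizes used in tests

Unit tests run on genomes of tens to a few thousand genes with brute-force
oracles (all-pairs scans, subset enumeration, exact rational arithmetic,
independent union-find). System-level checks use 20,000-gene genomes, 10
permutations or seeds, and 50–100 planted clusters — sizes at which every
statistic of interest is stable while the full suite stays fast.

## Known limitations

* Greedy first-come chaining is order dependent; a gene consumed upstream
  cannot seed or join a downstream chain even when that assignment would score
  better.
* e = p·N does not correct for the number of families tested (see the residual
  false-positive analysis above).
* The generator's dropout is independent per gene and dataset; real annotation
  gaps are correlated (gene models, clades, pipelines), so merged-recovery
  gains measured here are optimistic.
* Cross-species comparison implements pairwise sharing composition only; no
  ancestral reconstruction of where a cluster first arose.
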