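# Methods

This note documents the models and procedures implemented in `hybridscan`,
the assumptions behind them, the defaults that matter, and what the built-in
simulator does and does not emulate.

## Problem setting

Rapid radiations — the motivating case is the cichlid species flock of Lake
Tanganyika, sampled with hundreds of anchored loci across ~150 species —
produce pervasive gene-tree/species-tree discordance from two sources:
incomplete lineage sorting (ILS) and introgressive hybridization. The
package implements the analytical layer that separates the two: Patterson's
D tests over individual permutations with bootstrap and FDR control,
per-locus introgression scans, locus-tree split-conflict analysis to
*generate* hybridization hypotheses, gene jackknifing to measure how tree
support accumulates with loci, and Mk-model ancestral-state reconstruction
to derive trait-based branch partitions.

## Simulator (multispecies coalescent with tree-switch introgression)

Gene trees are drawn under the standard MSC: within each species-tree
branch, `k` lineages coalesce at rate `k(k-1)/2` per coalescent unit
(2N generations), merging at internal nodes and finishing above the root.
The species tree must be rooted and ultrametric with branch lengths in
coalescent units.

Introgression uses a *tree-switch* model: an event is (recipient leaf,
donor lineage, inheritance probability γ, event time). Independently per
locus, with probability γ the recipient's pendant branch is cut at the
event time and re-attached to the donor branch at that time; MSC
coalescence then runs in the modified history. This is the simplest
generative mechanism that yields the ABBA/BABA asymmetry D detects, and it
is analytically checkable: with no events and internal branch `t`, the
probability that a quartet gene tree matches the species tree is
`1 − (2/3)e^{−t}`, which the test suite verifies at t ∈ {0.5, 1, 2} over
5,000 loci. Restrictions (by design): at most one event per recipient, the
event time must lie on the recipient's pendant branch, no recombination
within loci, no demographic size changes.

Sequences evolve along each gene tree under JC69: uniform root state, and a
branch carrying `m = θ·ℓ` expected substitutions/site flips each site with
probability `(3/4)(1 − e^{−4m/3})`, uniformly to another base. θ is
expressed as expected substitutions/site per coalescent unit so that one
scale covers both time and mutation. Missing data is injected by masking
exactly `round(f·cells)` uniformly chosen cells with `?`; the default
`f = 0.051` mirrors the ~5% missingness typical of anchored-enrichment
matrices. One global seed expands into counter-based per-locus streams, so
datasets are reproducible regardless of evaluation order.

What the generator does *not* emulate: alignment error, paralogy,
rate variation among sites or loci, base-composition bias, selection, and
intralocus recombination. Passing tests on simulated data therefore
demonstrate the correctness and calibration of the statistics under the
MSC + JC69 model, not robustness to those real-data artifacts. The
curation filters (gap/ambiguity/stop-codon screens) target exactly such
artifacts but are exercised on constructed fixtures.

## Patterson's D

Site classification takes the outgroup allele as ancestral; a site is
informative only if biallelic with P3 carrying the derived allele, giving
ABBA for (P1,P2) = (ancestral, derived) and BABA for the reverse. Sites
with gaps, `N`/`?`, or IUPAC ambiguity in any role are unusable. The pooled
(Durand et al.) form uses derived-allele frequencies `p1..p4`
(derived = any allele other than the outgroup-majority allele; outgroup
ties make the site unusable; sites with two or more distinct derived
alleles get zero weight), with weights `ABBA = (1−p1)p2p3(1−p4)` and
`BABA = p1(1−p2)p3(1−p4)`. With singleton groups the two forms coincide
exactly — bit for bit, including the bootstrap, because both feed identical
per-site weight vectors through one resampling routine.

### Bootstrap unit

Significance uses Z = D / SD over 100 bootstrap replicates and a two-sided
normal p-value (matching the Z > 3 reporting convention). The default
resampling unit is the **locus** (block bootstrap). This was a deliberate
design decision backed by a calibration experiment: sites within a locus
share one gene tree, so ABBA/BABA outcomes are positively correlated
within loci, and a per-site bootstrap understates the variance of D. Under
the null study conditions below, per-site resampling produced |Z| > 3 in
11.5% of replicate datasets versus 4.5% for the locus bootstrap (nominal
≤ 5%). Per-site resampling remains available (`bootstrap="site"`) and is
used inside the per-locus scan, where a single locus is tested and its
sites are conditionally independent given the gene tree. Bootstrap
replicates whose resample contains no ABBA/BABA weight are dropped from
the SD; if the SD degenerates to zero, Z is reported as signed infinity
with a warning rather than silently.

### Hypothesis harness

A hybridization hypothesis assigns taxon sets to P1/P2/P3/outgroup.
`PattersonDTest.fit()` evaluates one D test per quadruple in the Cartesian
product of the four sets, adjusts p-values with Benjamini-Hochberg within
the hypothesis (cross-hypothesis adjustment is the caller's choice), and
declares a row significant only when both Z > 3 and adjusted p < 0.05.
Quadruples with no informative sites stay in the table as flagged rows but
are excluded from the BH family, preserving the permutation census.
Direction: significant D > 0 reads as P2–P3 gene flow (ABBA excess),
significant D < 0 as P1–P3 (BABA excess).

The per-locus scan runs the pooled D separately on each locus and flags
loci with fewer than 5 ABBA+BABA (weighted) sites as unusable — such
counts make D essentially unestimable; usable loci are ranked by |D|.

### Study conditions used by the tests and the acceptance script

Chosen once, as the package's reference conditions: species tree
`(((P1:1,P2:1):1,P3:2):1,O:3)` (internal branch 1 coalescent unit),
200 loci × 300 bp per dataset, θ = 0.0025 substitutions/site/coalescent
unit (≈1% ingroup pairwise divergence), 5.1% missing data, events at time
0.5 on the recipient's pendant branch with donor P3. Null calibration and
power use 200 replicate datasets; at γ = 0.3 the significant-and-correct-
direction rate is ~0.85–0.9 in both flow directions. The per-locus scan
demonstration uses 300 loci × 1000 bp at θ = 0.02 with γ = 0.1 so that
~100 loci pass the <5-informative-sites filter and the top-decile
enrichment of truly introgressed loci is estimable rather than a
three-locus lottery.

## Split support, conflicts, and jackknifing

Conflict analysis is expressed directly on bipartitions instead of drawing
split networks: the hypothesis-generation role and both published
thresholds are preserved (drop splits supported by fewer than 50 locus
trees; report conflicting splits supported by ≥20% of trees), while the
supernetwork/galled-network drawing machinery is deliberately out of
scope. A tree supports a candidate split if the split restricted to the
tree's leaf set is nontrivial and present in the tree; this restriction
rule handles incomplete taxon sampling across loci. When candidates are
not supplied, they are collected from trees that sample the full taxon set
— a partially sampled split consistent with several extensions would
credit each, which is the same ambiguity split networks resolve by
closure; supply `candidate_splits` explicitly for stricter control.

Gene jackknifing draws, for each dataset size, `n_rep` locus subsets
without replacement (independently across replicates), infers a tree per
subset with a pluggable estimator, and reports each reference split's
recovery frequency plus the percentage of reference splits recovered in
strictly more than 75% of replicates. Two desk-scale estimators replace
the heavyweight ML/quartet tools: neighbor joining on Jukes-Cantor-
corrected distances of the concatenated subset (pairwise deletion of
uncalled sites; p ≥ 0.75 raises a saturation error), and greedy split
consensus of the locus trees (splits accepted in descending frequency
order when compatible with all accepted splits; the output is provably
pairwise compatible and is checked per run). Both recover the generating
topology on low-ILS simulations, and recovery is non-decreasing from 10 to
500 loci.

## Mk ancestral-state reconstruction

Discrete traits (diet, habitat, breeding mode, colour dimorphism) are
modelled with the equal-rates k-state Mk model: single symmetric rate α,
flat stationary/root distribution, transition probabilities in closed form
(`P_ii = 1/k + (k−1)/k·e^{−kαt}`). The likelihood is computed by
Felsenstein pruning with per-node rescaling; unknown tip states are
integrated over (partial likelihoods of ones) rather than pruned, so the
branch-partition output covers the whole tree. α is estimated by bounded
1-D maximization over log α in [1e−8, 1e3] — the log scale matters because
the likelihood plateaus over several decades at both ends and defeats a
linear-scale search. The trait must show at least two states at the tips;
otherwise the rate is unidentifiable and the fit refuses.

Marginal posteriors use the re-rooting method: each node's posterior is
what the pruning algorithm yields at the root after re-rooting the tree at
that node under the flat prior. Because the model is reversible this is
computed in one up/down message pass; the result is verified against
exhaustive enumeration over all internal-state assignments on 4-, 5- and
6-tip fixtures to 1e−10, and the posterior at the original root equals the
plain pruning root posterior exactly. Nodes are assigned a state only when
their maximum posterior strictly exceeds the confidence threshold
(default 0.85); a branch is a character change when both endpoints are
assigned different states, and per-state branch sets are emitted as
foreground/background partitions for downstream rate analyses. On
simulated 3-state traits over 64-tip trees, the ML rate lands within a
factor of two of truth in ≥90% of replicates.

## Numerical and degenerate-input choices

- Thresholds taken from the published filters are strict or inclusive
  exactly as written: gap filter removes columns with gap fraction
  strictly above 0.8; ambiguity screen flags strictly above 3% of called
  bases (N counts as missing, not ambiguous, by default); split filter
  keeps counts ≥ 50; conflict report keeps fractions ≥ 0.20; jackknife
  recovery counts frequencies strictly above 0.75; state assignment
  requires posterior strictly above 0.85.
- Bipartitions canonicalize on the side not containing the smallest taxon
  label, making equality orientation-free and hashing stable.
- The ambiguity-fraction denominator is the non-gap sequence length
  (fractions of called bases).
- Stop-codon screening skips codons containing gaps or ambiguity and
  exempts the final (terminal) codon.
- Zero-length alignments, zero-signal quadruples, saturated distances,
  monomorphic traits and empty quartet products all raise typed errors
  rather than returning silent defaults.

## Known limitations

- The tree-switch introgression model re-routes the entire recipient
  lineage; it cannot represent per-lineage migration, multiple interacting
  events per recipient, or post-event backflow.
- JC69 only; no rate heterogeneity, no indel process (missing data is
  injected, not evolved).
- The split-conflict analysis is a hypothesis generator, not a network
  inference; with heavily incomplete taxon sampling its default candidate
  collection can miss splits no complete tree displays.
- The normal approximation for the bootstrap Z is coarse in the extreme
  tails; the package follows the Z > 3 convention rather than reporting
  exact tail probabilities.
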