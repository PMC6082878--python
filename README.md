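# hybridscan

Introgression detection and tree-support analysis for multi-locus
phylogenomic datasets.

Rapid radiations — the Lake Tanganyika cichlid flock is the archetype —
leave two kinds of conflict among gene trees: incomplete lineage sorting
(ILS) and introgressive hybridization. `hybridscan` implements the
analytical layer that tells them apart on per-locus alignments and locus
trees:

- **Patterson's D (ABBA/BABA)** in single-haplotype and pooled
  allele-frequency (Durand et al.) form, with a 100-replicate bootstrap
  (block/locus resampling by default), Z-scores, and Benjamini-Hochberg
  FDR control;
- **hypothesis harness**: one D test per individual quadruple in
  P1 × P2 × P3 × outgroup, summarized as a distribution (mean/median D,
  fraction significant, sign consistency, violin plot);
- **per-locus introgression scans** with the <5-informative-sites filter;
- **split support and conflict reports** over locus trees (≥50-tree and
  ≥20%-of-trees thresholds) to generate hybridization hypotheses;
- **gene jackknifing** (sets of 10–500 loci, 100 replicates) with built-in
  NJ-on-concatenation and greedy-consensus estimators;
- **Mk-model ancestral-state reconstruction** (re-rooting method, ML rate,
  strict >0.85 posterior calls) producing foreground/background branch
  partitions for trait-linked analyses;
- a **multispecies-coalescent simulator** with tree-switch introgression
  (inheritance probability γ), JC69 sequences and missing data, so every
  stage is testable end to end without external data.

The central statistic: for a quartet on the asymmetric tree
(((P1,P2),P3),O), with the outgroup allele ancestral,

    D = (nABBA − nBABA) / (nABBA + nBABA)

is zero in expectation under ILS alone; significant D > 0 indicates
P2–P3 gene flow, significant D < 0 indicates P1–P3.

## Worked example

Simulate 200 loci (300 bp) on a quartet species tree with a
γ = 0.3 introgression pulse from P3 into P2, then run the permutation
harness over all 16 individual quadruples:

```python
import hybridscan as hs

model = hs.SpeciesTreeModel(
    "(((P1:1,P2:1):1,P3:2):1,O:3);",
    samples={"P1": 2, "P2": 2, "P3": 2, "O": 2},
)
event = hs.IntrogressionEvent(recipient="P2", donor="P3", gamma=0.3, time=0.5)
cfg = hs.SimConfig(n_loci=200, locus_length=300, theta=0.0025, seed=42)
data = hs.simulate_dataset(model, [event], cfg)

groups = hs.GroupAssignment({
    "P1": {"P1_1", "P1_2"}, "P2": {"P2_1", "P2_2"},
    "P3": {"P3_1", "P3_2"}, "O": {"O_1", "O_2"},
})
res = hs.PattersonDTest(data.alignments, groups).fit(n_boot=100, seed=7)
print(res.summary().to_string())
print(res.consensus_direction())
```

Output:

```
label                   hypothesis
n_quartets                      16
n_failed                         0
mean_d                    0.786177
median_d                  0.800133
q25_d                     0.725687
q75_d                     0.824654
fraction_significant           1.0
sign_consistency               1.0
P2-P3
```

All 16 quadruples give strongly positive D (e.g. the first row counts 83
ABBA against 8 BABA sites, D = 0.82, Z = 10.4, BH-adjusted p ≈ 5e-25), so
every row is significant with a consistent sign and the harness calls
P2–P3 gene flow — the direction the simulation actually contained. Under
γ = 0 the same pipeline centres D on zero and calls almost nothing
(see `docs/methods.md` for the calibration).

A command-line interface mirrors the library
(`hybridscan simulate|dstat|scan|locus-scan|splits|jackknife|asr`); each
subcommand is a thin wrapper over the functions above and writes TSV
tables.

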