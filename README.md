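# hybridexpr

Inheritance-mode analysis of reciprocal interspecific hybrid
transcriptomes, built around the catfish system: channel catfish
(*Ictalurus punctatus*, PC), blue catfish (*I. furcatus*, PB), and their
reciprocal F1 hybrids (F1BC: blue female × channel male; F1CB: channel
female × blue male). The package is for researchers asking how gene
expression is inherited in hybrids — additively, dominantly, or
*transgressively* (outside the range of both parents) — and whether
hybrid phenotypes show heterosis.

## What it computes

**Expression profiling.** Raw read counts are normalized to RPKM
(`count × 10⁹ / (length_bp × library_size)`), replicates are averaged
per genetic type, and the expressed universe is defined as genes with
type-mean RPKM > 1.0 in at least one genetic type.

**Differential expression.** For each pair of genetic types, counts are
modelled as negative binomial with variance `μ + φμ²`. A common φ is
fit by conditional maximum likelihood (qCML) on depth-equalized counts;
per gene, an exact two-sided p-value conditions on the pooled total and
sums the probabilities of all splits no more likely than the observed
one (at φ = 0 this is the exact conditional Poisson/binomial test).
DEGs satisfy |log2FC| > 1.5 and Benjamini–Hochberg adjusted p < 0.05.

**Transgressive classification** (the core). A gene is transgressive in
a hybrid when its type-mean expression is at least 20% beyond the
parental envelope: `f1 ≥ 1.2·max(PC, PB)` (up) or `f1 ≤ 0.8·min(PC, PB)`
(down). The calls in the two reciprocal hybrids combine into:
*concordant* (same direction in both), *discordant I* (transgressive in
exactly one), *discordant II* (opposite directions), or
non-transgressive.

**Phenotype statistics.** Mid-parent heterosis
`100·(F1̄ − MP)/MP` with `MP = (PC + PB)/2` and `F1̄` the reciprocal-F1
average; heterobeltiosis relative to the best parent; trait
standardization by total length; and exact Mann–Whitney U tests
(complete enumeration of all C(n₁+n₂, n₁) group assignments for the
study's n = 6 per type).

**Synthetic data.** A seeded generator plants inheritance modes (null,
additive, dominant, concordant up/down, discordant I/II) into NB counts
whose expected values invert exactly under RPKM normalization, plus
truncated-normal phenotype tables — so the whole pipeline is testable
without external data.

## Worked example

```sh
python examples/01_simulate_and_classify.py
```

```
expressed genes: 2535 of 2535
   non_transgressive: 2075
       concordant_up: 61
     concordant_down: 300
        discordant_I: 74
       discordant_II: 25
transgressive share of expressed genes: 18.1%
planted transgressive modes recovered correctly: 100.0%
```

2,535 genes were simulated with 435 planted transgressive genes
(60 concordant-up, 300 concordant-down, 50 discordant I, 25 discordant
II) at low biological noise (φ = 0.01, 3 replicates/type). The
classifier recovers every planted transgressive gene; the small excess
in `discordant_I` (74 vs 50) is sampling noise pushing borderline genes
across the 20% margin in a single hybrid — the characteristic failure
direction of the rule, since one noisy call suffices. Other examples
cover differential expression (`02`), heterosis with exact Mann–Whitney
tests (`03`), and the orchestrated end-to-end run (`04`). A thin CLI
mirrors the stages: `hybridexpr simulate | expression | de |
transgressive | pheno | all`.

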