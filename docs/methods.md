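# Methods

## The model

Four genetic types are compared: two parental species, PC and PB, and
their reciprocal F1 hybrids, F1BC and F1CB. The F1s share an identical
nuclear genome configuration and differ only in cross direction
(maternal genome, mitochondria, maternal environment), so expression
differences *between* the reciprocal hybrids isolate parent-of-origin
effects, while genes whose expression escapes the parental range in
*both* hybrids mark genuine regulatory incompatibility or transgressive
inheritance.

Read counts for gene *g* in sample *s* are modelled as negative
binomial with mean μ_gs and variance μ_gs + φ·μ_gs² (edgeR-style
dispersion φ; φ = 0 is exact Poisson). All inference downstream of
counting treats the count matrix as given; read processing and
alignment are out of scope.

## Normalization and the expressed universe

RPKM = count × 10⁹ / (length_bp × library_size). The library size
defaults to the per-sample column sum of the count matrix, because the
true "million mapped reads" denominator is not recoverable from a
count matrix; an explicit library-size table overrides this, and
synthetic runs use the generator's configured depths (there the truth
is known, and column sums would absorb a global expression shift into
the normalization — the classic composition effect).

A gene is *expressed* when its type-mean RPKM is strictly greater than
1.0 in at least one genetic type. The filter operates on type means
(not individual samples): with two replicates per type, a per-sample
filter would be dominated by the noisier replicate. The strict
inequality at the boundary is deliberate and tested.

## Differential expression

A single common dispersion is estimated per comparison by maximizing
the exact conditional likelihood of the replicate counts given each
gene's group total (qCML), summed over genes and both groups, on
counts rescaled to the geometric-mean library size and rounded.
Optimization is over log₁₀φ on [−8, 1.5], floored at 0 when the
likelihood is maximal at the Poisson boundary. Tagwise (per-gene)
shrinkage is intentionally absent: with two replicates per type,
per-gene dispersion estimates are unstable, and a common φ is the
honest choice at this design size.

The per-gene test conditions on the pooled total t = s_a + s_b. Each
split (k, t−k) has probability proportional to the product of the two
group-sum NB pmfs (group sum of n i.i.d. NB(μ, φ) is NB(nμ, φ/n));
the two-sided p-value is the total conditional probability of all
splits no more likely than the observed one, ties included
(conservative). At φ = 0 the conditional distribution is
Binomial(t, n_a/(n_a+n_b)) exactly; φ below 10⁻⁸ is routed through
that branch for numerical stability. Exact agreement with a
brute-force enumeration oracle is tested for totals ≤ 30 at
φ ∈ {0, 0.1, 0.5}, and null p-values at 5,000 simulated genes
(φ = 0.1) are uniform to KS distance < 0.05.

Fold changes are computed from type-mean RPKM with pseudocount 1.0
(configurable; the zero-handling convention is not dictated by the
count model). DEG thresholds |log2FC| > 1.5 and BH-adjusted p < 0.05
are strict inequalities. Bit-compatibility with edgeR is a non-goal:
the test is validated by enumeration oracles and null calibration
rather than against another implementation's rounding.

## Transgressive classification

With m the margin (default 0.2), the per-hybrid call is

- up: f1 ≥ (1+m)·max(PC, PB) and f1 > 0,
- down: min(PC, PB) > 0 and f1 ≤ (1−m)·min(PC, PB),
- none otherwise.

Boundaries are inclusive ("at least 20%"). The rule is formalized
against the parental *envelope* (max for up, min for down); a reading
that demands 20% beyond each parent separately is algebraically
identical, since exceeding both parents by 20% is exceeding the larger
one. For a gene silent in both parents, any positive hybrid expression
is an up call (the extra f1 > 0 guard prevents calling an all-zero
gene), and a down call is unreachable. The rule is applied to
point-estimate type means, as in the source analysis; no statistical
test is attached to the 20% margin.

The pair of per-hybrid calls maps to the class by a fixed truth table:
(up,up) → concordant_up, (down,down) → concordant_down, opposite
directions → discordant_II, exactly one `none` → discordant_I,
(none,none) → non-transgressive. Classification is restricted to the
expressed universe, and the reciprocal-hybrid overlap
(concordant + discordant II) / (all transgressive) follows from the
table. All report percentages are recomputed from integer counts at
render time, never stored rounded.

## Phenotype statistics

Heterosis% = 100·(F1̄ − MP)/MP with MP = (PC+PB)/2 and F1̄ the average
of the two reciprocal-hybrid means; heterobeltiosis% replaces MP with
the best parent. "Best" defaults to larger-is-better (growth traits)
and is configurable per trait — direction is an analytic choice, not
hard-coded biology. Shape traits and body weight can be standardized
by total length per individual before comparison.

The Mann–Whitney U test uses mid-ranks for ties and enumerates the
full permutation distribution of U over all C(n₁+n₂, n₁) group
assignments whenever that count is ≤ 200,000 — the design's 6 vs 6
needs 924 — with tied assignments contributing their whole probability
to the tail and two-sided p = min(1, 2·min(tails)). Beyond the cap the
tie-corrected normal approximation is used and labelled in the result.
ANOVA with Tukey post hoc is deliberately omitted; the pairwise
comparisons of interest are Mann–Whitney.

## Synthetic data

The generator plants one inheritance mode per gene, fixing expected
RPKM-scale expression per type: null (all at baseline b); additive
(parents at b and b·e, hybrids at the mid-parent); dominant_PC /
dominant_PB (hybrids at the named parent); concordant_up / down
(parents at b, both hybrids at b·e or b/e); discordant_I (up in F1BC
only — the hybrid choice is arbitrary but fixed and recorded in the
truth table); discordant_II (up in F1BC, down in F1CB). Expected
counts are expression × (length/1000) × (library_size/10⁶), so RPKM
computed with the configured library sizes inverts the construction in
expectation — the generator is self-verifying, and tests confirm the
inversion to ~2% at 3 replicates.

Defaults model the study design: 2 replicates per type, 5 million
reads per sample (depth is a free choice; 5M is a typical bulk liver
RNA-seq depth), baseline 50 on the RPKM scale, gene lengths uniform on
500–3000 bp, φ = 0.1, effect size 2. The default mode mix reproduces
the study-scale composition: 13,420 genes of which 60 concordant-up,
925 concordant-down, 106 discordant I and 49 discordant II. Phenotype
tables draw from normals truncated at zero (morphometric and plasma
traits are non-negative), six individuals per type; sd = 0 returns the
group means exactly, which is how the printed-mean arithmetic checks
are driven.

What the generator does *not* emulate: maternal/allele-specific
effects, GC- or length-dependent counting bias, library-composition
artifacts, batch structure, or correlated genes. Passing tests
therefore demonstrate the correctness of the algorithms under the
stated count model, not robustness to real-data artifacts.

## Numerical and design choices

- Exact-test tie tolerance: splits within a 10⁻¹⁰ relative log-pmf
  band of the observed probability count as ties and enter the
  rejection mass.
- Gene sets in counts vs lengths files are reconciled by strict
  intersection with a logged warning naming the dropped ids.
- Results tables are written with 17 significant digits so that write →
  read round-trips are exact for doubles; manifests carry SHA-256
  checksums, and identical configs produce identical checksums.
- Problem sizes in the test-suite simulations (e.g. 5,000-gene null
  calibration, 20 × 400-gene FDR sanity runs, 3-replicate recovery
  runs) were chosen as the smallest sizes at which the targeted
  moments and rates are stable; they are package choices, documented
  here once.

## Known limitations

- With two replicates per type and the 20% point-estimate rule,
  false transgressive calls (mostly discordant I) are common at
  moderate dispersion — at φ = 0.05 a null gene has a nontrivial
  chance of a single-hybrid call. The recovery guarantees quoted in
  the tests hold in the low-noise regime (φ ≤ 0.01–0.05, 3
  replicates); on 2-replicate data the discordant I class should be
  read as an upper bound, not a clean parent-of-origin signal.
- The common-dispersion assumption ignores mean–dispersion trends.
- The exact test enumerates all splits of the pooled total; it is
  intended for desk-scale totals (≲ 10⁵ per gene), which covers
  realistic per-gene depths.
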