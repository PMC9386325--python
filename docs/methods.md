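# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test-suite, the numerical conventions, and the design choices
made where the analysis left room for interpretation.

## Statistical kernel

All stages share one kernel (`stattests`), a thin, validated surface over
scipy and statsmodels:

- **Fisher's exact test** uses the point-probability two-sided
  convention: the p-value sums hypergeometric probabilities of all tables
  with the observed margins whose probability is at most that of the
  observed table (relative tie tolerance 1e-7). The test-suite checks it
  against an independent exhaustive enumeration for every 2×2 table with
  total count ≤ 40.
- **Mann–Whitney U** is exact (full permutation distribution) when the
  pooled sample has ≤ 12 untied observations, otherwise a normal
  approximation with tie and continuity corrections. `tail="greater"`
  means the first sample tends larger.
- **Wilcoxon signed-rank** drops zero differences, ranks |d| with
  midranks, and for n ≤ 15 enumerates all 2ⁿ sign patterns exactly —
  tied magnitudes are handled by the enumeration, which is why this
  branch is written in-package rather than delegated. Larger n use the
  continuity-corrected normal approximation.
- **BH adjustment** is the step-up definition with input order restored;
  it is checked against both a literal-definition oracle and an
  independent library implementation.
- **Logistic regression** is maximum likelihood (Newton/IRLS) with Wald
  95% CIs on the odds-ratio scale. Complete separation and
  non-convergence are reported through a `converged` flag rather than an
  exception, because specimen-level contingency patterns in small cohorts
  frequently separate.

## Expression panel processing

Samples with fewer than 170 000 aligned reads are discarded; the rest are
down-sampled to exactly 170 000 reads by drawing without replacement from
the probe-labelled read pool (multivariate hypergeometric), which
conserves column totals exactly and preserves the hypergeometric
marginals. log₂CPM uses `log2((count + c)/(total + 2c) · 1e6)` with
pseudocount c = 0.5 by default; gene-level values sum probe counts first.

Batch adjustment for preservation type (FFPE vs frozen) is location-only:
per gene, each batch mean is moved to the grand mean. A constant added to
one batch is absorbed up to a per-gene constant (the preserved grand mean
necessarily moves with the shift); variance differences between batches
are deliberately not rescaled. FFPE samples extreme (strictly outside the
10%/90% quantiles of the whole series) for more than 125 genes are
excluded; using strict quantile comparisons means tied values never count
as extreme, so a constant gene excludes nobody.

Outlier fences are computed on the disease-free reference cohort with
quantiles by linear interpolation between order statistics. Two fence
types are supported — Tukey (Q1 − 1.5·IQR, Q3 + 1.5·IQR) and median ± IQR
— because the outlier print uses the tighter median + IQR rule for the
five telomerase-complex genes and Tukey fences for TINF2 (high) and POT1
(low). Fence comparisons are strict; a value exactly on a fence is not an
outlier.

A gene is a differential-expression candidate through either route:
two-tailed Mann–Whitney p < .05 with BH q < .15, or at least a twofold
higher Tukey-outlier frequency in the aggressive cohort. When the
reference frequency is zero the ratio is undefined; the rule then
requires at least two aggressive outliers, which honours "twofold higher"
without dividing by zero.

TERT expression is called negative when **every** one of the four TERT
probes has fewer than 3 reads after down-sampling. The summed reading
(total TERT reads < 3) is available as `rule="sum"`; per-probe is the
default because the panel's four probes target different transcript
regions and a single well-covered probe is positive evidence.

## TERT-promoter methylation and mutation

Per-site methylation is `100·C/(C+T)`. Region means are unweighted over
covered sites (depth > 0); zero-depth sites are dropped with a warning
and the coverage fraction is reported. A specimen is methylated when the
UTSS mean **or** the full 39-CpG mean reaches 16.1% (inclusive). Pattern
discovery is agglomerative hierarchical clustering (average linkage,
Euclidean distance on per-CpG percentages) cut at k = 3, with clusters
named high/moderate/low by descending mean methylation; specimens are
sorted by id before linkage so labels are order-invariant, and incomplete
profiles are labelled `unassigned`.

Hotspot calls at c.-124 (C228T) and c.-146 (C250T) are threshold-based:
mutant when depth ≥ 100 and the T-allele fraction ≥ 5%. Both thresholds
are package choices (exposed as flags) — amplicon sequencing at these
depths makes a 5% variant fraction comfortably distinguishable from
bisulfite/PCR noise, and 100× is a conservative floor for a clonal
hotspot. Copy-number gain flags are consumed as input data only.

## Q-FISH telomere classification

Telomere length per specimen is the median of per-nucleus mean
intensities (a.u.f.). The reference range is mean ± 2 SD over the
**pooled per-nucleus means** of the normal thyroids; pooling (rather than
specimen medians) uses two orders of magnitude more observations and is
switchable via `level="specimen"`. Short means median ≤ lower bound
(inclusive); the % of shortest telomeres counts per-signal intensities
strictly below 20 a.u.f. The ALT-suspect flag fires when more than 1% of
signals exceed 5× the specimen median — a quantitative proxy for the
ultra-bright ALT-associated foci that are otherwise identified visually;
both parameters are exposed.

## Subtelomeric enrichment

Chromosome arms are tiled with 5-Mb windows anchored at the telomere:
p-arms from position 0 inward to the centromere start, q-arms from the
chromosome end inward to the centromere end, so index 0 is always
telomere-adjacent and the centromere-proximal window may be partial.
Acrocentric p-arms are skipped. Genes are assigned to the window
containing their midpoint (0-based half-open; TSS assignment available),
and windows with fewer than 15 expressed genes are excluded from testing
but reported.

The per-gene statistic is a two-group moderated t: pooled variance s²_g
with df = n₁+n₂−2 is shrunk to s̃²_g = (d₀s₀² + df·s²_g)/(d₀+df), where
(d₀, s₀²) are fitted by method of moments on log s²_g — the empirical
variance of log s²_g in excess of the trigamma(df/2) sampling component
determines d₀ through a trigamma inverse (Newton iteration), and the mean
determines s₀². When the excess is non-positive, d₀ = ∞ and all genes
share s₀². The moderated t has d₀+df degrees of freedom; `d0_override=0`
reproduces the ordinary t exactly. The test-suite verifies the whole fit
against R limma's `eBayes` (agreement to ~1e-6) and recovers planted
(d₀ = 4, s₀² = 0.05) within 15% from 5000 genes.

Window enrichment is classic preranked running-sum GSEA with weight
exponent 1: genes ranked by t descending, hit steps ∝ |t|, miss steps
uniform, ES = running-sum extremum. The null permutes gene labels
preserving set size (sample permutation is impossible on a preranked
statistic); NES divides ES by the mean |null ES| of matching sign;
nominal p is the same-sign null tail; FDR follows the standard pooled-NES
procedure (a BH-on-nominal-p alternative is available for sensitivity
analysis). A window spanning the whole universe has no miss pool and is
returned as undefined with a warning.

The compartment comparison reports the median moderated t over
subtelomeric (index-0) vs interior genes, a paired Wilcoxon across arms —
each arm contributes its subtelomeric median minus its interior median,
which is the most defensible pairing unit for a matched-pairs test
between two unequal gene sets (an unpaired Mann–Whitney alternative is
also reported) — and a Fisher test on counts of FDR < 0.1 windows by
compartment.

## Co-FISH proximity

A red/green probe pair is adjacent when its distance is at most 0.7 μm
(inclusive — "maximum distance" is read as inclusive) and separated
otherwise. Distance mode is canonical; pre-scored adjacent/separated
labels are accepted for visually scored data since no quantitative visual
criterion exists. Summaries below 200 nuclei are flagged insufficient,
not dropped.

## Synthetic-data model

Every generator draws from its own RNG stream spawned from the master
seed (`SeedSequence(seed, spawn_key=(k,))`), so generators are mutually
independent and byte-reproducible. Defaults encode the study conditions:

- **Expression**: 58 disease-free + 48 aggressive samples, 187 genes on
  227 probes (four for TERT), 250 000 reads/sample, Dirichlet(0.5) probe
  weights, multinomial counts. Planted outliers multiply a gene's probe
  weights by 2^effect in a penetrance fraction of aggressive samples:
  the five holoenzyme genes (effect 1.5–2.5, penetrance 0.5; TERT is
  switched from a near-silent baseline of < 3 expected reads to strong
  expression) and the two shelterin genes TINF2 (+3, 25%) and POT1
  (−3, 25%). Because counts are compositional, strong planted outliers
  slightly depress every other gene in carrier samples — exactly as in
  real CPM-normalized panel data — so a handful of passenger genes can
  reach nominal significance at the default effect sizes; under a zero-
  effect configuration the cohorts are exchangeable and type-I error is
  calibrated (verified by test).
- **Bisulfite**: methylated counts ~ Binomial(coverage = 1000, class
  rate) at 39 CpG sites; default pattern classes high/moderate/low at
  60/25/5% with 15/39/34 specimens.
- **Q-FISH**: per-nucleus means log-normal with class-level arithmetic
  mean/SD — normal (28.5, 2.75), short (15, 3) — with a 0.5 a.u.f.
  specimen-level spread nested **inside** the class SD so the pooled
  normal spread stays at 2.75 and the derived range lands at ≈ (23, 34)
  a.u.f.; 100 nuclei/specimen, 30 signals/nucleus scattered (SD 8) around
  the nucleus mean; ALT specimens replace 2% of signals with 10× the
  median.
- **Toy genome**: four 60-Mb chromosomes with a 28–32-Mb centromere, 40
  genes per 5-Mb window placed uniformly, gene noise SD 1.0 log₂; genes
  within 5 Mb of an arm end gain δ = 0.5 log₂ in the 10 short-telomere
  samples vs 5 normal. 48 windows (8 subtelomeric) give the enrichment
  stage a realistic multiple-testing burden while a full 1000-permutation
  run completes in ~1 s.
- **Pairs**: per-nucleus distance ~ max(0, Normal(0.45 + 0.008·%shortest,
  0.30)) μm, 220 nuclei/tumour across the 18 Q-FISH tumours — short-class
  tumours (≈ 70% shortest) sit near 1.0 μm mean distance and normal-class
  (≈ 15%) near 0.57 μm, spanning the 0.7 μm cutoff.

What the generators do **not** emulate: sequencing error and mapping
artifacts, per-CpG rate heterogeneity within a pattern class, intensity
calibration drift between Q-FISH batches, nucleus segmentation error, and
spatial correlation between probe pairs within a nucleus. Passing tests
therefore demonstrate correctness of the computational procedures and
their calibration under the assumed stochastic models, not robustness to
those instrumental artifacts.

## Numerical conventions and degenerate inputs

0-based half-open genomic coordinates throughout; BED native. Quantiles
by linear interpolation. Sample SD (ddof = 1) everywhere. Strict
inequalities at outlier fences and at the 20-a.u.f. shortest-telomere
cutoff; inclusive at the 16.1% methylation cutoff, the 23-a.u.f. short
rule and the 0.7-μm adjacency rule (all following the stated rules'
wording). Degenerate cases: an all-zero contingency table, an empty
specimen profile and an all-zero-depth promoter profile raise; a
zero-width reference range, a single-member batch and a degenerate
clustering warn and proceed; sub-analyses inside association bundles fail
independently and are reported as missing.

## Problem sizes

The default synthetic study is full cohort scale for every stage
(106 expression samples, 88 bisulfite specimens, 27 Q-FISH specimens,
~1800 toy-genome genes, 18 × 220 probe pairs); the enrichment stage uses
1000 permutations in the acceptance run and 300–500 in the unit tests,
chosen so the complete suite and the acceptance script each finish in a
couple of minutes on one CPU.

## Known limitations

- The pooled-NES FDR, like the standard procedure it follows, can be
  noisy when very few windows are tested; the BH alternative is provided.
- The batch adjustment is location-only and cannot correct FFPE-induced
  variance inflation; heavily degraded samples are instead caught by the
  extreme-value exclusion.
- The hotspot caller assumes clonal-fraction mutations at two fixed
  positions; it is not a general variant caller.
- Methylation pattern labels come from a k = 3 tree cut; when the data
  hold fewer than three genuine patterns the split within a homogeneous
  block is arbitrary (a warning reports the effective cluster count).
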