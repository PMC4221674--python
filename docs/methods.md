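# Methods

## Design and model

Every stage is keyed on one factorial layout: four physiological conditions
(young virgin, young mated, aged virgin, aged mated females) with replicate
sample pools per condition (two in the emulated study design). Differential
abundance of a feature — a miRNA count, a transcript count, or the
background-corrected signal of a merged ChIP peak — is modeled as

    Y = μ + C + ε

with a four-level condition factor C. The omnibus test is a permutation
one-way ANOVA on the classical F statistic; the four pairwise contrasts are
evaluated post hoc with a fixed sign convention (mated − virgin within an
age class, aged − young within a mating status) and a minimum-effect gate of
one pooled standard deviation, i.e. √MSE of the within-condition residual.

### Permutation p-values

p = #{label assignments with F ≥ F_obs, identity included} / #{assignments
evaluated}. When the number of distinct assignments (the multinomial
coefficient N!/Πn_g!) is at most a configurable cap (default 10,000) the
space is enumerated exhaustively — 2520 assignments for the 4 × 2 design —
otherwise seeded Monte Carlo with the identity counted in numerator and
denominator, so p > 0 always. F ties are counted inclusively (conservative)
with a 10⁻⁹ relative tolerance; an infinite F_obs (zero residual variance
with a real group effect) keeps its threshold at +∞ so exact ties still
count. Sums of squares are computed on per-feature-centered data and the
residual SS is floored at zero below a 10⁻¹² relative tolerance, because the
SST − SSB identity loses catastrophically many digits exactly in the
zero-noise regime the synthetic tests exercise.

### Attainable p-values: a structural floor

Two facts bound the permutation p from below independent of effect size:

1. F is invariant under permuting the group *labels*, so the identity ties
   with its 4! relabelings: p ≥ 24/2520 = 1/105 for the 4 × 2 design.
2. More severely, a feature shifted by the *same* amount in j conditions is
   reconstructed by every assignment that regroups the shifted samples into
   j full groups, and those assignments tie or beat F_obs about half the
   time because the shifted (and unshifted) values are exchangeable among
   themselves. For a single-condition shift at 2 replicates the floor is
   ≈ (4/C(8,2))/2 = 1/14; for an on/off (two-condition) pattern
   ≈ 108/2520 ≈ 0.043.

Combined with Benjamini–Yekutieli — q ≥ p·c(m) for any test count m, with
c(m) ≥ 1 growing like ln m — this makes q < 0.05 *mathematically
unattainable* at two replicates for planted panels of realistic size,
whatever the effect size. This is a known limitation of the analysis recipe
at minimal replication, and it dictates the problem sizes below. Designs
with more replicates shrink the reassembly probability combinatorially:
(4/C(20,5))/2 ≈ 1.3×10⁻⁴ at five replicates for a single-condition shift.

### FDR and post hoc calls

Benjamini–Yekutieli step-up q-values (statsmodels' `fdr_by`) adjust the
omnibus p-vector across all features of one table. A contrast is called
significant when q < α (default 0.05) and |Δ of condition means| > pooled
SD. Both the gate and the q-threshold are exposed.

### Quantile normalization

Each column's rank-r value is replaced by the across-column mean of rank-r
sorted values; ties receive the mean of the reference values at their tied
ranks (a constant column maps to the grand mean of the reference). The
transform assumes columns share a common underlying distribution. Two
consequences matter for interpretation: (i) shifts that preserve every
feature's rank in every sample are *invisible* after normalization — in the
zero-noise synthetic regime all planted peaks move together and keep their
ranks, so the exact-recovery demonstrations run the corrected-FPKM route
without the final quantile step; (ii) when a large fraction of features
truly changes, ranks of null features shift and normalization redistributes
part of the signal. With noisy data and changes spread through the
distribution (the realistic regime) the transform behaves as intended.

## ChIP signal

Per-sample peak calls are pre-merged within a sample (overlapping calls
count once), pooled, and single-linkage clustered: sorted by start, an
interval joins the growing cluster when it intersects the cluster union by
at least `min_overlap_bp` (default 1 bp — the least-assumption reading of
"present in more than one sample"). A merged peak (the union interval) is
kept when supported by ≥ 2 distinct samples and wider than 146 bp, the DNA
span wrapped by a single nucleosome. FPKM uses the merged width and each
sample's total mapped reads; background is the per-sample median FPKM over
1 kb bins tiling non-peak space (fixed bins make the median well defined),
subtracted and floored at zero since negative enrichment is not meaningful.
Candidate genes are assigned within ±2 kb of the gene span, strand-ignored;
a peak may receive many genes and vice versa.

## Small-RNA degradation calls

Read-length classes: degradation fragments 15–18 nt, miRNAs centered at
22 nt, rasiRNAs at 30 nt (window half-widths configurable; windows must not
overlap). A gene is called a degradation source when ≥ `min_reads`
(default 1 — no threshold is imposed beyond presence) fragments in the
degradation window overlap its span in **every** young-mated replicate and
**zero** such fragments overlap it in any other sample. The
present-in-all-replicates reading is the strictest one; a
one-replicate-suffices mode is available behind a flag. Overlap is ≥ 1 bp,
strand-ignored.

## Persistence and accelerated-aging markers

A post-mating mark (significant in the young virgin-vs-mated contrast) is
*persistent* when the mated young-vs-aged contrast shows no significant
reversal — not significant, or significant with the same sign. "Persisted"
admits a second reading (significance of the aged virgin-vs-mated contrast
in the same direction); both are implemented, non-reversal being the
default since it is the only definition expressible from the four available
contrasts without further assumptions. An *accelerated-aging marker* is a
persistent mark whose virgin young-vs-aged contrast is significant with the
same direction as its post-mating change; direction matching is required.
The summary reports the marker/persistent fraction and the unique genes
attached through the peak→gene map.

## Networks

Target layer: predicted targets of plastic miRNAs that are themselves
differentially expressed in the chosen contrast. Partner layer: interaction
neighbors of the target layer with ≥ 2 *distinct* target-layer neighbors
("more than one miRNA target" read as two distinct genes, not two edges);
interactions are treated as undirected, self-loops dropped, and a gene
already in the target layer is never demoted to a partner. Histone
annotation marks a gene (or miRNA locus) when any differential peak of that
mark is assigned to it; multiple marks accumulate. TSV and GraphML exports
round-trip losslessly; SIF carries typed edges for graph viewers.

## Validation statistics

The overexpression effect rule marks a target gene "+" when its
virgin-vs-mated expression difference is significant (pooled-variance
two-sided Student's t, α = 0.05) in exactly one of the control and
overexpression crosses — the rule is symmetric in the two p-values. On the
bundled 20-row table the marks imply 14/20 = 70% affected; the accompanying
prose count of "13" disagrees with its own "70%", so the implementation
reports both the mark count and the fraction rather than resolving the
discrepancy. Reference-gene normalization (expression divided by the
sample's Gapdh value, rescaled by the cross-sample mean) is a pluggable
default since no formula is canonical. Egg-laying counts are compared
many-to-one against the control line with Dunnett's test (scipy's
multivariate-t implementation, seeded); the k = 1 case reduces to the plain
two-sample t-test within integration error.

## Synthetic data

The generator emulates the study conditions, not any particular dataset:

* **Counts** — negative binomial with Var = μ + φμ², φ = 0.05 (typical
  sequencing overdispersion), per-feature baselines lognormal around 100
  with σ_log = 1. Planted features receive a log2 fold change (default 2)
  in a random nonempty proper condition subset; an optional on/off feature
  mimics a maternal-cluster miRNA expressed only in mated flies. φ = 0
  yields noise-free rounded means for exact-recovery tests.
* **Peaks** — master intervals placed in the 2 kb flank downstream of
  distinct genes (so gene assignment is exercised and masters never
  overlap), jittered ±20 bp per sample. Planted amplitude patterns:
  *marker* (1, f, 1.05f, 1.1f across YV/YM/AV/AM), *persistent-only*
  (1, f, 1, 1.05f), *reverting* (1, f, 0.9, 1.1), with f = 4; the slight
  distinctness keeps zero-noise permutation ties at the 4!-relabeling
  minimum while preserving each pattern's sign structure. Narrow (60–100 bp)
  and single-sample masters exercise the width and support filters.
  Library size is a config constant (10⁶) — sequencing depth is a property
  of the library, not the biology, and letting it track simulated read
  totals would cancel planted folds out of FPKM compositionally.
* **Small RNAs** — discrete length mixture with modes at 22 and 30 nt
  (supports 19–26 / 27–33), plus a 15–18 nt component placed strictly
  inside designated source genes in young-mated samples only.
* **Interactions** — partners planted with exactly one vs ≥ 2 links into
  the plastic-target layer, plus decoy edges among unrelated genes.
* **Oviposition** — normal egg counts (control mean 250 per 5-female vial
  over 18 h, SD 25, 10 replicates) with planted percent effects of
  +16 / −34 / −37 / +33 for the four overexpression lines.

All draws descend from one master seed through named substreams, so any
(seed, config) pair is byte-identical; derived stage seeds stay below 2³¹.

What the generator does **not** emulate: read-level sequences, alignment
artifacts, GC or mappability bias, fragment-size distributions, correlated
features, or tissue compartmentalization. Passing the planted-truth suites
therefore demonstrates correctness of the computations, not performance on
real libraries.

## Problem sizes used in the test and acceptance suites

* Exhaustive-oracle agreement: 20 random vectors on the 4 × 2 design,
  compared exactly against brute-force enumeration of all 2520 assignments.
* Null calibration: 2000 exchangeable null features, 4 × 2 design. The
  attainable p-values are multiples of 1/105, so the expected rejection
  rate at p < 0.05 is exactly 5/105 ≈ 0.048.
* Planted-truth recovery: 200 features, 5% planted at 4-fold (≥ 3 pooled
  SDs as realized), on a 4 × 5 design with 20,000 Monte Carlo permutations —
  the smallest design on which the structural p-floor (see above) leaves
  the BY threshold reachable for a 5% panel.
* Zero-noise marker recovery: 4 × 3 design, dispersion 0, no background
  reads, quantile step off, 5000 Monte Carlo permutations.

## Known limitations

* The structural permutation-p floor means the minimal 2-replicate design
  cannot produce BY-significant calls under this exact recipe; richer
  replication or a different omnibus statistic is required for discovery.
* Quantile normalization redistributes signal when many features change or
  when changes are rank-preserving (see above).
* Peak→gene assignment by proximity cannot establish regulatory causality
  and ignores long-range contacts.
* The effect rule for overexpression compares significance statuses, not
  effect sizes; near-threshold p-value pairs flip the mark discontinuously.
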