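# Methods

This note documents the models, procedures, numerical choices and known
limitations behind `coremicro`, in the order a meta-analysis runs them.

## Input handling and inclusion filters

Count tables are OTU × sample matrices of non-negative integers with unique
identifier lists. Two on-disk dialects are supported: tab-separated text
(OTUs as rows, first column `otu_id`, header row of sample ids) and
BIOM-JSON v1.0 (via `biom-format`). The TSV orientation is fixed and never
auto-detected: silent transposition of a merged table is a worse failure
mode than a loud error on a transposed file.

Inclusion filters reflect standard practice for merged 16S collections:
samples need ≥ 2000 reads (boundary inclusive — a 2000-read sample is
retained; `floor` is exposed for the stricter reading), and features need a
total count ≥ 11 with detection in ≥ 2 samples ("frequency ≤ 10 or
single-sample" exclusion, with frequency read as total count across samples,
the QIIME2 feature-frequency semantics). Both filters are idempotent and
never increase any count.

Metadata harmonisation maps heterogeneous per-study fields onto fixed
categories. Ages bin into 18–30 / 31–55 / 56+ (under-18 → unknown); any
e-cigarette or tobacco use → smoker; any alcohol use → drinker; locations
outside North America/Europe/China, regions outside V3-V4/V4 and
swab-collected samples pool as "others"; missing values become "unknown".
Samples with unknown (or, for host categories, "others") levels are dropped
from analyses *of that category only*, never globally.

Tree pruning keeps an exact leaf set and collapses the unary chains this
creates by summing branch lengths. When everything above the kept taxa's
common ancestor collapses, the stem is kept as an explicit unary root edge
rather than being redistributed: redistribution would preserve root-to-leaf
path lengths but split a single shared branch into several, inflating the
raw weighted-UniFrac numerator (triangle inequality). With the stem kept,
weighted UniFrac is exactly invariant to pruning taxa absent from the table.

## Normalisations

* **RAR** — subsampling without replacement (multivariate hypergeometric) to
  a fixed depth, default 5000; shallower samples are dropped, not padded.
  The with/without-replacement choice follows the QIIME2/vegan convention.
* **TSS** — per-sample relative abundance.
* **RRA** — TSS of the rarefied table.
* **CLR** — count-zero-multiplicative replacement then centred log-ratio.
  Per sample with total `N` and `Z` zeros, each zero becomes `δ/N` of the
  composition with δ = 0.65 (the zCompositions default), non-zero parts are
  multiplied by `1 − Zδ/N` to keep the composition closed, then each part is
  logged against the column's geometric mean. CLR is applied to the raw
  filtered counts (whether one rarefies before CLR is genuinely ambiguous in
  common practice; raw counts are the default here, and the caller can pass
  a rarefied table instead).

## Diversity and PERMANOVA

Alpha diversity: bias-corrected Chao1 `S + F1(F1−1)/(2(F2+1))` (defined when
no doubletons exist; the classic form is available by flag), Shannon in
natural log, and Gini–Simpson `1 − Σp²` (the common reading of "Simpson's
index"; inverse Simpson is deliberately not silently substituted). Chao1
refuses non-integer tables.

Weighted UniFrac is computed from a per-branch embedding: one post-order
traversal assigns each branch its subtree proportion per sample; the raw
distance is the branch-length-weighted L1 difference, the normalised form
divides by the weighted sum and is bounded in [0, 1]. Normalised is the
default, matching use alongside Bray–Curtis. The implementation is
cross-checked against scikit-bio to machine precision, and against the
closed form on a star tree (raw = L1 distance between proportion vectors at
unit branches).

PCoA eigendecomposes the Gower matrix `−½ J D² J`. Negative eigenvalues are
reported but excluded from the proportion-explained denominator by default
(no Cailliez correction); coordinates exist only for positive axes.

PERMANOVA partitions `tr(G)` sequentially (Type-I) over ordered terms via
projection matrices, which reproduces `vegan::adonis2(..., by="terms")`.
"Adjusting for the study" therefore means listing `study` first; an
alternative is restricted permutation within study blocks (`strata=`), and
both are provided because published descriptions rarely distinguish them.
p-values use `(1 + #{F* ≥ F}) / (1 + n_perm)` with free or within-strata
permutation, or exact enumeration of all n! relabellings for n ≤ 8. A
perfect fit (residual SS ≈ 0 relative to total) reports pseudo-F = ∞, and
permutation comparisons use a relative tolerance so exact ties count as
exceedances. Type-I error is calibrated: over 1000 null replicates at
α = 0.05 the rejection rate falls in [0.03, 0.07].

## Core definitions

Abundance-occupancy statistics are computed on the table rarefied to 5000
reads (detection = nonzero rarefied count; MRA on the TSS of the rarefied
table), since rarefaction is the stated precondition of the ranked
procedure and keeps occupancy comparable across depths.

1. **Threshold core** — member iff MRA > 0.1% AND (occupancy > 75% of all
   samples OR 100% occupancy in > 10 studies). All three comparisons are
   strict, following the quoted wording ("greater than", "more than").
2. **Ranked core** — OTUs ranked by mean per-study occupancy (ties: MRA
   descending, then lexicographic id). The alternative ranking key in the
   original abundance-occupancy procedure (sum of within-study occupancy
   ranks) gives the same ordering up to ties here and was not duplicated.
   For each prefix of the ranking, `explained(r)` is the mean over sample
   pairs of the prefix-restricted dissimilarity *numerator* over the
   full-table numerator — for Bray–Curtis `Σ_prefix |x_i−y_i| / Σ_all
   |x_i−y_i|` on the rarefied counts, for weighted UniFrac the same ratio of
   branch-weighted L1 sums. Holding the denominator at its full-table value
   makes the curve monotone non-decreasing with `explained(R) = 1` exactly;
   the fully re-normalised per-prefix metric does not have this property
   (adding a taxon equally abundant in two samples *lowers* their restricted
   Bray–Curtis), which is why the numerator-share form — also the form used
   by the published abundance-occupancy code, which fixes the Bray–Curtis
   denominator at twice the rarefaction depth — is the implemented
   semantics. The core stops at the largest rank whose marginal gain is
   ≥ 2% of the curve's total gain (threshold configurable); if no rank
   qualifies the single largest gain is kept, with a warning when the curve
   is entirely flat.
3. **Consensus** — exact set intersection, order-independent and idempotent.

Sub-group profiles report each core OTU's MRA within every level of the
requested categories plus the per-level cumulative core relative abundance
(mean ± SD of the per-sample core fraction). Profile clustering is
agglomerative Ward on log10(MRA + 1e−6), cut at k = 4 by default.

## Co-occurrence network

Spearman ρ with midrank ties on relative abundances; two-sided p from the
t-approximation on n−2 degrees of freedom (hence the ≥ 5-sample
precondition). Edges require |ρ| > 0.5 AND p < 0.01 on the raw p-values, as
is conventional for this screen; a Benjamini–Hochberg mode is available.
Hubs are nodes in the joint upper 0.95 quantile of degree and exact
betweenness (raw shortest-path pair counts) that actually lie on shortest
paths — a clique, where every node ties at the degree cutoff with zero
betweenness, has no hubs. Spearman-on-compositions can produce spurious
associations; the method is reproduced as practised, and the caveat stands.

## Random-forest association and differential abundance

One ensemble per (category × taxonomic level × normalisation) crossing: 500
trees, √p features per split, out-of-bag error as the score, samples with
unknown levels excluded per category. Tree construction is
implementation-defined, so all forest-level guarantees are statistical
rather than bit-exact across library versions (bit-exact under a fixed seed
within one environment).

Important-feature selection ranks features by permutation importance of the
fitted forest (accuracy drop over 5 shuffles) — the mean-decrease-accuracy
analogue available through scikit-learn's public API. The cross-validation
curve evaluates geometrically halved feature counts with features re-ranked
inside each training fold; "the point where the error curve stabilises" is
formalised as the smallest feature count whose mean CV error is within one
pooled standard deviation of the minimum (the 1-SD rule; factor
configurable).

Differential abundance: two-sided Wilcoxon rank-sum with midranks, exact
when both groups have ≤ 25 samples and no ties, normal approximation
otherwise; BH correction across taxa; fold change
`log2((med_A + ε)/(med_B + ε))` with ε the smallest nonzero relative
abundance in the table. Taxa all-zero in both groups are excluded.

## Independent-cohort validation

ZOTU→OTU affiliation is pinned down as global pairwise alignment (match +1,
mismatch −1, gap open −2, extend −1) with identity = matches / alignment
columns, gaps counting as columns; assignment to the best reference at
identity ≥ 0.97, ties to the lexicographically smallest id. At the 97%
threshold, variants 1% diverged from a reference re-affiliate essentially
always and variants 6% diverged essentially never.

Core prevalence is the per-sample sum of TSS values over core-affiliated
rows (invariant to raw-count vs relative input). Classifier transfer
reconciles the test cohort to the training feature space by dropping unseen
taxa and zero-filling missing ones — stated explicitly because it
materially affects cross-cohort accuracy — and reports per-sample votes,
majority labels, accuracy and ROC AUC (None when undefined).

## Synthetic data generator

The generator emulates the statistical shape of a pooled multi-study
collection, not its biology. Taxa fall into three abundance-occupancy
archetypes: a planted core (default 68 of 900 taxa; host prevalence
U(0.90, 1.00); log-normal abundances, σ = 0.30), a small sub-core of
"occasional dominants" (8 taxa, ~2% MRA each, prevalence U(0.65, 0.74)) and
a rare tail (prevalence U(0.20, 0.70), log-normal σ = 1.0) of which 60% are
undetectable under one randomly chosen hypervariable-region label (the
technical dropout that makes region a visible batch axis). Per-study
multiplicative log-normal biases (σ = 0.7 for the tail, damped to 0.25 for
the core — batch effects hit rare taxa much harder than dominant ones, and
core detection must stay near-certain in every study) sit on top, then
per-sample category effects (each affected taxon ×2^effect in one level),
then Dirichlet-multinomial sampling (concentration 350) at log-normal depths
(median ≈ 15k reads, so almost every sample clears the 5000 rarefaction).
The core block's scale is calibrated by bisection against the realised
per-sample expectation so the cumulative core share hits its 0.72 target
under everything the other mechanisms do to it.

Under these defaults the study factor explains ~35–45% of Bray–Curtis
variance and every host factor < 10% (typically ~2%), the threshold core is
exactly the planted 68, the ranked cores reach into the low 70s, and the
consensus recovers the planted core with no false inclusions — the same
qualitative geometry as a real pooled salivary collection (threshold core >
consensus; ranked cores slightly larger than consensus).

What the generator does **not** emulate: phylogenetic signal in abundances
(the tree is random, so UniFrac clustering by clade does not arise),
taxon-taxon interactions (co-occurrence edges come from shared batch/host
responses, not ecology), read-level artefacts (chimeras, PCR errors), and
compositional correlation structure beyond the Dirichlet. Passing tests on
synthetic data therefore demonstrate the *procedures* are correct and
calibrated, not that real oral communities satisfy their assumptions.

## Problem sizes and numerical choices

The contribution curve is quadratic in samples per rank; for the
800-sample default study it is estimated on a seeded random subset of 150
samples (11k pairs), which the package exposes as `max_samples`. PERMANOVA
permutations are vectorised and chunked at ~40M matrix cells per block.
The acceptance script runs the full default study (20 × 40 samples, 900
OTUs), 1000 null PERMANOVA replicates at n = 24 with 199 permutations, a
10-seed random-forest ordering experiment at 8 studies × 25 samples × 250
OTUs, and 30-reference affiliation at 250 nt — a few minutes on one CPU.
Ties everywhere break deterministically (mergesort sorts, lexicographic
ids); degenerate inputs (flat curves, empty intersections, all-zero
samples/taxa) warn or raise as documented on each function.

## Known limitations

* Sequential (Type-I) PERMANOVA makes host-factor R² depend on term order;
  that is inherent to "adjusting for study" by covariate ordering, and the
  strata-based alternative is provided but not asserted equivalent.
* The ranked-core stopping rule is a formalisation of a verbal "last 2%
  gain" criterion; different published formalisations (relative vs absolute
  gain) coincide on the test cases here but can differ on extreme curves.
* Permutation importance on the training table overstates importances for
  deep forests relative to out-of-bag permutation importance; rankings (the
  quantity used downstream) are far more stable than magnitudes.
* The affiliation scoring scheme (simple affine gap penalties) is a pinned
  choice; published "re-clustering" workflows vary, and identities near the
  0.97 boundary can flip under other schemes.
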