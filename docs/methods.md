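# Methods

This note documents the models, defaults and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
design decisions taken where the underlying study workflow left the choice
open.

## Study design assumed

A paired two-group design: each patient contributes one tumor (TT) and one
matched adjacent non-neoplastic (NNT) sample. The modeled study measured
nine miRNAs (plus two endogenous miRNA controls, miR-103a-3p and
miR-423-5p) in 13 validation patients and an 83-gene mRNA panel (plus seven
candidate control genes) in 24 patients, in technical triplicate on a
nanofluidic qRT-PCR platform. All statistics in this package assume that
pairing: differences are taken within patients, and permutation nulls flip
tumor/normal labels within patients.

## Quantification

**Replicate aggregation.** Mean of the technical triplicates by default;
median is available for robustness against single failed wells. Replicate
values are retained on each record for audit.

**CT usability filter.** Records with aggregated CT ≥ `max_ct` (default 24
cycles) are dropped with a reason string. The inequality is strict
("lower than 24"): CT = 24.0 drops. The filter is applied to the mRNA
panel by default and is configurable for miRNA assays, since late
amplification on the nanofluidic platform is unreliable while the miRNA
assays were run on a different chemistry.

**ΔCT.** For target *t* in sample *s*, ΔCT = CT<sub>t,s</sub> − mean(CT of
controls in *s*). Averaging control CTs (= geometric mean of linear
quantities) is the standard multi-reference choice; a sample missing any
control is excluded and reported rather than imputed. Matrices store −ΔCT
so that larger values mean higher expression.

**ΔΔCT and fold change.** Per patient, ΔΔCT = ΔCT<sub>TT</sub> −
ΔCT<sub>NNT</sub> and FC = 2<sup>−ΔΔCT</sup>, which assumes doubling per
cycle (amplification efficiency 2; no Pfaffl efficiency correction). A
feature's summary is the arithmetic mean ± sample SD (ddof 1) of the
per-pair fold changes — the reporting shape that produces values like
"FC 122.28, SD 127.75", which only arise from a per-pair FC distribution.
A geometric-mean mode is provided; it answers a different question (the
typical ratio rather than the expected ratio) and gives symmetric behavior
under label swap.

**Reference-gene stability.** A model-based two-group decomposition in the
NormFinder family. On log-scale values of the candidate panel (k ≥ 3
candidates), the per-sample mean across candidates is removed:
z<sub>igj</sub> = y<sub>igj</sub> − ȳ<sub>·gj</sub>. Then per candidate
*i* and group *g*:

* intra-group variation: s²<sub>ig</sub> = Var<sub>j</sub>(z<sub>igj</sub>) (ddof 1);
* inter-group deviation: d<sub>ig</sub> = z̄<sub>ig</sub> − mean over
  groups of z̄<sub>ig</sub> (for two groups, half the between-group
  difference relative to the candidate average, which is zero by
  construction);
* stability = mean over groups of |d<sub>ig</sub>| +
  √(s²<sub>ig</sub>/n<sub>g</sub>).

Lower is more stable. This keeps the two ingredients of the original
model-based approach — systematic group shift and within-group noise, the
latter entering as the sampling uncertainty of the group mean — without the
original's variance-shrinkage refinement of the group difference, which
matters only for very small candidate panels and is deliberately omitted
for transparency. The best pair minimizes the same score for the average of
two candidates (d averaged, variances averaged as for independent genes:
s²<sub>pair</sub> = (s²<sub>a</sub> + s²<sub>b</sub>)/4). Ties in the
ranking break lexicographically.

## Differential expression

**Permutation paired t.** The observed statistic is t = mean(d) /
(sd(d)/√n) on per-patient differences d. Under the paired null the two
tissue labels within a patient are exchangeable, so the reference
distribution is built by sign-flipping each patient's difference. With
2<sup>n</sup> ≤ the permutation budget the full enumeration is used and
p = #{|t<sub>perm</sub>| ≥ |t<sub>obs</sub>|} / 2<sup>n</sup> (the identity
assignment makes p ≥ 2<sup>−n</sup> automatically); otherwise 2000 random
sign vectors (default) with the finite-sample-valid
(count + 1)/(n<sub>perm</sub> + 1) convention. Zero-variance differences
with nonzero mean give t = ±∞, handled by the permutation count; all-zero
differences give p = 1. Equality of |t| values is compared with a 1e-12
absolute guard so that the identity flip and its negation always count.

**FDR.** Benjamini–Hochberg step-up on the permutation p-values
(delegated to statsmodels). The original analysis tool's exact adjustment
is undocumented; BH is the reproducible standard.

**Threshold regimes.** Microarray screen: FC > 2 or FC < 0.5 ("at least
two-fold" read symmetrically on the linear scale) AND p < 0.01 AND
FDR < 0.05. Validation: p < 0.05 AND FDR < 0.05. Regulation is `up` iff
mean FC > 1, `ns` whenever any gate fails.

**Moderated t.** For array-style data a simplified empirical-Bayes paired
t: s̃² = (d₀s₀² + d·s²)/(d₀ + d) with d = n − 1, referenced to t with
d₀ + d degrees of freedom. The prior variance s₀² defaults to the mean of
the per-feature variances; the full marginal-likelihood prior fit of the
limma family is out of scope and the implementation is labeled
accordingly. d₀ = 0 recovers the ordinary paired t.

## ROC diagnostics

AUC is the trapezoidal area over all distinct thresholds, identical to the
Mann–Whitney U statistic divided by n₊·n₋ with ties half-credited (the
test suite keeps an explicit pair-counting oracle). TT is the positive
class. When the raw AUC < 0.5 (a marker reduced in tumors) the scores are
negated and the orientation recorded, so reported AUCs are always ≥ 0.5
with their direction explicit. For miRNA–mRNA pair features the per-sample
score is (−ΔCT<sub>miRNA</sub>)/(−ΔCT<sub>mRNA</sub>); because −ΔCT
crosses zero this ratio is non-monotone, so samples with |denominator| <
ε (default 1e-6) are excluded and reported, and a monotone difference-based
score is available behind a flag.

## Correlation disruption

For every (miRNA, gene) pair, the Pearson correlation of −ΔCT profiles is
computed separately in TT and NNT on pairwise-complete samples (n ≥ 3
required; two-sided p from t = r√((n−2)/(1−r²))). Each pair becomes a
point (r<sub>NNT</sub>, r<sub>TT</sub>). Concordant regulation lies along
a rising trend from (−1, −1) to (1, 1); disruption is departure from that
trend.

Two band constructions are exposed, and every record names its residual and
band halfwidth:

* **regression** (default): OLS of r<sub>TT</sub> on r<sub>NNT</sub> over
  all pairs; flagged = outside the two-sided 99% *prediction* interval,
  halfwidth t<sub>1−α/2,n−2</sub>·s·√(1 + 1/n + (x−x̄)²/S<sub>xx</sub>).
  A confidence-of-mean band would shrink with n and flag nearly every pair
  in a large panel; only the prediction reading yields a small outlier set
  (the modeled study flagged 8 of 747).
* **anchored**: the fixed identity line with a constant band
  z<sub>0.995</sub> × residual SD — the literal "(−1,−1) to (1,1)"
  reading.

Sign flips are recorded separately from band exit, so both outlier
definitions remain queryable. At least 10 pairs are required; fewer make
the band meaningless. No multiplicity correction is applied to per-pair
correlation p-values: flagging uses the band, not p.

A note on calibration: the prediction band assumes identically distributed
residuals. Sample correlations have variance ≈ (1−ρ²)²/(n−3), so pairs
near ρ = 0 scatter more than pairs near ±1; with correlation targets
spread over (−0.9, 0.9) the pooled band flags mid-range pairs slightly
above the nominal 1% (≈2% at n = 24 per group in the test conditions).
The detector's 1% guarantee holds exactly in the homoscedastic regime the
band models, which is how the specificity test is framed; the sensitivity
test runs end-to-end through the generator.

## External concordance

A feature's external call from a log2 tumor/normal ratio is `up` iff
ratio > threshold, `down` iff ratio < −threshold (strict at ±1.0 by
default: exactly ±1 is `unchanged`). Sample-level external matrices reduce
to one ratio per feature by the *median* across tumor samples (matching
the "median values above 1.0 or below −1.0" convention of the external
comparison this mirrors), either against a pooled-reference profile or on
per-sample ratio matrices. Confirmation = direction agreement with the
internal call; features absent from the external table are listed, and
zero overlap is an error rather than a silent full pass.

## Enrichment

**Network.** Interaction edges (user-supplied table, e.g. a miRTarBase
export with strong/weak evidence and support counts) restricted to the
query miRNAs, ranked strong-before-weak then by support descending, ties
broken lexicographically by (miRNA, gene), truncated to the top 100 by
default.

**Over-representation.** p = hypergeometric upper tail P(X ≥ overlap) with
parameters (|universe|, |set ∩ universe|, |query|); BH across sets;
gene_ratio = overlap/|query| (the denominator is stated because web tools
differ on it).

**Preranked GSEA.** Features sorted by score descending (name-tiebreak for
determinism); sets filtered to sizes strictly inside (10, 500) after
intersection with the ranking. The running sum increments at hits by
|score|<sup>w</sup> normalized over hits (w = 1 default, w = 0 for the
classic KS variant) and decrements uniformly at misses; ES is the signed
maximum deviation. p comes from gene-label permutations — the only scheme
available for a preranked list — counting permutation ES values as or more
extreme on the matching sign, (count + 1)/(n + 1). The leading edge is the
member run up to the ES extremum.

## Synthetic-data generator

CT(assay a, sample s of patient i, group g) = baseline<sub>a</sub> +
patient<sub>i</sub> + sample-offset<sub>s</sub> − shift(a, g) + ε, with ε
i.i.d. N(0, noise_sd²) per technical replicate and shift = the planted
log2 fold change for tumor samples of DE assays (one PCR cycle = one log2
unit, the efficiency-2 assumption made explicit). Control assays carry the
same patient and sample offsets with zero shift, so ΔCT normalization is
exact in expectation and planted effects are recovered bias-free.

Defaults and why: noise_sd 0.25 cycles (typical qRT-PCR triplicate
scatter), patient effect SD 1.0 cycles (biological heterogeneity; the real
magnitude is unknowable from summary tables, so this is a stated default,
not an inference), sample offset SD 0.5 cycles (loading variation the
controls absorb), baselines uniform on 18–23 cycles so that panel features
clear the CT < 24 filter in most samples, 24 patients and triplicates as
in the modeled gene panel.

Correlation planting uses the conditional-Gaussian construction: within
each group the gene profile is rebuilt as r·z(miRNA) + √(1−r²)·ε on
standardized values (with ε orthogonalized against the miRNA so sample
correlations track targets tightly), then rescaled to the gene's original
within-group mean and SD. Targets are hit exactly in expectation;
sampling scatter at n = 24 is about ±0.1–0.15 depending on |r|.

What the generator does **not** emulate: probe-level microarray structure,
counts/sequencing noise, amplification-efficiency differences between
assays, plate/batch effects, clinical covariates, HPV status, and
correlated patient effects between miRNA and mRNA panels. Passing recovery
tests therefore demonstrates correctness of the statistical machinery
under the stated model, not robustness to platform artifacts.

## Problem sizes used in tests and the acceptance script

Worked examples run on the published 9-miRNA and 37-gene summary tables.
Simulation-based checks use 12–24 patients, up to 1000 features for
type-I calibration (2000 permutations), 50 seeds for stability and
disruption-sensitivity recovery (500 concordant pairs + 1 planted flip,
n = 24 per group), and 25 seeds / 10 null studies in the acceptance
script — sizes chosen so each suite completes in about a minute on one
CPU while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

* The NormFinder-style stability omits the original's shrinkage of the
  group-difference term; rankings agree on clear cases but exact stability
  values differ from the Excel add-in.
* The moderated t uses a fixed-form prior, not the fitted prior of limma.
* The ratio pair-feature is non-monotone around −ΔCT = 0 by construction;
  the difference mode is the safer default when samples straddle zero.
* Permutation p-values are granular at 1/(n_perm+1); with 2000
  permutations the smallest attainable p is ≈ 5×10⁻⁴, which caps how far
  BH can separate features in small panels.
* External concordance consumes already-computed log2 ratios; upstream
  normalization of the external datasets is out of scope.
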