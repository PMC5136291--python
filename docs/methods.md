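# Methods

## Model and testing procedure

`pathkat` tests whether rare genetic variation, aggregated over a
biological pathway, is associated with a quantitative trait. The
procedure:

1. **Variant-level QC.** Dosages are read from VCF (`DS` preferred over
   `GT` hard calls, since imputed data carry their information in `DS`;
   multi-allelic records decomposed per alternate allele). Variants are
   kept when MAF ≤ `maf_max` (default 0.01, boundary inclusive), when
   imputation INFO ≥ `min_info` if that filter is active (inclusive;
   variants without a score are dropped), and when the Hardy–Weinberg
   exact-test P is strictly greater than `min_hwe_p` if active. The HWE
   exact test sums, over all heterozygote counts compatible with the
   observed allele totals, the conditional probabilities not exceeding
   that of the observed configuration; it applies only to integral
   genotypes — for dosage data the filter is assumed pre-applied upstream
   and skipped with a warning.
2. **Functional filtering.** One of three regimes: `nonsynonymous`
   (missense plus all loss-of-function terms), `lof` (stop gain/loss,
   splice donor/acceptor, frameshift), or `cadd` (phred-scaled CADD
   score ≥ threshold, default 20 — by CADD's construction the top 1% most
   deleterious substitutions, hence no empirical percentile is computed).
   The exact consequence vocabulary behind "nonsynonymous" is a documented
   assumption: missense plus the LoF set. One consequence per variant
   (most-severe-consequence resolution is upstream of this tool).
3. **Collapsing.** Variants map to genes by position against BED regions
   (VCF positions 1-based, BED 0-based half-open; a variant at position p
   belongs to a gene iff p−1 ∈ [start, end); conversion happens in exactly
   one place). Gene footprints are full transcript spans — intronic
   variants are deliberately in scope under the CADD regime. A pathway's
   variant set is the deduplicated union over member genes; variants in
   overlapping genes join every overlapping gene. Sets with ≥ 2 surviving
   variants are *eligible*; the eligible count is the Bonferroni
   denominator `alpha / n_eligible`, recomputed per regime.
4. **Kernel test.** See below.
5. **Permutation validation, gene-level scan, subnetwork dissection,
   replication.** As described in their sections.

Assumptions: unrelated (exchangeable) samples; quantitative traits with
approximately Gaussian residuals after covariate adjustment (ten
principal-component covariates by default); no kinship or mixed-model
structure; binary traits are out of scope.

## The SKAT-O engine

With null-model residuals `r` (OLS of trait on covariates, residual
variance `σ̂² = RSS/(n−k)`), weights `w_j` (Beta(1, 25) density of MAF —
the field's convention; the weighting is configurable, including flat
weights), and scores `S_j = g_j'r`:

    Q(ρ) = (1−ρ) Σ_j (w_j S_j)² + ρ (Σ_j w_j S_j)².

Under the null, `Q(ρ) ~ Σ_i λ_i χ²_{1,i}` where the `λ_i` are the nonzero
eigenvalues of `σ̂² · R(ρ)^{1/2} W G' P G W R(ρ)^{1/2}`, `P` the projector
off the covariate span and `R(ρ) = (1−ρ)I + ρ11'` (its matrix square root
is closed-form). Missing dosages are mean-imputed per variant at test
time; the stored matrix keeps explicit missingness.

The combined p-value conditions on the shared burden-direction component:
decompose the projected weighted genotype matrix `Z` along its row-mean
vector `z̄`, giving the conditional eigenvalues (of the orthogonalized
part), the mixture moments `MuQ`, `VarQ` and the per-ρ coefficients
`τ(ρ) = (m²ρ + (1−ρ)Σ_j c_j²)·z̄'z̄` with `c = Z'z̄ / z̄'z̄`. For the
observed minimum grid p-value `T`, each ρ's `T`-quantile `q_min(ρ)` is
obtained by moment-matched (Liu) inversion, and

    p_SKAT-O = 1 − ∫ F_cond( s·(h(x) − MuQ) + MuQ ) f_{χ²₁}(x) dx,
    h(x) = min_ρ (q_min(ρ) − τ(ρ)x) / (1−ρ),

with `s = sqrt((VarQ − VarRemain)/VarQ)` the small-variance adjustment for
the product cross-term. The result is clamped into
`[min_ρ p_ρ, |grid| · min_ρ p_ρ]`, both bounds being mathematically valid
for the omnibus.

Numerical choices:

* ρ grid: {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1} (configurable). Grid
  values ≥ 0.999 are computed at 0.999: at ρ = 1 the interpolation matrix
  is rank one and the conditioning division by (1−ρ) degenerates, so the
  burden endpoint participates in the omnibus at the cap. Reported
  `rho_used` records this; the shift perturbs the endpoint p by ~0.1%.
* The conditioning integrand `h(x)` is a minimum of lines in x. Its
  envelope breakpoints and its crossing into the region where the
  conditional CDF is zero are located exactly, and integration (in
  s = √x, which removes the χ²₁ density's edge singularity) never
  straddles a kink: adaptive quadrature with those points for one-shot
  tests, per-segment Gauss–Legendre for the permutation fast path.
* Eigenvalues below 1e-10 of the per-set maximum are truncated to zero;
  an absolute anchor (1e-12 of the pre-projection column scale) guards
  against projection residue masquerading as signal. A set whose spectrum
  vanishes raises a degenerate-set error.
* `σ̂²` uses denominator n−k; p-values are clamped to [1e-30, 1].

### Tail probabilities of chi-square mixtures

`davies_pvalue` inverts the characteristic function via Imhof's integral
representation. The integrand is multi-scale — the largest eigenvalue
creates a boundary layer near u = 0 while the oscillation frequency tends
to q/2 — so the integral is evaluated on geometric panels from the
boundary-layer scale outward, each panel's Simpson point budget matched to
its local phase and amplitude rates (one vectorized evaluation over the
concatenated grid; per-panel Richardson refinement on demand). Beyond the
truncation point the oscillatory tail is integrated analytically by parts
(two boundary terms; the truncation point is pushed out until the
next-order residual estimate is below tolerance). Default absolute
accuracy 1e-9; verified in the test suite against exact chi-square tails
(equal eigenvalues) and 10⁷-draw Monte-Carlo simulation. A
single-component mixture *is* a scaled 1-df chi-square and is evaluated
exactly. Probabilities below the inversion's floating-point resolution
(~1e-9) switch to a Lugannani–Rice saddlepoint approximation; outright
integration failure falls back to the Liu moment-match (mean, variance,
skewness matched to a scaled noncentral chi-square) with the convergence
flag cleared.

## Permutation validation

The trait vector is shuffled among individuals (genotypes and covariates
fixed), the null model re-fit on the shuffled trait, and the full SKAT-O
p recomputed, B times. Shuffling raw phenotypes follows the validation
design literally; it also breaks the trait–covariate link, so a
residual-permutation alternative is available behind a flag (off by
default). A hit is robust when at most `floor(10·B/100000)` permuted
p-values fall strictly below the observed one — the "≤ 10 of 100 000"
rule scaled proportionally so reduced B remains meaningful (at B = 999
the ceiling is 0). The empirical p-value uses the (+1)/(+1) correction;
the robustness decision uses the raw count.

Since genotypes and covariates are fixed across permutations, the per-ρ
eigenvalues and the conditioning structure are fixed up to the σ̂² scale.
The permutation engine computes them once, tabulates each survival
function on a 257-knot monotone (PCHIP) spline of log-p, and re-fits only
the null model per permutation — numerically equivalent to a from-scratch
recomputation (agreement with the direct path is tested at ~1e-7; the
observed p is evaluated through the same tabulated path for exact
comparability of the permutation counts). Per-set seeds derive from the
run seed plus a CRC of the set label, so results are independent of set
iteration order.

The permutation-consistency check compares each null set's empirical p
against its analytic p at the per-set 99% binomial CI; across 20 sets up
to two exceedances are accepted, the family-wise reading of twenty
simultaneous 1% tests.

## Follow-up and replication

*Gene scan*: the same kernel test per gene region genome-wide, Bonferroni
denominator = eligible genes, with a Manhattan export (gene, chromosome,
midpoint, p, target-pathway flag).

*Subnetworks*: hub genes are the top-k (default 3) pathway genes by
degree on the subgraph induced by the pathway's genes (cross-pathway
neighbours count neither for ranking nor membership — the
induced-subgraph reading; ties break by summed edge score, then symbol).
Each hub's subnetwork is the hub plus its direct pathway neighbours,
tested as one variant set. Duplicate edges keep the maximum score;
self-loops are dropped; the evidence-score threshold defaults to 0.

*Replication*: restricted to discovery hit pathways, with INFO ≥ 0.4 and
HWE P > 5×10⁻⁷ activated (a replication config missing INFO scores is a
configuration error), plus gene-level collapse of the same variants and a
per-variant OLS scan (Frisch–Waugh projection; Wald t p-values;
monomorphic and covariate-collinear variants flagged with absent p).

Per-trait sample handling: samples missing the trait or any covariate are
dropped for that trait only, never imputed. Variant filters and MAF (and
hence weights) are computed once on the full loaded cohort; a set that
becomes degenerate within a trait's subsample is reported untestable.

## The synthetic-data generator

`synthgen` emulates the statistical structure the pipeline assumes: rare
variants (binomial genotypes under Hardy–Weinberg, MAF uniform on
[0.0005, 0.01] with a 10% common-variant admixture to exercise the MAF
filter) tiled across non-overlapping gene regions on synthetic
chromosomes (`chrS1…`, fixed stride, so gene assignment has known truth);
pathways partitioning genes; a trait built as causal dosages × effects
plus ten standard-normal covariates (γ ~ N(0, 0.2)) plus unit Gaussian
noise; CADD-like scores high (≥ 20) for 30% of causal and 5% of null
variants; consequence labels drawn independently (5% LoF, 15% missense);
and an interaction graph whose designated hub connects to every causal
gene, making the subnetwork dissection's planted-signal tests meaningful.

Defaults are the generator's study conditions: n = 500 samples, 12
pathways × 5 genes, one causal pathway with effects in 5 genes, half the
causal effects negative, causal per-allele effects |N(0, 1.5)| trait-SD.
The effect scale was set by a design-time power calculation: with ~4–6
causal variants surviving the CADD filter at MAF ≈ 0.005, the expected
per-variant score non-centrality at n = 500 is ≈ n·2pq·β²/σ² ≈ 8, which
puts the causal pathway's p in the 1e-5–1e-7 range — the same
signal-to-noise regime a cohort of several thousand reaches with β ≈ 0.5
SD effects. Desk-scale experiments therefore probe the method's ranking
and calibration behaviour, not its absolute power at publication-scale
cohorts.

Optional switches: per-gene exchangeable latent-haplotype correlation
(`ld_rho`) to exercise the Davies machinery under linkage disequilibrium;
genotype missingness; HWE-violating variants generated with inbreeding
F = 0.9 — homozygote excess, because for rare alleles a heterozygote
excess mostly shifts the estimated allele frequency and is nearly
invisible to the exact test; `DS` dosage emission; and cohort
partitioning with imputation-INFO degradation for the replication arm.

What the generator does **not** emulate: realistic LD beyond the
exchangeable block model, population structure actually confounded with
genotype (the "principal components" are independent noise), genotyping
error, allele-frequency spectra from demography, multi-transcript
annotation ambiguity, or related individuals. Passing tests therefore
demonstrate statistical correctness and calibration of the machinery
under its stated assumptions — not robustness to the confounders of real
cohort data.

## Problem sizes used in the test and acceptance runs

Chosen to keep the full suite within a normal CI budget on one core:
null calibration pools 2000 eligible pathway tests from ~44 bundles
(n = 200, 50 pathways, 14–20 variants per gene, CADD regime);
Davies-vs-Monte-Carlo uses 50 random eigenvalue sets (m ≤ 10) at 10⁷
draws; the combination bound is checked on 500 random sets; permutation
consistency uses 20 null sets at B = 999; planted-signal recovery uses
100 discovery runs (n = 500, 10–16 variants per gene) with a gene-level
scan per run. `scripts/acceptance.py` recomputes the same quantities at
moderately reduced replicate counts (printed alongside each value as
`n`).

## Known limitations

* Quantitative traits only; no kinship/mixed models; no meta-analysis.
* The burden endpoint enters the omnibus at ρ = 0.999 (the canonical
  device); reported per-ρ values at the endpoint inherit it.
* Imhof inversion resolves p down to ~1e-9; deeper tails rely on the
  saddlepoint approximation (accurate in the far tail but approximate).
* The exact HWE test requires hard calls; dosage data pass that filter
  untested.
* Mean imputation of missing genotypes slightly deflates variance at low
  call rates; how the original call sets handled missingness at test time
  is not recorded, so this is a package choice.
* P-values below 1e-30 are reported as 1e-30.
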