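# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the design decisions behind
`sogwas`, in the order the pipeline runs.

## Panel representation

A hybrid genotype at a marker is an *unordered* pair of gametes, each
gamete an `(allele, origin)` pair with allele ∈ {0, 1} and origin ∈
{D, F}.  The four SNP-Origin alleles (0D, 1D, 0F, 1F) combine into ten
SO genotype classes, canonically ordered

    0D0D 1D0D 1D1D | 0F0F 1F0F 1F1F | 0D0F 0D1F 1D0F 1D1F

The two mixed-phase double heterozygotes 0D1F and 1D0F are distinct
classes: they carry the same dosage and the same background but differ
in which origin holds allele 1, which is the phase signal the Δ_LD
contrast measures.  A factorial inter-group hybrid has one D and one F
gamete everywhere and can only realize the last four classes.

## Synthetic panel generator

The generator mirrors the construction of a two-pool hybrid breeding
program and is deterministic given a seed.

* **Founders.**  Two pools of fully homozygous inbred lines.  Per
  marker, an ancestral allele frequency is uniform on [0.1, 0.9] and
  each pool's frequency is a Balding–Nichols Beta draw around it with
  an Fst-like `divergence` parameter (default 0.25 — strong but not
  fixed differentiation, the regime in which background-specific
  effects are interesting).  At `divergence = 1` pools are fixed; at 0
  they coincide.  No within-pool linkage disequilibrium is simulated:
  founder alleles are independent across markers, so LD in derived
  panels comes only from co-inheritance bookkeeping, not from realistic
  haplotype structure (see *Limitations*).
* **Factorial F1s.**  Uniform draws without replacement from all D×F
  pairs, with a per-parent contribution cap (default 5).  Gamete slot 0
  is the Dent parent, so origins are (D, F) by construction.
* **Doubled haploids.**  Each DH line is one recombinant F1 gamete
  doubled.  Crossovers follow a Haldane (no-interference) model:
  Poisson count with mean span/100 cM per chromosome, positions uniform
  on the span.  The origin label of every locus is the origin of the
  contributing F1 haplotype, so origin labels are conserved through
  meiosis by construction.
* **Diallel.**  Uniform sparse draws of unordered DH pairs (cap 4 by
  default, no self-crosses).  Because DH lines are homozygous, each
  parent transmits its single haplotype unchanged; expected genome
  composition of a random diallel is DD 25%, DF 50%, FF 25%.
* **Phenotypes.**  Plot value = mean + environment effect + precocity
  block effect + QTL class means + polygenic draws (A, D, I^aa, I^ad,
  I^dd from the NOIA kinships) + per-environment AxE/DxE draws + row +
  column + error.  Four checks are replicated per environment (default
  4×); experimental hybrids are planted `exp_reps` times per
  environment (default 1, mirroring a sparse trial).  Precocity blocks
  are a median split on the main genetic value, occupying contiguous
  row bands, which reproduces the block–genetics confounding of a real
  earliness-grouped trial.

A QTL's ten class means are assembled from within-background biological
effects plus origin terms:

    β_0D0D = −a_DD + o_a      β_0F0F = −a_FF − o_a     β_0D0F = −a_DF + o_d
    β_1D0D =  d_DD + o_a      β_1F0F =  d_FF − o_a     β_0D1F = d_DF + o_d + Δ/2
    β_1D1D =  a_DD + o_a      β_1F1F =  a_FF − o_a     β_1D0F = d_DF + o_d − Δ/2
                                                       β_1D1F =  a_DF + o_d

With this construction the origin contrasts evaluate to o_a and o_d
exactly only when the background additive effects are equal
(`o_a00 = o_a + (a_FF − a_DD)/2`); generative effects interact, as they
do biologically.  Recovery tests therefore use single-effect
architectures.

**Default architecture** (`TrueArchitecture`): trait mean 100 (a
days-like scale), σ²_a = 1.0, σ²_d = 0.15, each epistatic component
0.05, AxE 0.15, DxE 0.25, plot error 0.5, row and column variances 0.2,
check effects (±0.8, ±1.5), block effect 0.5.  These describe a highly
heritable, additivity-dominated trait in which the dominance-by-
environment variance exceeds the dominance main variance — the
qualitative pattern expected for phenology-like traits in such panels.
An optional MAF filter (`apply_maf_filter`, 5%) mirrors the marker
panel's quality control.

## Field correction and heritability

Per environment and trait, the row–column model

    Y = μ + λ_check + δ_block + R_row + C_col + G_hybrid + ε

is fitted by REML with fixed checks (4 check levels + experimental) and
optional fixed precocity block, and independent random row, column and
genotype effects.  Row and column BLUPs (û = σ̂² Z′Py) are subtracted
from the raw values; check, block and genetic effects remain in the
corrected value.  `select_field_model` reports AIC/BIC for the four
spatial variants (row+col, row, col, none) and picks the AIC minimum,
ties going to the model with fewer variance parameters.  Low-density
plots are discarded when their plant count is strictly below the
per-environment median minus 15; an optional robust outlier filter
(|value − median| > 3 IQR per environment, off by default) is provided
as a generic stand-in for ad-hoc outlier removal.  Two trial networks
are put on a common scale by shifting one by the mean difference of
their shared-check corrected phenotypes.

Broad-sense heritabilities are standard entry-mean formulas,

    single-env:  H² = σ²_G / (σ²_G + σ²_ε / r̄)
    multi-env:   H² = σ²_G / (σ²_G + σ²_GxE/n_env + σ²_ε/(n_env · r̄))

with r̄ the harmonic-mean replicate count.  With one replicate per
genotype the genotype and error kernels coincide and REML cannot
separate them — only their sum (and hence the multi-environment H²,
where replication across environments identifies σ²_G) is meaningful;
single-environment H² requires within-trial replication.  Note that
single-environment σ²_G absorbs that environment's GxE deviations, so
under strong GxE the single-env H² can exceed the multi-env one.

## NOIA codings and kinships

With B the counted allele (allele 1) and observed genotype frequencies
(p_BB, p_Bb, p_bb) from the analyzed hybrid panel itself (not the
founders):

    h_a = p_Bb + 2 p_bb − n_b            (n_b = 2 − dosage)
    h_d = (−2 p_Bb p_bb, 4 p_BB p_bb, −2 p_BB p_Bb) / den   for BB, Bb, bb
    den = p_BB + p_bb − (p_BB − p_bb)²

Both codings have zero frequency-weighted mean and zero weighted
cross-product (orthogonality holds per marker to machine precision).
Markers with `den ≤ 0` (no heterozygotes and one homozygote class
absent) are excluded from H_d only.  Kinships are trace-normalized
cross-products, K = HH′/(tr[HH′]/n); the epistatic matrices are
Hadamard products of K_a and K_d with the same normalization, so every
matrix has mean diagonal exactly 1.  Leave-one-chromosome-out sets
rebuild all five matrices (including the epistatic ones) from the
retained markers, rather than masking whole-genome versions — the
Hadamard products of LOCO K_a/K_d are not equal to masked whole-genome
Hadamards, and rebuilding keeps the exclusion exact.

## REML engine

All mixed models run through one engine: y = Xb + Σ_k u_k with
u_k ~ N(0, σ²_k V_k) for arbitrary PSD V_k (kinships through
plot-to-hybrid incidence as ZKZ′, per-environment masks, identity
residuals).  The optimizer takes average-information steps with
step-halving so the restricted likelihood never decreases, falling back
to an EM-type ascent direction (σ² ← σ² + σ⁴·2g/n) when the AI step
fails; components are projected to ≥ 0 and a component pinned at zero
with negative gradient is frozen as a boundary estimate.  Convergence:
relative log-REML change < 1e-8 and maximum parameter change < 1e-6,
cap 500 iterations; non-convergence raises an error carrying the
likelihood trajectory.  A diagonal jitter of 1e-10·var(y) keeps V
positive definite when residual components hit the boundary.

Identifiability caveat: in a weakly related panel the epistatic
kinships are nearly identity (mean |off-diagonal| ≈ 0.004–0.016 at
n = 300 versus ≈ 0.09 for K_a), so under pure noise REML can trade
error variance into them along an almost flat ridge.  σ²_a and σ²_d are
well identified; estimates of the epistatic components should be read
jointly with the error.

The MONO model fits the five genetic components plus one error; the
MULTI model adds fixed environment effects (reference coding),
independent per-environment AxE and DxE components on K_a/K_d, and
per-environment error variances; epistasis-by-environment terms are
deliberately absent.  `variance_report` expresses each main component
as a share of the main genetic variance (their sum) and averages
AxE/DxE/error over environments.

## Marker tests

**Eligibility.**  A marker enters a contrast only if panel MAF ≥ 5%
and every SO class with a nonzero coefficient in that contrast has at
least 5 carriers, so the candidate set is contrast-dependent (a global
minor-observed-class variant is available as `minor_class_filter`).
The Gad analogue requires 5 carriers of each observed dosage class.

**Covariance (P3D).**  Variance components come from the no-marker H0
fit with the LOCO kinships of the tested chromosome.  Per marker the
component ratios stay fixed and a single variance scale is re-estimated
from the GLS residual quadratic form, s² = r′V̂⁻¹r/(n − p).  This
avoids per-marker REML at the cost of treating V̂ as known; it is an
approximation chosen for the usual reason (orders-of-magnitude
speed-up with negligible effect at these sample sizes).

**Estimation.**  The marker term is a cell-means design over the
observed classes (no separate intercept, which makes all listed
contrasts estimable and invariant to adding a constant); remaining
fixed effects (environment dummies in MULTI) are appended and handled
by the same GLS solve.  For a contrast L: estimate Lβ̂, covariance
s²L(X′V̂⁻¹X)⁻¹L′, Wald statistic est²/var for 1-df contrasts and the
quadratic form with df = rank for the global tests, referred to a
chi-square (df recorded so F-type variants can be re-derived).  Global
tests g are joint Wald tests of all pairwise-free differences among
participating classes (df = k − 1): g_shared uses the 4 inter-group
classes (testable in both designs, including within a diallel), g_all
all 10 classes.  Contrasts referencing an unobserved class
are skipped with the reason recorded.

**Multiple testing.**  BH step-up within each (contrast, panel, model,
trait) family, pooling the p-values of all environments and the MULTI
layer of that family.

**Dominance classification.**  |d/a| > 1 is overdominant, 0 < |d/a| ≤ 1
partial dominance, d = 0 additive; a = 0 with d ≠ 0 leaves the ratio
undefined and is reported as overdominant with an explicit `a=0`
annotation.

## QTL clustering

LD is the squared dosage correlation between hybrids (origins ignored).
For each significant marker and side, the window starts at 0.5 cM and
the observed r² within it are fitted against the Hill–Weir
drift-recombination expectation

    E[r²] = (10 + C)/((2 + C)(11 + C)) ·
            (1 + (3 + C)(12 + 12C + C²)/(n(2 + C)(11 + C)))

with C = ρ·c(d), c(d) the Haldane recombination fraction of d cM and
ρ ≥ 0 the single fitted parameter (unweighted least squares over all
pairs in the window).  The LD extent is the distance where the fitted
curve crosses r² = 0.1.  While the extent exceeds the window, the
window grows by 0.1 cM and the fit repeats; the final extent (truncated
at the chromosome end) is the window length.  Fewer than 5 usable pairs
or a degenerate fit fall back to the current window; data flat below
the threshold give extent 0.

Significant markers whose closed cM windows overlap (touching endpoints
included) form one QTL; the interval is the union span, converted to bp
by linear interpolation on the map.  QTLs from different environments,
layers or models merge into meta-QTLs when intervals overlap, but only
within the same trait and effect family (additive: a, a_DD, a_DF, a_FF,
s_a, t_a, α; dominance: the d twins and δ; origin: o_a, o_d and their
components; LD and global separately) — families are never merged
together.

## What the simulations do and do not show

The generator reproduces the *bookkeeping* of the breeding design
(origin tracking, class combinatorics, mating structure, field layout)
and the *covariance structure* of the models (NOIA kinships, GxE,
spatial effects), so passing tests demonstrate that the estimators
recover what the models define, at the stated sample sizes.  It does
not emulate founder haplotype structure or selection history: founder
alleles are exchangeable across markers, so LD decay in simulated
panels is far weaker than on a real dense array, allele-frequency
spectra are symmetric, and no repulsion-phase linkage (pseudo-
overdominance) arises spontaneously — tests of the LD-window machinery
therefore use panels with LD built in by construction.  Power numbers
are specific to the simulated class frequencies and error scales and
should be read as orderings, not absolute rates.

## Problem sizes

Statistical checks run at: n = 300 hybrids (200 DH parents, 120
founders per pool, 400 markers on 2 chromosomes) for REML recovery (50
seeds), null calibration (2,000 independent null markers), FDR control
(200 replicates of an 80-null/20-causal scan) and the power comparison
(100 replicates per scenario, DD-only effect 0.85 against a phenotypic
SD near 1.1, homogeneous effect 0.35); 10,000 hybrids from a 400-line
DH pool on 10 chromosomes for genome composition; 100 random interval
sets for the clustering oracle.  These sizes put Monte-Carlo error
comfortably below the tolerances asserted in the tests.

## Known limitations

* Single-trait, two-origin groups only; >2 groups would generalize the
  class algebra but is untested.
* The P3D scale re-estimation is an approximation to full per-marker
  REML; heavily structured panels may prefer exact refits.
* Wald/chi-square reference (not F): slightly anti-conservative at
  small n; measured type-I error at n = 300 is within [0.04, 0.06].
* No spatial splines or AR(1) residuals in the field model; no
  haplotype-based or multi-locus association models.
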