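# Methods

This note documents the models, conventions and design choices behind
`needlehydro`, in the order the pipeline runs them.

## Conductivity law and trait aggregation

Per tracheid, theoretical hydraulic conductivity uses the
Hagen–Poiseuille law with the elliptical-conduit effective radius

    k_t = (π ρ / 8 η) · d_max³ d_min³ / (8 (d_max² + d_min²)),

ρ = 998.205 kg m⁻³, η = 1.002 × 10⁻⁹ MPa s (water at 20 °C). Diameters
are measured in µm and converted to metres before evaluation, which puts
k_th = Σ k_t on the 10⁻¹¹–10⁻¹⁰ kg m s⁻¹ MPa⁻¹ scale of the reference
study's tables. The formula is symmetric in the two diameters, reduces
to the circular law (π ρ/8η)(d/2)⁴ when d_max = d_min, scales as the
fourth power of overall size, and is strictly increasing in each
diameter; these properties are tested against an independent
exact-rational oracle.

Aggregation to the needle follows the sampling convention: diameters,
lumen area and flatness are averaged over the tracheids of a section
(flatness as the mean of per-tracheid ratios d_max/d_min, which under
natural size variation exceeds the ratio of the mean diameters);
conductivity and lumen area are summed (k_th, N_lum); N_t is the count.
Proportional areas A_x% and A_p% are relative to the needle section area
after unit harmonisation (A_n, A_v are carried in mm²; A_x, A_p in µm²).

**k_s unit convention.** The reference tables print k_s on a ×10⁻¹²
"kg m⁻¹ s⁻¹ MPa⁻¹" scale that is only reproduced when k_th is divided by
A_x expressed in µm²; dividing by A_x in m² (dimensionally proper SI)
gives values ~10¹² larger. The package computes both, labels them `k_s`
(reported-scale, default output, comparable with the printed tables) and
`k_s_si`, and never mixes them. All derived *ratios* of k_s are
identical under either convention.

**Convexity diagnostic.** For tracheid populations whose diameter
variation is dominated by overall size scaling, Σ k_t ≥ N_t · k_t(mean
d_max, mean d_min) (k_t is strictly convex along scaling rays). The
elliptical kernel is not jointly convex once d_max/d_min exceeds ≈ √3,
so this inequality can fail for contrived populations; it is therefore
exposed as a per-needle diagnostic (`NeedleTraits.jensen_gap`) and
verified on generated anatomies rather than enforced as a validation
rule on arbitrary data.

## Synthetic data generator

The generator reproduces the study design: 2 watering treatments (one
plot each) × 3 trees per plot × 2 canopy positions × 5 shoots × 7
needles = 420 needles, scalable in every dimension. Group mean targets
for N_t, d_max, d_min, F_t, A_n, A_v, A_x, A_p come from the shipped
reference group-means fixture (2 × 2 cells).

Distributions (the study reports group means and CIs, not distributions,
so these are the package's modelling choices):

* sizes and multiplicative random effects are lognormal — positive,
  right-skewed, typical of anatomical dimensions;
* tree and shoot-within-tree random intercepts act multiplicatively on
  the tracheid diameter scale, with coefficients of variation 0.08 and
  0.05 (modest within-stand values; the study reports no variance
  components);
* per-tracheid minor diameters are lognormal with CV 0.25; flatness is
  1 + gamma-distributed excess (mean F_t − 1, excess CV 0.5), enforcing
  F_t ≥ 1; lumen area is the exact ellipse area π d_max d_min / 4;
* tracheid counts are rounded lognormals around the group target
  (CV 0.12), so count dispersion is tunable independently of the mean;
* xylem area is the needle's total lumen area divided by a drawn packing
  fraction, lognormal with mean 0.35 (the value implied by the reference
  sun-control means, N_lum/A_x ≈ 713/2060) and CV 0.10;
* A_n, A_v, A_p chain from A_x by the calibration's area ratios with 5%
  lognormal noise, with a final pass enforcing the section hierarchy
  (A_v < A_n, A_x + A_p ≤ A_v, Σ lumen ≤ A_x) on every needle.

**Mean anchoring.** Two corrections make the group means land on the
calibration targets in expectation, verified by the recovery test
(within 3% at 30 trees/plot, seed-averaged):

1. The printed mean flatness (mean of ratios, e.g. 1.75 for sun/control)
   exceeds d_max/d_min of the printed mean diameters (6.2/3.8 = 1.63),
   so d_max, d_min and F_t targets cannot all be met by independent
   multiplicative draws. The generator anchors d_max and F_t: the minor
   diameter scale is d_max_target/F_t_target, and E[d_max] =
   E[d_min]·E[f] then equals its target exactly. The realised d_min mean
   floats ~5–7% below its printed target — the price of the printed
   table's own mean-of-ratios convention.
2. The expected xylem area E[A_x] is computed in closed form from the
   generator's own parameters (lognormal second moments are explicit)
   and the A_n chain is scaled by A_n_target/E[A_x] rather than by the
   raw printed A_n/A_x ratio, which would propagate the second-moment
   bias of the lumen sum into every section area.

A corollary of the bottom-up construction is that the A_x *target*
itself only enters feasibility checking and area ratios: the realised
xylem area is whatever the lumen sum and packing fraction produce. Where
the printed targets are slightly mutually inconsistent across groups,
the simulated xylem proportion A_x% varies a few percent between groups
and carries almost no tree-level variance — unlike the field data, where
A_x% was flat across groups with wide intervals. Treatment-null
behaviour of A_x% is therefore tested with the no-drought calibration
(drought cells copying control cells), under which its test is exactly
null and well calibrated.

Determinism: one `numpy` generator seeded from the config; identical
config ⇒ byte-identical CSV output (tested).

## Geometric measurement surrogate

`geometry` builds an idealised cross-section from a needle record:
concentric 2:1 ellipses for the needle outline and vascular cylinder
(the flattened shape of a spruce needle section), xylem and phloem
ellipses side by side inside the cylinder, and elliptical lumina placed
in the xylem largest-first by dart throwing with rejection (bounded
attempts; lumen packing above 0.6 of the xylem is rejected as
infeasible — random sequential placement of ellipses jams not far above
that). Layout region areas equal the section's areas exactly by
construction.

Rasterisation uses pixel-center point-in-ellipse membership with no
anti-aliasing, so results are bit-reproducible across platforms.
Re-measured areas are pixel counts; on the mask, the major lumen
diameter is the maximum pairwise pixel-center distance plus one pixel
and the minor diameter the minimal rotating-caliper width plus one pixel
(one convention among several an image-analysis package might use; the
+1 px term accounts for pixel extent and biases diameters slightly high,
~3% at 4 px/µm). Lumina under 4 pixels are flagged. At the default
4 px/µm the four region areas come back within a few hundredths of a
percent, and traits recomputed from re-measured sections rank-correlate
with the truth at ρ ≥ 0.95. This module validates the measurement chain;
the main pipeline consumes measurement tables directly.

## Mixed-effects inference

Observations enter at needle level (35 per tree and canopy position).
Each trait is fitted with a linear mixed model: fixed effects from
{canopy, drought, canopy+drought, canopy×drought}, random intercepts for
trees and for shoots nested in trees (variance components). k_th is
log-transformed (strong right skew); its group means are back-transformed
and flagged geometric. Estimation uses maximum likelihood wherever a
likelihood-ratio comparison is taken (REML likelihoods with different
fixed effects are not comparable) and REML for the final reported group
means — standard practice. The test ladder per trait:

* canopy height: (drought) vs (canopy + drought), 1 df;
* drought: (canopy) vs (canopy + drought), 1 df;
* interaction: (canopy + drought) vs (canopy × drought), 1 df;

each a χ² LRT; the AIC of both models in a comparison is reported
(whether the published tables print the simpler or the more complex
model's AIC is not decidable from them, so both are labeled). Group
means use Wald 95% intervals from the REML fit (a deliberate, portable
simplification relative to Satterthwaite-based intervals, expected to be
slightly narrow in small samples). No multiple-testing correction is
applied across the 14 traits, matching per-trait reporting convention;
this is a documented choice, not an oversight.

**Numerical care at the variance boundary.** For traits with ~zero
random-effect variance the quasi-Newton optimiser can stop short of the
optimum while reporting convergence, which corrupts likelihood-ratio
differences. Fits suspected of this (a variance component below 10⁻³ of
the residual variance, or non-convergence) are polished by direct-search
refits, and every ML fit is floored by the OLS likelihood — the exact ML
solution when all variance components are zero. Zero-residual-variance
data (e.g. a zero-dispersion simulation) short-circuit to OLS with zero
variance components, flagged `degenerate`.

The sap-flow comparison is a classical pooled-variance two-sample
two-tailed t-test on per-tree accumulated totals (the published report
prints only per-plot totals, 198 vs 87 mm; per-tree totals are
synthesized around those means where needed), plus the percent
difference of group means.

## Simulation-based validation

The published per-trait p-values are not reproducible without the raw
data, so the inference machinery is validated on the generator:

* **Type-I error** of the drought LRT under the no-drought calibration:
  500 replicates at 30 trees per plot; empirical rejection at nominal
  0.05 must lie in [0.03, 0.07], and the null p-values must pass a KS
  uniformity check. The χ² calibration of this plot-level test is
  asymptotic in the number of *trees*: at the field design of 3 trees
  per plot it is markedly liberal (~0.17 in pilots) — the expected
  small-sample behaviour of likelihood-ratio asymptotics, which is why
  the calibration runs at the scaled-up design (type-I ≈ 0.055 in the
  pre-build pilot).
* **Power**: the study calibration has a built-in drought × canopy
  interaction for A_n (sun −17%, shade −3%); at 30 trees per plot the
  interaction LRT must detect it in ≥ 80% of 200 replicates (observed:
  ~100%).
* **Parameter recovery**: seed-averaged group means of d_max, N_t, A_n
  within 3% of targets at 30 trees per plot.
* **Coverage**: nominal-95% Wald cell-mean intervals cover the
  calibration truth in ≥ 90% of cells (Wald under-covers mildly).
* **Reproducibility**: the full pipeline bundle is byte-identical across
  re-runs at a fixed seed (the run manifest is timestamp-free by
  default; `--timestamp` opts in and intentionally breaks this).

Problem sizes (replicate counts, 30 trees per plot, 12 recovery seeds,
4 round-trip needles at 4 px/µm) are the package's chosen validation
scale: large enough for the asymptotics and acceptance bands above,
small enough to run routinely.

## Known limitations

* The generator reproduces group means and a plausible two-level
  variance structure, not the full covariance of real needle anatomy:
  within-needle diameter correlations, non-elliptical lumina,
  within-shoot position effects and genotype (family) effects are absent
  (family labels are carried as metadata only). Passing tests show the
  pipeline is correct and calibrated under these conditions, not that
  the field data satisfy them.
* Theoretical conductivity overestimates measured conductivity (real
  tracheid networks add end-wall/pit resistance); no attempt is made to
  model that, nor cavitation vulnerability.
* The exploratory "sun–shade gap shrink" summary depends on an
  aggregation convention (mean relative gap shrink over canopy-sensitive
  traits) that the reference report leaves unstated; it is reported but
  never used as an acceptance quantity.
* The printed reference means are rounded; derived statistics computed
  from them can differ in the last digit from statistics computed on
  unrounded data (e.g. the drought-plot sun/shade conductivity fold is
  2.6 from rounded means versus the reported "~2.5").
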