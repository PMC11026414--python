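# Methods

## The model

`vsprofile` treats a panel of protein missense variants as a spatial
dataset.  Each variant contributes one point in a two-dimensional plane:
its residue position normalized by the chain length (x = position / L,
default L = 418 for the alpha-1-antitrypsin preprotein) and one measured
phenotype on a normalized scale (y, e.g. secreted monomer with wild type
= 1).  A second phenotype z (e.g. neutrophil-elastase inhibitory activity)
is modelled as a realization of

    z(x, y) = mu + W(x, y) + eps,

with a constant unknown mean mu, a zero-mean spatially correlated field W,
and white noise eps.  The premise is that variants that are close in this
plane — nearby in sequence and with similar impact on the y phenotype —
perturb the fold in related ways, so their z phenotypes covary.

### Variogram

The spatial structure is summarized by the semivariogram.  For every
unordered pair of points the separation is the Euclidean distance h in the
(x, y) plane and the semivariance is gamma = (z_i - z_j)^2 / 2.  Pairs are
averaged in equal-width lag bins (default 12 bins up to half the maximum
pair distance; each bin reports mean, SEM and pair count).  Four isotropic
families are fitted by weighted least squares with pair counts as weights
and bounds c0 >= 0, c >= 0, 0 < a <= 2 max_lag:

| family      | gamma(h) - c0                    | effective range |
|-------------|----------------------------------|-----------------|
| spherical   | c (1.5 h/a - 0.5 (h/a)^3), h < a | ~0.82 a         |
| exponential | c (1 - exp(-h/a))                | ~3 a            |
| gaussian    | c (1 - exp(-(h/a)^2))            | ~1.73 a         |
| pure nugget | 0                                | 0               |

The *effective range* is reported as the distance at which gamma reaches
95% of the sill C(0) = c0 + c, so families are comparable; multiplied by L
it converts to a residue span (a normalized range of 0.11 on a 418-residue
chain spans 46 residues).

Model selection runs leave-one-out cross-validation of the kriging
predictor for each fitted family and keeps the family with the highest
Pearson r (ties broken by lower weighted RSS).  Two identifiability guards
apply, both of the package's own design:

* a winning structure whose effective range is below one lag-bin width is
  collapsed to pure nugget — structure below the resolution of the
  empirical variogram cannot be distinguished from noise;
* a structured family is only adopted if its LOOCV r is significantly
  positive (one-sided t test, p < 0.05).  Without evidence of predictive
  spatial covariance the honest model is pure nugget.  In simulations with
  iid z this guard is what keeps spurious weak structure (fitted partial
  sills of 10–20% of the nugget) from being reported as signal.

### Ordinary kriging

Predictions use the covariance form C(h) = C(0) - gamma(h).  For each
target u the weights solve the augmented system [[C_ij, 1], [1', 0]]
[w; mu_L] = [C_iu; 1], giving z*_u = sum_i w_i z_i with sum w_i = 1 and
kriging variance sigma^2_u = C_uu - (sum_i w_i C_iu + mu_L), clamped at
zero against round-off.  All n points enter every solve (no search
neighborhood: panels are desk-scale and truncation would add an
undocumented parameter).  The landscape grid places x at every residue
(i/L, i = 1..L) and y on 101 evenly spaced values spanning [0, 1.05
max(y)].  Exact duplicate (x, y) data are merged by averaging beforehand;
the solver refuses duplicate coordinates.

Leave-one-out cross-validation holds the variogram fixed across folds (as
common kriging cross-validation implementations do) and computes each
held-out prediction from the inverse of the full augmented matrix: deleting
point i is a rank-one downdate, so the fold prediction is z_i - (M z~)_i /
M_ii and the fold variance 1 / M_ii, where M is the inverse and z~ = [z; 0].
This is algebraically identical to the explicit removal loop (verified in
the tests) at O(n^3) total instead of O(n^4).  The Pearson r of held-out
predictions versus measurements gets a two-sided p from the t distribution
with n - 2 degrees of freedom (equivalent to the single-predictor ANOVA F
test).

### Confidence gating and barcodes

Kriging variances over the grid are bimodal — low near data, approaching
the sill in the far field.  A two-component Gaussian mixture (EM, best of
10 restarts, seeded; values sorted first so the fit is order-invariant) is
fitted on the raw variances, and the mean of the low-variance component is
the high-confidence cutoff; contour levels descend from the cutoff in steps
of that component's SD while positive (the same level set is exported on
the SD scale as its square roots).  If the two component means collapse
(closer than 1e-3 of the spread) the data is effectively unimodal and the
overall mean is used with a warning.

Each residue column of the masked landscape is collapsed by inverse
variance weighting, z_hat = sum(z_i / s_i^2) / sum(1 / s_i^2) over
high-confidence cells, with weights capped at 1e12 for variances below
1e-12.  A column with no high-confidence cells is NA by default (an
`all`-cells fallback exists but is off: the gate is the point of the
procedure).  Condition deltas are oriented so positive means improvement
(treated - basal for monomer/activity, basal - treated for polymer), and
the activity-to-monomer ratio barcode is formed per condition from the two
IVW barcodes and then differenced (cells are not divided before
aggregation; the ratio of smoothed quantities is the better-conditioned
convention and is recorded in output metadata).

### Bayesian parameter averaging

To propagate variogram-estimation error, the selected family's (c0, c, a)
get a flat prior on a bounded 15x15x15 grid around the WLS fit (nugget
[0, max(2 c0, 0.1 sill)], partial sill [0.25 c, 2.5 c], range [0.25 a,
3 a]).  Each node is weighted by the GP marginal likelihood with the
constant mean integrated out under a flat prior (GLS profile plus the
log(1' C^-1 1) term), computed in log space.  The Bayesian landscape is the
posterior-weighted mean of per-node kriging surfaces; its variance is the
weighted within-node variance plus the between-node variance of the
predictions (law of total variance), hence never smaller than the average
fixed-model variance.  For tractability the average uses the top-weighted
nodes covering all but 1e-8 of the posterior mass, capped at 400 nodes; a
point-mass posterior reproduces the fixed-model landscape to 1e-10.
Agreement between the Bayesian and fixed-model results is quantified as
Pearson r over grid predictions and over IVW barcodes computed with one
shared confidence gate (the fixed-model landscape's mixture), so that the
comparison isolates prediction differences from gate placement.

### Variant-level statistics

Independent of the landscapes: activity classes I (< 0.75 of WT), II
(0.75–0.90, boundaries inclusive) and III (> 0.90), with polymer strata
high (> 0.50 of the Z polymer reference) and low; responder calls by
two-sided pooled-variance Student's t on replicate arms (n = 3 typical;
zero pooled variance degenerates to p = 1 for equal means, p = 0 flagged
otherwise); and Fisher-z comparison of two Pearson coefficients,
(atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)) against the standard
normal.  No multiple-testing correction is applied across variants.

### Structure projection

Residue barcodes are written into PDB B-factor columns 61–66 (%6.2f) by
fixed-column text editing, leaving every other byte of the file unchanged.
Full-length (preprotein) numbering is reconciled with mature-structure
numbering by an offset (default 24: full-length residue 366 is structure
residue 342).  NA residues receive a 0.00 sentinel and are listed in the
run summary; an optional clamp linearly rescales out-of-window values.

## The synthetic generator

`vsprofile.synthetic` draws panels with exactly the structure the analysis
assumes: positions uniform over the chain (without replacement when the
panel fits), y iid Uniform(0, 1) by default (a latent-field y mode exists),
and z = mean + W + noise where W is drawn by Cholesky factorization of the
full-sill covariance (nugget on the diagonal, 1e-10 jitter).  Defaults
emulate the study conditions: 76 variants on a 418-residue chain,
triplicates with replicate SD 0.05 on the WT-normalized scale (the studies
report tight triplicate assays but no noise magnitude; 0.05 is this
package's choice), panel mean 0.73 (a realistic mean activity for a panel
dominated by partially defective variants), and an exponential variogram
with nugget 0.05, partial sill 1.0, range 0.3.  Condition pairs share the
underlying standard-normal draws by default, so treatment effects
(rescaled range/sill, shifted mean) are compared within matched
realizations — mirroring measurements of the same variants under vehicle
and drug.

What the generator does not emulate: assay-specific error structure (plate
effects, heteroscedasticity), biological pleiotropy linking y and z beyond
the shared field, non-missense variants, or any relationship between amino
acid identity and effect size.  Tests passing on these panels show the
inference machinery is correct under its own assumptions, not that real
variant panels satisfy them.

## Numerical choices and problem sizes

Cholesky jitter 1e-10; duplicate (x, y) synthetic draws re-jittered in y by
1e-6; kriging variance clamped at 0 (values below -1e-6 would warn);
weights checked to sum to 1 within 1e-8; mixture EM reg_covar 1e-12.
Simulation-based tests use panels of 30–300 variants and grids of up to
418 x 101 cells; Monte-Carlo claims are judged over 10–20 fixed seeds.
The acceptance script reproduces the Bayesian/fixed agreement on 76-variant
panels over 5 seeded replicates and reports medians.

## Known limitations

* Range and sill of a long-range field are only weakly identifiable from a
  single realization on a bounded domain: with an exponential range
  parameter of 0.3 on a ~1.4-wide domain the realized variance fluctuates
  by ~30% across realizations, so fitted sills (and with them effective
  ranges) scatter accordingly.  This is a property of the estimation
  problem (under infill asymptotics only c/a is micro-ergodic), not of the
  implementation; the parameter-recovery stress test documents it.
* The y coordinate is used as measured; its own measurement error is not
  propagated into the distance metric.
* The mixture gate assumes the variance field is two-regime; landscapes
  with data spread very evenly can be effectively unimodal, in which case
  the overall-mean fallback applies.
* Bayesian averaging explores a bounded box around the WLS fit; a fit that
  is badly wrong is not rescued by the posterior.
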