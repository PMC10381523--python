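# Methods

## The modeling problem

Seven commercial intra-oral bone-substitute materials (bovine and porcine
bone minerals, a nanocrystalline hydroxyapatite paste, β-TCP, biphasic
calcium phosphate, and porous titanium granules) were characterized by
chemical composition (wt% of HAp, β-TCP, CaCO₃, collagen, H₂O, Ti),
macroporosity (colonized-area fraction, %), and profile surface roughness
(Pa, Pq, Pt in µm), and implanted in a rabbit sinus-lift model. The in vivo
outcome modeled here is the bone-to-material contact (BMC) at six months:
the percentage of particle perimeter in direct contact with newly formed
bone. The package links the physico-chemical predictors to BMC with partial
least squares regression (PLSR) and reproduces the three published modeling
scenarios.

Only group summaries (mean ± SD) are available, so the response is the
seven (or six) group means — an n-of-7 regression. PLSR is the appropriate
tool precisely because n ≈ p and the predictors are strongly coupled.

## PLSR engine

Univariate-response NIPALS with closed-form components. Predictors and
response are centered; by default both are scaled to unit variance (SD with
the n−1 denominator). For component a = 1..A on the deflated residuals
(E, f):

    w_a ∝ Eᵀf (unit norm),  t_a = E w_a,
    p_a = Eᵀt_a / t_aᵀt_a,  q_a = fᵀt_a / t_aᵀt_a,
    E ← E − t_a p_aᵀ,       f ← f − q_a t_a.

The scaled coefficient vector is b = W (PᵀW)⁻¹ q; back-transforming gives
the original-scale equation β_j = b_j·s_y/s_{x_j}, β₀ = ȳ − Σ β_j x̄_j,
which reproduces the model's predictions exactly. Scores are mutually
orthogonal by construction, and at A = rank(X) the coefficients coincide
with ordinary least squares (both verified in the test suite against
independent oracles: an iterative NIPALS re-implementation, the normal
equations, and scikit-learn's PLSRegression).

Numerical choices:

- **Component truncation.** Extraction stops when the residual weight
  vector or score norm falls below 1e-10 of the initial block norm (rank
  exhausted). Without this, rank-deficient cross-validation folds produce
  numerically exploded components.
- **Constant columns.** At the top level a zero-variance predictor is an
  error that names the column. Inside cross-validation folds a column that
  degenerates to a constant (the titanium content when the only
  Ti-containing material is held out) is treated as *inert*: its scale is
  set to 1, the centered column is identically zero, and it receives a
  coefficient of exactly 0 — the standard-scaler convention. An A is
  flagged invalid only when an entire fold design is constant. This is the
  only reading under which leave-one-out is defined at all on the
  all-materials design.
- **Tie-break.** Component selection is the argmin of the LOO RMSE curve;
  exact ties resolve to the smaller A.
- **RMSE convention.** All n held-out residuals are pooled before the
  single square root (denominator n).

## Cross-validation and component selection

Leave-one-out: each material is held out once and predicted by a model
refit on the remainder (preprocessing recomputed inside the fold). The
component count is chosen by the minimum of the RMSE curve over
A = 1..min(p, n−2). On the all-materials design the curve is nearly flat
between two and three components: under the nominal composition convention
the minimum falls at A = 2 (matching the published choice of two latent
components); under the rescaled default A = 3 wins by about 0.1%. Both
results are recorded in the acceptance suite.

## Composition conventions

The composition table is textual for the composite grafts, so two
coercions are supported (a config switch):

- **rescaled** (default): BioOss-Collagen = 90% BioOss mineral + 10%
  collagen with all mineral fractions rescaled (HAp 84.24, CaCO₃ 3.06,
  collagen 12.7);
- **nominal**: keep the printed CaCO₃ 3.4 wt% for the mineral phase.

MP3's "bone mix" is coded as pure HAp (90%) + 10% collagen; its
pre-hydration water and trace phases are not quantified by the manufacturer
and are set to 0. The water term of the CaP-only model is driven by the
paste (65 wt% H₂O) alone. Particle size is stored as an interval and never
used as a numeric predictor.

## Scenario models

Three scenarios mirror the published models: all seven materials
(predictors CaCO₃ wt%, Ti wt%, macroporosity), calcium-phosphate materials
only (titanium graft excluded; CaCO₃ wt%, H₂O wt%, macroporosity), and
paste-free (aqueous paste excluded; same predictors as the first). A fourth
model is mentioned in the source narrative without a printed equation; the
free-form scenario API (custom predictor/exclusion sets) covers such
variants without guessing its identity. Reports carry the back-transformed
equation, the CV curve, held-out predictions, fitted values, residuals
(measured − fitted, exactly), and predicted-vs-measured Pearson r in both
modes.

**Correlation modes.** Reports always include both the cross-validated
correlation (`r_loo`, computed from the held-out predictions at the
selected A) and the in-sample correlation (`r_fitted`). The headline
default is the cross-validated value, the statistically conservative
choice. Measured on this data the two differ substantially: r_loo ≈ 0.69
for every scenario, convention and scaling variant, while r_fitted is
0.94 (all materials), 0.86 (CaP-only) and 0.91 (paste-free). The published
"80% correlation" for predicted-vs-measured BMC lies in the fitted-mode
range and is not attainable by any cross-validated variant we computed;
the package keeps the conservative default and reports both numbers so the
discrepancy stays visible.

**Backward elimination.** A threshold-free audit trail for predictor
selection: drop the lowest-VIP (or lowest |standardized coefficient|)
predictor, re-select A by LOO, stop when the best LOO RMSE increases.
Starting from the full ten-predictor pool on the builtin table this retains
a six-predictor superset of the published {CaCO₃, Ti, macroporosity} set —
recorded as a characterization, since small-n LOO curves are nearly flat
and the published iteration protocol is not specified.

**Extrapolation guard.** `predict_new` flags inputs outside the training
min/max box; the equations are affine and extrapolate linearly, which is
meaningful only near the training hull (CaCO₃ ≤ 3.4 wt%, macroporosity
15.8–70.2%).

## Image quantification

**Binarization** — Otsu's threshold by default (backscatter contrast:
mineral ≫ resin), fixed threshold for reproducibility. All-material or
all-background results are degenerate-mask errors.

**Profile extraction** — stylus-like outer envelope: for each scan column
the distance from the scan edge to the first material pixel. Pores opening
to the surface deeper than the first hit are invisible by construction.
Columns without material are dropped and flagged rather than interpolated
(no invented surface). Heights are converted to µm with the
outward-positive sign convention and referenced to the arithmetic mean
plane. Optional form removal before referencing: a least-squares line
(tilt) or a least-squares circle (Kåsa fit) for granule silhouettes whose
nominal form is circular — form removal before computing primary-profile
parameters is standard profilometry practice, and the circle mode is what
makes roughness on a curved granule boundary measurable at all.

**Roughness parameters** — unfiltered primary-profile definitions:
Pa = (1/n)Σ|y_i|, Pq = √((1/n)Σy_i²), Pp = max y, Pv = min y, Pt = Pp − Pv.
The 40 µm minimum evaluation length is a quality warning, not an error.
Image sets aggregate per-image parameters as mean ± SD (n−1); per-image
failures are collected and only fatal if all images fail.

**Macroporosity** — exact pixel counting: 100·|colonized|/|zone|, with
shape, emptiness and subset checks. ROI definition is left to the mask
supplier.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
the imaging physics:

- `gen_table` — X uniform per column in its ranges (default (0, 100), the
  wt%/percent scales of the study's predictors), optionally rank-deficient
  through latent factors; y = β₀ + Xβ + N(0, σ²). Noise acts on the
  response only: the study's measurement SDs sit on both sides, so passing
  recovery tests demonstrates estimator correctness, not robustness to
  predictor noise (a documented limitation).
- `gen_study_table` — schema-valid records: compositions on the 100%
  simplex (apatite-dominated Dirichlet draw), ordered roughness triples,
  and a known linear BMC model, so dataset IO and the modeling path can be
  exercised end-to-end.
- `gen_granule_image` — a filled quasi-circular granule whose boundary
  radius is base + order-2 waviness + a sinusoidal roughness term of known
  amplitude A, with closed forms Pa = 2A/π and Pq = A/√2 attached as ground
  truth. The roughness wavelength is snapped to an integer number of
  periods around the circumference (continuous boundary); the effective
  wavelength is reported. Default geometry: 480² pixels at 0.25 µm/px,
  45 µm base radius, A = 1.2 µm, λ = 8 µm — the apex window used for
  recovery spans ≈69 µm, comfortably above the 40 µm minimum. Measured
  recovery through binarize → envelope → circle detrend → parameters is
  within ~2% of the closed forms (10% is the asserted bound). No ESEM
  texture, noise, or partial-volume effects are simulated.
- `gen_mask_pair` — colonized masks with exactly round(target/100·area)
  pixels, so the area fraction is recovered to within half a pixel's worth
  of percent.

All randomness flows through `numpy.random.default_rng` (PCG64) under the generator
spec's seed; identical specs produce identical artifacts.

## Problem sizes

Everything runs in seconds: the study designs are 6–7 rows, the synthetic
recovery table is n = 50, the full-rank-equivalence sweep uses 100 random
designs with n ≤ 12, p ≤ 4, and the granule images are 480² pixels.

## Known limitations

- The source software's preprocessing (centering-only vs autoscaling) is
  unknown; both are supported and the published equations are matched
  within a ±25% characterization band (sign agreement exact; several
  coefficients agree to print precision at specific component counts:
  the all-materials and paste-free equations at A = 1, the CaP-only
  equation at A = 2).
- Group means stand in for the unpublished per-sample histomorphometry;
  uncertainty in the predictors is ignored.
- The envelope tracer measures one profile line per image/direction;
  multi-line pooling is a settings choice, not a default.
- Roughness of re-entrant (overhanging) boundaries is under-measured by
  any single-direction envelope.
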