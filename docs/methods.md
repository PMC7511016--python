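# Methods

This note documents the models implemented in `denscape`, the assumptions
behind the synthetic-landscape generator, and the numerical choices made
where the underlying methodology leaves a convention open. Every number
quoted here is computed by the test-suite or by `scripts/acceptance.py`.

## The selection model

Den-site selection is modelled with an exponential resource selection
function (RSF), `w(x) = exp(β₁x₁ + … + βₙxₙ)`, estimated by logistic
regression contrasting used den locations (coded 1) with random available
points (coded 0). Availability is sampled at the whole-study-area scale
(second-order selection) at 500 points per km², and all dens are pooled at
the population level (Design II). Two consequences follow:

- the intercept only reflects the arbitrary used:available ratio; it is
  estimated but never interpreted and never used in prediction, so the RSF
  surface is a *relative* probability of selection;
- because the available points are drawn uniformly over the unmasked area,
  the log density ratio of used to available points is exactly linear in
  the covariates, and the logistic slope estimates are consistent for the
  β of the exponential RSF without any rare-use approximation.

All covariates are standardized — `(x − x̄)/SD(x)` — against the available
sample before fitting; the availability sample *defines* the habitat on
offer, so its moments are the natural reference (using used+available or
all raster cells instead would only rescale coefficients). The
standardization parameters are stored on the covariate stack for inverse
transforms.

### Covariates

| name | meaning | units / range | notes |
|---|---|---|---|
| `dtm` | elevation | m | from the terrain model |
| `slope` | Horn 3×3 finite-difference slope | degrees [0°, 90°) | edge cells nodata |
| `tpi` | elevation minus mean elevation within a 140-m circular window | m | centre cell excluded; positive = convex |
| `vrm` | 1 − (resultant of unit surface normals)/N over a 15-m window | [0, 1] | 0 = smooth; flat cells contribute the vertical normal |
| `twi` | ln(specific catchment area / tan slope) | dimensionless | MD8 flow routing after pit filling; tanβ floored at tan 0.1° |
| `solrad` | clear-sky daily solar on the tilted surface, 1 April, 59.3° N | Wh m⁻² day⁻¹ | direct (air-mass transmittance 0.7) + isotropic diffuse (fraction 0.3), 15-min steps, self-shading only |
| `snow.load` | scaled elevation × leeward exposure | [0, 1] | exposure `(1 + cos(aspect − 315°))/2`, maximal opposite the 135° prevailing wind; flat cells get 0.5 |
| `vhi` | surface model − terrain model | m | canopy proxy; > 5 m treated as forest and masked |

Conventions fixed where the lineage tools do not print a formula:

- **TPI** excludes the centre cell ("surrounding cells"); including it
  would only rescale the index. The elevation-difference definition is
  used throughout (an alternative slope-based description exists in parts
  of the lineage but is not self-consistent).
- **Snow-load exposure** uses the cosine form above: it is the simplest
  function that is standardized to [0, 1] and maximal exactly opposite the
  prevailing bearing.
- **TWI** uses Freeman MD8 multiple-flow-direction routing (exponent 1.1)
  on a priority-flood pit-filled surface; a D8 single-direction variant is
  kept as the simple oracle for tests.
- **Solar radiation** is a daily integral, not an instantaneous value, and
  models self-shading only (no cast shadows). Only the relative ordering
  of cells matters to the RSF, and the aspect/slope signal survives both
  simplifications.
- **Edge policy**: moving-window metrics use whatever neighbours exist;
  the study-area mask applied downstream governs validity. Horn slope and
  aspect are nodata on the one-cell border.

### Study-area mask and design table

A cell belongs to the study area when its centre is within 1,500 m of the
survey route, its elevation is ≥ 300 m, its VHI is ≤ 5 m (not forest), and
it is not glacier. Raster cells are half-open
(`[x₀, x₀+cs) × (y₀−cs, y₀]`), so every point belongs to exactly one cell
and the den simulator's within-cell jitter is exactly invertible. Available
points are uniform over the *continuous* unmasked area (uniform cell, then
uniform within-cell offset). Covariate extraction is containing-cell
lookup; rows hitting nodata are dropped with a logged count (an error above
10% loss in strict mode). A collinearity screen reports pairwise Pearson
|r| ≥ 0.7 and VIF ≥ 2 but never drops covariates automatically — the
candidate set is fixed a priori, and silent removal would change it.

### Candidate set and fitting

Eighteen a-priori models from six hypothesis families (terrain;
terrain+vegetation; terrain complexity; dry-snow climate;
thermal-insulation climate; combined terrain–climate) are fitted and ranked
by AICc (`−2ℓ + 2k + 2k(k+1)/(n−k−1)` with n = all rows, k including the
intercept; ties break toward fewer parameters, then lower id). Where the
published family descriptions are ambiguous about which optional quadratic
terms a variant carries, the reconstruction matches each model's published
term count, taking quadratics in the family's listed factor order; one
published count (model 12, K = 12) exceeds what its factor family can
produce and is implemented as the family's full 10-term variant.

Fitting is maximum-likelihood IRLS with step halving: the Newton step is
accepted only if the log-likelihood does not decrease, which keeps
ill-conditioned quadratic terms from overshooting. Convergence is declared
on a small step (max |Δβ| < 1e−8) *or* on a deviance plateau (relative
log-likelihood change < 1e−10, the glm convention) — the latter matters
because sparse covariates such as VHI on a nearly bare landscape can put a
coefficient on a monotone-likelihood ray; the fit then stops at the plateau
with an enormous Wald SE, which is the honest statement of that
coefficient's information content. Complete separation (log-likelihood at
zero) and singular designs (aliased terms are named) are errors. Standard
errors are Wald from the inverse observed information; 95% CIs are
β ± 1.96 SE, and a coefficient is flagged non-informative when its CI
crosses zero. The used:available imbalance is fitted as-is, without case
weights.

## Validation

Binned k-fold cross-validation: per iteration the used points are shuffled
into 5 folds; for each fold the model is refitted on the remaining dens
plus *all* available points; available-point RSF scores are cut into 10
equal-count bins; expected proportion per bin = bin mean score / Σ bin
means; the observed proportion is the share of held-out dens per bin (same
breakpoints, ties to the lower bin); ρ is the Spearman rank correlation of
observed vs expected. The per-iteration statistic averages ρ over folds
(pooling held-out dens across folds before a single ρ is available as an
option), and the procedure repeats for a configurable number of random
re-partitions (the "iterations"). Scores are computed as
`exp(η − max η)` — a common positive rescaling that leaves both ranks and
bin-mean proportions untouched while preventing overflow from extreme
fitted coefficients.

Two behavioural anchors, both verified by the acceptance tests on 500
simulated dens: under the generating model the mean ρ exceeds 0.9; under
uniformly placed dens (no selection) it is near zero. A subtlety worth
recording: even under the null, this procedure has a mildly positive
expectation (≈ +0.1–0.2), because the folds partition a *single* realised
den draw — the chance covariate lean of that draw is shared between the
training and held-out subsets, and the refit "recovers" it consistently.
The null test therefore averages over several independent den draws; the
effect is intrinsic to within-sample cross-validation, not an artifact of
this implementation.

## Habitat classes and risk surface

The RSF surface is classified into five classes of equal pixel count
(breakpoints at the 20/40/60/80 order statistics, upper-inclusive; heavy
ties that make an equal split impossible are an error reporting the
achievable split). "Prime" denning habitat is the union of the top two
classes — 40% of the study area by construction. Classification depends
only on ranks, so it is invariant under any strictly increasing transform
of the surface.

Helicopter-use intensity is a bivariate Gaussian product-kernel density of
the flight fixes evaluated exactly on the raster's cell centres.
Coordinates are standardized per axis and a single bandwidth multiplier h
is chosen by golden-section search on log h minimizing the least-squares
cross-validation score

LSCV(h) = ∫f̂² − (2/n) Σᵢ f̂₋ᵢ(xᵢ),

both terms in closed form for Gaussian kernels (pairwise distances are
evaluated in row chunks so the 9,790-fix case stays within memory). The
per-axis bandwidths are (h·SDx, h·SDy), floored at one cell size with a
warning when duplicate-heavy data drive LSCV toward zero. The impact-risk
surface is the cellwise product of the *raw* intensity and the *raw* RSF
(multiplying the 1–5 class grids instead is available but not the
default), then classified into five quantile classes. Overlap summaries
report prime-habitat area and den counts inside/outside permit polygons,
den counts per risk class, and distance to the nearest permit boundary for
in-bounds dens; percentages are always computed from raw counts or areas
first and rounded (half away from zero) last.

## The synthetic landscape

The generator emulates a coastal-mainland alpine study area; all defaults
are fixed study conditions, not tuning knobs:

- terrain: Fourier spectral synthesis (amplitude ∝ f^−1.8) rescaled
  exactly to 300–2,048 m on 5-m cells;
- forest line: mean 480 m, SD 168 m (a smoothed Gaussian field clipped at
  ±2 SD); canopy follows a logistic profile of depth below the line with
  a 25-m ceiling and a 40-m krummholz taper, so cells 200 m below the
  line carry > 5 m canopy and high-alpine cells carry < 1 m;
- glaciers: the highest `glacier_fraction` of cells; survey route: a
  smoothed path tracking the mid-elevation band; heliports: separated
  low-elevation sites, with permit areas as discs of the operating radius
  (a synthetic stand-in for administratively drawn permit units);
- flight fixes: an equal-weight Gaussian mixture on the heliports with a
  per-heliport elongation axis (repeated ski runs);
- dens: drawn *without replacement* at cell level with probability
  ∝ exp(βx) via Gumbel top-k (exact successive sampling), then jittered
  uniformly within the cell. The reference truth echoes field-scale
  magnitudes on the 8-term terrain+dry-snow structure:
  β = (−1.91, −1.78, 0.64, −0.17, 0.23, −0.37, 0.18, −0.48) for
  (dtm, dtm², slope, slope², snow.load, twi, vhi, vrm), with 89 dens in
  the headline configuration and 500 in recovery experiments.

What the generator does **not** emulate: physically based snow
redistribution, temporal den reuse, bear movement, spatially clustered
(non-independent) den placement, observation error in den coordinates, and
land-cover classes. Passing recovery tests therefore demonstrate that the
estimation machinery is correct under the stated sampling model, not that
field data of this kind would identify the same coefficients.

## Problem sizes and determinism

Recovery experiments use 256×256-cell landscapes (1.28 × 1.28 km at 5-m
cells, ≈ 750 available points at 500 per km²), 100 replicates: 95% Wald
CIs cover each true β in ≥ 90/100 replicates and AICc ranks the generating
model first in ≥ 80/100. Validation experiments use a 384×384-cell
landscape (≈ 1,700 available points), 20 fold-resampling iterations. The
reproduction script (`scripts/acceptance.py`) runs one 256×256 study with
89 dens and 9,790 flight fixes. Every generator and every stochastic
procedure is a pure function of an explicit seed; the acceptance script
derives all stage seeds from its single `--seed` argument.

## Known limitations

- The logistic MLE carries small-sample bias at few hundred availability
  points; recovery experiments show it is negligible at the sizes above
  but visible (≈ 0.05–0.1 on a coefficient of 1) on very small
  landscapes.
- Quasi-separated coefficients (e.g. VHI on a bare landscape) stop at a
  deviance plateau with huge SEs rather than being penalised
  (Firth-style); that matches the glm-family behaviour the analysis
  chain is modelled on.
- The LSCV objective is evaluated under a single bandwidth multiplier on
  standardized coordinates; fully independent per-axis bandwidths are not
  searched.
- No spatial autocorrelation correction is applied to the RSF; dens are
  treated as independent, as in the underlying design.
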