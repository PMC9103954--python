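# Methods

`steamhybrid` implements a two-stage framework for daily air-pollution
exposure assessment: a semiparametric spatio-temporal land-use regression
(ST-LUR) in the first stage, and combination ("hybrid") models in the second
stage that fold in predictions from independent methods such as dispersion
modelling or ensemble machine learning. Everything is exercised on seeded
synthetic monitoring data with known ground truth, so the statistical
properties of the estimators can be tested directly.

## The ST-LUR model

For pollutant concentration $y_{it}$ at site $i$ on day $t$, the model on the
link scale $f(y_{it})$ ($f=\log$ for NO₂/PM-like pollutants, identity for an
O₃-like pollutant that is approximately normal) is

$$
f(y_{it}) = \beta_0 + W_{it}^\top \beta + \sum_l f_l(S_{l,it})
          + h(x_i, y_i) + \varepsilon_{it},
\qquad \varepsilon_{it} \sim N(0, \sigma_\varepsilon^2),
$$

where $W$ collects covariates with linear effects (buffer traffic load, road
length, urban share, inverse road distance, calendar indicators), $f_l$ are
univariate penalized splines of covariates with smooth effects (meteorology,
within-year day count) and $h$ is a bivariate penalized smooth of the planar
site coordinates absorbing residual spatial correlation. Study-year indicator
variables are always included when the panel spans more than one year.

### Penalized-spline engine

Smooths are P-splines: cubic B-spline bases on equally spaced knots with a
second-order difference penalty, sum-to-zero centring constraints absorbed by
a null-space reparameterisation. The spatial smooth is a tensor-product
P-spline with an isotropic penalty $S_x \otimes I + I \otimes S_y$ and a
single smoothing parameter — appropriate because both coordinates are in
metres. Smoothing parameters are chosen by Gaussian REML (profiled over
$\sigma^2$; Nelder–Mead over the log smoothing parameters with a bounded
search window $\log\lambda \in [-7, 16]$) or by GCV where that criterion is
called for. Effective degrees of freedom come from the trace of the hat
matrix and feed the adjusted-R² used throughout. A tiny adaptive ridge
(≈1e-10 relative) keeps the normal-equations factorization viable under
exact collinearity in degenerate designs.

A design choice worth flagging: back-transformation from the log scale is
plain exponentiation without a smearing correction, a small known bias source
for log-scale models.

### Forward selection

From a base model (intercept, spatial smooth, year indicators, any forced
terms) the algorithm repeatedly evaluates each unused candidate in both its
linear and spline form, refitting the whole model each time, and adds the
candidate with the largest adjusted-R² gain provided

* the gain exceeds 0.01 **absolute** adjusted-R² units (the common LUR
  convention for a "1 %" rule), and
* a sign-constrained spatial covariate entering linearly has the declared
  direction of effect (traffic and urban covariates must be positive);
  candidates violating the constraint are skipped in that form.

Ties are broken by candidate-list order, which makes selection fully
deterministic given the data. Selection stops when no candidate clears the
threshold. The linear-vs-spline choice per candidate is decided by
adjusted-R² at that step; spline smoothness is re-estimated by REML at every
trial fit, warm-started from the incumbent model's smoothing parameters.

## Hybrid combination models

**Hybrid 1** forces a univariate penalized spline of each auxiliary
prediction channel (dispersion-like, ensemble-ML-like) into the ST-LUR base
model before selection runs. The "spatio-temporal smooth" of the auxiliary
predictions is read as a univariate smooth of the prediction value (the
reading consistent with method weights varying along the concentration
range); a tensor interaction with the coordinates is possible but not the
default. With all channels removed the code path is exactly the standalone
ST-LUR, which realises the stated nesting (auxiliary coefficient = 0 ⇒
non-integrated model).

**Hybrid 2** is a Gaussian GAM of the *untransformed* concentration on one
penalized-spline transform per input channel, with smoothness chosen by GCV.
Channels that saw the response during their own fitting (the LUR, any ML
method) enter as leave-site-out cross-validated predictions; the dispersion
channel enters raw. Channel terms are constructed in sorted-name order so
predictions are invariant to the order the caller lists them.

**Ensemble combiner** — a GAM with one REML smooth per learner-prediction
channel plus a bivariate coordinate smooth. The learners themselves are
pluggable sklearn regressors; a convenience routine produces leave-site-out
predictions from a small grid-searched zoo (gradient boosting, random
forest, k-nearest neighbours) selected on CV mean-squared error. The module's
contract is the combiner, not the learners.

Predictions of channel smooths outside the fitted channel range are clamped
to the boundary basis with a warning. Consequence: under leave-site-out CV a
site at the extreme of the channel range retains a small extrapolation
error, so channel-smooth routes approach but do not exactly reach CV-R² = 1
even in the noise-free limit.

## Bias-correction surface (multilevel B-splines)

Model-minus-measurement discrepancies at scattered sites are interpolated by
a multilevel B-spline approximation: at each level a uniform cubic B-spline
control lattice (4×4 cells initially, doubling per level) is fitted to the
current residuals by the per-control-point weighted least-squares formula,
and the summed hierarchy is the surface. Two levels give a smoothly varying
correction that deliberately does **not** pin the model output to the
measurements; with points in distinct, mutually isolated finest-level cells
the hierarchy interpolates them essentially exactly by around eight levels.
The surface is fitted to mean-centred residuals with the mean carried as an
explicit constant offset, so a constant residual field is reproduced exactly
at any depth — the raw per-control-point formula alone would not do this
away from the data.

## Validation and agreement

Leave-site-out 10-fold CV partitions *sites* (uniformly, unstratified) into
balanced folds; each fold's model is fitted on the complement and predicts
every row of the left-out sites. Metrics on the concentration scale:

* **overall CV-R²** — squared Pearson correlation of pooled held-out
  predictions and observations (a 1−SSE/SST variant is available);
* **RMSE**, **mean bias** with the fixed convention observed − predicted;
* **temporal R²** — daily deviations from site-year annual means, predicted
  regressed on observed, pooled over sites;
* **spatial R²** — site-year annual-mean predictions regressed on annual-mean
  observations across sites.

Agreement between two prediction panels is summarised at the spatial level
(per-location annual means) and the temporal level (daily area-wide mean
series; a pooled-pairs mode exists) by Lin's concordance correlation
coefficient (population 1/n moments, per Lin's definition), Pearson's r, and
Bland–Altman mean difference with 95 % limits of agreement mean ± 1.96·SD
(sample n−1 SD, per the Bland–Altman convention).

## Synthetic data generator

The generator emulates an urban monitoring study on a 50 × 50 km planar
domain (metres, not degrees — the spatial smooth then has isotropic units):

* **Network** — uniform random background/traffic sites (default 100 sites,
  1 year of days; both configurable).
* **Covariates** — GIS-buffer-style variables built from cumulative
  non-negative ring increments, hence monotone across nested buffers;
  traffic sites draw systematically larger traffic covariates.
* **Meteorology** — seasonal sinusoid + AR(1) temperature, bounded humidity,
  gamma wind speed, integer cloud okta, near-1013 hPa pressure.
* **Truth** — model-scale sum of linear covariate effects, smooth
  meteorology effects (U-shaped temperature, log-dilution wind), a static
  spatially correlated Gaussian field (exponential covariance, drawn exactly
  at the site locations by Cholesky), day-of-week offsets, a within-year
  seasonal cosine, optional per-year offsets, and iid Gaussian noise
  (default SD 0.25 on the log scale); measurements back-transform through
  the link. The noise-free truth surface is returned for recovery tests.
* **Auxiliary channels** — scale·truth + spatially correlated additive bias
  field + iid noise, floored at 0.1 µg/m³; the dispersion channel is
  complete by construction.

The inter-site correlation range (default 12 km) is a free knob, not an
empirically anchored value. What the generator does *not* emulate: missing
data, instrument drift, spatially structured covariate error, realistic road
networks, atmospheric chemistry. Passing tests therefore demonstrate the
estimators' statistical behaviour under the model's own assumptions, not
performance on real monitoring networks.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale studies chosen as the package's own
defaults: nesting and coefficient-recovery checks at 100 sites × 365 days,
hybrid-improvement and selection checks at 20–30 sites × 60–100 days with a
six-candidate pool, the end-to-end acceptance pipeline at 60 sites × 150
days with 10-fold leave-site-out CV. Degenerate inputs (constant channels,
zero-variance columns) drop the corresponding smooth with a warning rather
than failing; zero-variance R²/CCC inputs raise informative errors. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`.

## Known limitations

* No smearing correction on log back-transformation.
* Errors are assumed independent; no temporal autocorrelation model.
* CV-R² by squared correlation rewards calibration-free linear association;
  use the SSE variant when absolute agreement matters.
* The boundary-clamping rule for channel smooths biases predictions at
  range-extreme sites (see above).
* The MBA lattice resolutions and domain padding are package defaults, not
  empirically anchored values.
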