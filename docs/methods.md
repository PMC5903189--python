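# Methods

This note documents the models, parameter choices and numerical
conventions behind `forestcarbon`, and what the synthetic study conditions
do and do not demonstrate.

## Sampling design and plot geometry

The design module encodes the arithmetic of a two-phase systematic cluster
survey. Forest clusters are selected 1-in-k starting at the **first**
cluster (indices 1, 1+k, 2k+1, …), giving ceil(n/k) selections — with the
shipped regime (999 forest clusters, k = 8) that is 125 clusters, 121 after
four access losses, and 121 × 6 = 726 subplots (12.1% of forest clusters).
Starting anywhere other than the first cluster would give 124 or 125
depending on phase; the fixed-first convention is the one consistent with
the regime's printed totals.

Each subplot is four nested concentric circles: stems are enumerated in
the 4, 8, 15 or 20 m circle according to half-open dbh classes
[5,10), [10,20), [20,30), [30,∞) cm. Half-open boundaries honour printed
class limits such as "20–29.9" without gaps or overlaps. Stems under 5 cm
are not enumerated anywhere and never reach any aggregate. A tally in a
circle of radius r converts to a per-hectare rate with the standard
area-ratio expansion factor 10⁴/(πr²); by construction
area(r) × factor(r) = 10⁴ exactly. Subplot coordinates are planar metres
relative to the cluster's grid knot (rows 150 m, columns 300 m apart); no
geodetic projection is attempted.

## Height–diameter model

Only every 5th tree (plus the first occurrence of any species otherwise
unrepresented) carries a measured height. Heights for all trees are then
predicted from a two-parameter saturating curve

h(d) = 1.3 + A·(1 − e^(−r·d)),

fitted per species group by nonlinear least squares
(`scipy.optimize.curve_fit`, bounds A ∈ [0.1, 150] m,
r ∈ [10⁻⁴, 2] cm⁻¹, start A = max(h) − 1.3, r = 0.05). The curve always
predicts above breast height for enumerable stems and is strictly
increasing, which is what the volume equation needs. Groups with fewer
than 3 height observations, or whose fit fails to converge, fall back to
a pooled model over all sampled trees (a fixed-effects, desk-scale stand-in
for the mixed-effects species-group models large inventories use). Measured
heights are kept for the sampled trees themselves; every other tree gets
the model prediction.

Under the synthetic conditions (n = 200 sampled trees, 10% multiplicative
height noise) the fit recovers the generating parameters with median
relative error below 10% over 20 seeds, and exactly (to optimizer
tolerance) in the noiseless limit.

## Volume, biomass, carbon

Stem volume is the species-specific log-linear allometry
ln v = a + b ln d + c ln h with d in cm, h in m, v in m³. The coefficient
`a` is implemented as the species intercept; descriptions of it as a basal
area are not usable as an equation and were set aside.

Biomass offers two modes. The physically meaningful default is
**volume-scaled**: M = v·ρ with air-dry wood density ρ in kg/m³. A
**literal** mode computing ln(v)·ρ is kept selectable because that form
circulates in print; it yields non-positive biomass for stems under 1 m³
(the package warns) and is almost certainly a typesetting artifact, which
is why it is not the default.

Air-dry mass converts to oven-dry mass with the fixed factor 0.91, and
oven-dry mass to carbon with a configurable fraction: presets 0.5 (the
volume-route convention, shipped default) and 0.47 (the biomass-route
convention). Both conversions are scalar multiplications, so they commute
and the whole chain is multiplicatively linear: scaling every tree's volume
by α scales subplot carbon by α exactly.

Per subplot, each stem's volume/biomass/carbon is multiplied by its
circle's expansion factor and summed (kg → t at aggregation); mean dbh is
the plain average over enumerated stems and tree count the raw tally. An
empty tree list produces an all-zero summary with a warning rather than an
error, so sparse subplots survive batch runs.

Note one arithmetic consequence of this chain: with realistic densities
(450–850 kg/m³) carbon is roughly 0.2–0.4 × stem volume, so a stand with
~154 m³/ha of stems carries ~45–55 tC/ha through this chain. Conventions
that apply a flat 0.5 directly to volume report higher figures for the
same forest; the fraction and route are configuration, not physics.

## Factor model

The analysis categorises subplot carbon's predictors at fixed cutpoints
(stem volume 91/199 m³/ha and dbh 27.1/43.4 cm — the survey regime's
quartiles; tree count at 20; altitude at 500/1000 m) with the middle
interval closed on both ends, so printed bounds like "91–199" include both
endpoints; two-level splits are `< b` vs `≥ b`. District-to-region grouping
is a user-supplied table (5 development regions over 25 synthetic district
codes by default).

The linear model uses sum-to-zero (deviation) coding built explicitly: an
L-level factor contributes L−1 columns (+1 own level, −1 last level, 0
otherwise), so level effects sum to zero, the last effect is recovered as
minus the sum, and the intercept is the grand mean of level means. The
least-squares fit itself is delegated to `statsmodels.OLS`; standard errors
use the unbiased residual variance, p-values are two-sided t, and
adjusted R² = 1 − (1−R²)(n−1)/(n−p−1). Rank-deficient designs abort with
the dependent columns named. Unobserved levels are dropped from the design
(fitting a level with no data is meaningless and would break rank).

Outlier handling follows the one-pass convention: fit, drop records whose
**raw** residual exceeds +40 tC/ha (one-sided — the rule targets the upper
tail a QQ plot flags; a two-sided option exists in configuration), refit
once. No iteration. Removal that would empty a factor level aborts with a
message. QQ coordinates use the plotting position (i − 0.5)/n on the normal
inverse CDF with residuals standardised to sample moments; constant
residuals degrade gracefully to a flat line.

Each level's adjusted mean is β₀ + eⱼ, i.e. the model's prediction with
every other factor balanced at its contrast zero. Its 95% CI is
cᵀβ ± t(0.975, n−p)·√(cᵀ·Cov(β)·c) with the exact linear-combination
variance. Classification against the overall mean (the mean carbon of the
analysed, post-removal records): CI entirely above → *above*, entirely
below → *below*, otherwise *around*; an endpoint exactly equal to the mean
counts as *around*.

## Synthetic study conditions

The generator's defaults are the emulated survey's regime, fixed once:

| quantity | default | basis |
|---|---|---|
| clusters × subplots | 121 × 6, 632 on forest land, 476 analysed | survey accounting |
| trees per subplot | round N(19.5, 8.8²), floor 1 | survey mean/sd |
| tree dbh | 5 cm + Weibull, mean 36.35, sd 14.24 cm | survey moments |
| altitude | 124 + 1508·Beta(1.1, 3.16) m (mean ≈ 513, sd ≈ 288) | survey range/moments |
| community ownership | Bernoulli(0.523) | survey share |
| regions | FW/MW/W/C/E with probs 3:5:4:7:6 / 25 | district grouping |
| stem volume (outcome route) | Gamma, mean 154.4, sd 86.45 m³/ha | survey moments |
| carbon truth | 30 + reference-coded effects (37.03, 82.70 / 12.66, 19.89 / −10.77 / 3.14, −3.51 / −1.29, 1.25, 1.17, 4.03 / −0.62) | reported effect magnitudes |
| residual sd | 13.6 tC/ha | calibration, below |
| outcome records | 477 (462 after the 15-record contamination scenario) | survey accounting |

The dbh law is a three-parameter (5 cm-shifted) Weibull with shape/scale
solved from the target moments; the shift enforces the enumeration floor
without truncation bias. The residual sd was calibrated once: a 200 000-row
draw of the default covariates gives the linear factor structure a variance
of S ≈ 963 (tC/ha)², and sd = √(S·(1−0.838)/0.838) ≈ 13.6 makes the model
explain ≈ 83.8% of outcome variance — the emulated survey's fit-quality
regime. Under the default truth the implied mean carbon is ≈ 77 tC/ha.

What the generator does **not** emulate: spatial correlation between
subplots of a cluster, realistic species composition, covariance between
stand predictors (stem volume, dbh and tree count are drawn independently
on the outcome route, whereas in real stands they are strongly dependent),
measurement error other than rounding, and any soil/litter carbon. Passing
tests therefore demonstrate the correctness and calibration of the
*procedures* under the stated conditions, not field accuracy on real
inventories.

One known limit of the conditions themselves: with residual sd 13.6 the
expected first-fit residual of a +60 planted outlier is ≈ 56.5 (shrunk by
its own leverage and by the mean shift the other outliers induce), so the
one-pass +40 rule detects ≈ 87–89% of them — slightly under a 90% bar —
while removing essentially no clean records. Larger shifts (e.g. +200 in
the accounting scenario) are detected exactly.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); a fixed seed reproduces byte-identical CSVs.
The shipped simulations use 476-subplot tree tables (~9 000 stems),
477-record outcome tables, 200 replicates for recovery/coverage and 50 for
calibration/detection; all of it runs in seconds on one CPU. The pipeline
writes a manifest (seed, full config snapshot, paths, timings, version)
sufficient to reproduce a run.
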