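# Methods

This note documents the statistical models, estimators and numerical
choices in `barkspat`, what the synthetic-study generator does and does not
emulate, and the known limitations.

## Setting and conventions

The bark surface of a log segment is unrolled to a planar rectangle:
x along the bole, y around the circumference with y = 0 at the upper rim.
No periodic wrap in y is applied (the data this mirrors were digitised
flat); attack coordinates are continuous cm, and two holes closer than
10⁻⁶ cm are rejected as duplicate records since entrance holes are physical
excavations.  Areas are kept in cm² internally and reported in dm²
(1 dm² = 100 cm²); densities are holes dm⁻².  Point-in-window tests are
boundary-inclusive with a 10⁻⁹ cm tolerance.  Spatial analyses run inside
the convex hull of the final pattern of a segment — the most compact convex
polygon containing all its holes — because attacks occupy only the
colonized patch, and using the full segment would dilute the intensity
estimate; per-census analyses reuse the *final* hull so the density
denominator is fixed along a trajectory.

## Summary-function estimators

**G (nearest-neighbour distribution).**  Reduced-sample (border)
estimator: with d_i the NN distance of point i and b_i its distance to the
window boundary, Ĝ(r) = Σ 1{d_i ≤ r, b_i > r} / Σ 1{b_i > r}.  For a
convex window, b_i is the minimum perpendicular distance to the supporting
lines of the edges, which is exact.  Where the erosion margin swallows
every point (denominator 0) the estimate carries its last defined value
forward and the position is flagged; the empirical G has saturated by
then, and the alternative (dropping to 0) injects spurious deviations into
integral test statistics.  The default grid is 512 equal steps on
[0, 20 cm]; 20 cm is safely beyond the interaction range of interest
(~2.5 cm) as a deviation-test upper limit should be.

**G′ (variance stabilisation).**  G′ = arcsin √G (Fisher's angular
transform).  For a binomial proportion this makes Var(G′) ≈ 1/(4m)
independent of G, so deviations at small r — where the inhibition signal
lives but G is small — carry the same weight as deviations at large r.

**K and L.**  Translation-corrected Ripley K,
K̂(r) = (A/n²) Σ_{i≠j} e_ij 1{d_ij ≤ r}, with e_ij = A / |W ∩ (W + x_j −
x_i)|.  On rectangles the set covariance |W ∩ (W+t)| has a closed form; on
convex polygon hulls it is evaluated once per window from the FFT
autocorrelation of a supersampled 256²-pixel window mask (fractional
coverage, bilinear lookup, normalised so e(0) = 1 exactly).  Against an
exact shapely polygon-intersection oracle the rasterised weights agree to
a few tenths of a percent, far below Monte-Carlo noise at the sample sizes
analysed.  L = √(K/π) linearises K (L(r) = r under CSR).  The isotropic
correction was not implemented; at the densities and window shapes
analysed the difference between translation and isotropic corrections is
second order.

**Replicate pooling.**  Ḡ(r) = Σᵢ Gᵢ(r)·n_{i,r} / n_r, where n_{i,r}
counts the points of replicate i farther than r from its boundary and
n_r = Σᵢ n_{i,r}.  Because the border estimator is a ratio of counts,
this equals pooling numerators and denominators directly, which is how it
is computed.  Replicates with fewer than two points carry zero weight.
With one replicate the pooled estimate reduces exactly to that
replicate's Ĝ.

## Monte-Carlo inference

**Null model.**  Complete spatial randomness (homogeneous Poisson).  For
*pointwise envelopes* the nulls are Poisson draws at the intensity
estimated from the pattern (count varies round to round, matching the
"CSR of density λ" convention for envelope displays).  For the *deviation
test* the nulls condition on the observed count (binomial processes): the
count carries no information about spatial arrangement under CSR, and
conditioning makes the test exact.  This was a deliberate design choice:
with Poisson-count nulls at an estimated intensity, the null counts carry
roughly twice the variance of the observed count (a Poisson mixed over a
Poisson estimate), which makes the test measurably conservative — the
p-distribution under CSR failed a χ² uniformity check at 500 runs.  With
count conditioning the check passes comfortably.

**Deviation test.**  U = ∫₀^rmax (T(r) − T̄(r))² dr by the trapezoid rule
on the r-grid, T ∈ {G′, L} for single patterns and the pooled G
(variance-stabilised by default, see below) for replicate lists, where
every null round re-simulates all replicates.  Every curve — observed or
null — is compared against the mean of the *other* nsim curves (the
observed deviation uses the mean of all nulls; each null deviation uses
the leave-one-out mean *including* the observed curve).  This symmetric
construction makes the nsim + 1 deviations exchangeable under the null, so
p = rank/(nsim + 1) is exactly uniform; ties rank against significance.
The direction of departure is the sign of ∫ (T_obs − T̄) dr: *below*
indicates larger empty spaces at short range than CSR, i.e. regularity.

**Stabilising the pooled statistic.**  The replicated test applies
arcsin √(·) to the pooled G before integrating.  The raw pooled G
concentrates null variance at large r, where erosion leaves few points and
no inhibition signal exists; at desk scale (5 replicates × 100 points at
~0.5 holes dm⁻²) that noise floor swamps the short-range signal and the
test loses its ability to rank a genuinely regular pattern first.  The
stabilised statistic weights all distances equally and detects the same
departures; the raw-G form remains available (`statistic_kind="G"`).

**Classification rule.**  regular ⇔ both the G′- and L-based tests have
p ≤ α with direction *below*; clustered ⇔ both *above*; anything else is
random (CSR).  Requiring agreement of two statistics roughly squares the
false-positive rate: measured type-I error for "regular" at α = 0.05 is
~1–3%.  Patterns with fewer than 10 points are labelled random with a
warning rather than tested.  The detection density λ_detection takes the
first census labelled regular, without a persistence requirement; the full
p-trajectory is returned so stricter rules can be applied downstream.

**Allocation null.**  Whether total holes split among segments in
proportion to area: multinomial allocation (the zero-inhibition limit of
sequential placement), pooled simulated densities vs the observed
densities by two-sample KS with asymptotic p.

## Sequential inhibition and colonization

`ssi_generate` proposes uniform points and accepts those at least r from
every accepted point, stopping at a target count or after `giveup`
consecutive rejections (default 1000, matching the rSSI sampler in R's spatstat).
Proposals are batched and screened against a KD-tree of accepted points;
the consecutive-rejection counter is maintained exactly across batches.
The exclusion zone is circular (isotropic), consistent with the observed
symmetry of X- and Y-axis NN distances in this system.

The give-up-terminated *saturation density* is budget-dependent: random
sequential packing approaches its jamming limit slowly, so a 10× larger
give-up packs measurably (~5%) denser.  Saturation scales as r⁻² when the
window is scaled with r; at a fixed window the comparison across r is
contaminated by a ~2% perimeter packing excess, which exceeds the tiny
Monte-Carlo error of saturation counts.  The r⁻² law is therefore checked
with proportional windows.  At r = 2.5 cm and give-up 5000 the saturation
density is ≈ 10.6 holes dm⁻² — an order of magnitude above observed attack
densities (0.4–1.2 dm⁻²), supporting the conclusion that the inhibition
distance does not set the colonization plateau.

`sequential_colonization` drives arrivals day by day:
N_j(t) ~ Poisson(α_j A_j Φ(t)) per segment (flux evaluated at the day's
midpoint), each arrival proposes one landing site with density
proportional to the texture weight (rough-bark sites always kept, smooth
kept with probability 1/w), settles only if ≥ r from every earlier attack
on the segment, and otherwise leaves — arrivals do not retry, unlike the
fixed-count sampler.  Attacks are stamped with the first census ≥ their
arrival day.

## Temporal models

The saturation fit H(t) = H_END (1 − e^(−βt)) uses nonlinear least
squares, initialised at H_END = 1.1 max(H) with β from a through-origin
fit of −log(1 − H/H₀) on t, tolerances 10⁻¹⁰; β is stored positive (decay
rate).  The two-stage split at day 11/12 is a fixed, configurable
boundary; no change-point estimation is attempted.  Susceptibilities come
from through-origin OLS of Λᵢ(t) on the reference segment's Λ(t) within a
stage — proportional densities under a shared flux imply a zero intercept,
so reported intercepts from free regressions are diagnostics only.
Changing the reference rescales all α by one constant.  The weighted sex
ratio uses sexed counts per day as weights; male landing intensity is
n_landed × SR / trap_area.

## Synthetic-study generator

Defaults (all configurable, fixed before any testing): 13 segments,
lengths 300–500 cm and circumferences 60–100 cm drawn per seed;
receptivities α evenly spaced on [1, 3]; inhibition r = 2.5 cm; rough-bark
weight w = 6.5 over disc patches (radius 3–8 cm, ~0.1 patches dm⁻², ≈10%
of area) around Poisson-placed branch bases; arrival flux Φ(t) = two
log-normal waves (medians day 4 and 14, weights 0.76/0.24, integrated
flux 0.2 holes dm⁻² per unit α) plus a third wave near day 33 seen only by
the landing traps (its arrivals never convert to attacks); censuses daily
to day 17 then weekly to day 45; trap area 50 dm² with a landing factor of
40 landings per attack-equivalent flux unit (so several hundred landings
support a stable sex-ratio estimate), 85% of landed insects sexed at sex
ratio 0.38.  These values put per-segment totals near 120 holes
(about 40–260 across seeds and segments) and final hull densities near
0.3–0.7 holes dm⁻² — the regime of the field system this emulates.  One
master seed spawns independent streams for geometry, traps and each
segment, so output files regenerate byte-for-byte.

Reference values for recovery scoring: H_END and β are defined as the
saturation fit to the *noiseless expected* pooled census
(Σ_j α_j A_j ∫Φ), since a two-wave flux is not literally a one-exponential
process; susceptibility truth is α_j/α_1; the texture truth is w; the
inhibition truth is r, estimated by the final minimum NN distance.
Measured recovery at defaults (median over 20 seeds): β and H_END within
~5%, susceptibility ratios ~8%, texture weight ~13% low (inhibition
suppresses settlement more on crowded rough bark than smooth, so the
realized density ratio underestimates the proposal weight), minimum NN
within ~4% of r.

**What the generator does not emulate:** weather/temperature forcing of
flight, pheromone-plume anisotropy, beetle walking before boring,
re-emergence, brood development, and attack-age effects on inhibition.
Passing recovery tests therefore show that the estimators invert the
stated mechanism at realistic sizes and noise — not that the mechanism is
a complete account of field data.

## Numerical and scale choices

Monte-Carlo sizes in the test suite are scaled to the information they
need: nsim = 999 where a p = 0.001 resolution is the point, nsim = 99 for
power/type-I rates over many repetitions, smaller grids (64–128 points)
for calibration sweeps.  Statistical assertions use 3-standard-error
bands, binomial margins, or fixed rate thresholds; seeded generators make every
test reproducible.  Degenerate inputs (fewer than 2 points for distance
estimators, < 3 non-collinear for hulls, < 4 censuses for saturation fits,
constant series for correlations, single compartments for the allocation
test) raise typed errors rather than returning silent defaults.

## Known limitations

- Windows are assumed fully observed; gaps in coverage (e.g. the underside
  of a bole) are not modelled.
- Only homogeneous CSR nulls: no inhomogeneous-intensity G/K variants.
- The translation correction is the only K edge correction provided.
- λ_detection depends on the census schedule and nsim granularity; it is
  reported with its full p-trajectory for that reason.
- The give-up-limited saturation density underestimates the true jamming
  limit by a few percent at practical budgets and carries a small
  window-perimeter excess.
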