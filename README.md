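# barkspat

Spatio-temporal point-pattern analysis of bark-beetle colonization on
weakly defended (felled) host trees.

When the European spruce bark beetle *Ips typographus* colonizes a fallen
spruce, each attacking beetle bores an entrance hole through the bark.  The
holes accumulate over a few weeks into a striking spatial arrangement:
early attacks scatter over the whole segment, later arrivals fill the gaps,
and no new hole appears within a minimum allowed distance (MAD, about
2.5 cm) of an earlier one, so the final pattern is statistically *regular*
rather than random.  `barkspat` implements the full analysis chain for this
kind of study — and a synthetic-study generator with known ground truth to
exercise it — for ecologists working with marked spatio-temporal point data
on unrolled bark surfaces.

## What it computes

Distances are cm, areas dm², densities holes dm⁻².

- **Geometry** (`barkspat.geometry`): rectangular segment windows and
  convex hulls of the attacked patch; segment density Λ = H/A_segment and
  hull density λ = H/A_hull; nearest-neighbour (NN) distances (planar or
  per-axis); CSV I/O for attack, segment, patch and trap tables.
- **Summary functions** (`barkspat.summaries`): the NN distribution
  function G(r) with the reduced-sample (border) estimator; the
  variance-stabilised G′ = arcsin √G; Ripley's K with translation edge
  correction (exact on rectangles, via the FFT set covariance on convex
  hulls) and Besag's L = √(K/π); erosion-weighted pooling of G over
  replicates, Ḡ(r) = Σᵢ Gᵢ(r) n_{i,r} / n_r.
- **Monte-Carlo inference** (`barkspat.inference`): CSR (homogeneous
  Poisson) simulation, pointwise envelopes, and the
  Diggle–Cressie–Loosmore–Ford deviation test on
  U = ∫₀^rmax (T(r) − T̄(r))² dr with exact Monte-Carlo ranking
  (p = rank/(nsim+1)).  A pattern is *regular* only when the G′- and
  L-based tests agree (both p ≤ α, observed below the null mean), and
  *clustered* for the mirror case.  The detection density λ_detection is
  the hull density at the census where a colonization sequence first reads
  regular.  An area-proportional multinomial allocation null with a
  two-sample KS test probes between-segment variability.
- **Inhibition simulation** (`barkspat.ssi`): simple sequential inhibition
  (SSI) sampling, give-up-terminated saturation (jamming) density, and a
  daily colonization simulator where segment j receives
  Poisson(α_j · A_j · Φ(t)) arrivals that settle only ≥ r from every
  earlier attack.
- **Colonization dynamics** (`barkspat.dynamics`): the saturating fit
  H(t) = H_END (1 − e^(−βt)); the day-11 two-stage split; trap landing
  series with the sexed-count-weighted sex ratio; landing–attack Pearson
  correlation; per-segment susceptibilities α as through-origin slopes of
  Λᵢ against a reference segment.
- **Study metrics** (`barkspat.metrics`): rough/smooth texture densities
  and their regression; along-bole spread and drift; power laws
  NN = γ λᵃ for mean and minimum NN distance (γ = 5.0 cm, a = −1/2 under
  CSR); MAD estimates from the first envelope crossing of G′ and the final
  minimum NN distance.
- **Synthetic studies** (`barkspat.synthesis`): a 13-segment study with a
  two-wave arrival flux, receptivities spread 1–3, a 6.5-fold rough-bark
  preference and r = 2.5 cm inhibition, censused daily to day 17 then
  weekly to day 45; byte-reproducible from a master seed, with parameter
  recovery scoring.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (outputs land in `results/`):

```
python analysis/01_simulate_study.py      # default study, seed 0
python analysis/02_colonization_dynamics.py
python analysis/03_spatial_patterns.py
python analysis/04_texture_and_spacing.py
python analysis/05_inhibition_packing.py
```

Output of the first three steps:

```
simulated 13 segments with master seed 0
total entrance holes: 1578
per-segment holes: min 59, median 107, max 226

saturation fits over 13 segments:
  H_END = 134.2 +- 65.4
  beta  = 0.117 +- 0.009 per day
  H_SECOND/H_FIRST median = 0.313
first-stage susceptibilities (ref seg01): 1.00 .. 2.95
weighted sex ratio = 0.354
landing-attack correlation: rho = 0.99, t = 29.96, df = 15, p = 8.5e-15
allocation null (area-proportional multinomial): KS D = 0.406, p = 0.0191

1 of 13 segments classified regular at the final census
detection density: median 0.49 holes/dm^2 (final median 0.42)
pooled test over all segments: U = 0.1025, rank = 1, p = 0.001 (below CSR)
```

Reading this: each segment's hole count saturates (H_END is the plateau,
β the steepness; most holes arrive in the first stage, the second stage
adds ~31%).  Landings and attacks track the same flux (ρ = 0.99), yet the
allocation test rejects area-proportional colonization (D = 0.406,
p = 0.019) because segments genuinely differ in receptivity.  At these
densities most individual segments cannot yet be told from CSR, but the
erosion-weighted pooled test across all 13 segments detects the spacing
regularity decisively (rank 1 of 1000, p = 0.001) — and the final minimum
NN distance (2.50 cm, step 04) recovers the built-in inhibition distance.

The same pipeline is available as a CLI:
`barkspat simulate --seed 0 --out data/`, then
`barkspat analyze --attacks data/attacks.csv --segments data/segments.csv
--out run/`, then `barkspat report --run run/`.

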