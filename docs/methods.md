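# Methods

This note documents the models implemented in `umbraflux`, the defaults
of the synthetic eclipse-day generators, the numerical choices that are
not visible from the API, and the limitations a user should know before
applying the pipeline to field data.

## Eclipse geometry

Contact times C1–C4 are inputs; no ephemeris is computed. Sun and moon
are modelled as equal apparent disks whose center separation falls
linearly from tangency (d = 2r) at C1 to zero at C2, stays zero through
totality, and returns to tangency at C4. The obscured fraction of the
solar disk is the standard two-disk lens-overlap area divided by the
solar disk area, clipped to [0, 1] and pinned to exactly 1 on [C2, C3].
The default contact times describe a 138-s totality within a partial
phase of 2 h 45 min 36 s, with mid-totality placed on a whole minute
(10:39:00 local standard time) so that 60-s logger grids sample the lag
of the thermodynamic minima without rounding. A Monte-Carlo
disk-point-sampling oracle (10⁶ points) agrees with the closed form to
better than 10⁻³ across the full separation range; this is enforced in
the test suite.

## Synthetic forcing

PPFD is a half-sine clear-sky diel curve (peak 1800 µmol m⁻² s⁻¹, solar
noon 12:00, day length 13.5 h) multiplied by the unobscured disk
fraction. Net radiation uses the same clear-sky shape (peak 650 W m⁻²)
rescaled affinely so that its totality value equals the configured
minimum (−111 W m⁻² by default); outside the eclipse it equals the
clear-sky curve exactly.

Air temperature and VPD are modelled as plateau baselines minus a
depression proportional to a *lagged* obscuration response: the response
D(t) solves dD/dt = (f(t) − D)/τ on a 1-s grid, where f is the
obscuration fraction. The time constant τ is solved at generation time
(Brent root finding) so that D peaks exactly `lag_minutes` after
mid-totality, and D is then normalized so its peak equals 1. The
channel minima therefore land exactly at `t_base_max − delta_t`
(28.0 − 6.4 = 21.6 °C) and `vpd_min` (1.2 kPa), exactly `lag_minutes`
(9) after mid-totality. For the default geometry the solved τ is about
790 s; it is recorded in the series metadata. Relative humidity is
back-computed from T and VPD through the Tetens saturation vapor
pressure (constants 0.61078 kPa, 17.27, 237.3 °C — chosen as standard
micromet practice and isolated in one place so alternates can be
swapped), so recomputing VPD from the stored T and RH round-trips to
within 10⁻⁹ kPa.

The midday plateau (08:30–16:30, sin² ramps of 3 h on either side) keeps
the pre-C1 baseline window flat, so the depression metrics return the
configured drops exactly. The plateau temperature of 28 °C was chosen as
a realistic August midday value for a sagebrush site at 2073 m that
keeps RH physical (2.2 kPa of VPD at 28 °C is RH ≈ 42 %); the printed
relative depressions of temperature and humidity in the source material
imply baselines that cannot be made mutually consistent with any
temperature under a standard saturation formula, so the absolute drops
(6.4 °C, 1.0 kPa) are treated as the calibration anchors. Optional
Gaussian noise per channel is drawn from a single seeded generator; with
all noise at zero (the default) the output is bit-stable.

## Synthetic leaf record

The chamber record is produced on a 30-s cadence (linear interpolation
of the 60-s forcing; timestamps at interval start). Chamber PPFD tracks
ambient; chamber VPD is held at the near-constant leaf value implied by
the chamber climate (21.4 °C, 50.9 % RH → 1.252 kPa), so transpiration
tracks conductance.

Stomatal conductance integrates dg/dt = (g_ss − g)/τ_g with
g_ss = g_min + (g_max − g_min)·[Q/(Q + K_g)]·[1/(1 + VPD/D0)], using the
exact exponential update per step. NPQ integrates first-order kinetics
toward NPQ_ss = npq_max·Q/(Q + K_npq) with asymmetric time constants —
induction 45 s, relaxation 90 s — so that quenching builds quickly under
high light but needs ~3·τ_relax = 270 s (longer than the 138-s totality)
to fully relax, reproducing the observed incomplete dark re-acclimation.
Assimilation follows the non-rectangular hyperbola below; Fm′ =
Fm/(1 + NPQ), Fo′ follows Oxborough–Baker, and the steady-state
fluorescence interpolates between Fo′ and Fm′ with a saturating
photochemical-quenching factor.

The kinetic defaults (g_max = 0.0248 mol m⁻² s⁻¹, τ_g = 75 s, npq_max =
2.083, K_g = K_npq = 200 µmol m⁻² s⁻¹) were calibrated once so the
zero-noise day hits the eclipse-day anchors: conductance ≈ 0.012 mol m⁻²
s⁻¹ just before first contact falling to 0.002 at totality, and NPQ 1.83
falling to 0.06. A stomatal time constant near one minute is at the fast
end of published ranges but is required for conductance to track the
rapid final collapse of PPFD into totality; it is exposed as a parameter.

Leaf water potentials come from the zero-capacitance linear supply model
Ψ_L(t) = Ψ_soil − E_L(t)/K_plant (Ψ_soil = −2.0 MPa, K_plant =
0.256 mmol m⁻² s⁻¹ MPa⁻¹), sampled at the field schedule (predawn 05:00,
10:00, 10:40, 11:25, 12:30) with Gaussian replicate noise. Because the
supply model is linear and capacitance-free, the downstream Darcy
regression recovers K_plant exactly at zero noise — this closed loop is
the main self-consistency check of the hydraulic stage.

## Analysis choices

- **Depression metrics**: baseline is the mean over the 30 min before
  C1 (configurable); the minimum is searched over [C1, C4]; ties break
  to the earliest time; a minimum on the window boundary yields an
  undefined (null) lag rather than a number. The lag is referenced to
  the midpoint of totality.
- **Hydraulic regression**: ordinary least squares of E on Ψ; K_L is the
  negative slope; predawn occasions are excluded by default because
  elevated nighttime VPD keeps predawn Ψ_L out of soil equilibrium. The
  implied soil water potential is reported from the fitted intercept,
  not assumed. Negative K_L estimates are surfaced with a warning, never
  clipped. Note the field-unit identity: 0.256 mmol H₂O m⁻² s⁻¹ MPa⁻¹ is
  4.6 × 10⁻³ g H₂O m⁻² s⁻¹ MPa⁻¹ (18.015 g mol⁻¹ × 0.256 mmol).
- **Fluorescence**: Fv′/Fm′ uses the same (Fm−Fo)/Fm form with
  light-adapted values; Fo′ is estimated by Oxborough–Baker when not
  measured (fluorometer-firmware convention). The recovery ratio uses
  floor (100·0.71/0.81 = 87.65 reports as 87); conventional rounding
  would report 88. The pre/post phase boundary for the binned hysteresis
  comparison is mid-totality; tests are Welch (unequal variances); no
  multiplicity correction is applied across the four PPFD bins, and the
  output carries a note to that effect. Bin sampling operates on
  timestamp-sorted rows so row order cannot change a seeded draw.
- **Light response**: the non-rectangular hyperbola is fitted with
  curvature θ free by default (a fixed-θ variant is exposed); the
  θ → 0 degenerate branch switches to the rectangular hyperbola below
  θ = 10⁻⁶. Initialization: φ from the OLS slope of the lowest-quartile
  PPFD points, Amax from the 95th-percentile assimilation plus the Rd
  guess, θ = 0.7, Rd from |min A|. The counterfactual PPFD defaults to a
  diel fit (q_max·sin^k of day fraction) to out-of-window observations;
  a transmission method (q/(1−f), bridging f > 0.99 by interpolation) is
  the alternative. The deficit integrates trapezoidally at the native
  30-s cadence over [C1, C4]. The counterfactual is clamped from below
  by the observation inside the window.
- **Upscaling**: umbra containment uses pixel centers, boundary
  inclusive; areas are pixel counts × pixel area on a planar equal-area
  grid; the binary threshold is inclusive (≥ 0.5). Cover-fraction and
  LAI uncertainties combine multiplicatively into one low/high leaf-area
  envelope. Carbon mass uses 12.011 g mol⁻¹ (carbon in CO₂). Because
  every square meter of leaf shares one flux series (big-leaf linearity
  + simultaneity), the percent reduction is independent of the leaf-area
  bound used; the totals are not. Worked arithmetic on the published
  regional totals: 100·(1 − 35.9/41.3) = 13.1 %, which the source
  rounds/reports as 14 %; the pipeline reports the unrounded value for
  its own runs and asserts nothing about 14.0.

## Synthetic landscapes

The fine 30-m raster is a Gaussian-filtered white-noise field
(correlation length 150 m) scaled to mean cover 0.45, SD 0.15, clipped
to [0, 1]. The coarse 90-m raster is the 3×3 block mean pushed through a
configurable linear relation (slope 1, intercept 0 by default) plus
Gaussian noise whose variance is set from the target regression R²
(0.67 by default) via var_noise = var_signal·(1 − R²)/R². The umbra
track is a straight line of 1-minute centers with a fixed 57.5-km radius
(a ~115-km-wide path of totality) crossing the default 20 × 20 km
extent at 900 m s⁻¹. What the generator does *not* emulate: real
land-cover class structure, spatial autocorrelation of classification
error, penumbral gradients within the extent, topographic shading, or
registration error between the two products — so passing parameter
recovery here demonstrates the estimators, not the quality of any real
cover product.

## Determinism and seeds

One global seed expands through `numpy.random.SeedSequence.spawn` into
named per-stage seeds (forcing, leaf, water, landscape, bins), each
reduced below 2³¹; the manifest written with every run echoes the
resolved configuration and the derived seed set. With all noise at zero,
every generator is deterministic and bit-stable, and rerunning an
identical configuration reproduces the report byte for byte.

## Problem sizes

The default day runs 05:00–20:00 at 60 s (901 forcing samples) and 30 s
for the leaf record (1801 samples); the default test landscape is
2.7 × 2.7 km (90 × 90 fine pixels) and the default pipeline landscape
20 × 20 km (666 × 666). The light-response recovery study uses 100
seeds × 600 points at σ = 0.05 µmol m⁻² s⁻¹ noise. These sizes keep a
full pipeline run under ten seconds on one core while leaving every
estimator with comfortably more data than it needs.

## Known limitations

- The lag calibration requires `lag_minutes` > half the totality
  duration; shorter lags cannot be realized by a first-order response.
- The simulated transpiration decline mirrors the conductance endpoints
  (0.012 → 0.002, an ~83 % decline) under constant chamber VPD; the
  separately reported ~70 % transpiration decline in the source data is
  not force-fit, since both cannot hold at constant VPD.
- The eclipse duration is quoted in two variants in the source
  (2:45:28 and 2:45:36); the defaults use the latter.
- Time-integrated deficits are reported in mol CO₂ m⁻² (and as a mean
  rate); a published deficit printed with a rate unit over a stated
  duration is not reproducible without the underlying series and is not
  a calibration target.
- No gap-filling or quality control for real logger data beyond
  rejection of non-finite values; no boundary-layer or leaf-temperature
  corrections in the conductance conversion; no Farquhar-type
  biochemistry; no reprojection of rasters (inputs must share one planar
  CRS).
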