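# Methods note

Model assumptions, parameter defaults, numerical choices and limitations
of the `pgti` package. Units throughout: positions cm, times ps (ns for
accelerator structure), energies MeV.

## 1. Proton transport

Protons are transported along +x through a stack of homogeneous slabs
(origin at the upstream face of the first slab).

- **Kinematics.** `beta(E) = sqrt(1 - (m/(m+E))^2)` with
  m = 938.272 MeV; inverse speed `1/(beta c)` in ps/cm with
  c = 29.9792 cm/ns.
- **Range–energy.** Bragg–Kleeman law `R_water = alpha E^p` with
  alpha = 0.0022 cm·MeV^-p and p = 1.77. Non-water materials carry a
  single water-equivalent stopping ratio (WER): residual range
  `alpha E^p / WER`. The PMMA WER is pinned by the calibration anchor
  *148 MeV protons stop after 13.4 cm of PMMA*, giving WER = 1.139 —
  slightly below the textbook 1.15–1.17 band; the anchor takes
  precedence (design decision; it also fixes the exit-speed slope of the
  63 MeV geometry at 106.3 ps/cm, versus 107 printed / 109 from a full
  Monte Carlo in the literature this emulates).
- **Air gaps** are lossless drift: constant speed, no energy loss.
- **Transit times** are composite-midpoint integrals of the inverse speed
  on steps of at most 0.1 mm (sub-ps accuracy, additive over consecutive
  slabs). The cumulative arrival-time map `T_p(x)` is tabulated on a
  0.02 cm grid (0.2 mm); node times are integrals from the slab entrance,
  so refining the grid leaves shared nodes unchanged. Because
  `1/(beta c)` diverges at the stopping point, the map ends 0.1 mm short
  of the range end.

## 2. Prompt-gamma emission

A parametric stand-in for nuclear-physics transport:

- **Depth profile**: a plateau over the material path with a fractional
  linear rise of 0.3 toward the Bragg peak, times a linear distal ramp of
  0.3 cm ending where the proton energy crosses the 2.5 MeV production
  threshold (`falloff_x`, within a fraction of a mm of the stopping
  depth). Air gaps carry zero density. Normalized by trapezoid rule,
  sampled by inverse CDF.
- **Energy spectrum**: 60% decaying continuum (tau = 2 MeV) on 2–7 MeV
  plus discrete lines at 4.44 MeV (25%, carbon) and 6.13 MeV (15%,
  oxygen).

## 3. Detection model

- **Geometry**: point-detector approximation; solid-angle weight
  `face_area / (4 pi d^2)` with the module position resolved from an
  angle plus distance from a named anchor (target entrance or Bragg-peak
  depth). Detector positions are resolved **once, in the reference
  geometry** — they do not move when a range shift is implemented.
- **Intrinsic efficiency**: sigmoid + linear curve per photoelectron
  threshold (3/6/9 p.e.), zero below 0.1 MeV, anchored at 5% for 2 MeV
  gammas at 6 p.e., saturating near 0.2–0.3 above 8 MeV (roughly the
  interaction probability of a cm-scale Cherenkov radiator).
- **Timing**: Gaussian jitter with the quadrature sum of the monitor and
  module FWHMs (e.g. 156 ps ⊕ 273.7 ps = 315 ps system CTR for the
  63 MeV preset). The thin-target transit smear is not an extra term: it
  arises automatically because vertices are sampled continuously in
  depth and `T_p(x)` varies across the target.
- **Thinning**: by default candidates are rejected against the *global*
  acceptance bound (sum over detectors of max efficiency × max solid
  angle) rather than against 1. The accepted sample follows exactly the
  same distribution — only the acceptance bookkeeping changes — and
  generation stays fast even at physical per-candidate acceptances of a
  few 1e-5. `thinning="literal"` restores plain `u < p` rejection, whose
  accepted fraction estimates the physical acceptance directly.
- **Backgrounds**: (i) flat-in-TOF dark random coincidences with expected
  count `f_dia × DCR × 2tau × livetime`; (ii) bunch-correlated random
  coincidences, Gaussian with the bunch sigma; (iii) an optional
  scattered-proton bump at the monitor→module flight time.

## 4. Accelerator and counting statistics

Bunch occupancies are Poisson with mean λ. Pulsed machines (S2C2 preset:
16 ns bunches, 8 µs pulses every 1 ms) use the duty-cycle-weighted
effective bunch rate (62.5 MHz × 0.008 = 500 kHz). Closed forms:

- random-coincidence rate `f_dia × DCR × 2tau`;
- λ estimate from empty/single bunch counts `P(1)/P(0) = lambda`;
- SPR delivery time `n / (rate × (1 - e^-lambda))` (only non-empty
  bunches deliver a usable proton);
- quadrature decomposition `sqrt(total² - component²)` of resolutions,
  with the FWHM ↔ rms factor `2 sqrt(2 ln 2) = 2.3548`.

## 5. Reconstruction (PGTI)

Each detector gets a reference map `x → T_p(x) + T_gamma(x, r_d)`
tabulated on a 0.02 cm grid over `[0, falloff + 1 cm]` (clipped to the
proton map support) and inverted by piecewise-linear interpolation.
Maps are validated to be strictly monotone; a non-monotone map is refused
with an error naming the offending interval. (For point detectors on the
beam axis monotonicity cannot physically fail — `|dT_gamma/dx| ≤ 1/c <
dT_p/dx` since beta < 1 — so the error path is exercised synthetically in
tests.) Out-of-range TOFs are clamped to the map boundary and **kept**,
flagged `in_range=False`: they carry cumulative mass, and dropping them
would renormalize the cumulative and bias the shift statistic toward
zero. They are excluded only from fall-off (distal-maximum) location.
Maps are deliberately never rebuilt for shifted geometries — reference
conditions are all a clinical monitor would have.

## 6. Fall-off shift and its error

The shift statistic compares normalized cumulative functions: with
`x_ref` the distal maximum of the reference profile and
`y_ref = F_ref(x_ref)`, the measured displacement is
`d = F_profile^-1(y_ref) - x_ref` by linear interpolation. Statistical
errors are estimated by subsampling **without replacement**: 5000 toys at
each size 30, 45, …, 135, the per-size spreads fitted with
`sigma = k/sqrt(N)` through the origin (least squares in `1/sqrt(N)`) and
evaluated at N = 600; `sigma2 = 2 sigma1` by construction. Subsample
sizes stay well below the sample size to limit dependence between toys.
Time shifts convert to range at the model slope (106.3 ps/cm for the
63 MeV preset).

## 7. Known limitations

- **Jacobian pile-up saturates the PGTI shift response at full
  resolution.** The reference map steepens from ~126 to ~455 ps/cm toward
  the proton stop, so the inverse map compresses late TOFs into the
  terminal spatial bins. With the full 315 ps FWHM blur this pile-up
  dominates the distal region and the measured-vs-implemented shift slope
  saturates around 0.1 (still strictly below 1). Without jitter the
  geometric bias is cleanly exposed: slope ≈ 0.65–0.75 for shifts up to
  6 mm, below unity because the maps attribute the shifted proton delay
  with reference-geometry conditions. Resolution-aware inversion (treating
  the time response as part of the estimator) would mitigate this but is
  out of scope.
- Edge clamping also saturates per-detector shift recovery once a shifted
  fall-off runs past the reference-map end; sensitivity scans therefore
  quote statistical errors at the reference geometry.
- The emission model is parametric (no nuclear cross sections), the
  detector is a point with a factorized efficiency, and protons are
  transported without straggling, scattering or beam-spot size.
  Consequently absolute yields and the exact fall-off *shape* are
  schematic; timing relations, counting statistics and the error-scaling
  machinery are quantitative.
- Backgrounds are stationary in time; no pile-up of multiple PGs per
  bunch is simulated (SPR operation makes this rare).

## 8. Problem sizes

Defaults are chosen so everything runs on one CPU in seconds: 600-event
profiles against a 20 000-event simulated reference, 5000 bootstrap toys
per size (a full sensitivity scan with five shifts takes a few seconds),
0.02 cm map grids, 50 ps time bins, 0.5 cm spatial bins. The acceptance
script completes in ~4 s; the test suite in ~5 s.
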