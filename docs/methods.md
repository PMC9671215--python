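# Methods

This note documents the models implemented in `lipoplex`, the defaults
and numerical choices behind them, what the synthetic-data generators
do and do not emulate, and the known limitations.

## Electrostatic design model

The package treats the antisense oligonucleotide as a rigid rod
polyanion (persistence length of short single strands far exceeds the
~5.4 nm contour of a 16-base rod, so flexibility is ignored). The two
governing quantities are:

* **Bjerrum length** `λ_B = e²/(4π ε₀ ε_r k_B T)`, computed from CODATA
  2018 constants (via `scipy.constants`) at a default temperature of
  298.15 K. Water (`ε_r = 80`) gives 0.7006 nm. The value is computed
  from `ε_r` and `T` in every code path; no solvent-specific Bjerrum
  length is hard-coded, because rounded literature figures for low-
  permittivity media are not mutually consistent with any single
  (ε, T) pair.
* **Manning coupling** `Γ = λ_B/l₀` with condensed fraction
  `θ = max(0, 1 − 1/Γ)`. θ is exactly 0 at and below the threshold
  `Γ = 1` and strictly increasing above it. For the default rod
  (`l₀ = 0.34` nm) in water, Γ = 2.061 and θ = 0.515; printed summaries
  round these to 2.1 and 0.5.

**Permittivity mixing.** No established closed form exists for the
ternary water/methanol/chloroform dielectric constant, so the default
is a volume-fraction-weighted linear rule over the endpoint values
(80/30/5). It is exact at the pure endpoints, bounded by the component
extremes, and deliberately pluggable (`mixture_permittivity(...,
model=callable)`) because real mixtures deviate from linearity.

**Regime classification.** Sub-critical below `Γ = 1`; weakly
condensing when `λ_B` is shorter than the rod; strongly condensing once
the Bjerrum "cage" spans the rod (`λ_B ≥ L_rod`), the regime in which
maximum-chloroform solvents drive dense lipoplex condensation.
Thresholds are arguments, not constants.

## Coarse-grained geometry and stoichiometry

Rod bookkeeping is purely geometric: length `n·l₀`, specific area per
charged unit `π D₀ l₀` (1.068 nm² for defaults), surface charge density
`q/(π D₀ l₀)` (−0.94 e/nm²). The amphiphile packing parameter
`v₀/(a₀ ℓ)` uses the **head-to-tail molecular length** (2 nm for
DC-cholesterol), not the nucleotide rise — the only reading that gives
the cylinder-like 0.9 for (0.9 nm³, 0.5 nm², 2 nm). Shape classes
follow the standard surfactant convention: ≤ 1/2 micellar (boundary
inclusive), (1/2, 1] bilayer former, > 1 inverted.

Counterion stoichiometry is reported under **two deliberately separate
rules** that do not agree for the default molecules:

* area matching — headgroups tiling the rod surface, half the specific
  area facing each of the two adjacent leaflets: `2·(A/2)/a₀ ≈ 2.14`;
* charge balance — `|q_rod|/|q_head| = 1` for ±1 e species.

The adopted downstream default is 2 (the area-matching round). The
result carries both ratios, a `consistent` flag and the neutrality
residual at the adopted ratio, so no rule is silently preferred.

## Ternary solvent arithmetic

Basis conversion is the exact algebraic map with default densities
1.0/0.8/1.5 g/cm³; mixing is ideal (volume-additive), matching how
bench protocols are written — excess volumes of mixing are ignored.
Compositions are stored to full precision and only rounded in reports.

**Binodal.** The one-phase/two-phase boundary ships as a synthetic
piecewise-linear polyline (CSV asset, weight basis), parameterised by
the chloroform share of the water+chloroform sub-binary against the
methanol height. It is constrained through the critical composition
(30% water / 15% methanol / 55% chloroform w/w) and shaped so that the
two protocol mixtures classify as the protocol states (the 480 µL
complexation pool monophasic, the 720 µL compaction pool biphasic).
It is a stand-in for a measured digitization and is replaceable by any
CSV with the same schema; classification happens in weight basis
regardless of input basis, with a ±0.5 %-methanol boundary band.
Tie-lines are user-supplied; no liquid–liquid equilibrium is predicted.

## Formulation arithmetic

Moles are `mass/M` with stock volumes converted through mg/mL
concentrations first; molar percentages keep raw (sum = 100) and
nearest-integer report values. Counterion excess is
`n_counterion/(s·n_monomer)` with default stoichiometry `s = 2`.
Monomer counting is `strands × declared bases`; because printed
protocol totals can disagree with that product, the monomer moles can
always be overridden directly and the recipe fixture carries the
protocol's printed value as data. Dose concentration is a plain ratio
kept at full precision.

## DLS model and cumulant analysis

Correlograms follow the Siegert relation with a discrete
intensity-weighted mixture of diffusers. The second-order cumulant fit
is a weighted linear least-squares solve of `ln(g₂−1)` against
`[1, τ, τ²]`, weights ∝ `(g₂−1)²` (the standard variance stabilisation
for log-transformed data). Choices:

* **Fit window**: lags with `(g₂−1)/β > 0.05` (configurable). The
  cumulant moments are an early-decay expansion; the wide default
  window trades a small truncation bias for noise robustness.
* **β**: fitted as the τ→0 intercept by default; can be pinned.
* **μ₂ clamp**: negative fitted μ₂ (possible under noise) is clamped to
  0 and flagged, so `PDI = 1 + μ₂/μ₁² ≥ 1` always holds.
* Sizing uses Stokes–Einstein with the instrument medium (default
  water at 25 °C, η = 0.89 mPa·s; laser 633 nm, n = 1.33, 90°
  detection — all configuration, not constants).
* A secondary size-dispersion convention `1 + σ_R/R_H` is provided as
  `pdi_from_size_cv` for comparison with instrument software output.

Measured behaviour on synthetic data (the test suite computes these):
noise-free monodisperse traces recover D exactly and PDI = 1; at peak
SNR 100 the per-seed diameter error of a 172 nm monodisperse sample is
typically < 1% (median ≈ 0.6%, occasional seeds reach ≈ 2.5% because
the μ₂ term absorbs noise), and the seed-mean is well within 2%; PDI is
monotone in the generating distribution width for CV 0.1–0.3.

## Electrokinetics

Smoluchowski limit only (`μ_e = ε ζ/η`), appropriate for particles much
larger than the Debye length; Hückel/Henry corrections are out of
scope. Module defaults describe the dilute-electrolyte measurement
cell (`ε_r = 100`, η = 1 mPa·s), intentionally distinct from pure
water. Replicate summaries report the sample standard deviation; the
neutrality band defaults to ±5 mV so a 0 ± 3 mV preparation is neutral
and a 44 mV one is not. Measured zeta values are "bare" low-ionic-
strength potentials; under physiological screening the effective
interactions drop by over an order of magnitude, so the neutrality
flag speaks to charge stoichiometry, not in-situ potential.

## Lamellar structure factor

    S(r) = B + S₀ e^{−kr} |sin(π r / (D (1 + δ r)))|^α

* **Grouping**: the dilation factor multiplies the **spacing**, i.e.
  the sine argument is `π r / [D(1+δr)]`, so positive δ swells the
  local repeat with radius (the behaviour of a hydrated corona). The
  alternative reading (δ inside the phase numerator) would compress
  spacing with radius and cannot produce a swollen outer shell.
* **Magnitude before exponentiation** keeps S real for non-integer α.
* **Baseline B** is an addition to the printed two-term model: real
  stained-image profiles have a nonzero background; B = 0 recovers the
  bare oscillation.

**Fitting.** Bounded trust-region least squares
(`scipy.optimize.least_squares`, bounds: k ∈ [0,2] nm⁻¹, δ ∈ [0,0.5]
nm⁻¹, α ∈ [1,16], D within the profile span). Initialization is
multi-start: α ∈ {1,2,4,8} crossed with the spectral period estimate
scaled by {0.8, 1.0, 1.2} (falling back to a coarse D grid if no
spectral peak is found). Convergence tolerance 1e-10 on relative
residual change; ties between starts break to the lowest residual,
then the lowest α. Standard errors come from the Jacobian-based
covariance at the solution. A profile on which every start fails
returns a fit flagged `converged=False` — never a silent answer — and
classification of such a fit is `unclassified`.

**Period estimation** detrends with a cubic polynomial, applies a Hann
window, zero-pads the FFT 16× and refines the dominant peak
parabolically; `|sin(πr/D)|^α` has fundamental period D, so the peak
maps directly to the repeat spacing. Significance requires the peak to
exceed 5× the median spectral power; numerically constant profiles
raise a dedicated error, and two-tone profiles return the stronger
period flagged ambiguous.

**Dense-layer thickness** uses an explicit full-width-at-half-maximum
convention: `d = D·(1 − (2/π)·arcsin(2^{−1/α}))`, giving (2/3)·D at
α = 1 and 1.41 nm at (D = 5.4 nm, α = 8). Other conventions (e.g.
1/e-width or stain-threshold width) give smaller numbers; outputs are
always labelled FWHM so the convention travels with the value.

**Typology thresholds** act on dimensionless per-repeat products:
A1 when `k·D ≤ 0.05`, `δ·D ≤ 0.05` and α ≥ 4; A2 when decay or
dilation is appreciable (`k·D > 0.05` or `δ·D > 0.05`) and α > 1.5;
B when the profile is smooth (α ≤ 1.5) without decay or dilation.
All thresholds are configurable; every classification carries a rule
trace naming the clauses that fired.

## Synthetic instruments

Generators are pure functions of (spec, seed) using
`numpy.random.default_rng`; each returns a ground-truth record with the
full parameter set and a SHA-256 content hash, and re-running a spec
reproduces the hash bit for bit.

* **Images**: radially symmetric intensity fields of the lamellar
  model inside an outer radius (optional corona region with its own
  model), Poisson noise (signal-dependent, count scale `c` so the
  variance at intensity I is I/c) followed by additive Gaussian read
  noise, then quantisation with the clean peak mapped to 60% of the
  8/16-bit dynamic range. SNR is defined as peak clean intensity over
  total noise sd at the peak. The default particle centre sits on a
  pixel centre so axis-aligned radial profiles sample the field exactly.
* **Profiles**: the same Poisson+Gaussian detector model applied
  directly to model intensities on a radius grid — the 1-D counterpart
  used for seed studies where rendering full images adds nothing.
* **DLS**: log-normal diffusivity mixtures discretised on 15
  Gauss–Hermite nodes, width set so the intensity-weighted relative
  variance of D equals PDI − 1 and location set so the mean diffusivity
  corresponds to the preset diameter; lags default to a logarithmic
  grid spanning 10⁻³–5 decay times.
* **Zeta**: Gaussian replicates around a true value.

Preset parameter sets (particle types A1/A2/B; pellet, supernatant and
clodronate fractions) carry the study's printed characterization
values; anything the study does not print — the A2 dilation magnitude
(δ·D = 0.1) and compaction exponent (α = 4), amplitudes, baselines,
noise scales — is a package choice tagged `synthetic_choice` in the
ground-truth record.

**What the generators do not emulate**: electron-optical effects
(defocus, astigmatism), stain granularity and partial staining,
particle overlap and aggregation, asymmetric or off-centre lamellae,
DLS baseline drift and dust events, correlated detector noise. Passing
recovery tests therefore demonstrates that the analysis chain is
correct and robust to shot/read noise at the stated SNR — not that it
is robust to every artefact of real micrographs or correlograms.

## Problem sizes

The seed studies run at sizes chosen to give stable statistics while
staying lightweight: TEM recovery uses 100 seeded replicates per preset
on 199-point profiles (0.2–40 nm, ≈ 5–7 repeats); DLS studies use
25–50 seeds on 200-lag correlograms; synthetic images default to
256×256 px at 0.5 nm/px.

## Known limitations

* The linear permittivity mixing rule is an uncalibrated default.
* The shipped binodal is synthetic; quantitative phase-boundary work
  must substitute a measured digitization.
* The cumulant fit is second order; strongly multimodal samples need a
  regularised inversion (CONTIN-type), which is out of scope.
* The lamellar fitter assumes an isolated, radially symmetric particle
  profile; it does not segment particles out of full micrographs.
* α and (k, B) are partially degenerate at low SNR — the multi-start
  grid and bounds mitigate but cannot eliminate this; classification
  accuracy is the measured quantity (≥ 95/100 at SNR 10 per preset).
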