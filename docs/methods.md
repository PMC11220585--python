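# Methods

## The estimation problem

Reaction yield by HPLC normally requires a calibration curve built from pure
product — exactly what a small-scale or automated campaign does not have.
`chromyield` estimates yield from a single chromatogram pair instead: a
photo-diode-array (PDA) absorbance matrix `A(t, λ)` and one or more
extracted-ion MS traces. The chain is

1. locate the product in time via its expected m/z in the MS traces;
2. resolve the corresponding PDA window into pure components by
   multivariate curve resolution (MCR);
3. integrate the resolved product at the reddest absorption maximum of its
   spectrum;
4. convert area to moles by Beer–Lambert with a *predicted* molar
   extinction coefficient ε, weighted for the mobile-phase composition at
   elution;
5. convert moles to yield with the injection volume, dilution and initial
   reactant concentration.

The governing relation: with flow rate `Q` (L/s) and path length `ℓ` (cm),
the peak area `a` (AU·s) at the quantification wavelength obeys
`n = Q·a / (ε·ℓ)` for `n` injected moles. Yield follows as
`(n / V_inj) · d / c₀ᵣ`, with dilution factor `d` (crude + diluent over
crude) and initial reactant concentration `c₀ᵣ`. Yields above 1.05 are
flagged, never clipped: over-unity values diagnose co-eluting look-alikes.

Assumptions: detector linearity inside the checked dynamic range
(0.01–2 AU), one product species per target m/z (isomers/isobars are
indistinguishable), products that ionize under the configured adducts, and
a bilinear PDA signal (each species has one spectrum throughout elution).

## Preprocessing

**Smoothing.** Savitzky–Golay along time, window 7 points, order 3 —
polynomial-preserving, so areas of peaks wider than the window are conserved
to ≪ 0.5%.

**Solvent front.** Dead-time masking (default `t_dead` = 24 s): early-eluting
unretained material is excluded from peak search and integration; data are
kept. Spectral subtraction of the solvent peak was considered and rejected —
masking has no tunable spectrum to get wrong.

**Baseline.** Per-channel arPLS: minimize
`Σ wᵢ(yᵢ−zᵢ)² + λ‖Δ²z‖²` with logistic weights
`wᵢ = 1/(1+exp(2(dᵢ−(2σ̂−m̂))/σ̂))` recomputed each iteration from the
negative residuals `dᵢ = yᵢ − zᵢ < 0`. Points far above the baseline
(peaks) lose weight; drift keeps it. The pentadiagonal system is solved in
banded LDLᵀ form for all 601 channels simultaneously (numba).

Two choices matter and were fixed by measurement on simulated gradients:

* `λ = 1e4` (default). At 1e5 the baseline's ~18-sample stiffness length
  bridges the gradient program's corners (e.g. the 390 s kink of the
  8-minute method) poorly, biasing areas integrated near them — including
  the internal-standard window — by several percent. 1e4 tracks the
  trapezoidal drift to < 1 mAU while remaining stiff over peak widths of a
  few seconds.
* The baseline is *estimated* on the unsmoothed trace and *subtracted* from
  the smoothed one. arPLS's weight update assumes serially uncorrelated
  noise; smoothing first correlates it and shifts the equilibrium several
  noise-sigmas below the drift, inflating every downstream area (≈ +5%
  measured at 2 mAU noise).

Known limitation: during the 100% hold and re-equilibration (t > 390 s in
the default program) the drift hump is indistinguishable from a broad peak
to any single-trace estimator and is partially cut under. Nothing elutes
there; all quantification happens on the ramp, where recovery is < 1% RMS
of the drift range at study noise levels.

**Internal standard.** 4,4′-di-*tert*-butylbiphenyl is spiked into the
diluent; its peak area at a configured wavelength/window, divided into its
nominal area, scales all reported areas. This cancels exactly the
multiplicative errors that hit sample and standard jointly — autosampler
injection-volume variability, dilution error, solvent water uptake. Factors
outside [0.8, 1.25] are flagged, outside [0.5, 2] clipped (gross handling
failure, not a correctable drift). Per-analyte stock-dispense error is *not*
correctable this way and remains in the error budget.

## MS target location

The product m/z is the monoisotopic mass plus an adduct shift ([M+H]⁺
+1.00728 Da by default; Na⁺/NH₄⁺/−H available). Channels match within
±0.5 Da (unit-resolution quadrupole). Peaks are local maxima above
`min_snr` (default 10) times the robust noise floor (1.4826 × MAD of the
median-subtracted trace); the window is the contiguous region above 5% of
apex extended to the nearest minima. The most intense peak across the adduct
list wins; intensity is used *only* to rank candidates — ionization
efficiency and absorptivity are uncorrelated, so it never enters
quantification.

The PDA→MS transit delay is a plumbing property. When configured
(`system.pda_ms_delay`) it is used directly; when absent it is estimated by
cross-correlating the total-absorbance trace with the summed MS intensity
over lags within ±30 s, with the correlation evaluated only on the joint
peak support of the two aligned signals and required to cover at least half
of the smaller support. The support restriction stops detector-specific
features (the non-ionizing internal standard, UV-weak products) from either
diluting the statistic or creating spurious single-peak alignments; a
sub-threshold correlation is a configuration error rather than a guess.

## Curve resolution

The window `A_w` around the located target is factored as
`A_w = C Sᵀ + E` with non-negative elution profiles `C` and non-negative
spectra `S` (columns unit-maximum; magnitudes live in `C`, so integrated
areas are `Δt·ΣC·S(λ_red)`). Fitting is alternating exact small-N
non-negative least squares (active sets enumerated — exact for N ≤ 3) from
a deterministic purest-row (maximum-angle) initialization, with an accepted
extrapolation step along the iterate difference: plain ALS converges
linearly and very slowly near zero-residual solutions, and the β-doubling
extrapolation reaches deep convergence (lack of fit ≲ 1e-6 AU·s on
noiseless data) in a few thousand iterations. Production defaults: relative
residual tolerance 1e-8, 500 iterations — far below the ~0.05 AU·s noise
floor of real windows.

Component count: fit N = 1, 2, 3 in order and keep the first whose lack of
fit — the time integral of the wavelength-RMS residual, `Δt·Σₜ
RMS_λ(E)`, in AU·s — is below 0.2 AU·s. This metric has the threshold's
units and is insensitive to the number of wavelength channels. If N = 3
still fails, the window is flagged overloaded and the yield withheld: more
species co-elute than an 8-minute gradient can support, and the honest
outputs are a flag and a rerun suggestion, not a number.

The target is the component whose elution apex is nearest the MS retention
time (ties to the more intense, logged; apexes farther than half the window
raise an ambiguity error). Quantification happens at the reddest qualifying
maximum of its resolved spectrum (≥ 220 nm — below that acetonitrile and
DMSO absorb; prominence ≥ 5% and height ≥ 10% of the spectrum maximum,
after light spectral smoothing, so single-channel noise in the red tail of
a weak spectrum cannot masquerade as a band).

Known failure modes, all reproduced in tests: near-identical spectra with
heavy co-elution merge into one component (yield overestimated); a spectrum
that shifts with solvent composition during elution breaks bilinearity and
over-segments the window; a weak target under a much stronger co-eluting
absorber can fall below the lack-of-fit threshold's ability to notice it.
These are properties of single-chromatogram curve resolution, not bugs; the
0.2 AU·s threshold trades them against spurious splitting.

## Extinction coefficient

`ε` comes from a pluggable predictor returning, per solvent, the mean and
spread of an ensemble of log₁₀ ε predictions at the compound's reddest
absorption maximum. Two implementations ship: a lookup table (tests,
simulations, user-supplied measurements) and an adapter that shells out to
an externally trained ensemble and reduces its per-model outputs to
mean/population-std. No predictive model is trained or shipped here.

Because elution happens mid-gradient, predictions for pure water and pure
acetonitrile are combined at the volumetric acetonitrile fraction φ of the
elution time: `ε = φ·10^μ_acn + (1−φ)·10^μ_water` (water–acetonitrile
polarity is near-linear on a volumetric basis, so the weighted average is
defensible). Averaging in linear ε space keeps Beer–Lambert linear in the
result; log-space averaging differs by ≤ a few percent over the plausible
μ gaps and is noted as an alternative. The relative ε uncertainty is
linearized as `ln10 · (φ·σ_acn + (1−φ)·σ_water)` and combined in
quadrature with the area uncertainty (the lack of fit restricted to the
component's support) to give the reported relative yield uncertainty.

## Simulated study conditions

The simulator generates the campaign the method was built for, with full
ground truth, by inverting the quantification algebra exactly: each
analyte's Gaussian elution profile carries area `n·ε(φ(t_R))·ℓ/Q`, its
spectrum is a Gaussian band mixture normalized to 1 at the reddest band
center, the baseline follows the gradient shape, and MS peaks sit at
retention + delay with random ionization efficiency. Defaults mirror the
platform conditions: 1–3 drug-like analytes per sample at millimolar
concentration (target concentration = yield × 15 mM / 3, i.e. ≤ 5 mM
injected), 2.0 µL injections, the printed 8-minute 5%→100% acetonitrile
program, a 2 mM internal standard at 360 s, 2 mAU detector noise, 50 mAU
drift, 0.5 µL pipetting error on 100 µL preparations, log₁₀ ε drawn
uniformly on [2.7, 4.4], and ~30% of impurities placed to co-elute with the
target. Error sources are seeded and *paired*: the underlying standard-normal
draws are consumed regardless of each source's magnitude, so campaigns
differing only in one magnitude are common-random-number comparable.

What the simulator does not emulate — and what passing tests therefore do
not show about real data: real (non-Gaussian) band shapes and tailing
peaks, retention-time variability of a real column, detector saturation
clipping (saturation is flagged, not simulated), adduct competition and
ionization suppression, isotope envelopes, and real ε prediction error
structure (injected as independent log-normal table noise instead). The
published experimental campaign's absolute error rates depend on a trained
predictor and real instrument data and are not reproducible here; the test
suite instead verifies inverse consistency (noiseless yield recovered to
≪ 1%), realistic-noise accuracy (100-sample campaign median error < 5%),
error-source ordering, internal-standard efficacy, and the documented
failure modes.

## Numerical notes

* arPLS: σ̂ floored at ~10·eps·scale; residuals within 1e-9·scale of zero
  count as non-negative (so constant traces converge in one iteration);
  logistic exponent clipped at ±500.
* NNLS active-set enumeration uses a tie tolerance relative to each
  column's own energy, so tiny peak-tail columns are fitted, not zeroed.
* All-zero resolution windows return a single zero component with zero lack
  of fit; all-zero spectra are validation errors.
* Degenerate MCR ties (a component's spectrum collapsing to zero) are
  re-seeded from the op's `seed`; everything else is deterministic, and
  identical inputs + config produce byte-identical reports (timings aside).
* Reported problem sizes: simulated chromatograms are 481 time points ×
  601 wavelengths (1 Hz, 1 nm over 200–800 nm); campaigns in the test
  suite and acceptance script use 16–100 samples.
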