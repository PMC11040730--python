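# Methods

## Problem

A crude (unpurified) reaction mixture produces a single ¹H NMR spectrum in
which the resonances of several compounds overlap.  Given *predicted*
spectra for a library of candidate compounds — chemical shifts with a known
error level, J-couplings, and proton counts, typically derived from
DFT-computed shieldings — `nmrdeconv` decides which candidates are present
and estimates their relative concentrations.  No experimental reference
spectrum of any individual compound is required; the price is that the
predicted shifts are wrong by a method-dependent amount (≈0.4 ppm for
rule-based predictors, ≈0.1 ppm for GGA-level DFT after linear scaling,
≈0.01 ppm for literature shifts), and the fit must tolerate that error.

## Forward model

Each proton environment *l* contributes an amplitude `a_l` (proportional to
its proton count) at shift `δ_l`.  The time-domain signal of a decaying
oscillation Fourier-transforms to a Lorentzian, so a resonance is rendered
as a unit-area Lorentzian of full width at half maximum `fwhm`; the
exponential decay rate is `λ = π·fwhm`.  The default intrinsic width is
2 Hz, typical of small molecules in solution.

Scalar couplings split a resonance by the first-order *N*+1 rule: a group of
*N* equivalent partners with coupling *J* produces *N*+1 lines with
binomial (Pascal-row) intensities and adjacent-line spacing *J* (a doublet
sits at ±J/2 about the shift).  Groups convolve, so (J₁,1)+(J₂,1) gives a
doublet of doublets.  Couplings are entered in Hz and converted to ppm
through the spectrometer frequency (default 500 MHz).  Second-order
(strong-coupling) effects are out of scope.

Before fitting, both the observed and the simulated spectra are convolved
with a unit-area Gaussian of 10 Hz fwhm.  This deliberately discards
multiplet fine structure and widens every feature so that a line predicted a
few hundredths of a ppm away from its true position still overlaps it —
without that overlap the likelihood gradient with respect to the shift is
zero and Hamiltonian dynamics cannot pull the line home.  Because couplings
barely matter after this broadening, J values and linewidths are held fixed
during fitting.  A simulated line after broadening is exactly a Voigt
profile (2 Hz Lorentzian ⊛ 10 Hz Gaussian).

## Shielding calibration

DFT shieldings carry systematic errors; regressing observed shifts against
computed shieldings and using the fitted affine map as the predictor acts as
an empirical correction.  The shipped default line
`δ = −0.9548·σ_iso + 30.435` ppm (R² = 0.9941, residual MAE ≈ 0.1 ppm) was
obtained from 33 CDCl₃ solution spectra against B3LYP/cc-pVTZ shieldings;
`fit_calibration` refits it from user pairs.  The training pairs are not
redistributed with the package, only the fitted constants.

## Joint posterior

The observed spectrum is normalised to unit area and treated as a
probability density `y(δ)`.  Latent variables:

| variable | prior | default scale |
|---|---|---|
| weight `w_i` per compound | Half-Cauchy | scale 1.0 |
| shift `δ_r` per resonance | Normal(prediction, σ_method) | 0.4 / 0.1 / 0.01 ppm |
| noise sd `σ` | Half-Cauchy | scale 0.05 |

The model density is the normalised weighted sum of the candidates' Voigt
spectra evaluated at the sampled shifts, and the likelihood is i.i.d.
Gaussian over grid points, `y_j ~ N(m_j(w, δ), σ)`.  The likelihood form and
the noise/weight hyper-scales are this package's own choices: the Gaussian
residual model with a self-tuning Half-Cauchy `σ` is the standard choice for
density matching with gradient-based MCMC, and `σ` then absorbs baseline
noise, lineshape mismatch, and unmodelled impurities alike.  Weights enter
through `w_i = exp(u_i)` and the analytic normaliser `Z = Σ w_i A_i`
(`A_i` = total proton weight of compound *i*), so the inferred composition
is invariant to the overall intensity scale of the data.  An optional
truncated-shift parametrisation (`PriorConfig.truncate_sd`) maps an
unconstrained variable through a scaled `tanh` so shifts cannot wander more
than ±k·σ from the prediction; the default is the plain Normal.

## Sampling

The posterior is sampled with an in-package No-U-Turn sampler (slice
variant, dual-averaging step size targeting 0.8 acceptance, diagonal mass
matrix estimated midway through warmup, divergence threshold 1000, maximum
tree depth 8 by default).  Gradients are analytic: a numba kernel evaluates
each line's Voigt profile and its shift derivative via Humlíček's four-region
rational approximation of the Faddeeva function (relative error ≈ 1e−4) and
accumulates the chain-rule products in one pass.  Two approximations keep a
gradient evaluation at ~0.1–0.4 ms:

- each line is evaluated only inside a ±0.3 ppm window that follows its
  current centre; the clipped Lorentzian tail mass (≈0.5% per line) is
  absorbed by the noise scale;
- the model is normalised analytically by `Z` rather than by its trapezoid
  integral, so edge truncation of lines near the spectral limits introduces
  a sub-percent scale mismatch, likewise absorbed by `σ`.

The full-length run is 1000 warmup / 3000 kept samples.  Noiseless
self-fits drive `σ` toward the numerical error floor and the resulting
razor-thin posterior produces divergence warnings; concentration estimates
remain accurate, and a warning is logged whenever more than 10% of
transitions diverge.

## Deconvolution loop

1. Fit all candidates; summarise the concentration as the geometric-mean
   **center** of the closed weight draws (compositional statistics on the
   simplex; zeros floored at 1e−12).
2. Remove candidates whose center falls below the cutoff (default 5%;
   10% is appropriate for spectra with substantial impurity signals).
3. Refit survivors; stop when the surviving set repeats.
4. If any surviving resonance keeps a shift-posterior spread larger than
   twice its prior σ — the signature of a line that found no peak — one
   extra iteration runs with shift priors widened to three times the base σ
   (0.3 ppm for DFT-level inputs), once only.
5. After `max_iter` (default 6) iterations without stabilising, the last
   fit is returned flagged unconverged.

`present` is the surviving set of the final fit; the reported composition
places pruned candidates at exactly zero.

### Interval mode

Intervals of ±0.5 ppm around every predicted line are merged and ranked by
the Bernoulli information entropy of the fraction `p` of library compounds
predicted to resonate inside: `H = −p·log₂p − (1−p)·log₂(1−p)`.  Intervals
where about half the candidates appear are the most likely to eliminate
someone and are fit first; ties are broken from least shielded (highest
ppm) downward, as in manual analysis.  An interval fit restricts the
*globally* normalised observed density and the member compounds' lines to
the interval and fits free member weights without renormalising, so each
weight estimates that compound's absolute share of the whole spectrum and
is compared with the cutoff directly; members of an essentially empty
region are therefore pruned.  Compounds with no lines in the interval are
untouched.  After all intervals, the global prune-and-refit loop runs on
the survivors.  The entropy reading of "information content" as
presence/absence (Bernoulli) rather than categorical over members matches
the elimination rationale; the categorical alternative would rank crowded
regions highest, the opposite of what elimination needs.

## Synthetic benchmarks

The generator emulates a small-molecule ¹H spectrum statistically: 10
resonances per compound, shifts ~ U(0, 10) ppm, integer amplitudes 0–3
(zero-weight resonances are legal and render to nothing; the astronomically
unlikely all-zero compound is redrawn), exactly 5 resonances made doublets
with J ∈ {5, 10} Hz, intrinsic width 2 Hz.  True mixtures weight the
components with a symmetric Dirichlet whose concentration equals the number
of mixed compounds — under a flat Dirichlet the probability that a true
mole fraction falls below the 5% decision cutoff is 18.6% per part, which
would cap even a perfect estimator's classification accuracy at ~91% and is
incompatible with the ~97% achievable at library-quality shifts; the
concentrated reading removes that ceiling (99.7%).  The composite is scaled
to unit maximum so that the optional baseline-noise sd of 0.01 is ≈1% of
the tallest peak.  The candidate library handed to the fit is the same
compound set with every shift independently jittered by N(0, σ_theory²).

What the generator does *not* emulate: correlated spectra of structurally
similar isomers (real crude mixtures concentrate many near-identical
multiplets in narrow regions), reciprocal coupling partners, solvent and
impurity peaks, phase/baseline distortion.  Passing benchmarks therefore
demonstrates tolerance to shift error and overlap by chance, not the harder
correlated overlap of real regioisomer mixtures.

Benchmark scoring: composition MAE `(100/D)·Σ|x̂_i − x_i|` over the full
candidate simplex with absent candidates at zero, and classification
accuracy `(TP+TN)/total` of present/absent calls at the 5% cutoff.

## Problem sizes and numerical defaults

Benchmark and test runs use deliberately reduced sizes chosen once: 10
repeats per condition (the full protocol uses 15), warmup 500 / 1000 kept
samples (the acceptance script shortens this to 400 / 800 for the
wide-margin targets and keeps 500 / 1000 for the hardest condition), a
2¹⁴-point generation grid, a
1024-point fit grid (≈4.6 points per broadened linewidth after the 10 Hz
filter; spectra are broadened at native resolution *before* downsampling),
and NUTS tree depth capped at 6.  Three-seed probes at these settings
reproduce or better the full-scale reference accuracy at every error level.
Rendering uses the 2¹⁴ grid (≈6.6 points per 2 Hz linewidth; a coarser grid
logs a warning below 4 points/fwhm).  FFT-based apodization accepts edge
effects within ~0.5 ppm of the grid limits.

## Known limitations

- First-order multiplets only; no roof effects or strong coupling.
- The i.i.d. Gaussian likelihood ignores the noise correlation introduced
  by the 10 Hz filter; `σ` is interpretable only as an effective scale.
- At 0.4 ppm shift error the posterior is strongly multimodal; chains can
  lock into wrong line assignments, and the reported spread of repeated
  benchmark runs is the honest uncertainty estimate.
- Absolute (molar) quantification, ¹³C/HSQC data, and raw-FID processing
  (phasing, baseline) are out of scope.
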