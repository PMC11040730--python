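# nmrdeconv

Bayesian deconvolution of ¹H NMR spectra of multi-compound reaction
mixtures.

High-throughput synthesis campaigns produce crude reaction mixtures whose
¹H NMR spectra contain several overlapping compounds — often constitutional
isomers that chromatography and mass spectrometry cannot tell apart.
`nmrdeconv` answers the two questions a bench chemist asks of such a
spectrum: *which* of the plausible products are actually present, and in
*what ratio* — using only **predicted** spectra (chemical shifts with a
stated error level, J-couplings, proton counts) for the candidates, e.g.
from DFT shieldings passed through a linear calibration.  No authentic
standards or reference spectra are needed, so the method extends to
compounds never made before.

## Model

Each candidate spectrum is a sum of unit-area Lorentzian multiplets: a
resonance of amplitude `a_l` (proton count) at shift `δ_l` with linewidth
`fwhm = λ/π` (default 2 Hz), split by each J-coupling group into N+1 lines
with Pascal-triangle intensities spaced J apart.  DFT shieldings map to
shifts through the calibrated line `δ = −0.9548·σ_iso + 30.435` ppm.

The observed spectrum, Gaussian-broadened (10 Hz fwhm) and normalised to
unit area, is treated as a probability density and modelled as

    y(δ) ≈ Σ_i w_i S_i(δ; δ_i + Δ_i) / Σ_i w_i A_i ,

with Half-Cauchy priors on the weights `w_i`, Normal priors
`Δ_r ~ N(0, σ_method²)` on every resonance shift (σ = 0.4 / 0.1 / 0.01 ppm
for rule-based / DFT / literature predictions), an i.i.d. Gaussian
likelihood over grid points, and a Half-Cauchy noise scale.  The posterior
is sampled with a No-U-Turn sampler using analytic gradients.  Candidates
whose geometric-mean simplex concentration falls below a cutoff (default
5%) are pruned and the fit repeats until the surviving set is stable;
entropy-ranked spectral intervals can be fit first to eliminate candidates
cheaply (`--intervals`).  See `docs/methods.md` for the full account and
`docs/formats.md` for the file formats.

## Worked example

Deconvolute a synthetic Wittig-olefination crude — benzaldehyde plus the E
and Z methyl cinnamates, mixed 20 : 55 : 25 — using a candidate library
whose shifts are deliberately wrong by ~0.1 ppm (DFT-level error):

```python
import numpy as np
import nmrdeconv as nd

lib = nd.read_library("docs/examples/wittig_library.json")

# "observed" spectrum: the same compounds at jittered positions
rng = np.random.default_rng(11)
true = nd.jitter_library(lib, 0.1, rng)
obs = nd.render_mixture(true, [0.20, 0.55, 0.25], nd.make_grid())

fit = nd.deconvolute(lib, obs, cutoff=0.05,
                     cfg=nd.SamplerConfig(warmup=500, samples=1000, seed=1))
for name, frac in zip(fit.library_names, fit.center_full):
    print(f"{name:22s} {frac:6.3f}  present={fit.present[list(fit.library_names).index(name)]}")
```

prints

```
benzaldehyde            0.178  present=True
methyl cinnamate (E)    0.643  present=True
methyl cinnamate (Z)    0.179  present=True
```

All three candidates are correctly called present, and the recovered mole
fractions track the true 0.20 / 0.55 / 0.25 composition with a mean
absolute error of ~6% — the residual error comes almost entirely from the
aromatic region near 7.2–8 ppm, where all three compounds overlap and a
0.1 ppm shift error blurs the E/Z attribution, while the well-separated
olefinic and aldehyde resonances anchor the presence calls.  The same run
from the shell:

```sh
nmrdeconv deconvolute --spectrum obs.csv --library docs/examples/wittig_library.json \
    --cutoff 0.05 --warmup 500 --samples 1000 --seed 1 --report out.json
```

The JSON report carries the composition with 95% credible intervals,
present/absent flags, per-resonance shift posteriors, the prune history and
sampler diagnostics.

## Synthetic benchmarks

`nmrdeconv benchmark` regenerates the artificial-mixture benchmark suite:
random 10-resonance compounds mixed with Dirichlet weights, library shifts
jittered at the chosen error level, optional 1% baseline noise, scored by
composition MAE and present/absent classification accuracy:

```sh
nmrdeconv benchmark --preset b3 --theory dft --n-true 5 --repeats 10 --seed 7 --out b3.csv
```

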