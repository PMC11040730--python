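# File formats

## Spectrum: two-column text

Whitespace- or tab-separated `(ppm, intensity)` pairs; `#` lines carry
`KEY=VALUE` metadata.  `MHZ` sets the spectrometer proton frequency
(default 500, with a logged warning when absent).  A descending ppm axis is
accepted and re-sorted.

```
# MHZ=700
0.000000	0.0000012
0.000610	0.0000034
...
```

## Candidate library: JSON

Either a bare list of compounds or an object with optional calibration:

```json
{
 "calibration": {"slope": -0.9548, "intercept": 30.435},
 "compounds": [
  {
   "name": "methyl cinnamate (E)",
   "shift_sigma": 0.1,
   "resonances": [
    {"shift_ppm": 7.69, "weight": 1, "couplings": [{"J_hz": 16.0, "N": 1}], "fwhm_hz": 2.0},
    {"shielding": 24.6, "weight": 3, "couplings": []}
   ]
  }
 ]
}
```

- `shift_ppm` *or* `shielding` per resonance; shieldings are converted
  through the calibration line (file header > function argument > shipped
  default).
- `weight` is the proton count (or any amplitude proportional to it).
- `couplings` follow the N+1 rule: `{"J_hz": J, "N": n}` adds one group of
  n equivalent partners.
- `shift_sigma` is the 1σ uncertainty of the predicted shifts in ppm
  (0.4 rule-based, 0.1 DFT, 0.01 literature).
- Compound names must be unique; every compound needs ≥1 resonance.

## Truth file (optional scoring), JSON

```json
{"composition": {"A": 0.6, "B": 0.4}, "present": ["A", "B"]}
```

## Run report, JSON

Written by `write_report` / `nmrdeconv deconvolute --report`: echoed inputs
(including the seed, so a rerun reproduces the draws exactly), per-compound
present flags, the geometric-mean center over the final survivors and over
the full original library (pruned candidates at 0), 95% credible intervals
of the closed weight draws, per-resonance shift posterior means/sds,
the interval table when interval mode was used, per-iteration prune
history, and sampler diagnostics (divergences, step size, mean acceptance).
Keys are sorted; two runs with identical inputs produce identical files.
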