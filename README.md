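# bcarskit

Simulation and spectral post-processing for **broadband coherent
anti-Stokes Raman scattering (BCARS) microscopy** — label-free chemical
imaging of cells and tissue at millisecond pixel dwell times.

A BCARS microscope records, at every pixel, a full vibrational spectrum
generated by a narrowband pump pulse (1035 nm, <9 cm⁻¹) and a broadband
Stokes continuum (≈1100–1600 nm). Two mechanisms contribute: *two-color*
excitation at the pump–Stokes detuning (reaching ≈3400 cm⁻¹ for a Stokes
edge at 1600 nm) and impulsive *three-color* excitation by the Stokes
pulse alone, which emphasizes the fingerprint region and vanishes with
increasing wavenumber. The raw spectra are distorted by the nonresonant
background (NRB) and by mixed Poisson–Gaussian detector noise.

`bcarskit` implements the full analysis chain used for such data, plus a
physics-based forward model so every stage can be validated without an
instrument:

| stage | estimator / function | method |
|---|---|---|
| synthesis | `cars_spectrum`, `render_hypercube`, `demo_scene` | χ⁽³⁾ = χ_R + χ_NR with Lorentzian modes; two-/three-color cross-correlation excitation; pump-limited resolution; pump–Stokes delay; Poisson–Gaussian noise |
| calibration | `WavenumberCalibrator`, `subtract_dark` | peak detection + polynomial channel→cm⁻¹ fit against known analyte lines |
| denoising | `AnscombeSVDDenoiser` | Anscombe variance stabilization → unfold → truncated SVD (M̂ = UŜV*) → inverse |
| NRB removal | `KramersKronigRetriever`, `kk_retrieve` | time-domain Kramers–Kronig: φ = H[½ ln(I/I_NRB)], Raman-like spectrum Im[√R e^{iφ}] |
| unmixing | `NFINDR`, `nnls_abundances` | simplex-volume maximization V = \|det E\|/(k−1)! in PCA-reduced space; nonnegative least-squares abundances |
| statistics | `integrate_band`, `box_stats`, `mann_whitney` | marker-band integrals (amide I 1620–1690, triglycerides 1715–1760 cm⁻¹), substrate masking, Mann–Whitney test |

The estimators follow scikit-learn conventions (`fit`/`transform`,
`get_params`, trailing-underscore attributes) and compose with sklearn
tooling.

## Worked example

The packaged `nash_vs_control` scene pair emulates a fatty-liver-disease
comparison: two 50×50 tissue scenes with identical protein/lipid layouts
on a quartz substrate, except that the triglyceride-bearing lipid
species' abundance is raised 1.5× in the diseased scene.

```bash
bcarskit demo out/ --seed 42
```

runs simulate → dark subtraction → Anscombe-SVD (rank 6) → Kramers–Kronig
→ N-FINDR (k = 2, joint fit of both scenes) → band statistics, and prints

```
amide I: p = 1.3e-157
triglycerides: p = 3.95e-230
```

with the full report in `out/report.json`:

```
amide I       | control median 6.118 | diseased median 5.013
triglycerides | control median 1.303 | diseased median 1.720
```

i.e. the control tissue scores higher in the protein (amide I) band, the
diseased tissue in the triglyceride ester band, and both differences are
overwhelmingly significant under the Mann–Whitney test — the expected
signature of hepatic triglyceride accumulation.

The same chain is available stepwise (`bcarskit simulate | calibrate |
denoise | retrieve | unmix | quantify | run`) and as a library:

```python
from bcarskit import (AnscombeSVDDenoiser, KramersKronigRetriever, NFINDR,
                      default_noise, default_pump, default_stokes,
                      demo_scene, render_hypercube)

scene = demo_scene("cells", shape=(64, 64), seed=0)
cube, truth = render_hypercube(scene, default_pump(), default_stokes(),
                               default_noise(0))
den  = AnscombeSVDDenoiser(rank=6, sigma=5.0).fit_transform(cube)
```

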