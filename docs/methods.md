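# Methods

## Signal model

The sample response is a third-order susceptibility
χ⁽³⁾(Ω) = χ_R(Ω) + χ_NR with a sum-of-Lorentzians resonant part,

    χ_R(Ω) = Σ_j A_j / (Ω_j − Ω − iΓ_j),

(positions Ω_j and half-widths Γ_j in cm⁻¹; an isolated mode has on-resonance
Im χ = A_j/Γ_j and Im-lineshape FWHM 2Γ_j) and a real, spectrally flat
nonresonant constant χ_NR. Quartz is modeled as pure χ_NR, which is why a
bare quartz coverslip serves as the NRB reference.

The rendered anti-Stokes amplitude on a Raman-shift axis Ω is

    A(Ω) = [ X₂(Ω) + X₃(Ω) ] · χ(Ω)   convolved with   |E_p|,
    I(Ω) = |A(Ω)|²,

where X₂ = E_S ★ E_p (pump–Stokes cross-correlation over frequency detuning)
and X₃ = E_S ★ E_S (Stokes intra-pulse autocorrelation) are evaluated with
the complex fields, so Stokes chirp suppresses X₃ and a pump delay
(implemented as a linear spectral phase) collapses X₂ on the pulse-overlap
timescale. Because χ_NR sits inside the modulus, resonances appear as
dispersive lineshapes whose raw maxima are *not* at Ω_j — the distortion the
Kramers–Kronig stage removes. Amplitudes are linear in the susceptibility, so
a pixel containing a mixture is rendered as |Σ_k a_k A_k|², i.e. species
interfere coherently within a focal volume.

Normalization: each mechanism's excitation amplitude is scaled to unit
maximum at zero delay, with a `mechanism_balance` factor for their ratio
(default 1). Absolute prefactors (powers, focusing, collection) are arbitrary
units; an instrument is in practice tuned so the fingerprint and CH-stretch
regions have comparable intensity, and the normalization encodes that tuning.

Time-delay physics: at pump delay τ > 0 the nonresonant and two-color terms
decay with the pump–Stokes envelope overlap, while impulsively driven
resonant coherences decay analytically as exp(−τ/T₂) with T₂ = 1/(2πcΓ_j).
This reproduces optical NRB suppression (>10× at 3 ps) with a surviving
resonant signal, without full time-domain propagation.

Fields: the pump is a Lorentzian-modulus line (etalon transmission) whose
squared modulus has the stated intensity FWHM (default 9 cm⁻¹ at 1035 nm);
its modulus, of FWHM ≈ 1.554× that, is the amplitude-domain resolution
kernel. The Stokes is a flat-top with raised-cosine edges (default width
60 cm⁻¹) over a configurable support (default 1100–1600 nm), an optional
short-wavelength hard mask, and a quadratic spectral phase set by GDD in fs².
A transform-limited 1200–1600 nm Stokes has a sub-20 fs intensity FWHM, short
enough to drive modes up to the ≈1380 cm⁻¹ band whose period is ≈24 fs; the
tuned impulsive coverage of the reference configuration is recorded as
`THREE_COLOR_BAND = (400, 1400)` cm⁻¹.

## Detector noise

counts = g·Poisson(I/g) + N(0, σ) + dark, so Var = g·I + σ². Defaults:
g = 1 count/photoelectron, σ = 5 counts, dark = 100 counts, exposure scale
set so the brightest clean channel is 5000 counts/ms. `poisson_gain = 0`
disables shot noise (the deterministic limit). All randomness flows through
a single seeded `numpy` Generator per rendered object.

## Processing chain

**Calibration.** Peaks of an analyte spectrum are detected
(`scipy.signal.find_peaks`, relative prominence, 3-point parabolic centroid),
matched in sorted order to a user-supplied line list and fitted with a
degree-1…3 polynomial (default 2); non-monotonic fits are rejected. Because
raw CARS maxima are interference-shifted, the recommended input is the
KK-retrieved analyte spectrum, with which the simulator round-trip recovers a
known axis to ≈0.03 cm⁻¹ RMS (vs ≈0.7 cm⁻¹ when fitting raw CARS peaks).

**Denoising.** Generalized Anscombe transform
(2/g)√(gx + 3/8 g² + σ²) → unfold to s×p → SVD → keep the leading
singular values → reconstruct → algebraic inverse. The cutoff is a fixed
rank (default 6), a singular-value threshold, or a log-scree knee; the
algebraic inverse keeps the round trip exact, and data driven negative by
dark subtraction are offset into the transform domain and shifted back.
Rank selection is deliberately manual-first: reproducibility over
cleverness.

**Kramers–Kronig retrieval.** φ = H[½ ln R] with R = I/I_NRB, computed by
FFT Hilbert transform on a copy padded to 4× length with a raised-cosine
bridge back to the first sample (no periodic jump). The slowly varying
error phase — quartz-vs-in-sample NRB mismatch and residual envelope — is
estimated with a Savitzky–Golay smoother (default window s/2, order 2) made
peak-robust by two outlier-masked refits, then subtracted; the output is
Im[√R·e^{i(φ−φ_err)}]. Short smoother windows follow the resonances and both
carve negative side-lobes and narrow retrieved lines (≈18% at Γ = 20 cm⁻¹ at
s/10, within 4% at s/2), which is why the long window is the default.
Negative retrieved values are kept (clipping is presentation-only). The
time-domain phase agrees with a direct principal-value Kramers–Kronig
integral to <10⁻³ rad RMS away from the edges.

**Unmixing.** Pixels are projected to (k−1) principal components; N-FINDR
seeks the k pixels maximizing V = |det[[1…1],[e₁…e_k]]|/(k−1)! by
endmember-major, pixel-minor single-pixel replacement with strict-increase
acceptance (candidate determinants for a slot evaluated in one pass via
Cramer's rule), until a sweep makes no change or `max_sweeps` is hit.
Five seeded restarts are run and the best volume wins; k stays manual.
Abundances solve min‖Ea − x‖², a ≥ 0 per pixel (`scipy.optimize.nnls`).
With pure pixels and exact linear mixing the composition recovers
abundances to <10⁻⁶.

**Quantification.** Trapezoidal band integrals (amide I 1620–1690,
triglyceride ester 1715–1760 cm⁻¹); substrate pixels are masked on a
tissue-presence band (CH stretch 2800–3020 cm⁻¹ total, threshold 0.2× its
pooled 95th percentile) and outliers dropped at median ± 5 IQR — one rule
object shared across all compared images so the comparison is not
distorted. Box statistics use linearly interpolated quantiles and
1.5×IQR whiskers. The Mann–Whitney test uses exact enumeration with
midranks for min(n) ≤ 8 (≤2×10⁵ assignments) and the tie- and
continuity-corrected normal approximation otherwise.

## Synthetic scenes

`demo_scene` builds seeded fixtures from smoothed random fields: `cells`
(lipid / protein / nucleic-acid species plus quartz substrate, ≥1 pure pixel
per species), `nash_vs_control` (a paired liver model: identical layouts,
lipid abundance ×1.5 in the diseased scene), and `tumor`
(tumor / healthy / connective-interface species). Mode lists use standard
band positions (e.g. phenylalanine 1002, amide I 1660, ester 1750, CH₂
2850 cm⁻¹) but are fixtures, not measured susceptibilities.

What the generator does **not** emulate: focal-volume and phase-matching
effects, wavelength-dependent detector throughput, spatial drift and laser
fluctuations, spectrally structured (non-constant) NRB, and real tissue
spectral diversity beyond a handful of Lorentzians. Passing tests therefore
demonstrate algorithmic correctness under the stated model, not performance
on any particular instrument's data.

## Problem sizes and numerics

Cube-level analyses run at 50×50 pixels × 1101 channels (900–3100 cm⁻¹ at
2 cm⁻¹) and single-spectrum analyses at 0.5 cm⁻¹ over 400–3200 cm⁻¹ —
desk-scale versions of 400×400 × 1340-channel instrument maps; the
statistical comparisons are insensitive to this (p-values are far below
thresholds at either scale). Degenerate inputs are defined errors
(zero-variance unmixing input, rank-deficient endmembers, empty bands,
all-masked images); N-FINDR ties never replace, keeping results
deterministic under a fixed seed; nonpositive NRB channels are floored at
10⁻⁶ of the reference maximum.
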