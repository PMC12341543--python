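# Methods

This note documents the models behind each module, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic striated fields

A field is rendered in a rotated coordinate frame: *u* runs along the
fiber axis, *v* across it. Z-disks are Gaussian-profiled stripes
perpendicular to the axis at spacing `period_um` (default 2.5 µm, within
the 2.2–2.5 µm range of resting sarcomeres), with cross-section
σ = 0.15·period — a width comparable to a diffraction-limited Z-disk
image without modelling optics. The C-zone doublet pattern places two
sub-bands per sarcomere, `doublet_gap_um` apart (default 0.9 µm); the
sub-bands use 0.6× the Z-disk σ because with the full width the two
0.9-µm-spaced Gaussians nearly merge and the doublet loses both its
two-maxima profile and most of its second-harmonic power — i.e. the
fixture would stop looking like a C-zone doublet.

Perturbations, each with ground truth retained:

- **Lateral breakage** — gap midpoints drawn from a Poisson process at
  `break_rate` per 100 µm of band length; each gap zeroes a fixed 0.5 µm
  of band. A single interpretable rate parameter; the gap log is stored
  for parameter-recovery tests.
- **Register jitter** — each band is shifted rigidly along the axis by an
  independent N(0, `register_jitter_um`²) offset. This produces
  out-of-register sarcomeres *without* lateral breakage (the skeleton is
  untouched) while attenuating the periodicity peak by the lattice
  Debye–Waller factor exp(−(2πσ/d)²).
- **Waviness** — a sinusoidal axial displacement of all bands as a
  function of *v* (amplitude, wavelength). Bands stay unbroken; their arc
  length, hence the continuity score, grows, while the straight-axis
  projection smears the periodicity peak.

Pixel size defaults to 0.1 µm/px (no calibration is implied by typical
60× metadata, so this is a free choice satisfying Nyquist by 12×).
Intensities are scaled to [0, 1] before additive Gaussian noise. The
generators are pure functions of their truth records (seed included), so
outputs are bit-identical across runs.

Not emulated: point-spread functions, optical sectioning or 3-D stacks
(analysis targets z-projected fields), fiber-to-fiber intensity
variation, tissue autofluorescence, or curved fiber bundles (orientation
is a single global angle). Passing tests therefore demonstrate
correctness of the *measurement* pipeline under controlled geometry, not
robustness to every real-tissue artifact.

## Organization scores

**Skeleton statistics.** The α-actinin image is Gaussian-smoothed
(σ = 1 px), thresholded (Otsu by default), cleaned of foreground objects
smaller than 0.25 µm² and thinned to a 1-px skeleton. Without the
denoising step the skeleton of any noisy field is dominated by shot-noise
speckle fragments, which no practical skeletonization workflow would
keep. The skeleton's pixel graph (8-connectivity) is decomposed into
maximal degree-2 paths between endpoints/junctions; branch length is the
polyline's Euclidean length × pixel size. Breakage = branches per
1000 µm² (area normalization makes fields of different size comparable);
continuity = mean branch length (the simplest statistic consistent with
"length of branches"; the branch-length array is exposed for
alternatives). A `min_branch_um` spur cutoff is available and defaults to
0 (off).

**Power spectrum.** The image is collapsed to a 1-D mean-intensity
profile along the fiber axis (by the projection-slice theorem this equals
sampling the 2-D FFT along that axis), Hann-windowed, zero-padded 8×, and
transformed; power is normalized by the window's coherent gain so a pure
cosine of amplitude *a* scores (a/2)² regardless of profile length or
orientation. Raw rectangular-window bin amplitudes scallop by up to ~36%
depending on how the period falls between bins, which would break
rotation invariance of the score; windowing + padding reduces this below
1%. The fiber axis is taken from the truth/config when known, otherwise
estimated from the dominant 2-D FFT component and refined (±2°) by
maximizing the projection variance — the projection is sharpest exactly
along the axis. The *order* score is the highest local spectral maximum
in the Z-disk band (default 0.30–0.55 µm⁻¹), the *localization* score the
same in the C-zone band (0.65–0.95 µm⁻¹); a field with no local maximum
above a 1e-12 numerical floor is flagged "no periodicity detected" and
scores 0. Amplitudes are read raw (no baseline subtraction), so scores
are comparable only within a run with fixed normalization.

**Classification.** Breakage, continuity and order are z-scored against a
reference panel of wild-type-like fields (≥ 3 required; the built-in
panel uses 10) and flagged high/normal/low at |z| > `z_cut`. Rules, in
precedence order: low order + high breakage → chaotic; high continuity
(without high breakage) → sarcomeric continuum; low order → disordered;
high breakage → lateral misalignment; otherwise prototypic. `z_cut`
defaults to 2.0: with three directional flags tested against a small
same-distribution reference, a 1.5σ cut would false-flag roughly one in
five healthy fields (Student-t tails at n = 10), an unacceptable
family-wise error for a screening call, while the pathological presets
sit ≥ 3σ from the reference on their defining score, so 2.0σ loses no
sensitivity. The wild-type panel itself carries mild field-to-field
variability (jitter U(0, 0.12) µm, break rate U(0, 0.8)/100 µm, waviness
U(0, 0.15) µm) so its spread reflects biology rather than only noise.

## DRX/SRX relaxation fits

Model: y(t) = P₁·e^(−t/T₁) + P₂·e^(−t/T₂) [+ b], fit by trust-region
nonlinear least squares with amplitudes and time constants bounded below
at 0 ("unconstrained" = no tie between P₁+P₂ and 1). Multi-start
initialization over the (T₁, T₂) grid {1, 10} × {100, 300} s spans
published DRX/SRX lifetimes and avoids the local minimum in which both
components collapse onto one lifetime; the lowest-RSS converged start
wins, components are reordered so T₁ < T₂, and fits with T₂/T₁ < 3 are
flagged poorly separated. Standard errors come from the Gauss–Newton
covariance (σ̂²(JᵀJ)⁻¹). Amplitudes are also reported as percentages of
P₁+P₂, the convention for myosin head populations. The optional constant
offset absorbs the non-exchanging fluorescence plateau; both
parameterizations are exposed because the appropriate choice depends on
the acquisition. ROI fits (typically 3 per fiber) aggregate to fiber
level as means over converged ROIs.

Default simulated conditions: 20%/80% DRX/SRX, T₁ = 20 s, T₂ = 200 s,
15-minute chase sampled every 3 s (≈ 300 points, > 4×T₂ for
identifiability), Gaussian noise SD 0.01 of the normalized signal.

## Force traces and contractility

The generator superposes unit-peak twitch kernels
k(t) ∝ e^(−t/τ_rel) − e^(−t/τ_act) at the pulse times of a 500 ms train,
scales the sum linearly so the plateau reaches `fmax_mN` at
`fusion_freq_hz` (default 150 Hz, the in vivo tetanic frequency), clips
at `fmax_mN` above fusion, and renders the post-train segment as a pure
exponential decay with τ_rel from the end-of-train force — the canonical
shape of post-tetanic relaxation, and the property that makes the
maximal relaxation rate analytically fmax/τ_rel. Defaults τ_act = 15 ms,
τ_rel = 80 ms describe a slow postural muscle in a 25 °C bath, where
relaxation is markedly slowed; τ_rel is deliberately large relative to
the 5 ms derivative-smoothing window so the max-slope rate estimator is
not resolution-limited. Sampling is 10 kHz; a 125 Hz down-sampler exists
only for figures.

Analysis: peak force is the baseline-subtracted maximum in
[stim start, stim end + 0.2 s]; rates are the extrema of the
moving-average-smoothed derivative (contraction within the train,
relaxation after it), in mN/s — absolute rather than %Fmax-normalized,
with the raw numbers exposed for renormalization. PCSA = mass/(ρ·L₀)
with ρ = 1.06 mg/mm³ (configurable); specific force divides peak force
by PCSA (ex vivo, mN/mm²) or muscle mass (in vivo, mN/mg).

## Morphometry and behavior

The kyphotic index uses the perpendicular distance to the *infinite* line
through C7–L6 rather than the segment; the two coincide whenever the
dorsal extremum projects inside the chord, which holds for anatomical
spine profiles. A perfectly straight profile yields an infinite KI with a
warning rather than an error. Hang trials are clipped at the 180 s cap
*before* averaging, so an animal at ceiling scores exactly 180 s.

## Statistical routing

Normality is tested per group with D'Agostino–Pearson; groups below its
n ≥ 8 minimum (common for ex vivo muscle cohorts of 4–5 animals) fall
back to Shapiro–Wilk, flagged in the output — the routing must still
operate at those sizes. Variances are compared with a two-sided F test.
Routing: both groups normal and variances similar → Student's two-tailed
t; any normality failure → Mann-Whitney U; variance failure only →
Welch's t. Significance at p < 0.05 with the */**/***/**** star
convention. Force–frequency curves are compared by two-way fixed-effects
ANOVA (group × frequency) on animal-level peak forces — one value per
animal per frequency, since cohort n counts animals — followed by
per-frequency contrasts using the pooled residual variance and Šídák
adjustment with m = number of frequencies. A repeated-measures treatment
of frequency within animal would be the natural extension; it is not
implemented.

The routed procedure's operating characteristics are checked empirically:
`type_one_error_check` simulates normal nulls through the full tree and
reports the rejection rate (the suite requires it to sit in
[0.035, 0.065] at nominal 0.05 with n = 20/group over 2000 simulations).

## Problem sizes and limitations

The built-in analyses use 256×256 px fields (25.6 µm square at
0.1 µm/px, ≈ 10 sarcomeres across), 10-field reference panels, 50-trace
Monte-Carlo fits and 2000-simulation error-rate checks — sizes chosen so
a full validation run completes in minutes on one core while keeping
Monte-Carlo standard errors well inside the tested tolerances.

Known limitations: the branch decomposition treats dense junction
clusters approximately (degree counting on 8-connected thinned skeletons
can merge adjacent junction pixels); spectral scores are unitless and
comparable only within a fixed normalization; the classifier's reference
panel must come from the same imaging conditions as the scored fields;
and the force model's clipped-linear saturation is a phenomenological
stand-in for calcium-handling dynamics, adequate for testing trace
reduction but not for simulating excitation–contraction coupling.
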