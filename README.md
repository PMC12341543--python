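# sarcotrem

Quantitative analysis of striated-muscle structure and function, built for
studies of sarcomeric myopathies (e.g. *MYBPC1*-linked disease models) that
combine immunofluorescence imaging, Mant-ATP chase assays, isometric
contractility and whole-animal morphometry. The package is aimed at muscle
physiologists and image analysts who want the common quantification steps of
such studies as tested, scriptable building blocks rather than ad hoc
FIJI/Prism workflows.

## What it computes

**Sarcomeric organization scoring.** An α-actinin (Z-disk) image is
thresholded, thinned to a 1-pixel skeleton and decomposed into branches:

- *breakage* = branches per 1000 µm² (fragmentation of striations),
- *continuity* = mean branch length in µm,
- *order* = amplitude of the Z-disk periodicity peak of the 1-D power
  spectrum taken along the fiber axis. For a sarcomere period *d* ≈ 2.5 µm
  the peak sits at 1/*d* ≈ 0.4 µm⁻¹.
- *localization* = amplitude of the C-zone doublet peak (~0.8 µm⁻¹) of the
  sMyBP-C channel; the doublet spacing within each sarcomere doubles the
  spatial frequency of the Z-disk lattice.

The three structural scores, z-scored against a wild-type reference panel,
drive a rule-based call into five organization patterns: prototypic,
lateral misalignment, sarcomeric continuum, disordered, chaotic.

**Myosin relaxation states.** Normalized Mant-ATP chase decays are fit by
unconstrained nonlinear least squares to

y(t) = P₁·exp(−t/T₁) + P₂·exp(−t/T₂) [+ b]

where the fast component (P₁, T₁) reports the disordered-relaxed (DRX)
myosin heads and the slow component (P₂, T₂) the super-relaxed (SRX) heads.
Fits are multi-start initialized, canonically ordered (T₁ < T₂) and
aggregated from ROI to fiber level.

**Contractility.** Force traces from 1–200 Hz stimulation trains reduce to
baseline-subtracted peak force, the force–frequency curve with its tetanic
entry, maximal contraction/relaxation rates (extrema of the smoothed dF/dt),
and specific force — peak force over PCSA = m/(ρ·L₀) ex vivo, or over muscle
mass in vivo.

**Morphometry & behavior.** Kyphotic index KI = |C7−L6| / max perpendicular
dorsal deviation; inverted-hang endurance as the mean of trials capped at
180 s.

**Statistics.** The study-style decision tree for two-group comparisons
(D'Agostino–Pearson normality → F-test on variances → Student's t / Welch's
t / Mann-Whitney U) and two-way ANOVA with Šídák-adjusted per-frequency
contrasts (p_adj = 1 − (1 − p)^m) for force–frequency curves.

A synthetic-data module generates striated fields, chase decays and force
traces with known ground truth (period, breakage rate, register jitter,
DRX/SRX fractions, twitch kinetics…), so every stage is testable without
any raw data.

## Worked example

```python
import sarcotrem as st

# a clean synthetic Z-disk field, 2.5 um period, 0.1 um pixels
field = st.generate_striated_image(st.ImageGroundTruth(period_um=2.5), 256, 256)
peak = st.order_score(st.power_spectrum(field.image))
print(f"order peak at {peak.peak_freq_um_inv:.3f} 1/um, score {peak.amplitude:.4f}")

# DRX/SRX fit of a noisy chase decay (truth: 20% DRX, T1=20 s, T2=200 s)
trace = st.generate_decay_trace(
    st.DecayGroundTruth(p1_frac=0.2, t1_s=20, p2_frac=0.8, t2_s=200,
                        noise_sd=0.01, seed=3))
fit = st.DoubleExponentialDecay(trace).fit()
print(f"DRX {fit.drx_percent:.1f}%  SRX {fit.srx_percent:.1f}%  "
      f"T1 {fit.T1_s:.1f} s  T2 {fit.T2_s:.1f} s")
```

Output:

```
order peak at 0.400 1/um, score 0.0581
DRX 19.6%  SRX 80.4%  T1 18.9 s  T2 198.1 s
```

The order peak lands at 1/2.5 µm = 0.400 µm⁻¹, i.e. the generator's
sarcomere period is recovered exactly, and the fitted head-state fractions
recover the simulated 20/80 DRX/SRX split to within the noise.

A CLI mirrors the library:

```bash
sarcotrem simulate image --seed 1 --out fields/
sarcotrem score-image --actinin fields/field_seed1.tif --out scores.csv
sarcotrem fit-decay --in chase_data/ --out fits.csv
sarcotrem hang 200 180 190
```

## Layout

- `src/sarcotrem/synthetic.py` — ground-truth generators (images, decays, forces)
- `src/sarcotrem/skeleton.py`, `spectrum.py`, `profiles.py`, `classify.py` — image scoring
- `src/sarcotrem/relaxation.py` — DRX/SRX model + results objects
- `src/sarcotrem/contractility.py` — force-trace reduction
- `src/sarcotrem/morphometry.py` — kyphotic index, hang summaries
- `src/sarcotrem/stats.py` — test routing, curve comparison
- `docs/methods.md` — models, parameter choices, limitations
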