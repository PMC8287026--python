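# Methods

This note records the models, numerical choices and limitations behind
`ocupulse`, in the order the pipeline runs.

## Synthetic B-scan sequences

The simulator renders a layered posterior-eye phantom per frame, top to
bottom along each A-scan: vitreous (intensity ~15), retina (~90), a bright
RPE band (~230, 5 px thick), choroid (~60) with smooth vessel texture, and
sclera (~150). Layer transitions are logistic with ~0.75 px softness, so
boundaries have sub-pixel structure. The defining dynamic is the choroidal
thickness

    ChT(t) = baseline + A·sin(2π·HR·t) [+ harmonic] + D·sin(2π·f_drift·t)

with defaults baseline 300 µm, pulse amplitude A = 5 µm (10 µm
peak-to-valley), HR 1.2 Hz, drift D = 3 µm at 0.1 Hz. Acquisition defaults
emulate a clinical optic-nerve-head video: 599 frames over ~5 s (the
4–7 s range arises from tracker pauses), axial spacing 3.87 µm/px — the
device's axial sampling is not published, so this is a configurable
default, not an asserted constant.

Other deliberate features:

- **Tilt** (0.05 px/A-scan linear RPE ramp) exercises the flattening step
  and, importantly, dithers the sub-pixel phase of the boundary across
  columns, which is what lets a column-averaged thickness beat the 1-px
  quantisation floor.
- **Optic-nerve stand-in**: a central vertical band (15% of width) with
  unlayered texture; its bounds go to the sidecar, matching an
  exclusion-by-mask design rather than detection.
- **Speckle**: multiplicative log-normal noise (σ = 0.2 in log-intensity)
  plus low-frequency vessel blobs; this reproduces the inflection-rich
  profiles the graph search must tolerate without modelling OCT physics.
- **Timing**: uniform nominal frame period with pauses of 0.3 s inserted
  with probability 0.01 per gap.
- The recorded `true_delta_t_um` is the mean peak-to-valley of the
  noise-free continuous ChT model evaluated densely over the acquisition
  span, so sparse or paused frame sampling cannot bias the reference.

What the phantom does **not** model: realistic OCT speckle statistics,
eye-motion artifacts other than pauses and tilt, curved (non-linear) RPE
geometry, pathology such as peripapillary atrophy, or axial shadowing.
Passing recovery tests therefore demonstrates correctness of the
algorithmic chain, not clinical-grade robustness.

## Cohort simulation

Latent (k, AL, ACV, OPA, SP-A1, SP-HC) are drawn from a multivariate
Gaussian with a configurable target correlation matrix and mapped to
physiological means/sds (k 0.015 ± 0.005 µL⁻¹, AL 24.8 ± 0.9 mm, ACV
175 ± 30 µL, IOP 17 ± 2 mmHg drawn independently). The default pairwise
pattern (k negatively correlated with AL and ACV, positively with OPA and
the stiffness parameters) is shrunk toward the identity just enough to be
positive semidefinite, leaving e.g. target corr(k, AL) = −0.475. Two
columns are then **constructed rather than drawn** so the analysis chain
can recover its inputs exactly:

- OPA = IOP·(e^{k·ΔV} − 1) with ΔV from the subject's Δt and AL — the
  exact Friedenwald inverse; the latent OPA draw is discarded, so the
  realized OPA correlations are emergent, not targeted.
- Corvis deflections δ_A1 = (AP1_adj − bIOP)/SP-A1 and
  δ_HC = δ_A1 + (AP1_adj − bIOP)/SP-HC, so the stiffness formulas
  round-trip.

## Segmentation

- **RPE detection** (not specified by the source method, so a design
  choice): per A-scan, the brightest band of the Gaussian-smoothed profile;
  posterior edge = last depth within 70% of the band peak; median filter
  (15 columns) across A-scans. A frame is unusable when more than half of
  the included columns lack a band with peak ≥ 2× the column median.
- **Flattening**: integer per-column shifts placing the posterior RPE on
  the median reference row, each side of the optic-nerve gap handled by its
  own columns; the shift map is kept for inverse mapping.
- **Nodes**: inflection points (sign change of the second difference of
  the σ = 2 px Gaussian-smoothed profile) below the RPE with positive
  first difference — the dark→bright signature of crossing from choroidal
  vessel into sclera. Raw second differences on speckle are sign-unstable;
  the smoothing σ is configurable. The strongest 6 candidates per column
  are kept.
- **Graph search**: node cost 2 − ĝ + ε (ĝ min-max normalised gradient per
  frame, ε = 1e−6), transitions allowed when |Δdepth| ≤ max_jump
  (default 15 px) per column of separation, skipping a candidate column
  costs 2.5 (above the largest node cost, so skips happen only when
  necessary — e.g. an outlier candidate displaced beyond the jump limit);
  a bounded lookback of 12 columns keeps the DP linear in width. The
  optimum is restricted to paths selecting at least two nodes, and its
  cost is verified against exhaustive enumeration in the tests. Skipped
  and empty columns are filled by linear interpolation; the optic-nerve
  gap is never crossed.
- Frames are segmented independently; all temporal structure is handled
  downstream in the waveform stage.

## Waveform analysis

- **Outliers**: |x − median| > 3 × scaledMAD removed, scaledMAD =
  1.4826·MAD (the Gaussian-consistent scale; the unscaled variant is a
  defensible alternative, this package pins the scaled one). Zero-MAD
  series are kept whole.
- **Resampling**: linear interpolation onto a uniform grid at
  max(4 × band-upper-edge, median sampling rate), followed by a
  forward–backward (zero net group delay) 4th-order Butterworth low-pass
  at 45% of the new Nyquist — this is the "anti-aliasing with delay
  compensation" step realised with zero-phase filtering.
- **Heart rate**: largest magnitude of the zero-padded FFT of the
  detrended series within 0.7–2.0 Hz; if no peak stands 2× above the
  band's median magnitude the estimator refuses and an explicit heart
  rate must be supplied (the rate's clinical source is outside this
  package; an explicit input is always honoured).
- **Band-pass**: an ideal frequency mask — FFT, zero every coefficient
  outside [0.5·HR, 3·HR] including DC and the below-band drift bins,
  inverse FFT. No taper is applied: after an ideal mask only a
  pre-subtracted trend's *in-band* spectral content can change the
  output, and experiments with line/joint-regression detrending showed
  they either do nothing or inject edge (sawtooth) leakage, while a taper
  breaks pass-band identity and bites into the amplitude of edge cycles.
  The residual cost of the bare mask is spectral leakage of off-bin
  out-of-band components, which at physiological drift amplitudes changes
  Δt by well under the 5% test tolerance.
- **Δt**: peaks and valleys with prominence ≥ 25% of the filtered signal's
  standard deviation (no peak-picking rule is prescribed by the method;
  this floor suppresses ripple); each peak is paired with the first
  following valley, so incomplete trailing cycles are excluded; Δt is the
  mean difference.

## Biomechanics

- ΔV defaults to the thin-shell formula 4π(AL/2)²Δt (the operative
  equation of the method); the exact two-sphere difference is selectable
  via `model.volume_model: exact` and always ≥ the thin-shell value, with
  relative gap ≤ 3Δt/R + (Δt/R)².
- The single-B-scan Δt is applied globally under the spherical-shell
  simplification — a known approximation of the measurement itself.
- **Schematic eye**: a single corneal refracting surface (medium index
  4/3, power (n−1)/r from the measured radius) plus a thin crystalline
  lens 5.7 mm behind it. The lens power is not hard-coded: it is solved at
  construction so that zero refraction at the reference radius (7.8 mm)
  returns exactly the configured emmetropic length (23.89 mm). Axial
  length then follows from the paraxial vergence chain under the
  axial-ametropia assumption (refraction < ±6 D, the study's inclusion
  range). Only the calibration anchor and monotonicity (myopes longer,
  steeper corneas shorter) are contractual; derived lengths are
  model-dependent. An independent ABCD ray-trace oracle checks the chain
  in the tests.

## Statistics

Two-sided throughout; listwise deletion per statistic with per-cell n
reported; no multiple-testing correction by default (a Holm flag exists).
Mann–Whitney p is exact (scipy's enumeration, verified against a
brute-force permutation oracle) when both groups have ≤ 8 observations and
no ties, otherwise the tie- and continuity-corrected normal approximation.
Pearson p uses the t-transform on n − 2 df. Bland–Altman limits are
bias ± 1.96·sd of the differences (sample sd).

## Problem sizes in the tests and acceptance script

The recovery studies run on scaled-down acquisitions chosen as the
package's own test geometry: 100-frame, 200 × 192 px stacks for
segmentation/Δt recovery and 90-frame, 160 × 160 px stacks for the
50-subject end-to-end study (the clinical-scale 599-frame default remains
the generator's default). With the tilt-dithered phantom these sizes leave
ample margin to the acceptance tolerances (observed: ChT error ≈ 0.6 px
against a 1 px bound, Δt error ≈ 1% against 5–10% bounds).

## Known limitations

- The CSI edge-weighting of the original open-source graph-search
  algorithm is not published in detail; the normalised-gradient cost is
  this package's reconstruction and satisfies the same dark→bright
  selection principle.
- Whether node-free A-scans should be dropped from the frame average or
  interpolated is unspecified in the source method; this package
  interpolates (the exclusion-invariance and recovery tests hold either
  way at the simulated noise levels).
- The heart-rate estimator is a stand-in for an unspecified clinical
  source; supply the measured rate when available.
- Segmentation quality on real enhanced-depth-imaging data (shadowing,
  atrophy, motion) is untested by construction; the synthetic phantom
  bounds algorithmic, not clinical, error.
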