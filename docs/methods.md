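# Methods

This note documents the models implemented in `ebcentroid`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Camera model

Grey values are integer A/D counts (ADU). Conversion to photoelectrons is

```
pe = max(0, ADU − base) × gain        (gain in pe/ADU, default 36)
```

Negative post-subtraction values are clamped to zero: photon counts cannot
be negative, and the Poisson likelihood requires non-negative data. The base
level (dark offset) drifts with sensor temperature between acquisitions; it
is estimated per stack — or per chunk, mirroring chunked processing of long
acquisitions — as the **mean of the per-frame minimum grey values**. The
alternative reading (minimum of per-frame means) was considered and
rejected; with a quantised, low-noise background the per-frame minimum is a
stable, slightly conservative estimator (it sits ≤ the true base, never
above it by more than the noise floor).

## Event model (simulator)

Each photon event deposits an integrated charge `A` (photoelectrons) with a
**narrow pulse-height distribution**, modelled as a normal truncated at
zero: mean 15 000 pe, CV 0.1 by default. The spatial profile is separable:

- vertical: Gaussian of `σ_y = 0.85 px`, integrated over pixel spans
  (difference of normal CDFs);
- horizontal: **exponentially-modified Gaussian** — Gaussian `σ_x = 0.95 px`
  convolved with a one-sided exponential of decay `tail_x = 0.8 px` toward
  +x, integrated over pixel spans (difference of EMG CDFs).

The tail stands in for the horizontal widening of EBCCD events by the CCD
read-out (charge smear along the transfer direction). A symmetric elliptical
Gaussian cannot reproduce the observed sub-pixel bias structure: any
left-right-symmetric shape gives a pixelation bias that is antisymmetric
about the pixel centre, so folded fractional positions stay centred on 0.5.
An asymmetric profile is the minimal model with the right phenomenology; the
tail direction (+x) is chosen to match the reported right-edge pile-up. The
ground-truth position of an event is the Gaussian (arrival) centre, not the
smeared centroid. True event wings may well be non-Gaussian; nothing beyond
second moments and the smear asymmetry is validated.

Default amplitudes put single-event peaks ≈ 45–60 ADU above base (raw peaks
≈ 165–180 ADU at base 120) — bright enough that the per-frame detection
threshold operates in the regime the method targets, and consistent with a
preprocessing step that assumes photon peaks below ≈ 200 ADU.

**Noise.** Frames are `base + N(0, σ_r) + Poisson(pe)/gain`, rounded to
integer ADU. Read noise defaults to `σ_r = 0.25 ADU`: electron-bombarded
gain (~10³ CCD electrons per photoelectron) pushes CCD read noise far below
one photoelectron, so the dominant Gaussian term surviving in photoelectron
units is the A/D quantisation itself (36/√12 ≈ 10.4 pe at this gain). This
matters for multi-emitter model selection (below).

**Ion events** (residual-gas ions striking the photocathode) are rendered
with the photon shape scaled by `size_factor = 2` and `amplitude_factor =
300`, at a rate of 1/3 per frame, positioned uniformly over the sensor. The
amplitude factor gives raw ion peaks of a few thousand ADU — bright enough
to reproduce the documented failure mode (a single ion inflates the
per-frame threshold until photon events are discarded), which is the reason
the clipping stage exists. Ion physics (a single ion impact liberates many
photoelectrons, each multiplied by the EB gain) supports amplitudes orders
of magnitude above single-photon events.

**Seeding.** The generator uses three independent sub-streams (photon, ion,
and one camera stream per frame). Consequently an ion-free twin built with
the same seed shares the photon ground truth and the camera noise exactly —
frames without ions are bitwise identical between twins — which is what
makes clean ablation experiments (clipping on/off vs twin) well-posed.
Stacks are bitwise reproducible for a fixed integer seed.

## Detection

The first wavelet plane is `F1 = V0 − V1`, where `V0` and `V1` are separable
convolutions of the input with the b-spline kernel of order 3
(`[1,4,6,4,1]/16`) and with the same kernel dilated à-trous by the scale
(zeros inserted between taps; scale 2 → `[1,0,4,0,6,0,4,0,1]/16`). Borders
reflect symmetrically. `F1` is zero-sum and linear; behaviour is pinned by a
dense-convolution oracle test, not by claimed equivalence with any
particular plug-in's kernel normalisation.

The peak intensity threshold is `k · std(F1)` computed **per frame** (this
per-frame adaptivity is exactly what ion events corrupt). Pixels
`F1 ≥ threshold` form 8-connected components; components containing several
regional maxima (3×3 plateau-tolerant) are split by a watershed on `−F1`
seeded at those maxima. Each region yields a candidate at its
intensity-weighted centroid, rounded to the nearest pixel (ties toward the
smaller index). With watershed enabled the candidate count is monotone
non-increasing in the threshold; raw component counts are not (a rising
threshold can split one component), which is why the monotonicity property
is stated for the watershed path.

A practical operating note: `k·std(F1)` assumes the frame's variance is
dominated by event power. On nearly empty frames (≪ 1 event/frame) the
threshold collapses to the noise floor and false candidates appear; the
published densities (150–460 photons/frame on 512² px) are far from this
regime.

## Sub-pixel localisation

All fitted methods share the parameterisation `(x₀, y₀, I, σ, b)` with a
symmetric Gaussian PSF — point-sampled at pixel centres, or pixel-integrated
(error-function form) for the integrated-Gaussian model. Optimisation is
L-BFGS-B with analytic gradients; bounds keep the centre inside the patch,
`I > 0`, `b ≥ 0` and `σ ∈ [0.3, 3] px`. The published "SD = 1.0 px" (or
1.6 px for the integrated model) is the **initial value** of a fitted σ, not
a frozen parameter — freezing it would erase most distinctions between the
fitting methods; a `fix_sd` flag restores the frozen behaviour. Convergence
uses the optimiser's objective/gradient tolerances (1e−14/1e−10) with at
most 1000 iterations; failed or degenerate fits (intensity below 1 pe) are
dropped and counted, never imputed.

The weighted least-squares integrated-Gaussian fit uses weights
`1/max(d, 1)` (inverse Poisson variance estimate). The local centroid is the
min-subtracted centre of mass. The radial-symmetry estimator computes
gradients on the half-pixel corner lattice (2×2 stencils) and returns the
gradient-magnitude-weighted least-squares intersection point of the gradient
lines; it is exact on radially symmetric data by construction.

On noise-free pixel-integrated events the point-sampled Gaussian fit
recovers positions to better than 1e−3 px for σ ≈ 1 (the model mismatch is
absorbed almost entirely by the fitted σ); at operating intensities the
Monte-Carlo variance of the MLE is within ~15% of the Cramér–Rao bound of
the Poisson imaging model.

## Multi-emitter fitting analysis

The two-emitter model shares σ and b: parameters
`(x₁, y₁, I₁, x₂, y₂, I₂, σ, b)`, with the second emitter initialised at the
brightest residual pixel of the single fit. Selection is a likelihood-ratio
test: accept two emitters iff `2(logL₂ − logL₁) > χ²₃(1 − p)` with
`p = 10⁻⁶` (three added parameters). An F-test would be the natural
alternative for least-squares objectives; the LRT matches the ML objective
used here. A non-convergent two-emitter fit falls back to the single fit;
with `max_emitters = 1` the result is exactly the plain MLE.

**Calibration caveat.** The χ² reference distribution holds when the data
are Poisson. Gaussian read noise of even ~9 pe per pixel makes the LRT
anti-conservative (measured: ~10% false splits at 9 pe, >50% at 36 pe,
0/300 in the pure-Poisson regime at the default event intensity). For EB
sensors this is the right regime — effective read noise is sub-photoelectron
— but A/D quantisation at 36 pe/ADU re-introduces ~10 pe of effective
Gaussian noise in the converted data, so pipeline-level MFA does split a
small fraction of single events; the 160 nm duplicate-removal stage absorbs
these (a false split is two records < 2 px apart). Users applying MFA to
high-read-noise cameras should not trust the nominal p-value.

Fitting regions of overlapping candidates are fitted independently;
duplicate removal (greedy, keep-brightest, within 160 nm = 2 px at
80 nm/px) reconciles the double counting. With keep-brightest merging and a
strict lower intensity cut, duplicates-then-filter and
filter-then-duplicates provably give the same accepted set; the pipeline
still fixes the order (duplicates first) for bookkeeping determinism.

## Accumulation and diagnostics

Localisations accumulate into count histograms at native or subdivided
resolution (bin `floor(x·s)`; pixel `(i, j)` spans `[i, i+1)`, so fractions
live in `[0, 1)` and the boundary bin cannot occur). Subdivision 5 summed
back over 5×5 blocks reproduces the subdivision-1 image exactly. The folded
5×5 sub-pixel occupancy feeds the fixed-pattern-noise metric
`(N_max − N_min)/N_mean × 100 %`; a 13×13 folding is provided for display
only. FPN is computed over all localisations by default (an optional region
restriction can be applied upstream by filtering the table). Note that FPN
has a positive sampling floor: for `N` unbiased localisations the 25
multinomial cells contribute an expected range of order `4.5·√(N/25)`
counts, so FPN below `≈ 100·4.5/√(N/25) %` is indistinguishable from
uniform.

## Sub-pixel bias structure

With the smeared (EMG) event shape, fitting windows anchored on the event's
centre (peak) pixel at radius 2 produce folded fractional-x distributions
shifted toward the right pixel edge for the ML Gaussian and the weighted
integrated-Gaussian fits, and most strongly for the local centroid; the
radial-symmetry estimator instead shows its bias along the vertical axis.
Two anchoring subtleties found while validating this, both documented
because they change what an experiment measures:

- anchoring the window on the **wavelet-centroid candidate** (which already
  includes the smear displacement) self-centres the tail and cancels the
  *mean* fractional shift, while leaving the phase structure (FPN) intact;
- plain **unweighted** LS with the point-sampled Gaussian shows no mean
  shift either way: its objective is dominated by the bright, nearly
  symmetric core, so it is insensitive to the faint tail truncation that
  drives the effect in the likelihood-weighted fits.

## What a green test establishes

The simulator emulates: event compactness and asymmetry (second moments +
smear), narrow pulse heights, paper-scale densities (150 and 460
events/frame equivalents), base-level offset, quantisation, rare bright
ions. It does not emulate: non-Gaussian wing structure, spatially varying
gain or base level, dark/clock-induced-charge speckle, ion-event substructure,
or detector saturation. Green pipeline tests therefore establish algorithmic
correctness and the stated mechanisms (threshold corruption by ions, overlap
separation, bias structure) in this idealised world — not quantitative
agreement with any particular camera's absolute photon counts or FPN
percentages, which depend on the true event shape.

## Defaults that matter

| parameter | default | unit | why |
|---|---|---|---|
| pixel size | 80 | nm | published camera setup |
| gain | 36 | pe/ADU | published camera setup |
| base level | 120 (estimated when unset) | ADU | middle of the 100–140 range |
| σ_x, σ_y, tail | 0.95, 0.85, 0.8 | px | compact, horizontally widened events |
| amplitude mean, CV | 15 000, 0.1 | pe | narrow PHD; peaks ≲ 200 ADU raw |
| read noise | 0.25 | ADU | EB gain ⇒ sub-pe read noise; quantisation-scale |
| ion rate / amp / size | 1/3, 300×, 2× | — | "every few frames"; kADU peaks |
| wavelet order / scale | 3, 2 | — | published filter settings |
| PIT multiplier | 2.0 (1.5 cell preset) | ·std(F1) | published thresholds |
| fit radius | 2 (3 IG; 7 for MFA) | px | published radii |
| init σ | 1.0 (1.6 IG) | px | published SDs, as initial values |
| MFA | ≤2 emitters, p = 10⁻⁶ | — | published selection threshold |
| duplicates | 160 | nm | published distance (= 2 px) |
| intensity cut | 4000 / 3000 | pe | published filters (USAF / cell) |
| clip margin ε | 0.05 | — | "slightly above" the photon maximum |
| photon-max quantile | 0.999 | — | robust peak bound, ion frames excluded |
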