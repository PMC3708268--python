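# Methods

This note records the models implemented in `lungcad`, the defaults and
why they were chosen, and what the synthetic validation does and does not
demonstrate.

## Degradation model and restoration

A degraded slice is the circular convolution of the clean image with a
normalized linear-motion kernel (length in pixels, angle in degrees; DC
gain 1), plus additive white Gaussian noise, clipped to [0,1] last. All
spectral operations use the FFT (circular) convention, so the forward
model is exactly `G = F·H` elementwise in frequency.

The restorer is

    F̂ = |H|²·G / (|H|²·H + K)

with `K ≥ 0` a scalar by default (a frequency grid is accepted). Two
properties matter in practice:

- At `K = 0` the estimator reduces algebraically to `G/H` and restoration
  of a noiseless blur is exact to machine precision — provided `H` has no
  exact zeros. Motion-blur spectra are sinc-like and *do* vanish at some
  frequencies for some lengths; that case raises an error rather than
  returning garbage.
- For `K > 0` the denominator `|H|²H + K` is **not** bounded away from
  zero: a symmetric motion kernel has a real spectrum that takes negative
  values, and wherever `H ≈ −K^{1/3}` the gain spikes. Restoration
  quality is therefore non-monotone in `K`, and `K` must be chosen with
  care. `wiener_k_sweep` evaluates an MSE-vs-reference curve (usable only
  on phantoms, where the clean image exists); on the standard
  blur-7/σ=0.02 phantom the best `K` is ≈ 0.046 and improves MSE over the
  degraded input by ≈ 3–4%. The pipeline default `K = 0.05` was fixed
  from that sweep. No automatic blind selection of `K` (or of `H`) is
  attempted.

The restorer is intentionally this exact estimator, pathology included;
the error metric exposed alongside it is the plain per-pixel MSE.

## Wavelet stage

The DWT uses the Haar basis with periodic extension. Haar keeps every
test value exactly representable and periodization preserves
orthonormality, so perfect reconstruction (≤1e-10) and Parseval energy
conservation (≤1e-8) hold to round-off rather than approximately. The
noise-location map is the sum of squares of the three finest-level detail
subbands, nearest-neighbour upsampled to image size: on piecewise-
constant content it is zero away from region boundaries, and on white
noise of variance σ² its mean approaches 3σ², which is the calibration
the tests check by Monte Carlo. Soft thresholding (`sign(c)·max(|c|−t,0)`
on details only) is provided with `t = 3σ` as the documented phantom
choice; threshold selection is otherwise left to the caller. The pipeline
treats this stage as a diagnostic branch — its output is written for
inspection but the segmentation consumes the restored image directly.

## Segmentation

Thresholding takes foreground **below** the threshold: lungs are
radiolucent, so on a min–max-normalized slice they sit near the bottom of
the intensity range. The stock values are 0.05555 for 2-D slices and
0.0678 for 4-D frames, interpreted on [0,1]-normalized intensity (integer
image files are min–max normalized on load). The lung-mask cleanup —
drop components touching the border (outside air is as dark as lung),
fill holes (nodules and vessels are bright islands), keep the two largest
components — is standard plumbing needed to turn a threshold mask into
lung fields.

Region growing uses 4-connectivity with a running-region-mean criterion
(a pixel joins if it differs from the current region mean by at most the
tolerance), seeds processed in order with first-seed priority. A 1e-12
slack on the comparison absorbs floating-point drift of the running mean
so that tolerance 0 floods exactly-constant regions. The adaptive variant
thresholds against a windowed local mean minus an offset.

## Left/right separation

Merged lungs are split by the maximum-cost top-to-bottom path through the
image gray levels: `S(r,c) = w(r,c) + max{S(r−1,c−1), S(r−1,c),
S(r−1,c+1)}`, ties broken toward the smaller column in both recurrence
and backtrace (deterministic output), weights equal to raw intensity —
the junction tissue between the lungs is brighter than parenchyma. The
search region is the middle third of the mask bounding box, or, when a
previous slice's path is available, a ±10-column band around it (the
junction drifts slowly through a volume). Decisions worth recording:

- The separation step runs only on masks that are a *single* component
  covering at least `min_fraction` (default 0.1) of the image.
- A maximum-cost path through *dark* pixels means the single component is
  one lung, not two merged ones; the cut is accepted only if the median
  intensity along the path exceeds the median mask intensity by 0.1.
  Otherwise the mask is labeled directly (a lone lung gets the label of
  its centroid side).
- The 1-px cut is widened at diagonal steps, since an 8-connected
  component otherwise leaks across them.
- If the cut alone does not disconnect the mask, up to 5 binary erosions
  are applied as a fallback before giving up with diagnostics.

Conditional dilation then grows each label inside the original mask, one
iteration at a time, refusing any pixel whose addition would create an
8-adjacency between labels 1 and 2. Label 1 grows before label 2 within
an iteration — a fixed priority that keeps results deterministic. A
consequence of the non-reconnection rule is that the 1-px junction cut
itself is never refilled (every cut pixel neighbours both lungs); what
the dilation restores is boundary area lost to erosion. Labels are
viewer-oriented: label 1 is the lung with the smaller centroid column
(the radiological convention would mirror them).

## Features, codebook, sequences

Candidates are 8-connected bright components inside the lung mask, above
the given quantile of in-lung intensity and at least `min_area` pixels,
ordered by centroid (row, column) so sequences are reproducible. The
feature vector is (area, perimeter, circularity, mean intensity,
intensity std, eccentricity). Perimeter counts exposed pixel edges — an
exact integer — which makes circularity of digitized disks plateau near
π²/16 ≈ 0.62 rather than 1 (a digital disk of radius 8 scores ≈ 0.54);
the feature still ranks round blobs above elongated ones, which is all
the classifier uses. Eccentricity comes from second central moments.

Two caveats on the quantile threshold: it always marks the top (1−q)
fraction of in-lung pixels, so on noisy slices small spurious components
appear (controlled by `min_area`), and if nodules occupy more than that
fraction the quantile lands *inside* the nodule intensity distribution —
hence the experiment uses q = 0.90 with larger blobs present.

The codebook is k-means (10 restarts, fixed seed) in z-scored feature
space, centroids stored in lexicographic order so the symbol alphabet
does not depend on k-means label permutation. Observation sequences are
one symbol per candidate in spatial scan order — the central interpretive
choice of this package; per-slice or per-pixel sequences would be equally
consistent with a discrete-HMM classifier but were not pursued.

## Discrete HMM

States are hidden; only symbols are observed. Parameters are π (initial),
A (transition, `a_ij`), B (emission, `b_j(k)`), all row-stochastic to
1e-9. The forward recursion is scaled per step (each scale factor is
`P(o_t | o_1..t−1)`), log-likelihood = Σ log scales; a structurally
impossible sequence scores −∞ rather than raising. The backward pass
shares the forward scale factors, normalized so that
`Σ_i α̂_t(i)·β̂_t(i) = 1` at every t, with base case `β̂_T = 1`.

Baum–Welch re-estimates π from the expected state occupancy at t=1, A
from expected transition counts over expected exits, and B from expected
symbol-emission counts over expected occupancy. Multiple sequences are
concatenated into one stream by default; a per-sequence accumulation mode
is provided and is the statistically cleaner alternative (concatenation
manufactures one spurious transition per boundary), and the two are
identical on single-sequence input. Numerical choices: re-estimated rows
are floored at 1e-12 and renormalized (degenerate all-one-symbol data
converges without NaNs); convergence is |Δ log-likelihood| < 1e-6 or 200
iterations. Likelihood is non-decreasing across iterations up to the
floor's perturbation (tested at 1e-8 slack).

Training is a local method and its fixed point depends heavily on the
initial model. The default initializer is uniform rows with seeded jitter
(ε = 0.05); parameter-recovery experiments start instead from the true
model blended 50/50 with uniform, which reliably converges to the
generating model (entrywise error ≈ 0.01 on T=2000 data from the
well-separated 2-state pair used in the tests), whereas near-uniform
starts can stall in symmetric local optima. State and symbol counts are
configuration (defaults N=2, M=8).

Classification scores a sequence under each labeled model's forward
recursion and returns the argmax, ties to the first label in sorted
order. An empty sequence is refused — no evidence, no call.

## The phantom, and what passing tests mean

The generator renders two elliptical lung fields (level 0.03) inside a
thorax ellipse (0.8) on black background, with nodules as filled disks
(0.6); malignant-like nodules add three satellite lobes at 0.9r with
radius 0.6r, giving larger, lumpier, more eccentric blobs. Defaults were
fixed once: the lung level stays below both stock thresholds even after
min–max normalization (0.03/0.8 ≈ 0.037 < 0.05555), and nodule/thorax
levels are far enough above threshold that holes fill cleanly. Nodules
are placed at least their full extent plus the blur length away from the
pleural boundary so the rendered nodule remains an interior hole of the
lung field even after degradation. With `junction_gap = 0` the lungs
overlap across the midline and a 1-px bright junction column is painted
there — the merged-lung case the separation stage exists for, with an
exact ground-truth junction position.

4-D sequences sample a sinusoidal breathing signal over one cycle
(default 4 frames per phase bin); each frame is tagged with its signal
value, and the lungs are rendered displaced cranio-caudally by
`amplitude · p/(n_phases−1)` where p is the frame's phase bin. Rendering
at the bin-representative displacement (stepwise motion) rather than the
continuous signal value gives every bin an exact reference position;
retrospective sorting partitions the observed signal range into
equal-width bins, with a degenerate (constant) signal assigned entirely
to bin 0. The end-to-end study simulates 200 scans at 128² (half benign:
2 nodules of radius 2–3.5; half malignant-like: 1 nodule of radius
4.5–6.5), blur 5 px, σ = 0.01, a 50/50 train/test split, an 8-symbol
codebook and one 2-state HMM per class; problem sizes were chosen so the
whole study runs in seconds.

What this does *not* show: the phantom has piecewise-constant anatomy, no
vessels or airways, stationary white noise, spatially invariant blur, and
class-conditional nodule distributions that are separated by
construction. Passing tests demonstrate that each algorithm meets its
contract exactly on data satisfying its assumptions — not that the
pipeline reaches any particular accuracy on clinical CT, about which this
package makes no claim.

## Known limitations

- The restorer's printed form is near-singular for `K > 0` at
  frequencies where the real blur spectrum is negative with `|H|³ ≈ K`;
  a poorly chosen `K` can amplify noise into streaks (visible as extra
  low-intensity candidates downstream).
- Thresholds assume min–max [0,1] normalization; raw DICOM/HU inputs are
  out of scope.
- Only left/right lung separation is implemented; subdivision into the
  five anatomical lobes along the fissures is not.
- Continuous-emission HMMs, Viterbi training, and model selection over N
  are not provided.
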