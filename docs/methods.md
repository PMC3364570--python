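# Methods

`ivusseg` segments a single intravascular ultrasound (IVUS) cross-section
into its two clinically relevant interfaces — the lumen/intima boundary
and the media/adventitia boundary — by chaining four stages: a contourlet
decomposition, multiresolution circular-Hough initialization, anisotropic
despeckling of the directional subbands, and a reinitialization-free
level-set evolution. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic phantoms do and do
not establish about performance on clinical data.

## Contourlet decomposition

The multiscale stage is a Laplacian pyramid built with the biorthogonal
CDF 9/7 filter pair (analysis lowpass normalized to unit DC gain,
synthesis lowpass to gain 2 so zero-upsampling preserves constants).
Synthesis is the standard pyramid reconstruction
`a_{j-1} = b_j + expand(a_j)`, which is exact in floating point for any
filter choice; measured round-trip error is at machine precision
(~1e-15). Odd-sized bands are mirror-padded by one row/column per level
and cropped on synthesis, so arbitrary image sizes round-trip exactly.

The directional stage is a **nonsubsampled** directional filter bank:
each detail band is split in the 2-D frequency plane into `2^l` antipodal
wedge pairs using raised-cosine angular windows that tile the plane as an
exact partition of unity (transitions span half a sector width; wedge k
is centred on angle `k*pi/2^l`). Because the windows sum to one at every
frequency, reconstruction is the plain pointwise sum of the subbands, and
because each window is symmetric under frequency negation the subbands
are real. This lattice-free construction trades the critical sampling of
a quincunx ladder bank for exact invertibility, full-resolution subbands
and an unambiguous per-level pooling rule (the sum), which is what the
despeckling stage needs.

Default depth is J = 3 pyramid levels with directional splits (2, 2, 3)
fine-to-coarse, i.e. 4 + 4 + 8 = 16 directional subbands plus one
low-pass band for a 384x384 frame.

## Initialization by multiresolution circular Hough transform

Both vessel interfaces are approximately circular, so initial contours
are circles detected by a voting circular Hough transform (CHT) on Canny
edge maps of the pyramid's approximation bands.

Two details matter on speckled images:

* **Edge thresholds are quantiles.** Canny hysteresis thresholds are the
  0.90/0.98 quantiles of the gradient-magnitude distribution. Thresholds
  expressed relative to the *maximum* gradient collapse on IVUS frames,
  because the bright ring-down halo owns the maximum and everything else
  floods through.
* **Fine-scale detection runs on log-compressed intensity.** Speckle is
  multiplicative, so on a linear scale the gradient distribution is owned
  by the brightest layer (adventitia) and boundary edges of darker layers
  never survive quantile thresholding (measured boundary edge recall of
  exactly zero). `log(I + 0.02)` equalizes the noise across layers —
  which is also what clinical B-mode log compression does. Coarse-level
  detection stays on linear intensity, where pyramid averaging has
  already suppressed the speckle and the strong media/adventitia contrast
  is the most reliable cue.

The search constraints — radius range (15, 40) px and centre-separation
bound D_c = 25 px — apply **at every pyramid level in that level's own
pixels**. Each level therefore detects interfaces at its natural scale:
for a typical diseased coronary segment (media-adventitia radius ~90 px,
lumen under half of that at 384x384), the media circle enters the range
on the level-2 band and the lumen on the level-1 band. Accumulator votes
are normalized by ring perimeter so a complete circle scores ~1 at any
radius; votes are box-smoothed (3x3x3) before peak picking.

Selection proceeds media-first: among strong peaks near the approximate
lumen centre (the intensity-weighted centroid of the dark blood pool
inside a central search disk, via Otsu thresholding), the media circle is
the candidate maximizing radial intensity contrast (median of
just-outside minus just-inside samples) times outer brightness — the
media/adventitia interface is the transition into the most echogenic
layer, which separates it from the lumen circle, often the stronger
accumulator peak. The lumen is then re-searched with its radius capped at
half the media radius (the cap implies cohorts with a media/lumen radius
ratio of at least two, i.e. significant plaque burden), scored by votes
plus the median log-intensity step, with concentric probe circles added
so a weak accumulator cannot leave the search empty. Both circles are
finally cascaded to full resolution by tight (+-2.5 px centre, +-2 px
radius), evidence-gated accumulator searches: a finer-level peak replaces
the rescaled seed only when its votes beat the seed's own interpolated
accumulator support by 10%. Ungated refinement measurably degrades the
estimate, because fine-level accumulators are speckle-dominated.

On the default phantom cohort this initialization lands within ~2 px of
the best-fit circles of both interfaces. Failures at any stage fall back
to the coarser estimate (never aborting), and the returned lumen circle
is clamped to lie strictly inside the media circle.

An optional parabola post-fit of the upper/lower arcs
(`fit_parabola_arcs`) is provided for study; the pipeline does not use
it.

## Despeckling by anisotropic diffusion of directional subbands

Every band-pass directional subband is evolved under the Perona-Malik
equation `dI/dt = div[c(|grad I|) grad I]` with the exponential
conduction `c(s) = exp(-(s/g)^2)`, 4-neighbour explicit scheme,
zero-flux boundaries (the scheme conserves the subband mean to machine
precision), `n_iter = 10` steps of `dt = 0.2` (stability requires
dt <= 0.25). The gradient threshold is adaptive per subband, 2.5x the
median absolute one-sided gradient, accommodating the very different
dynamic ranges of fine and coarse subbands; the multiplier was calibrated
on development phantoms by the final contour accuracy of the full
pipeline. The filtered subbands of each level are pooled (summed — the
nonsubsampled bank's reconstruction) into one detail band and the frame
is rebuilt with the *untouched* low-pass band. Setting `n_iter = 0` makes
the whole despeckling stage an exact identity, which pins the pooling
convention.

A conduction that *increases* with gradient, `exp[1 + (s/g)^2]`, is
available as `conduction="printed"` for study; it anti-diffuses edges and
is numerically unstable, and is never used by default.

## Level-set evolution without reinitialization

Each contour is the zero level set of a field phi (negative inside)
evolved under

    dphi/dt = mu [ Lap(phi) - div(grad phi / |grad phi|) ]
              + lambda delta_a(phi) div( g grad phi / |grad phi| )
              + nu g delta_a(phi)

where `g = 1/(1 + |grad(G_sigma * I)|^2)` is the edge indicator and
`delta_a` the cosine-regularized Dirac of half-support alpha. The first
term penalizes deviation of phi from a signed distance function, which
removes periodic reinitialization and admits the binary initial field
phi0 = -C inside / +C outside. Defaults: mu = 0.04, lambda = 5,
alpha = 1.5, sigma = 1.5, C = 4, dt = 5 (mu*dt = 0.2 within the
stability bound), max_iter = 500. Intensity is scaled by 255 before the
edge indicator — the formulation's constants assume an 8-bit range; on
unit-range data the gradient term would be ~1e-2 and g would never leave
1.

Two independent fields are evolved on the same despeckled frame. The
balloon weights are small and opposite: nu = -0.3 for the lumen
(gentle expansion) and nu = +1.0 for the media (shrink). Large balloon
weights (|nu| ~ 1.5 on the lumen) measurably drag contours past weak
speckled edges. Crucially, the evolution is seeded with deliberately
biased circles — the detected lumen circle deflated by 4 px, the media
circle inflated by 6 px — so each balloon pushes its contour toward the
boundary *from a known side*. A circle through the middle of an interface
(the natural CHT output) straddles it, and the half that starts on the
wrong side is dragged through the echolucent media band, collapsing the
contour; the bias exceeds the initialization's circle error (~3 px) and
makes the approach direction deterministic.

Convergence is declared when the maximum per-step change of phi over the
active band (|phi| <= alpha, where the Dirac is nonzero) stays below
1e-3 for five consecutive iterations; the signed-distance penalty keeps
reshaping phi far from the interface indefinitely, so a whole-field
criterion would never trigger. On heavily speckled frames the interface
jitters above that tolerance and the iteration cap is what stops the
evolution; the `converged` flag reports this honestly.

Contours are extracted as the longest closed marching-squares isocontour
of phi = 0, oriented counter-clockwise; if the final lumen polygon leaks
outside the media polygon it is clamped radially to 2 px inside, with a
warning.

The "traditional" baseline is the same level-set module with the same
initialization and parameters, run on the raw frame instead of the
despeckled one, so measured differences isolate the contourlet-domain
filtering.

## Synthetic phantoms

Phantoms are built in polar coordinates around the catheter (frame
centre), mimicking ultrasonic image formation:

* **Geometry.** Both interfaces are low-order Fourier perturbations
  (harmonics 2 and 3, amplitudes 1-3 px) of circles around a vessel
  centre offset up to 5 px from the catheter. Default cohort geometry
  models diseased coronary segments at ~37 px/mm on a 384x384 grid:
  lumen base radius uniform in [38, 44] px, media-adventitia radius in
  [2*lumen + 6, 96] px. The factor-2 margin matches the initialization's
  radius cap (lumen <= media/2).
* **Echogenicity.** Dark blood pool (0.08), echolucent intima/media band
  (0.25), bright adventitia (0.55) on a unit intensity scale.
* **Speckle.** The magnitude of a complex Gaussian field smoothed in the
  polar domain (correlation length 1.2 polar px along and across beams,
  wrapping in angle), normalized to unit mean — so the single-pixel law
  is exactly Rayleigh even at nonzero correlation length, and a
  homogeneous region passes a Kolmogorov-Smirnov test against a fitted
  Rayleigh at n = 5000. `speckle_scale` interpolates linearly between
  the noise-free layer image (0) and fully developed speckle (1,
  default).
* **Artifacts.** A bright ring-down halo (amplitude 0.9, radial decay
  4 px) added around the catheter, unspeckled (it is a coherent
  transducer artifact); and a guide-wire shadow sector (0.3 rad wide,
  random orientation) multiplying intensity by 0.2 beyond the wire
  radius. Clipping to [0, 1] stands in for display saturation; no other
  normalization is applied, so the noise-free limit reproduces layer
  echogenicities exactly.
* Scan conversion to the Cartesian grid is bilinear; fixing the seed
  makes a phantom bitwise reproducible.

What the phantoms do **not** model: RF-level point-spread anisotropy,
log compression of the display image (phantoms are linear envelope),
calcification shadows, side branches, pull-back motion, non-uniform gain
(TGC), or real tissue texture beyond first-order Rayleigh statistics.
Passing the cohort benchmark therefore demonstrates the method's
correctness and its robustness to fully developed multiplicative speckle
and the two catheter artifacts — not clinical-grade accuracy on
in-vivo pull-backs.

## Evaluation metrics

For every vertex p of a detected contour, D(p) is the exact minimum
Euclidean distance to the reference *polyline* (segment-wise, via exact
geometric projection) and q its foot point. MD is the mean of D(p) in
pixels; RMD is the mean of D(p)/d(q, O) in percent, with O the vertex
centroid of the reference. The metric is one-directional
(detected toward reference); a symmetric variant is offered separately as
a convenience and is not used in the benchmark. MD is
translation-invariant and scales linearly under common scaling; RMD is
scale-invariant — both properties are tested.

## Problem sizes and determinism

The cohort benchmark runs 20 phantoms at 384x384 with both methods
(~20 s per phantom for the pair on one core, dominated by the two
500-iteration level sets per method). All randomness flows from a single
batch seed through `numpy.random.default_rng`; per-phantom seeds are
drawn below 2^31. Fixed seed implies bitwise-identical phantoms and,
because every downstream stage is deterministic, identical contours.

## Known limitations

* The lumen radius cap (half the media radius) makes the initialization
  inapplicable to near-healthy vessels whose lumen hugs the media; the
  cap comes from the method's own search-update rule.
* The shrinking media front can stall 3-5 px short of the boundary in
  strong speckle minima; mean media error on the default cohort is a few
  pixels rather than the sub-pixel accuracy seen on noise-free frames.
* Two independent level sets cannot exchange information; containment of
  the final contours is enforced post hoc rather than by a coupled
  energy.
* The explicit scheme caps the stable time step; no narrow-band or
  sparse-field acceleration is implemented (grids are small).
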