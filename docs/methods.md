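# Methods

## Trace preprocessing

Each ROI trace F_t (arbitrary fluorescence units, default frame interval
1.29 s) passes through four stages, in this order:

1. **ΔF/F₀** — F₀ is the mean of the first 10 frames (`f0_frames`,
   default 10); output is (F_t − F₀)/F₀. Scale invariant; a zero F₀ is a
   degenerate-baseline error.
2. **Six-frame smoothing** — the mean of frames t−2 … t+3
   (`smooth_window = (2, 3)`). The window is asymmetric by the formula's
   construction and undefined at the first two and last three frames; the
   default boundary handling (`truncate`) averages only the in-range
   frames, so no padding invents data. A `reflect` mode (mirror padding)
   is available for users who prefer a fixed six-term mean everywhere.
3. **Background removal** — threshold θ = median(trace) + δ with δ
   (`threshold_offset`) defaulting to 0.035, the midpoint of the
   documented 0.02–0.05 range. Values below θ are set to 0; values at or
   above θ are kept unchanged. Zeroing (rather than subtracting θ)
   preserves transient amplitudes; whether the original analysis zeroed or
   subtracted is not determinable from its description, so subtraction is
   available behind `subtract_threshold=True`. This is the largest
   documented divergence risk in the trace track.
4. **Min–max rescaling** — (x − min)/(max − min), so every non-degenerate
   trace attains exactly 0 and 1. A trace constant after background
   removal has no dynamic range; it is flagged *degenerate*, stored as
   all-zeros, and excluded from correlation instead of producing NaNs.

The stage order matters: smoothing before thresholding lets a brief
transient survive at 1/6 height; the suite pins the implemented order with
a planted single-transient trace.

## Correlation and pair classes

Pearson correlations are computed between all pairs of fully preprocessed,
non-degenerate traces (r is invariant to the min–max step itself but not
to background zeroing, so the full pipeline is applied first). A pair is
*correlated* iff r > 0.1 — strict and one-sided; anticorrelated pairs are
never counted. Pairs are stratified by their endpoints' compartment labels
(host–host, host–implant, implant–implant; upper/deep layer labels work
the same way), and the per-class fraction is
100 · n_correlated / n_possible. Possible-pair counts over the classes sum
to C(n, 2) by construction.

**Similarity-matrix ordering.** The toolbox that produced the original
ordered similarity matrices does not document its algorithm, so the
package defines its own deterministic substitute: average-linkage
hierarchical clustering on distance 1 − r, with the subtree of higher mean
internal correlation placed first at every merge (ties broken by smallest
ROI id). Strongly correlated groups therefore form contiguous top-left
blocks; the ordering is documented as a substitute, not a reproduction.

**Permutation null.** The null rate of pair calls is estimated by
independently permuting each ROI's *raw* time axis, re-running the full
preprocessing, and recomputing the matrix (default 1000 permutations).
Shuffling before preprocessing matters: smoothing and the indicator decay
autocorrelate processed traces, and a null that shuffles processed traces
would lack that autocorrelation and understate chance correlations. For
i.i.d.-noise recordings the raw-shuffle null is exact by exchangeability.

## Synthetic calcium recordings

`simulate_traces` emulates the statistical structure the analysis assumes,
not the optics: per-frame Bernoulli events (a continuous Poisson process
adds nothing at a 1.29 s frame interval), a single-exponential indicator
kernel with instantaneous rise (transient rise times are unresolved at
this frame rate), amplitude · exp(−t/τ) with τ = 3 s by default, additive
Gaussian noise, and clipping at zero to keep fluorescence physical.
Members of a planted community share event frames (plus private events at
`background_event_rate`, default 0.02/frame); all other ROIs fire only
privately. Defaults — 30 host + 20 implant ROIs, 300 frames (~6.5 min),
baseline 100, amplitude 20 (ΔF/F₀ ≈ 0.2), noise SD 4 (amplitude/noise
= 5) — are chosen as a realistic spontaneous-activity regime; recording
duration and ROI counts per field are not published quantities, so they
are configurable, not claims.

Not emulated: photobleaching, motion, spatially overlapping ROIs, 3-D
structure. Passing tests therefore demonstrate correctness of the
computations on data matching the model's assumptions, not robustness to
acquisition artefacts.

Note the per-class correlated fractions on synthetic recordings
(~10–25%) sit well above the low single-digit percentages typical of real
interface recordings: sparse autocorrelated transients over a few hundred
frames produce substantial chance correlation. The calibration tests
therefore compare against the matched permutation null rather than against
absolute published fractions.

## Synthetic morphology scenes

`simulate_morphology_image` renders, on a pixel grid of known µm/px: a
bright implant slab (x < boundary; only the boundary-adjacent
`implant_fill_fraction` of it is labelled, giving coverage a planted
truth); a process-outgrowth ramp inside a horizontal stripe, decaying
linearly from the implant intensity at the boundary to the detection
threshold *exactly* at the planted outgrowth distance (linear because it
is trivially invertible in tests; any monotone decay would do); a faint
sub-threshold exponential tail of scale `decay_length_um` beyond the
endpoint, emulating diffuse background without affecting the planted
metric; and disk-shaped somata (radius 5 µm ⇒ ~78 µm² footprint, within
the 30–300 µm² plausibility range) with coincident 3 µm nuclear blobs,
placed outside the stripe at uniform distances in the migration band.
Distractor cells at chosen distances and nucleus-free blobs can be planted
to exercise the band and colocalisation rules.

## Morphometry

* **Intensity profile**: mean signal per one-pixel bin of signed distance
  to the boundary (positive into the host) within a user box; the box must
  straddle the boundary.
* **Outgrowth**: farthest bin beyond the boundary with profile ≥
  threshold; 0 if none. The profile's "width of the decreasing phase" and
  the farthest-detectable-signal readings coincide on a monotone profile;
  the farthest-supra-threshold rule is implemented.
* **Detection threshold**: the original readout is visual ("could be
  detected"); the default here is Otsu's threshold on the host-side signal,
  overridable per call and stored in image metadata — the largest
  divergence risk in the image track.
* **Migrated neurons**: supra-threshold connected components with
  30–300 µm² footprint whose centroid lies 200–400 µm beyond the boundary
  and whose footprint overlaps (≥ 1 px) a nuclear blob. Density is
  normalised to 0.1 mm² of the band area actually present in the image.
* **Coverage**: percent supra-threshold pixels in a rectangular region.
* Geometry: coordinates are pixel-centred and 0-based; distances in µm.
  Straight axis-aligned boundaries are the fast path; polyline boundaries
  use nearest-segment Euclidean distance with the sign fixed by a host-side
  reference point.

## Numerical and design choices

* Degenerate traces are excluded, never NaN-propagated; errors carry the
  offending ROI id.
* Pair threshold exactly 0.1 is excluded (strict >).
* Hierarchical-ordering ties and graph edge order are broken by ROI id, so
  all artefacts are byte-stable for a given seed.
* CSV is comma-separated UTF-8 with header row and '.' decimal; TIFF
  carries µm/px both in resolution tags and a JSON description; manifests
  record parameters, seed, version and input SHA-256 checksums.

## Problem sizes

Test and reproduction runs use 32–50 ROIs × 200–300 frames for the
calcium track (with 200–1000 permutations for null estimates) and
1400 × 600 µm scenes at 2 µm/px for the image track — sizes chosen to make
Monte-Carlo bounds tight while keeping the whole suite fast on one CPU.

## Known limitations

* No ROI segmentation, motion correction, spike inference, lagged or
  directed connectivity, or edge-level significance testing.
* No 3-D morphometry, process tracing, or timepoint registration.
* The background-removal semantics (zero vs subtract) and the detection
  threshold are documented choices where the original procedure is
  under-specified; both are exposed as parameters.
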