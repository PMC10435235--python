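# Methods

## The measurement

The quantity of interest is the per-cluster recruitment lag between two
adhesion proteins imaged in separate fluorescence channels of a TIRF
time-lapse: a red *reference* channel (Cas, the earliest-arriving scaffold)
and a green *query* channel (vinculin, β1 integrin, or Crk). For each
tracked cluster the averaged intensity trace of each channel is rescaled to
[0, 1], smoothed, and the time of the first upward crossing of 0.5 is
linearly interpolated between the two bracketing samples; the lag is

Δt½ = t½(query) − t½(reference),

positive when the query protein arrives later. Working with half-maximal
rise times rather than onset times makes the statistic insensitive to the
absolute brightness of either channel and robust to the exact shape of the
rise, at the cost of assuming both channels rise monotonically through
their half-maximum within the movie. Traces that start at or above 0.5
(rise not captured) or never reach 0.5 are flagged invalid and excluded,
with the reason recorded.

All times live on the acquisition grid t_k = k·`frame_interval_s` (frame 0
is the first acquired frame); all pixel coordinates are 0-based (row, col)
at pixel centres.

## Pipeline stages and parameters

Stage order is fixed and logged: drift estimation → drift correction →
denoising/background equalization → segmentation → tracking → trace
extraction → kinetics.

**Drift correction.** Stage drift is modelled as a rigid per-frame
translation. Consecutive frames of the registration channel (reference/red
by default, since it has signal earliest) are registered by subpixel phase
correlation (upsampling factor 50, ≈0.02 px granularity) and the pairwise
shifts composed cumulatively. A pairwise shift is accepted only if applying
it raises the Pearson correlation between the frames to at least 0.2 and
above the unaligned correlation; otherwise the pair contributes zero shift
and the trace is flagged low-confidence. Without this gate, phase
correlation on structure-free frame pairs (before any cluster has formed)
returns arbitrary shifts, and resampling by those shifts correlates pixel
noise into large connected blobs downstream. Correction translates both
channels identically with bilinear interpolation, filling vacated borders
with the frame median so no spurious threshold crossings are created;
zero-shift frames pass through bit-exactly.

**Preprocessing.** Per frame and channel: a median filter (default 3×3;
kernel 1 = identity) followed by a white top-hat with a disk structuring
element (default radius 15 px). The disk is deliberately much wider than an
adhesion's few-pixel width at 0.16 µm/px, so clusters survive while any
smooth background wider than the disk maps to ~0. Both filters use
edge-replicating boundary handling: reflection padding would fold a smooth
background gradient into bright border ridges. The filter sizes are
package defaults (the processing steps are prescribed, their kernel sizes
are not) and are configurable.

**Segmentation.** Per channel, the threshold is
`threshold_fraction` (¼) × the intensity of the `threshold_rank`-th (50th)
brightest pixel, computed on the preprocessed data either per frame
(default) or over the whole dataset. Both scopes exist because the two are
useful in different regimes: per-frame adapts to bleaching and focus drift,
per-dataset is the more stable choice for short movies with sparse early
signal. The cluster mask is the union of the two channel masks —
a cluster counts as present once *either* protein is above threshold — and
8-connected components must strictly exceed `min_cluster_area_px` (20 px,
i.e. ≥21 px ≈ 0.5 µm² at 0.16 µm/px survive).

*Noise floor.* The rank rule presumes the rank-th brightest pixel belongs
to a real structure. In a frame containing only noise it is a noise-tail
value, and a quarter of it falls below the typical noise level, flooding
the mask. The effective per-frame threshold is therefore floored at a
robust noise estimate, median + 5 × (1.4826·MAD) of the preprocessed
frame (`noise_floor_sigma`, 0 disables). The floor scales linearly with
intensity, so mask scale-invariance is preserved, and in frames with
genuine clusters the rank threshold sits far above it and governs alone.

**Tracking.** Per-frame masks are stacked into an XYT volume and labelled
as 3D connected components (default 26-connectivity, so clusters moving
≤1 px/frame stay linked; 6-connectivity available). Components present in
fewer than `min_track_frames` (3) distinct frames — i.e. shorter-lived than
40 s at a 20 s interval — are discarded. Survivors are relabelled 1..K by
first appearance, ties broken by scanline position, making the labelling
canonical and independent of the labelling library's visit order.

**Trace extraction.** For each tracked frame f of a cluster, the frame-f
mask is used to measure a mean-intensity series over *every* movie time
point; the cluster's averaged trace (per channel) is the pointwise mean of
those series over all tracked frames. Averaging over the mask's own
history reduces sensitivity to the mask of any single frame. Traces are
measured on the preprocessed data, the pipeline's working representation.

**Kinetics.** Conditioning follows the fixed order rescale → smooth:
min–max rescale to [0, 1] (constant traces flagged invalid), then a
centred moving average (default 3 frames, odd only) whose window shrinks at
the trace edges rather than inventing padding values. When a trace crosses
0.5 several times, the *first* upward crossing is used — the statistic
targets recruitment onset, not later fluctuations.

## Statistics

- **Per cell:** the median Δt½ over valid clusters; a 95% CI from exact
  binomial order statistics — the smallest symmetric pair
  (x₍ⱼ₎, x₍ₙ₊₁₋ⱼ₎) with coverage 1 − 2·P(Bin(n, ½) < j) ≥ 0.95. This is
  assumption-free; for n < 6 no such interval exists and the full range is
  returned, flagged. The "median > 0" test is a one-sided Wilcoxon
  signed-rank (a sign test is available); the nonparametric test for this
  hypothesis is a package choice.
- **Across cells:** mean of per-cell medians ± SEM (sd/√n), treating cells
  as the independent replicates.
- **Group comparisons:** two groups — two-sided Mann–Whitney U, computed by
  exhaustive permutation enumeration for combined n ≤ 20 (midranks make the
  enumeration valid under ties, which scipy's exact mode does not handle)
  and by the tie-corrected normal approximation above; three or more —
  Kruskal–Wallis followed by Dunn's z-tests with the standard tie
  correction, Holm-adjusted (the multiplicity correction is a package
  choice).

## Fixed-image analyses

**Line profiles.** A sampling line (5 px wide × 25 px long at 0.16 µm/px,
i.e. 0.8 µm × 4 µm) starts at the outer-edge end of an adhesion's major
axis and points inward; each of the 25 axial steps averages 5
bilinearly-interpolated samples across the width. Line placement is an
explicit input (`LineProfileSpec`) because it is a manual step in practice;
a helper can derive specs from labelled masks via the region's principal
axis, taking "inward" as toward a supplied cell-body point (image centre by
default). Profiles are min–max normalized per ROI and channel, aligned by
integer-bin shifts so each ROI's reference-channel peak lands on the modal
peak bin (integer granularity; no subpixel alignment procedure is defined
for this analysis), and averaged with per-bin SEM over the ROIs
contributing to that bin. ROIs with a flat reference channel carry no
alignment information and are dropped with a warning.

**Endpoint quantification.** The two channels are summed; a binary mask is
derived with the Yen entropic threshold on a 256-bin histogram (bin count
is a package default); 8-connected components strictly larger than 20 px
are counted and their mean area and per-channel mean intensities reported.
Cell area uses a Triangle-threshold mask keeping components of ≥50 px.
Intensities are quantified on the image as provided — no background
subtraction is applied by default.

## Synthetic data

The generator emulates what the pipeline must cope with, with exact ground
truth: elongated elliptical clusters near-disjointly placed; per-cluster
red onset times and a programmable red→green lag; a monotone rise —
linear ramp by default, which gives the analytic oracle
t½ = onset + rise/2, logistic optionally; optional red decay after the
plateau (off by default; decay is not part of the lag statistic); a smooth
uneven background (offset + linear gradient); rigid stage drift; Poisson
shot noise on the gain-scaled signal plus zero-mean Gaussian read noise,
clipped at zero and quantized to 16-bit.

Standard conditions (`default_cell`): 128×128 px at 0.16 µm/px, 60 frames
at 20 s, 50 clusters (semi-axes ≈ 4.5 × 2 px, area ≈ 28 px, just above the
20 px cut, mimicking nascent adhesions), rise duration 120 s per channel,
onsets uniform through the usable movie, drift 0.08–0.12 px/frame,
background 100 photons with a mild gradient, read noise σ = 2. "SNR 5"
fixes the amplitude A by solving A/√(A + B + σ²) = SNR at the plateau
(A ≈ 65 photons for B = 100).

What the generator does **not** emulate — and therefore what passing tests
do not demonstrate about real movies: cluster growth/sliding/merging and
splitting, protrusion-coupled appearance at a moving cell edge,
photobleaching, non-uniform illumination changes over time, defocus, and
channel crosstalk or misregistration. Recovery results on synthetic cells
validate the estimator's correctness, not the biology of any particular
Δt½ value.

## Numerical choices and degenerate inputs

- Thresholds use strict `>`; an all-zero movie yields an empty result
  table, not an error.
- The rank-threshold arithmetic ("quarter of the 50th brightest") is exact
  and oracle-tested; the noise floor is applied downstream of it.
- Half-rise interpolation is linear between the bracketing samples;
  invalidity (starts ≥0.5, never reaches 0.5, constant trace) is a value,
  not an exception.
- Canonical track labelling makes results invariant to connected-component
  visit order; ties in the modal profile-peak bin resolve to the smallest
  bin.
- Problem sizes in tests and in `scripts/acceptance.py` (one 128×128×60
  simulated cell per condition, five cells for the population summary,
  2000 draws for CI coverage, 200 random volumes for the tracking oracle)
  are chosen to exercise every stage at full fidelity while keeping a
  complete run in the order of a minute.

## Known limitations

- On *noiseless* frames that contain no clusters, a monotone background
  gradient leaves a small top-hat border residue that the per-frame rank
  threshold can latch onto (the MAD noise floor is zero there); the
  dataset threshold scope avoids this. Real (noisy) data are covered by
  the noise floor.
- Drift correction assumes pure translation; rotation or non-rigid tissue
  motion is out of scope.
- 26-connectivity tracking links clusters that touch in consecutive
  frames; two adhesions that collide are merged into one track from the
  first contact (no splitting model).
- The averaged-trace construction assumes the cluster footprint is
  meaningful over the whole movie; for clusters that move far from their
  tracked footprint, early/late trace segments sample background.
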