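# Methods

## The measurement model

A nucleus expressing H2B-GFP is a compact fluorescent object whose
projected area and mean intensity are tightly coupled to chromatin state.
During interphase both are stable.  At mitotic entry the chromatin
condenses: the projected area falls steeply while the fluorescence packs
into a smaller footprint, so the mean intensity rises — typically within
a single acquisition interval.  The area keeps falling through
prometaphase and metaphase, reaches its minimum when the chromatids
segregate, and recovers over roughly an hour as the daughter nuclei
re-form.  The detector in `mitotrace.tsa` is a set of change-point rules
written directly against this signature; it classifies nothing per-frame
and needs no training data.

### Candidate divisions (Fmin/Fmax)

A trace with no area value below `area_thresh` (230 px) is pure
interphase.  Otherwise the trace is scanned in consecutive,
non-overlapping `min_window` = 47-frame *period windows*; the frame with
the smallest area in each window is an Fmin if it is below threshold
(earliest frame on ties).  One minimum per period window encodes the
biological floor on division frequency (cells do not divide more than
once per ~10 h at 12-min imaging).  We deliberately use tiled period
windows rather than a centered sliding window: on a monotonically
decreasing arrest trace a centered-window rule admits no interior local
minimum at all and the arrest would be invisible, whereas the period-window
rule yields exactly one candidate per window, of which only the first
survives the IPT stage.  A narrow area dip that straddles a window
boundary can produce two candidates for one division; duplicates are
collapsed downstream because both resolve to the same IPT.  Each Fmin is
paired with the Fmax, the frame of maximal area among the `lookback` = 50
preceding frames (earliest on ties).

### IPT

Derivatives are **forward differences**, `dX(t) = X(t+1) − X(t)`, so a
change is attributed to the last frame *before* it.  Consequently the IPT
is the last interphase frame.  This convention matters at sparse
sampling: when early prophase falls between acquisitions, the transition
is attached to the preceding (interphase) frame, which over-measures
duration by up to one interval — the same behaviour as a human scorer who
cannot see early prophase, and the reason measured median/mean mitotic
duration grows as the imaging interval grows.  With the alternative
backward convention the subsampling error is symmetric and the
frequency-bias trend disappears into quantization noise.

Intensity branch: among frames `t ∈ [Fmax, Fmin)` with `dI(t) >
di_thresh` (30 grey-levels/frame on a 12-bit scale), the one closest to
Fmin is the IPT (clamped to `Fmax + 1` so that `Fmax < IPT` always
holds).  Area branch (no intensity spike anywhere in the window): if Fmin
and Fmax are adjacent frames the candidate is rejected — a one-frame
"division" is almost never real.  Otherwise the first frame after Fmax
with `dA < da_entry_thresh` (−50 px/frame) qualifies, provided (i) its
area is below `spike_guard_pct` (120%) of the previous frame — this
rejects the frame *after* a single-frame segmentation spike, whose
plunge back to baseline mimics condensation — and (ii) its area exceeds
`sustained_pct` (120%, or `sustained_pct_long` = 111% when
`Fmin − Fmax > short_mitosis_frames` = 10) of **every** subsequent area
through Fmin, which rejects transient dips.  If no frame qualifies the
candidate pair is dropped entirely.

### MAT

The area minimum over `(IPT, IPT + mat_window]` with `mat_window` = 50
frames.  Two refinements: (a) when the minimum is a strict local minimum
and the previous frame's area lies within `mat_prevframe_pct` (105%) of
it, the minimum sits on the *second* anaphase frame (the daughters were
not separable one frame earlier) and the MAT moves one frame back — the
local-minimum precondition keeps the correction away from arrest traces,
where the previous frame is always within tolerance and the correction
would silently turn the 50-frame cap into 49; (b) if the movie ends
inside a truncated search window with the area still at its running
minimum, anaphase was never observed and the event is discarded rather
than reported with an under-measured duration.

A cell that arrests in mitosis (area drifting slowly downward, never
recovering) therefore reports exactly `mat_window` frames — 600 min at
12-min imaging, 200 min at 4-min — the method's measurement ceiling.

### Trace removal

Nuclei have no way to gain projected area abruptly; a single-frame rise
of `dA > removal_da_thresh` (130 px/frame) betrays a segmentation error
or two nuclei crossing.  Any trace containing one such frame is removed
before event calling, with the reason logged.  Together with border and
completeness exclusion this is deliberately conservative: it costs
events (and slightly biases against long, motile mitoses) but keeps the
surviving traces nearly error-free.

### Events and lineage de-duplication

At a division each daughter continues as an independent trace carrying
the parent's full history, so every division is detected once per
daughter.  Events are de-duplicated on (lineage segment at the IPT, IPT
frame): the IPT always lies in the shared pre-division history, so both
sibling traces produce the same key.  The segment identity is carried in
the trace table (`segment_id` column) so de-duplication survives CSV
round-trips.  Interphase events (MAT of division *k* to IPT of division
*k + 1*) require at least two divisions in a trace.

## Upstream pipeline

**Segmentation** — Gaussian smoothing (σ = 1), tile-wise local-mean
thresholding (block ≈ 2× expected nucleus diameter, offset 10 grey
levels, floored at 4× a median-absolute-deviation noise estimate so flat
noise cannot percolate), hole filling, a debris filter at 25% of the
expected interphase area (small enough to spare condensed mitotic
nuclei), watershed seeded at smoothed distance-transform maxima, and
fragment re-merging whenever a union is at least as solid (convex) as
the better of its parts — the two halves of an over-split nucleus merge,
two genuine nuclei joined along a thin neck do not.  Finally each
object's boundary is re-cut at half of its interior plateau intensity
(75th-percentile estimate), because the local-mean threshold otherwise
admits a blurred-edge halo that inflates areas by ~15–20%.  Objects
touching the raster boundary by even one pixel are flagged and removed.
The one parameter a user must set per cell line is the expected nuclear
area.

**Features** — eleven geometric features per nucleus per frame (area,
mean intensity, perimeter, eccentricity, solidity, extent, major/minor
axis lengths, orientation, equivalent diameter, circularity).  Mean
intensity is taken over the mask eroded by one pixel; boundary pixels
only partially sample the nucleus and would dilute the average.  Only
area and mean intensity feed the detector; a wide classifier-style panel
(`extract_full_features`: moments, co-occurrence texture, wavelet
energies) exists solely as a benchmarking stub, and the geometric subset
is required by test to be at least twice as fast.

**Tracking** — globally optimal bipartite assignment
(`linear_sum_assignment`) per frame pair over a composite cost with equal
weights on normalized components: |ΔA|, grey-histogram L1 distance,
displacement, speed change, direction change, shape dissimilarity, and
Delaunay-neighborhood dissimilarity; candidates are restricted to a
30-px radius and speed/direction are inactive on a trace's first link.
After assignment, an unmatched object adjacent to a matched parent is
promoted to a one-to-two division link when each putative daughter is
below 80% of the parent's area and the two daughters' summed area is
within 45% of it.  Chains become traces; incomplete traces (not spanning
every frame) are dropped.

## The synthetic generator

`mitotrace.simgen` emulates the statistical structure the detector
assumes, with all kinetic parameters in *minutes* so per-frame slopes
stay physiological at any imaging interval:

| parameter | default | meaning |
|---|---|---|
| interphase area | 400 ± 40 px | HeLa at 20×, 2×2 binning |
| metaphase-plate area | 150 ± 15 px | trace minimum scale; below the 230-px threshold |
| daughter area at anaphase | 0.6 × plate | trace minimum; sum = 120% of parent |
| interphase intensity | 500 ± 50 grey | 12-bit scale |
| condensation intensity gain | +200 grey | single-frame dI ≫ the 30 threshold |
| interphase duration | 1224 ± 180 min | ~20.4 h |
| mitotic duration | 60 ± 12 min | ≥ 2 frames enforced |
| condensed hold after anaphase | 12 min | telophase chromatin still compact |
| full decondensation | 60 min | max dA ≈ 100 px/frame at 12-min imaging, below the 130 removal threshold |
| motion | 2 px/frame random walk | reflected at the frame edge |
| noise | 5 grey levels | additive Gaussian on A and I, drawn once per lineage node |

Lineages grow by recursive division; traces are root-to-leaf paths.
Daughters inherit the parent's H2B-GFP expression (small jitter) — an
independent redraw would place a spurious intensity step at anaphase —
and separate deterministically for a few frames (anaphase B /
re-spreading) before resuming independent walks.  Optional fractions of
cells arrest in mitosis (area drifts down by 0.2%/frame, noiseless so
monotonicity is exact) or are forced to cross a neighbor for one frame
(both traces record the merged object's summed area — the trace-removal
signature).  Rendering rasterizes each nucleus as a uniform filled
ellipse (axis ratio 1.2) into 16-bit frames with Gaussian read noise.

What the generator does *not* emulate — chromosome-level texture,
photobleaching, uneven illumination, cell death, out-of-focus drift,
densely packed colonies — bounds what passing tests show: they validate
the detector's logic and the pipeline's contracts on data that satisfy
the model's assumptions, not robustness to every real-world artifact.
On real movies the practical failure mode is tracking loss in crowded
fields, which surfaces as removed traces, not wrong durations.

## Numerical choices and degenerate inputs

Ties in argmin/argmax go to the earliest frame.  All window arithmetic is
clamped to trace bounds.  An all-background frame segments to an empty
(valid) labeling; an empty trace list yields empty event lists.  The
Mann–Whitney–Wilcoxon test enumerates the exact null distribution of U
(midranks for ties) when `n_a + n_b ≤ 12` — at most C(12,6) = 924
assignments — and otherwise uses the normal approximation with
continuity and tie correction; identical constant samples give p = 1,
and p-values below 2×10⁻¹⁶ are printed as "≤2e-16".  Two-sided
throughout.  All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configurations are bit-identical.

## Known limitations

- Mitoses shorter than ~3 frames at the chosen interval are missed or
  quantized to the minimum measurable duration; choose the imaging
  interval so a typical mitosis spans several frames.
- Measured durations carry a +1-interval offset (IPT = last interphase
  frame); comparisons between conditions are unaffected.
- Durations saturate at 50 frames; severe arrest phenotypes are
  right-censored at the cap.
- Trace removal and completeness filtering analyze a non-random subset
  of cells (slow, well-separated nuclei), which slightly under-represents
  long mitoses in crowded movies; effect sizes between conditions are
  preserved because both arms are filtered identically.
- The tracker does not close gaps across missing frames or recover
  merged objects after occlusion; such traces are excluded by design.
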