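# mitotrace

Automated measurement of **mitotic and interphase duration** of individual
cells from single-plane wide-field time-lapse movies of H2B-GFP-expressing
nuclei.

Perturbations of the cell cycle — spindle poisons, DNA damage, checkpoint
knockdowns — often shift the duration of mitosis or interphase by only a
frame or two of a time-lapse movie.  Scoring thousands of divisions by eye
is impractical, and per-frame classifier approaches need retraining for
every cell line and imaging condition.  `mitotrace` instead detects the
two transitions that bound mitosis directly from how two simple features
of each tracked nucleus change over time:

- **A** — nuclear area (pixels), which collapses as chromatin condenses
  and reaches its minimum at anaphase;
- **I** — average grey-level intensity over the nucleus, which rises
  sharply at mitotic entry for the same reason.

For each trace (one nucleus followed through the movie, one daughter per
division) the detector:

1. finds candidate divisions as local area minima below an absolute
   threshold (`A < 230 px` by default), one **Fmin** per 47-frame period
   window, each paired with the area maximum **Fmax** of the preceding 50
   frames;
2. locates the **interphase–prophase transition (IPT)** as the frame
   closest to Fmin with a single-frame intensity rise `dI > 30`
   grey-levels/frame, falling back to a guarded, sustained area drop
   (`dA < −50` px/frame) when no intensity spike exists;
3. locates the **metaphase–anaphase transition (MAT)** as the area
   minimum within 50 frames after the IPT (with a one-frame correction
   when the minimum falls on the second anaphase frame).

Mitotic duration is `(MAT − IPT) × interval`; interphase duration runs
from one division's MAT to the next division's IPT in the same trace.
The 50-frame search window caps measurable mitotic duration at 50 frames
(600 min at 12-min imaging), which is what an arrested cell reports.
Traces with single-frame area *increases* above 130 px/frame — the
signature of segmentation errors and nuclei crossing — are removed before
analysis, as are traces that ever touch the image border or do not span
the whole movie.

The package also contains the full upstream pipeline (adaptive-threshold +
watershed segmentation, cost-based frame-to-frame tracking with division
handling, geometric feature extraction), a synthetic movie/trace generator
with ground-truth event logs for validation, and rank-based statistics
(Mann–Whitney–Wilcoxon at α = 0.05) with cumulative-frequency reporting.

## Worked example

Simulate a 48-hour movie (241 frames at 12 min) of 30 HeLa-like lineages,
run the time-series analysis on the trace table, and summarize:

```bash
mitotrace simulate --n-cells 30 --n-frames 241 --seed 1 --out-dir sim
# wrote 142 traces, 117 true divisions to sim/

mitotrace tsa sim/traces.csv --interval-min 12 --out-dir events
# 112 mitotic and 82 interphase events -> events/

mitotrace report events/mitotic_events.csv --labels control --out-dir report
# condition   N  median_min  mean_min
#   control 112        72.0 74.142857
```

The generator injected mitotic durations of mean 60 min; the measured
median of 72 min reflects the one-extra-interval convention of the
detector (the IPT is the last interphase frame) plus the 12-min
quantization — the same offset applies to every condition, so
between-condition shifts are preserved.  112 of 117 true divisions are
recovered; the missing ones are mitoses truncated by the end of the movie,
which are deliberately discarded rather than under-measured.  `events/`
also contains `interphase_events.csv` (82 events for cells that divided
twice) and a `run_log.json` recording parameters and trace-removal counts.

Other subcommands: `mitotrace run` (movie TIFF or trace CSV → everything),
`segment`, `track`, `subsample` (model sparser imaging by keeping every
k-th frame), and `--help` on any of them.  All eleven detector thresholds
can be overridden by flag (`--area-thresh …`) or config file (`--config`,
`key = value` lines).

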