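# punctacoloc

Quantitative image analysis for punctate fluorescent biosensors: does a probe
sit on a membrane compartment, and does it leave when the lipid it reports is
destroyed?

Fluorescent lipid biosensors (GFP fusions of lipid-binding domains such as
FYVE or the TRPML1 N-terminus) are read out by where they sit in a cell.
Validating such a probe requires two quantitative readouts on live-cell
confocal images:

1. **Colocalization** of the probe with compartment markers (Rab5, Rab7,
   LAMP1), scored per cell with the **normalized mean deviation product
   (nMDP)**.
2. **Dissociation kinetics**: the probe's mean intensity at marker-positive
   compartments, normalized to the whole cell, followed over a time-lapse
   after a drug addition that depletes the target lipid. A genuine lipid
   sensor dissociates (its compartment enrichment collapses toward 1); a
   probe held by other interactions persists.

`punctacoloc` implements both readouts plus the machinery around them:
automated compartment masking by à-trous B3-spline wavelet decomposition,
cohort statistics (one-way ANOVA with Tukey's multiple comparison),
representative-cell selection, TIFF/CSV/YAML I/O, a CLI, and a synthetic
image generator with full ground truth so that the entire pipeline is
testable without any microscope data.

## The core quantities

**nMDP.** Within a whole-cell ROI, each channel is normalized to its mean
intensity and rescaled to [−1, 1]:

    I_norm = (I − mean) / (max − mean)   if I ≥ mean
             (I − mean) / (mean − min)   otherwise

so mean → 0, brightest pixel → 1, dimmest pixel → −1. The nMDP image is the
pixelwise product of the two normalized channels — positive where the
channels co-vary, negative where they anti-vary — and the scalar nMDP score
of a cell is the mean of that product over the ROI. For display, pixels dim
in both channels (a positive product) are blacked out for clarity, strictly
*after* the score is computed; correlating bright pixels render gold,
anti-correlating pixels green.

**Normalized compartment intensity.** Each probe frame is divided by its
whole-cell ROI mean (recomputed every frame, cancelling bleaching), and the
mean over the marker-derived compartment mask is reported per frame:
1 = indistinguishable from the cell average, values ≫ 1 = enriched.

**Compartment masks.** Marker frames are decomposed with the undecimated
à-trous transform (B3-spline kernel 1/16, 1/4, 3/8, 1/4, 1/16, taps spaced
2^(j−1) px at scale j). Detail planes at scales 2–3 are hard-thresholded at
k = 3 robust noise sigmas (MAD/0.67449); pixels positive at every selected
scale, cleaned of objects < 4 px, form the mask — rebuilt independently at
every time point.

## Worked example

```bash
punctacoloc simulate --out sim/ --seed 3          # 2-channel synthetic cell
punctacoloc nmdp --image sim/stack.tif --roi sim/roi.tif --out nmdp/
# nMDP score = 0.045113
punctacoloc run --config examples/demo.yaml --out demo/
```

The demo simulates two cohorts of three cells (10 frames, drug addition at
frame 3): a *dissociation* group whose probe enrichment is programmed to
decay 3.0 → 1.0, and a *persistence* group whose enrichment drifts up 5%.
`demo/percent_change.csv` then reads (abridged):

| group         | cell            | baseline | plateau | % change |
|---------------|-----------------|----------|---------|----------|
| dissociation  | dissociation_00 | 12.04    | 7.24    | −39.8    |
| dissociation  | dissociation_01 | 10.10    | 6.04    | −40.2    |
| persistence   | persistence_00  | 9.80     | 9.99    | +1.9     |
| persistence   | persistence_01  | 10.57    | 10.71   | +1.3     |

Baseline/plateau are the probe's mean normalized intensity at
marker-positive compartments before the event and in the final frames: the
dissociating probe loses ~40% of its compartment signal within 7 frames
(the programmed decay has not fully plateaued by frame 9), the persisting
probe gains ~2%. `demo/timecourse.png` plots the cohort mean ± s.e.m.
traces, `demo/nmdp_scores.csv` the per-cell colocalization scores, and
`demo/anova.csv` / `demo/pairwise.csv` the one-way ANOVA with Tukey's
multiple comparison across groups.

Everything is importable as a library, e.g.:

```python
from punctacoloc import (dissociation_config, make_scene, render_timelapse,
                         timecourse, percent_change)
stack, truth = render_timelapse(make_scene(dissociation_config(seed=1)))
table = timecourse(stack, ["probe"], "marker")
print(percent_change(table, event_frame=5))
```

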