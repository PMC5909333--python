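# nfmri

Quantification of myocardial infarcts (MI) and their central **no-flow
region** (NF, often called microvascular obstruction) on contrast-enhanced
cardiac MRI, plus pixel-wise T2 relaxometry and serial post-contrast
kinetics statistics. The package is aimed at researchers who work with
short-axis late-gadolinium-enhancement (LGE) data and want an auditable,
fully tested implementation of the classic remote-referenced *n*-SD
threshold protocol — validated end-to-end against a built-in digital
short-axis phantom with exact, voxel-count ground truth.

## What it computes

Given a short-axis inversion-recovery post-contrast stack and manual
endo/epicardial + remote-ROI contours:

* **Enhancement threshold** — mean signal of a remote-myocardium ROI (at
  least 100 pixels) plus *k*·SD, *k* = 5 by default. Myocardial pixels with
  SI strictly over the threshold are MI pixels.
* **Indirect NF measurement** — the NF is the sub-threshold core fully
  enclosed in-plane by enhanced tissue; total MI = enhanced ∪ NF, and the
  NF area equals total minus enhanced exactly. A manually drawn NF contour
  is honoured as an alternative path.
* **Volumes, mass, fractions** — V = Σ pixels · pixel area · slice
  thickness; LVM = myocardial volume × 1.05 g/ml; MIF = MI/LVM %, NFF =
  NF/LVM % and NF/MI % (both the volume-basis and literal ml/g conventions
  are emitted).
* **T2 maps** — per-pixel two-parameter least-squares fit of
  SI = SI₀·e^(−TE/T2) over a multi-echo train, with regional mean ± SD.
* **Serial NF kinetics** — NF volume per post-contrast minute; a one-way
  repeated-measures ANOVA (F = MS_time / MS_time×subject) gates
  Holm-corrected paired *t* tests against the 2-min reference to find the
  earliest sustained significant reduction. Independent/paired *t* and
  Kolmogorov–Smirnov normality helpers cover the group comparisons.

The phantom module generates the validation data: an LV annulus with a
transmural infarct sector whose NF core shrinks over the post-contrast
period on a dictated schedule, rendered through the spin-echo decay and
magnitude inversion-recovery signal equations with Rician noise, and with
every true mask and volume queryable.

## Worked example

```python
from nfmri import (PhantomSpec, build_phantom, render_lge_series,
                   render_t2_series, segment_lge, quantify,
                   compute_t2_map, region_t2)

spec = PhantomSpec.reperfused(seed=1234)      # defaults: LVM 69.4 g, MI 17.1 ml, NF 7.7 ml
truth = build_phantom(spec)
masks = segment_lge(render_lge_series(truth, 2.0), truth.contours, k=5.0)
result = quantify(masks)
print(result.lvm_g, result.mi_volume_ml, result.nf_volume_ml)

t2map = compute_t2_map(render_t2_series(truth), truth.myocardium_mask)
```

printed (formatted), with the configured ground truth in parentheses:

```
LVM          69.4 g                                (69.4 g)
total MI    17.10 ml   (enhanced 9.39 + NF 7.70)   (17.1 / 7.7 ml)
MIF          25.9 %LVM
NFF          11.7 %LVM   (45.1 %MI)
T2 remote    58.0 +/-  4.7 ms  (n=3567)            (57 ms)
T2 infarct   95.1 +/-  8.2 ms  (n=684)             (94 ms)
T2 no-flow   56.7 +/-  4.4 ms  (n=561)             (56 ms)
```

The 5-SD segmentation reads the infarct and no-flow volumes back to within
a fraction of a percent at the default noise level; the fitted regional T2
means carry the expected small positive magnitude-noise bias (about 1–2 %
at image SNR 20, no noise-floor correction is applied).

There is also a CLI for file-based workflows:

```bash
nfmri run-all --seed 7 --out demo/          # simulate → t2map → segment → quantify → kinetics
nfmri simulate --seed 7 --out data/
nfmri segment --image data/lge_0002min.nii.gz --contours data/contours.json \
      --out masks.npz --report seg.csv
```

## Layout

```
src/nfmri/
  phantom.py         digital phantom, signal models, cohort simulator
  io.py              NIfTI + sidecar JSON series I/O, contour JSON I/O
  t2map.py           pixel-wise mono-exponential T2 fitting
  segmentation.py    5-SD thresholding, enclosed-core NF detection
  quantification.py  volumes, mass, fractions
  kinetics.py        RM-ANOVA, paired/independent t, KS, serial analysis
  pipeline.py, cli.py  orchestration and command line
docs/methods.md      model assumptions, parameter defaults, limitations
```
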