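# Methods

This note documents the models behind `nfmri`, the defaults and why they
were chosen, what the synthetic phantom does and does not emulate, and the
numerical conventions that matter when auditing results.

## Segmentation model

The infarct is delineated by a remote-referenced intensity threshold on
inversion-recovery post-contrast images: the mean signal of a
remote-myocardium region of interest containing at least 100 pixels, plus
*k* standard deviations (*k* = 5 by default, configurable). The ROI-size
floor is a hard validation error, not a warning. Pixels strictly *over*
the threshold are MI pixels; a pixel exactly at the threshold is not
enhanced. Thresholds are computed per slice from each slice's own remote
ROI, because inversion nulling and coil shading vary between slices.

The no-flow core is, by definition, at or below remote intensity, so it is
measured **indirectly**: sub-threshold myocardium is partitioned into
4-connected components, and a component belongs to the NF iff it is fully
enclosed in-plane by enhanced tissue. Enclosure is the fixpoint of an
exclusion rule — a component is *outside* if any of its 8-neighbours lies
off the myocardium (cavity, background, image border) or belongs to an
outside component — so islands walled in by enhanced tissue, possibly via
other enclosed islands, are NF, and anything connected (even diagonally,
through sub-threshold chains) to remote myocardium is not. The 4/8
connectivity split is the standard foreground/background duality. With
this construction `total MI = enhanced ∪ NF` holds exactly, the two are
disjoint, and the NF area equals total-minus-enhanced identically. A
manually drawn NF contour can replace detection; where it overlaps
enhanced pixels the overlap is clipped to the enhanced class with a
warning.

Limitations: a no-flow core that genuinely reaches the endo- or epicardial
border is classified as remote (it is not enclosed); papillary muscles and
blood pool are excluded only insofar as the endocardial contour excludes
them; no alternative thresholding schemes (FWHM, Otsu) are provided.

## Quantification

Volume is pixel count × pixel area × slice thickness; mass uses the
myocardial specific gravity 1.05 g/ml. The %LVM fractions are computed on
a volume basis — numerator volume over myocardial volume (LVM/1.05) — so
numerator and denominator share units; the literal ml-per-gram reading
differs by the constant factor 1.05 and both are emitted in the output
tables under explicit column names. With no infarct, NF-as-%-of-MI is
undefined and reported as missing, never zero.

## T2 relaxometry

Each pixel's echo train is fitted with SI = SI₀·e^(−TE/T2) by nonlinear
least squares in the signal domain (not log domain), initialised from a
log-linear regression over the positive samples. T2 is bounded to
[1, 2000] ms; fits that hit a bound, have fewer than three positive
samples, or fail to converge are flagged and excluded from regional
statistics, so a non-decaying pixel can never contribute a silently huge
T2. Regional values are mean ± sample SD (n−1).

No Rician noise-floor correction is applied. On magnitude images this
biases fitted T2 upward; at image SNR 20 (defined below) the regional-mean
bias is about +1.3 to +1.9 % for tissues with T2 in the 56–96 ms range and
the eight-echo 12–105 ms train. Users needing unbiased estimates at low
SNR should be aware of this documented limitation.

## The digital phantom

The phantom is the package's validation instrument: a stack of identical
short-axis slices holding an LV annulus (endo/epi circular contours,
64-gon polygons), a transmural infarct sector, a remote-ROI sector
opposite it, and a no-flow core inside the infarct. Acquisition geometry
follows the protocol it emulates: 300-mm field of view on a 256×256 matrix
(1.171875-mm pixels), 10-mm slices, echo train 12, 20, 30, 45, 60, 75, 90,
105 ms, post-contrast acquisitions at 2 min (early, fixed TI 500 ms) and
10–45 min in 5-min steps (TI set to null remote myocardium). Flip angle,
TR and views-per-segment are carried as metadata only.

**Exact ground truth.** Volume targets are realised in voxel counts. The
MI mask takes the `round(target/voxel)` myocardial pixels nearest in
wrapped angle to the sector centre; the no-flow masks NF(t) keep the top-n
pixels of the one-pixel-eroded MI mask ranked by internal distance
transform, ties broken lexicographically, so the NF(t) are nested prefixes
of one fixed ordering and their volumes hit the requested schedule to
within one voxel (0.0137 ml). The epicardial radius of the presets is
calibrated by bisection on the *rasterised* voxel count, because lattice
fluctuations in pixel-centre counts of near-circular polygons reach a few
percent at this resolution.

**Signal model.** Two textbook equations only: mono-exponential spin-echo
decay per tissue class, and magnitude inversion recovery
M₀·|1 − 2e^(−TI/T1)| with the repetition-interval recovery term neglected.
Post-contrast T1 per class follows fast-exchange relaxivity,
R1(t) = R1_pre + r1·C(t) with r1 = 4.5 L·mmol⁻¹·s⁻¹ and per-class
mono-exponential washout concentrations. Contrast kinetics are *not*
mechanistically simulated: the PhantomSpec dictates the true NF
volume at each minute and the renderer labels pixels by the truth masks at
that minute, so that recovered kinetics can be compared to an exact
schedule. Pre-contrast T1 values (remote and NF 900 ms, enhanced infarct
1200 ms, blood 1400 ms) and the washout curves are phantom assumptions,
chosen to reproduce the qualitative imaging behaviour (remote nulled,
bright rim, dark core below the 5-SD threshold at every timepoint), not
reported tissue measurements. The NF concentration tracks 0.95× the
remote curve, which keeps the core just past the remote null point — dark
at both the early fixed-TI acquisition and the remote-nulled late ones.

**Noise.** Rician by default (magnitude of complex Gaussian), Gaussian and
noise-free available. For the T2 series the noise SD derives from an image
SNR parameter using the operational definition — remote-myocardium signal
on the first echo divided by the noise SD (default SNR 20) — since the
TE = 0 amplitude is never observed. The post-contrast series use an
absolute SD of 12 a.u. against a proton scale of 1000 a.u., giving an
enhanced-rim SNR near 50, a realistic LGE contrast-to-noise regime.

**Default volumes and kinetics.** Preset geometries carry the two
experimental-group presets: LVM 69.4/80.2 g, MI 17.1/19.4 ml, NF 7.7/8.1 ml falling to
1.82/3.05 ml at 45 min, with the drop beginning at 20 min (reperfused) or
25 min (non-reperfused). Intermediate schedule values are package choices:
a small (≈0.1 ml/step) decline before the drop — below measurement
resolution but keeping the true and measured series strictly decreasing —
then an approximately linear fall to the 45-min value. Regional T2
defaults are per group (remote 57/63, infarct 94/96, NF
56/60 ms).

**What the phantom does not emulate.** No Bloch-equation simulation,
k-space/segmented-readout artefacts, partial-volume at tissue interfaces,
cardiac or respiratory motion, coil sensitivity profiles, perfusion or
diffusion physiology, papillary muscles, or through-plane tapering of the
ventricle (all slices are identical). Passing recovery tests on the
phantom therefore demonstrates the correctness of the measurement chain
under ideal geometry and known noise — not robustness to motion,
partial-volume bleed at the rim, or contouring error on real images.

## Cohort simulator and serial statistics

For statistical analyses a volume-level simulator draws per-subject NF
curves around a group schedule: a multiplicative subject amplitude
N(1, 0.31) — matching the reported between-animal coefficient of variation
of NF size (2.4/7.7) — plus independent per-measurement noise of 0.25 ml,
a repeatability assumption. Values are clipped at zero.

The serial analysis mirrors the serial-acquisition design: one-way within-subject
ANOVA across timepoints (F = MS_time/MS_time×subject, no sphericity
correction by default; Greenhouse–Geisser is out of scope) acts as a
gatekeeper; if significant, each later timepoint is compared to the 2-min
reference by a paired *t* test with Holm correction, and the reported
onset is the earliest timepoint that is significant *with every later
timepoint also significant*. The many-vs-one structure motivates Holm over
Tukey; gating plus Holm keeps the family-wise error of a spurious onset
below α on null cohorts. Degenerate inputs follow explicit contracts
rather than propagating NaN: an all-equal matrix gives F = 0, p = 1;
identical paired samples give t = 0, p = 1; incomplete matrices are
errors (no imputation). The independent-samples *t* test is
pooled-variance by default with Welch behind a flag. The normality check
reports the Kolmogorov–Smirnov distance from a normal law with mean and SD
estimated from the sample, as clinical statistics packages apply it; with
estimated parameters the p value is conservative (a Lilliefors-style
correction is deliberately not applied, to match that convention).

## Numerical conventions

* World coordinates in mm, origin at the image corner; pixel (row, col)
  centred at ((col+0.5)·spacing, (row+0.5)·spacing). A pixel belongs to a
  polygon iff its centre is inside (even-odd rule); contours are stored in
  mm so they survive resampling.
* NF truth contours are iso-contours of the truth mask at the 0.5 level;
  rasterising them back recovers the mask up to a one-pixel boundary band.
* All randomness flows from explicit seeds; a pipeline run with the same
  configuration and seed reproduces byte-identical output tables, and
  provenance blocks (version, seed, config hash) carry no timestamps.
* Echo order is irrelevant to T2 fitting (pairs are sorted internally);
  duplicate echo times are rejected.

## Problem sizes used in the test suite

Unit tests run on a two-slice phantom with proportionally scaled infarct
targets (identical per-slice geometry to the full presets); the recovery
suite runs the full six-slice, 256×256 presets for both groups, and the
detection statistics use 100 simulated 7-subject cohorts per condition
with the step-onset construction (flat at the reference level until the
drop). These sizes were chosen so the entire suite exercises every
full-size path while remaining quick to run routinely.
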