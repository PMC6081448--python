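# Methods

## Scope and conventions

All volumes are indexed `(slice, row, column)` = `(z, y, x)`; slice 0 is the
most cranial; the column axis runs right→left, so the subject's left lung is
at higher column index. Spacing is in mm per axis, voxel volume is the
product of the three spacings, and volumes are reported in ml. Attenuation is
in Hounsfield units and is used unscaled. NIfTI-1 is the interchange format;
images are reoriented to closest-canonical on read so these conventions hold
regardless of how the file was written. Each scan is analyzed independently;
serial-scan registration is out of scope.

## Densitometry

The densitometry chain is deliberately minimal: per lung, the mean HU over
all lung-labeled voxels, the linear density map ρ = (1000 + HU̅)/1000 g/ml,
volume by voxel summation, and mass = volume × density. Because mass is
linear in HU, combined-lung mass equals the sum of per-lung masses exactly.

Two auditing switches exist. `convention="as_printed"` evaluates the
alternative sign form ρ = (1000 − HU)/1000, which appears in some published
method sections; it assigns air 2 g/ml, so the air-referenced form is the
default. `exclude_vessels=True` drops intrapulmonary voxels above −300 HU
from the HU average (the default keeps them, since standard lung extraction
only removes the central vasculature).

The height-predicted total lung mass uses the fixed linear reference
`9.8759·height − 1019.1` g (height in cm), derived from standard CT of
healthy adults. The coefficients are used as printed; refitting them is out
of scope. Heights outside 100–220 cm produce a warning, not an error.
`percent_of_predicted = 100 + percent_error` is reported alongside the
percent error.

## Lung segmentation

Voxels below the lung threshold (default −500 HU, the standard aerated-lung
window) are candidates; components connected to the grid boundary are
exterior air and are removed; candidate holes are filled in 3-D **before**
component analysis because dense lesions (ground-glass and above) are holes
in the aerated-lung mask and can otherwise fragment a heavily involved lung
into several components. The largest one or two surviving components are the
lungs; a single merged component is split by erosion into two seeds and
nearest-seed assignment (mid-sagittal fallback). Per-slice hole filling then
recovers any remaining dense inclusions. A sub-−950 HU component that
reaches the most cranial lung slice near the midline is relabeled as airway;
the detector is deliberately conservative and is a no-op on phantoms (which
contain no airway tree). A user-supplied organ map can bypass segmentation
entirely.

Raising the threshold toward 0 HU only grows the candidate set, so the lung
mask is monotone in the threshold, and re-segmenting a volume whose non-lung
voxels were set to soft tissue reproduces the same mask (idempotence); both
properties are asserted in the tests.

The 12-zone partition divides each lung's cranio-caudal extent into equal
thirds (upper/middle/lower) and splits each third into a peripheral shell —
voxels within 15 mm of that lung's boundary by a spacing-aware Euclidean
distance transform — and a central core. Equal-height thirds and the 15 mm
rim are this package's dialect; production regional schemes use proprietary
anatomic landmarks that are not public.

## Parenchymal pattern classification

Class taxonomy: `normal`, `low_mild`, `low_moderate`, `low_severe`
(emphysema-like low-attenuation bands), `ggo`, `reticular`, `honeycomb`.
Features for a voxel come from the 15×15×15 box centered on it, restricted
to in-lung voxels and clamped at grid boundaries: a normalized histogram
over 32 equal-width bins spanning [−1024, 100] HU (values outside clamp to
the end bins), plus five auxiliary features (mean HU, sd HU, 15th-percentile
HU read off the binned distribution, fraction < −950 HU, fraction
> −300 HU). Boxes with under 25% in-lung coverage are unclassifiable; such
voxels inherit the label of the nearest classified voxel, as do off-lattice
voxels when a stride > 1 is used (default stride 1, per-voxel).

Signatures are per-class means of the same features over labeled
single-class training boxes (≥ 2 classes, ≥ 10 boxes each); the phantom
module supplies those boxes with balanced counts, playing the role
radiologist-consensus regions play in production classifiers. The distance
from a voxel to a signature is

```
d = 0.7 · χ²(h, h_sig) + 0.3 · e/(1+e),   e = ‖z(aux) − z(aux_sig)‖ / √k
```

with symmetric chi-square on histograms and a **bounded** Euclidean term on
z-scored aux features. The bound matters: boxes straddling a lesion boundary
have an sd far outside anything in the (pure) training distribution, and an
unbounded aux term lets that single feature dominate the histogram evidence,
systematically mislabeling the boundary band. Exact distance ties resolve by
the fixed class order above; signatures are stored in that canonical order,
so the supplied order never affects the result. The whole sliding-box pass
is vectorized as per-bin box-sum filters; a default-size phantom classifies
in a few seconds.

Voxels above −300 HU can optionally be excluded from classification as
vessels, but the default keeps them: reticular septa and honeycomb walls
live above −300 HU, so the exclusion would delete the very densities the
reticular class exists to detect.

The rollup reports per-zone and whole-lung class volumes and percentages.
**Involved lung** is ground-glass + reticular volume over total segmented
parenchymal volume; honeycombing joins the involved set only via an explicit
flag, because the involved/uninvolved dichotomy for alveolar proteinosis
names only ground-glass and reticular densities (and PAP lacks
honeycombing). Per zone, class percentages sum to 100; involved +
uninvolved = 100; zone volumes sum exactly to whole-lung volumes.

## Synthetic phantoms

The phantom is a soft-tissue ellipsoid body (+40 ± 10 HU) in scanner air,
containing two mirror-symmetric lung ellipsoids (−850 HU) with a chest wall
kept ≥ 3 voxels thick at any grid size. The default grid is 96×128×128 at
(2.5, 2.0, 2.0) mm — about 2.9 l of lung — so the full pipeline runs in
seconds; Gaussian noise (default sd 5 HU) is added everywhere. The 5 HU
default keeps every between-class mean gap above 5× the noise sd (the
tightest pair is the −950/−980 HU low-attenuation bands, 30 HU apart), so
class separability is a property of the design, not luck.

Lesion classes are laid down as a few **compact spheroidal foci**: a ball
around a deep-lung center, clipped to available lung, its radius bisected so
the focus hits its voxel quota almost exactly (achieved class fractions land
within ±0.02 of target, usually much closer). Foci of the same class keep
≥ 12 voxels of spared lung between themselves; foci of different classes may
abut. This morphology is deliberate: a 15-box majority classifier cannot
resolve lesion islands or spared corridors thinner than its box, so speckled
morphologies make involved-percent recovery fail for reasons that say
nothing about the method. Real PAP is likewise geographic, with contiguous
involved and spared regions. One normal core ball per lung is reserved in
the upper third so spared parenchyma always contains a training-box-sized
region, except in lungs too small to afford it — there, training boxes fall
back to smaller odd patch sizes (a pure patch of any size estimates the same
normalized histogram).

Per class: ground-glass is −350 HU with a partial-volume-like soft edge
whose 50% attenuation level sits exactly on the truth boundary (so the
apparent extent equals the truth extent); reticular foci carry 1–2-voxel
septa at −100 HU in three random plane families (5-voxel spacing) over lung
background; honeycomb foci are −100 HU walls punched with ~2-voxel air
cysts; the low-attenuation bands are uniform −910/−950/−980 HU. Lesions stay
≥ 2 voxels inside the lung surface: a lesion touching the pleura merges with
the chest wall under threshold segmentation and the lung envelope is no
longer recoverable — a genuine limitation of threshold-based extraction that
the phantom respects rather than triggers.

All randomness flows from a single integer seed through numpy's PCG64
generator, which is platform-stable: identical seeds give voxelwise
identical bundles.

**What the phantoms do and do not show.** They exercise unit conversions,
conservation properties, segmentation topology, signature learning and the
recovery of volumetric class fractions under controlled noise. They do not
contain airway trees, vessels, cardiac structures, gravity-dependent
gradients, reconstruction-kernel texture, or the full within-class
heterogeneity of clinical HRCT, so passing tests demonstrate correctness of
the computational chain, not clinical classification performance.

## Assay calculators

Pure functions with explicit validity checks: efflux % = 100·media/(media +
cells) (bounded, scale-invariant); esterified = total − free (free > total
is a measurement inconsistency and raises, never clamps);
cholesterol:phospholipid ratio carries assay-dependent units symbolically;
turbidity = OD600 × (sample + diluent)/sample. qPCR efficiency comes from
the least-squares slope of Cq vs log10 input over ≥ 4 points spanning ≥ 3
logs, E = 10^(−1/slope); relative expression uses the Pfaffl ratio
E_t^ΔCq_t / E_r^ΔCq_r with ΔCq = Cq(calibrator) − Cq(sample), normalized to
a reference gene. The exact efficiency-corrected formula is rarely printed
in method sections; the Pfaffl form is the documented default here and the
classic 2^−ΔΔCq is available as a flag (identical when both efficiencies
are 2).

## Numerical choices and degenerate inputs

Histogram normalization tolerances are 1e-9; percentage-partition
invariants 1e-6; mass additivity 1e-6 g. Empty result tables, non-3-D
images, non-finite voxels, labels outside vocabulary, missing lungs, and
more than two plausible lung components all raise with messages naming the
offending property. When a subject height is absent, predicted-mass fields
are `None`, never zero. Reports carry no timestamps, so identical configs
and seeds produce byte-identical output files.

## Problem sizes

The test suite and the acceptance script use the default 96×128×128 phantom
(≈ 290k lung voxels) for segmentation, densitometry and the involved-percent
recovery grid (burdens 10/30/50% × 3 seeds), and a 64×96×96 phantom for the
end-to-end determinism checks; these sizes exercise every code path while
keeping a full run in the low minutes on one CPU.
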