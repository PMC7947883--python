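# Methods

`gtvconcord` quantifies how well alternative gross-target-volume (GTV)
contours of a thoracic oesophageal tumour agree with one another, and
provides a fully synthetic test bed on which every reported number has a
known ground truth.  This note documents the models, the conventions that
affect numbers, and the limits of what the synthetic results demonstrate.

## Coordinate and voxel conventions

Arrays are ordered `(CC, AP, LR)` — cranio-caudal slices first — while all
user-facing coordinates are reported `(LR, AP, CC) = (x, y, z)`.  The
centre of voxel `(i, j, k)` is at `(i·dz, j·dy, k·dx)` mm.  A voxel belongs
to an analytic shape iff its **centre** satisfies the shape inequality;
this single rule is shared by the generator and by the brute-force oracles
used in the tests, so voxel counts are comparable exactly.  Threshold
comparisons are inclusive (`≥`), which is bit-stable under exact ties.

## The phantom

Each synthetic patient is a pair of volumes on one grid (default
160×128×128 voxels at 3×1×1 mm; 3 mm is a typical planning-CT slice
thickness):

* **CT (HU)** — lung-density background (−700 HU), a mediastinal fat block
  (−80 HU), an oesophagus modelled as a gas-filled tube (lumen radius 2 mm,
  normal wall 2.5 mm at 40 HU), and a tumour: an annular cylinder of outer
  radius `tumor_radius` and wall `wall_thickness` (60 HU) centred at one of
  three stations — upper, middle, distal (groups A/B/C at 70%, 50%, 30% of
  the CC extent).  Middle/distal cases also carry a 20 mm-radius cardiac
  sphere (40 HU).
* **PET (SUV)** — background 1.0 with a uniform-uptake plateau at
  `tumor_suvmax` over the tumour wall and a cosine taper of width
  `pet_taper` (default 1 mm) **centred on the tumour boundary**, i.e. the
  edge sits at half maximum, as for an evenly blurred uniform lesion.  This
  placement makes absolute-SUV and fraction-of-maximum thresholds select
  nested, nearly unbiased regions.  The heart carries SUV 1.8 by default —
  deliberately below the enrolment criterion of 2 — and can be raised to
  exercise the heart-repair rule.
* **Noise** — additive Gaussian (SUV σ = 0.2, HU σ = 10), clipped to
  physical ranges.  σ = 0.2 keeps thresholding stable at the default
  uptake levels.  The RNG seed in the spec fully determines the volumes.

Default tumour geometry (length 85 mm, radius 15 mm) gives volumes near
55 cm³ and lengths near 8.5 cm, the scale reported for thoracic
oesophageal GTVs.  SUVmax must lie in [3.21, 49.50] (the observed clinical
range; every patient therefore passes the SUVmax ≥ 2 enrolment filter);
cohort draws are log-normal with mean ≈ 13.

### Contour variants

Each patient gets three contours — `GTV_3D` (planning-CT contour),
`GTV_PET-ref` (CT contour drawn with visual PET reference) and
`GTV_PET-reg` (threshold contour on the deformably registered PET) —
realised as the truth cylinder perturbed by a per-variant
`PerturbationSpec`: a COM shift (mm per axis), a length delta, an outer
radius delta, and an optional sinusoidal AP bend standing in for residual
inter-frame misalignment.  Perturbed shapes are re-voxelised analytically;
masks are never resampled, so a zero perturbation reproduces the truth
mask bit for bit and lattice-aligned shifts are exactly recoverable.

### Cohort distributions

The default cohort is 72 patients split 32/24/16 across groups A/B/C.
Per-variant perturbations are Gaussian.  The calibration intends two
properties: (i) total-cohort median conformity index ≈ 0.70 between any
two variants, and (ii) distal tumours (group C) roughly three- to
five-fold larger centroid displacement than upper tumours, reflecting the
greater motion of the distal oesophagus.  Size disagreement carries most
of the CI deficit (length σ = 8 mm, radius σ = 1.05 mm per variant) because
mm-scale COM shifts alone barely move the CI of a 30 mm-wide cylinder; the
PET-referenced variant is biased +6 mm longer and ≈1 mm narrower, the
threshold-derived variant slightly shorter and narrower, mirroring the
qualitative clinical pattern (PET contours longer, CT contours wider).
Deltas drawn beyond physical validity (wall < 1 mm, length < one slice)
are truncated.  These distributions are configurable per group and are a
plausibility calibration, not a claim to reproduce any clinic.

## Delineation rules

* **SUV threshold** — inside a user-placed ROI sphere, the effective
  threshold is `T = max(2.5, 0.20 × SUVmax_ROI)`, SUVmax being taken
  within the sphere.  The combination of the absolute 2.5 floor and the
  20 %-of-maximum criterion is not standardised; the default treats both
  as floors and yields a single contour, and each criterion alone is
  exposed as a mode.  Raising T can only shrink the mask (asserted as a
  property).  An ROI SUVmax below 2 raises an enrolment error.
* **CT wall rule** — after clamping to the mediastinal window (width
  400 HU, level 40 HU), soft tissue (windowed HU ≥ 0) is segmented per
  axial slice; the connected component nearest the oesophageal axis is
  kept iff estimated wall thickness > 5 mm **or** in-plane diameter
  > 10 mm.  Thickness is estimated as the diameter of the largest
  inscribed disc (2 × max distance transform, exact to one pixel for an
  annulus); diameter as the in-plane Feret diameter plus one pixel.  The
  published rule is an instruction to a human observer; this estimator is
  an explicit machine surrogate for phantom work, accurate to about one
  voxel.
* **Heart repair** — subtraction of a CT-derived heart mask from a PET
  contour, a stated surrogate for the manual "repair the heart on CT"
  step, which has no quantitative published rule.

No partial-volume or point-spread correction is applied.

## Concordance metrics

For contours A, B with voxel counts |A|, |B| and intersection |A∩B|:

* COM: unweighted mean of member-voxel centres (contours, not images, are
  compared); displacement is reported per axis (LR, AP, CC) and as the 3D
  vector `V = (Δx² + Δy² + Δz²)^½`.
* Conformity index `CI = |A∩B|/|A∪B|` (Jaccard); degree of inclusion
  `DI(A in B) = |A∩B|/|A|`; Dice `= 2|A∩B|/(|A|+|B|)`.  The identities
  `CI = Dice/(2−Dice)` and `CI = 1/(1/DI_AB + 1/DI_BA − 1)` hold exactly
  and are asserted to 1e−12.  `1 − DI(A in B)` is the fraction of A
  irradiated unnecessarily when B is the reference.
* Hausdorff distance: symmetric max-min over member-voxel centres,
  computed with Euclidean distance transforms on the joint bounding box —
  exact for voxel-centre point sets and equivalent to the surface-based
  value for the maximum.
* Shape: volume (count × voxel volume), CC length = occupied-slice extent
  × slice thickness, and maximum transverse diameter = largest in-plane
  pairwise centre distance on any slice plus one in-plane voxel
  (full-width convention).  How length and maximum diameter are measured
  on-screen clinically is not standardised; these slice-extent and Feret
  conventions are explicit stand-ins, stated because the reported cm
  values depend on them.  Metrics are computed in mm and reported in
  cm/cm³.

Masks must share a grid; a nearest-neighbour resampling helper maps a
mask onto a reference geometry first (nearest neighbour preserves
binarity).  One empty contour yields CI = 0, DI of the empty side 0 (with
a warning) and an undefined Hausdorff; two empty contours are an error.

## Cohort statistics

Per group (Total/A/B/C) the pipeline reports median, linearly interpolated
quartiles, mean and sample SD (n−1).  Paired comparisons use the Wilcoxon
signed-rank test for position, volume, CI and DI (zero differences
dropped, ties mid-ranked, exact null for ≤ 25 usable pairs, otherwise a
continuity-corrected normal approximation — the common SPSS behaviour;
both the zero handling and the switch point are configurable) and the
paired t test for length and maximum transverse diameter.  CI–vector
association uses Spearman's rho with a two-sided t-based P.  P values are
read per comparison at 0.05 with no multiplicity correction by default
(a Holm option exists).  Degenerate inputs (all-zero differences,
zero-variance differences, constant ranks) are flagged rather than
reported as numbers.

Type-I error of both paired tests is verified by simulation to lie in
[0.03, 0.07] at α = 0.05 over 2000 null cohorts of n = 30.

## Pipeline and reproducibility

`run_all` chains simulate → delineate → compare → stats, writing every
intermediate (manifest, masks, delineation QA, metrics, tables) plus a
`run_info.json` carrying the seed and a SHA-256 digest of the
configuration.  The contours compared in the tables are the simulated
variants, whose differences are known by construction; the rule-based
delineation runs on the same volumes as a per-patient QA stage (effective
threshold, ROI SUVmax, Dice against truth) rather than replacing them —
the tables then measure exactly the perturbations the generator applied.
One global seed expands into per-patient substreams keyed by a stable hash
of the patient id, so enlarging a cohort never reshuffles existing
patients.  A fixed configuration and seed reproduce every CSV byte for
byte.  The default 72-patient run takes about a minute on one CPU; tests
use a 40×48×48 phantom for speed.

## Known limitations

* The phantom has no anatomical CT texture, no respiratory (4D) motion,
  no lymph nodes, and a strictly cylindrical tumour; deformable
  registration itself is not modelled — only a parameterised residual
  misalignment.  Passing tests therefore demonstrate correctness of the
  metrics, rules and statistics on controlled geometry, not clinical
  accuracy of any delineation method.
* The perturbation distributions are loosely calibrated to published
  summary magnitudes (mm-scale vectors, median CI ≈ 0.7); clinical
  inter-observer and inter-modality variability is richer than a
  translate-and-scale model.
* The CT wall-thickness estimator is exact only to about one voxel and
  assumes the oesophageal wall is separated from other soft tissue by
  lower-density fat, as in the phantom.
* No DICOM/DICOM-RT I/O (NIfTI only) and no dose or surface-distance
  (mean, 95th-percentile) metrics.
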