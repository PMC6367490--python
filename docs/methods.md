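# Methods

## Image model and conventions

All volumes are 3-D scalar fields on an anisotropic voxel lattice with
voxel-centre physical coordinates `x = origin + index · spacing` (mm,
0-based indices).  SUV images carry values in g/mL, finite and
non-negative.  Binary masks and lesion label fields live on the exact grid
of their source image; the pipeline never resamples, and test and retest
scans are analysed each on their own grid (no between-day registration).
Connected components default to the 26-neighbourhood (faces, edges,
corners), the most inclusive standard order in PET segmentation tools;
6- and 18-neighbourhoods are configurable everywhere a connectivity
matters.  Volumes in mL are voxel counts times the voxel volume
`prod(spacing)/1000`.

## Delineation operators

Candidate lesions are seeded as connected components of a whole-body fixed
threshold (default 2.5 g/mL) with components below `min_lesion_ml`
(default 0.1 mL) discarded; each candidate is analysed in a bounding box
grown by `margin_mm` (default 20 mm).  All threshold comparisons are
inclusive (`SUV >= T`), which makes recovery of a noiseless uniform lesion
exact rather than off by the boundary voxels.

- **SUV25 / SUV40** — global thresholds at 2.5 / 4.0 g/mL over the whole
  body.
- **41MAX** — per lesion, `SUV >= 0.41 · SUVmax`, restricted to the
  connected component containing the max voxel.  Background activity does
  not enter.
- **SUVpeak** — the highest mean SUV of a 1 mL sphere whose centre voxel
  lies inside the lesion.  The sphere is the set of voxels whose centres
  fall within radius r, (4/3)πr³ = 1 mL (r ≈ 6.20 mm); sub-voxel centre
  placement is not attempted.  At the image boundary only in-image voxels
  enter the mean.  The implementation is a normalised convolution over the
  lesion's bounding box and is algebraically identical to the exhaustive
  centre scan it is tested against.
- **Local background** — the mean SUV of a single-voxel-thick 3-D shell at
  25 mm Euclidean distance (anisotropic-aware distance transform, physical
  mm) outside the lesion's 70 %-of-SUVmax isocontour; shell voxels with
  SUV strictly above 2.5 are excluded, as are voxels belonging to any
  other candidate lesion (preventing neighbouring-lesion contamination).
  The shell is the band `25 mm <= d < 25 mm + min(spacing)`.  If the
  exclusions empty the shell, the unexcluded shell mean is used and a
  warning logged: aborting a whole-body run over one pathological lesion
  would be worse than a locally biased background.  If the shell falls
  entirely outside the image, the non-lesion voxels of the analysis box
  serve as fallback, again with a warning.
- **A50P** — `T = 0.5 · (SUVpeak − BG) + BG`, restricted to the component
  containing the peak-sphere centre.  Because T < SUVpeak whenever
  SUVpeak > BG, the operator still works when lesion uptake is below
  twice the local background.  An inverted contrast (SUVpeak ≤ BG) yields
  an empty mask with a warning.

The per-lesion component restriction means a mask cannot leak through its
margin box into a neighbouring avid structure unless the two are actually
connected above threshold — the known low-contrast failure mode of
fraction-of-max thresholds is thereby bounded by the margin box.

## Consensus masks

MV2 and MV3 are voxel-wise: each of the four standard whole-body masks
contributes one vote per voxel, and the consensus keeps voxels with ≥ 2
(MV2) or ≥ 3 (MV3) votes.  This gives the strict chain
∩(all four) ⊆ MV3 ⊆ MV2 ⊆ ∪(all four), and consequently
TMATV(MV3) ≤ TMATV(MV2) always.  Consensus lesions are re-derived by
connected components afterwards; components that no single method produced
as a whole are retained.  No per-lesion matching, weighting or
probabilistic fusion (e.g. STAPLE) is attempted.

## Metrics

Per lesion: MATV = voxel count × voxel volume; SUVmean over all in-mask
voxels (blur-tail voxels are not excluded); TLG = MATV × SUVmean (g).
Per patient and condition: TMATV = Σ MATV (mL), TTB = Σ TLG (g) — both
invariant under any re-partition of the same foreground voxels.  The
Jaccard index is computed between whole-body masks (the union over
lesions), not between matched lesion pairs; two empty masks score 0 by
convention (avoiding 0/0) with a warning.  Cohort accuracy is summarised
as the per-method mean JI with its interquartile range, per scan day.

## Test-retest statistics

For each patient × condition (uptake ∈ {60, 90} min, reconstruction ∈
{EARL-like, PSF-like}, method ∈ six) and metric ∈ {TMATV, TTB}:
TRT = day2 − day1 and TRT% = 100 · TRT / pair mean (bounded in ±200 % for
positive values), with absolute variants aTRT, aTRT%.  Cohort summaries
report the mean and the repeatability coefficient RC = 1.96 · SD, using
the sample SD (n − 1 denominator, the convention of the test-retest
literature); mean ± RC is the 95 % band for a repeat difference.
Agreement is additionally summarised by ICC(3,1) — two-way mixed model,
consistency type, single measures — computed from the ANOVA mean squares
`(MS_subjects − MS_error) / (MS_subjects + MS_error)` for k = 2 days;
consistency type deliberately ignores a fixed between-day shift, and the
absolute-agreement ICC is deliberately not used.  ICC is computed on raw
(untransformed) values.  Degenerate inputs: zero between-subject variance
gives NaN (undefined); zero error variance with subject variance present
gives exactly 1.  Pairs missing one day are excluded listwise from a
condition's SD/RC/ICC (with `n_pairs` reported) but kept, with missing
cells, in the long-format export so external GEE-style software can handle
the missingness via the patient term.  No multiple-comparison correction
is applied anywhere.

## Synthetic phantom

The generator emulates a paired-scan whole-body study: per virtual
patient, four scans (2 days × 2 uptake intervals) × two reconstructions.
Defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_patients | 10 | cohort size |
| lesions_per_patient | 1–15 | uniform integer draw |
| lesion_radii_mm | 5–30 | base semi-axis; per-axis anisotropy 0.85–1.18 |
| lesion_suv_max | 3–15 g/mL | uniform lesion uptake |
| background_suv | 1.0 g/mL | uniform soft-tissue background |
| blur_fwhm_earl / psf | 7.0 / 4.5 mm | isotropic Gaussian, σ = FWHM/2.3548 |
| noise_sd | 0.10 g/mL | additive Gaussian after blur, clipped at 0 |
| uptake90_scale | 1.15 | lesion (not background) intensity at 90 min |
| day2_uptake_jitter | 0.10 | lognormal σ of per-lesion day-2 uptake factor |
| day2_shift_mm | 3.0 | per-axis uniform day-2 lesion translation |
| grid | 64×64×160 @ 4 mm | ~26×26×64 cm whole-body-like field of view |

Lesions are uniform ellipsoids rasterised by the voxel-centre-inside test;
placement rejects overlaps (sphere bound plus a gap budget covering the
day-2 shift) with bounded retries.  Blur is applied before noise; the
smoother EARL-like kernel emulates harmonised reconstruction, the sharper
PSF-like kernel resolution-modelled reconstruction.  Ground truth (label
field and analytic volumes) is the pre-blur, pre-noise object.  Day-2
truths differ from day-1 only by the uptake jitter and translation; no
lesion appears or disappears, consistent with stable disease over a few
days.  The 4 mm isotropic grid, the blur widths and the day-2 jitter
magnitudes are this package's own modelling choices.

Randomness is organised as one root seed spawning independent substreams
per patient and per scan condition, so generating a subset of conditions
reproduces exactly the volumes of a full run.

What the phantom does *not* emulate: anatomy and physiological uptake,
Poisson counting statistics and reconstruction artefacts, respiratory
motion, partial-volume effects beyond Gaussian blur, and inter-observer
contouring variability (a programmatic observer emulator — a biased global
SUV 4.0 threshold restricted to true components — stands in for a human
reference).  Tests passing on this phantom therefore validate the
operators, the consensus algebra and the statistics, not clinical
segmentation accuracy on real heterogeneous lesions: real-data Jaccard
scores and repeatability coefficients will be substantially worse than the
phantom's.

## Problem sizes and numerical choices

The default experiment (10 patients, 80 volumes of 64×64×160 voxels, six
methods) runs in well under a minute on one CPU; the test suite uses
scaled-down grids (typically 40×40×80, 3–5 patients) chosen so that every
property is exercised on multi-lesion, multi-condition studies while the
whole suite stays interactive.  Exactness choices worth knowing: inclusive
thresholds; deterministic component labelling in scan order; float64
throughout; CSV output with fixed `%.10g` formatting so identical
config + seed reproduces byte-identical tables.

## Known limitations

- The A50P threshold uses the background-corrected 50 %-of-peak rule; other
  software lineages implement slightly different contrast corrections
  (iterative or calibrated variants), so absolute A50P volumes are not
  interchangeable across tools.
- The background shell is a discrete band one voxel thick at ≥ 25 mm;
  on coarse grids its mean can differ slightly from a continuous-shell
  integral.
- Whole-body fixed thresholds include any avid structure; on the phantom
  there is none, but on real data SUV25 in particular needs the candidate
  filtering and physiological-uptake removal that the observer workflow
  provides.
- GEE fitting of condition effects is intentionally out of scope; the
  long-format export is the interface to external statistical software.
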