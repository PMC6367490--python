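"""Synthetic paired test/retest whole-body PET phantom generator.

Emulates a 10-patient study design in which every virtual patient is
scanned on two days, at two tracer-uptake intervals (60 and 90 min
post-injection), with each scan reconstructed twice: once with a smoother,
harmonised (EARL-like) kernel and once with a sharper, resolution-modelled
(PSF-like) kernel.  Lesions are uniform ellipsoids of elevated SUV on a
soft-tissue background; reconstruction is emulated as isotropic Gaussian
blur (FWHM per protocol) followed by additive Gaussian noise clipped at
zero.  Ninety-minute images scale lesion (not background) intensity,
emulating continued tracer accumulation; day-2 scans perturb each lesion's
uptake (lognormal multiplicative jitter) and position (small translation).

Ground truth is the analytic, pre-blur, pre-noise object: the rasterised
lesion label field and the analytic ellipsoid volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image_model import BinaryMask, Grid, LabeledLesions, SuvImage, label_components

__all__ = [
    "PhantomSpec",
    "PhantomStudy",
    "PatientPhantom",
    "Lesion",
    "PhantomError",
    "FWHM_TO_SIGMA",
    "generate_study",
    "emulate_observer",
    "ALL_CONDITIONS",
]

#: Gaussian FWHM to standard deviation: sigma = FWHM / (2 sqrt(2 ln 2)).
FWHM_TO_SIGMA = 1.0 / 2.3548

DAYS = (1, 2)
UPTAKES = (60, 90)
RECONSTRUCTIONS = ("earl", "psf")
#: canonical (day, uptake, reconstruction) render order; also the RNG stream order
ALL_CONDITIONS = tuple((d, u, r) for d in DAYS for u in UPTAKES for r in RECONSTRUCTIONS)


class PhantomError(RuntimeError):
    """Raised when lesion placement cannot satisfy the non-overlap constraint."""


@dataclass(frozen=True)
class PhantomSpec:
    """Study-design parameters of the synthetic paired-scan phantom.

    Defaults mimic the scale of an advanced-NSCLC whole-body cohort:
    10 patients with 1-15 avid lesions each, lesion radii 5-30 mm,
    SUVmax 3-15 g/mL over a uniform soft-tissue background of 1.0 g/mL.
    """

    n_patients: int = 10
    lesions_per_patient: tuple[int, int] = (1, 15)
    lesion_radii_mm: tuple[float, float] = (5.0, 30.0)
    lesion_suv_max: tuple[float, float] = (3.0, 15.0)
    background_suv: float = 1.0
    noise_sd: float = 0.10
    blur_fwhm_earl: float = 7.0
    blur_fwhm_psf: float = 4.5
    day2_uptake_jitter: float = 0.10
    day2_shift_mm: float = 3.0
    uptake90_scale: float = 1.15
    shape: tuple[int, int, int] = (64, 64, 160)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    seed: int = 0
    axis_ratio_range: tuple[float, float] = (0.85, 1.18)
    min_lesion_gap_mm: float = 8.0
    placement_retries: int = 500

    def __post_init__(self) -> None:
        if self.lesion_suv_max[0] <= self.background_suv:
            raise ValueError("lesions must be avid: min SUVmax must exceed background")
        if self.blur_fwhm_earl < self.blur_fwhm_psf:
            raise ValueError("EARL-like blur must be at least as wide as PSF-like blur")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.lesions_per_patient[0] < 1 or self.lesions_per_patient[0] > self.lesions_per_patient[1]:
            raise ValueError("invalid lesions_per_patient range")

    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.shape), tuple(self.spacing_mm))


@dataclass(frozen=True)
class Lesion:
    """One uniform ellipsoidal lesion: centre and semi-axes in mm, uniform SUV."""

    centre_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    suv: float

    @property
    def volume_ml(self) -> float:
        """Analytic ellipsoid volume (4/3 pi abc) in mL."""
        a, b, c = self.radii_mm
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0

    @property
    def max_radius_mm(self) -> float:
        return max(self.radii_mm)


@dataclass(frozen=True)
class PatientPhantom:
    patient: int
    lesions: dict[int, tuple[Lesion, ...]]            # day -> lesions (index = id-1)
    truth: dict[int, LabeledLesions]                  # day -> pre-blur label field
    images: dict[tuple[int, int, str], SuvImage]      # (day, uptake, recon) -> image

    def true_volumes_ml(self, day: int) -> list[float]:
        return [les.volume_ml for les in self.lesions[day]]


@dataclass(frozen=True)
class PhantomStudy:
    spec: PhantomSpec
    patients: tuple[PatientPhantom, ...] = field(default_factory=tuple)


def _rasterise(lesions, grid: Grid) -> np.ndarray:
    """Integer label field: voxel-centre-in-ellipsoid test, ids in lesion order."""
    labels = np.zeros(grid.shape, dtype=np.int32)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    for lid, les in enumerate(lesions, start=1):
        c = np.asarray(les.centre_mm)
        r = np.asarray(les.radii_mm)
        lo = np.maximum(np.floor((c - r - origin) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + r - origin) / spacing).astype(int) + 1, grid.shape)
        if np.any(lo >= hi):
            continue
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        axes = [origin[k] + spacing[k] * np.arange(lo[k], hi[k]) for k in range(3)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        inside = (
            ((xx - c[0]) / r[0]) ** 2 + ((yy - c[1]) / r[1]) ** 2 + ((zz - c[2]) / r[2]) ** 2
        ) <= 1.0
        labels[sl][inside] = lid
    return labels


def _sample_patient_lesions(spec: PhantomSpec, rng: np.random.Generator):
    """Draw day-1 lesions with non-overlap; derive day-2 by jitter + shift."""
    n = int(rng.integers(spec.lesions_per_patient[0], spec.lesions_per_patient[1] + 1))
    extent = np.asarray(spec.shape) * np.asarray(spec.spacing_mm)
    day1: list[Lesion] = []
    for _ in range(n):
        placed = False
        for _attempt in range(spec.placement_retries):
            base_r = rng.uniform(*spec.lesion_radii_mm)
            radii = np.clip(
                base_r * rng.uniform(*spec.axis_ratio_range, size=3), *spec.lesion_radii_mm
            )
            suv = rng.uniform(*spec.lesion_suv_max)
            margin = radii.max() + spec.day2_shift_mm + 1.0
            if np.any(extent - 2 * margin <= 0):
                raise PhantomError("grid too small for the requested lesion radii")
            centre = rng.uniform(margin, extent - margin)
            # sphere-bound overlap check with a gap budget covering the day-2 shift
            sep_ok = all(
                np.linalg.norm(centre - np.asarray(other.centre_mm))
                > radii.max() + other.max_radius_mm + spec.min_lesion_gap_mm + 2 * spec.day2_shift_mm
                for other in day1
            )
            if sep_ok:
                day1.append(Lesion(tuple(centre), tuple(radii), float(suv)))
                placed = True
                break
        if not placed:
            raise PhantomError(
                f"could not place lesion {len(day1) + 1}/{n} after "
                f"{spec.placement_retries} retries"
            )
    day2 = []
    for les in day1:
        jitter = rng.lognormal(mean=0.0, sigma=spec.day2_uptake_jitter) if spec.day2_uptake_jitter > 0 else 1.0
        shift = rng.uniform(-spec.day2_shift_mm, spec.day2_shift_mm, size=3) if spec.day2_shift_mm > 0 else np.zeros(3)
        day2.append(
            Lesion(tuple(np.asarray(les.centre_mm) + shift), les.radii_mm, float(les.suv * jitter))
        )
    return tuple(day1), tuple(day2)


def _render(spec: PhantomSpec, lesions, labels: np.ndarray, uptake: int, recon: str,
            rng: np.random.Generator) -> SuvImage:
    grid = spec.grid
    values = np.full(grid.shape, spec.background_suv, dtype=float)
    scale = spec.uptake90_scale if uptake == 90 else 1.0
    for lid, les in enumerate(lesions, start=1):
        values[labels == lid] = les.suv * scale
    fwhm = spec.blur_fwhm_earl if recon == "earl" else spec.blur_fwhm_psf
    if fwhm > 0:
        sigma_vox = fwhm * FWHM_TO_SIGMA / np.asarray(grid.spacing)
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=grid.shape)
    np.clip(values, 0.0, None, out=values)
    return SuvImage(values, grid.spacing)


def generate_study(spec: PhantomSpec, conditions=None) -> PhantomStudy:
    """Generate the full paired-scan study for every virtual patient.

    Parameters
    ----------
    spec : PhantomSpec
        Study design; identical spec (and seed) gives bit-identical output.
    conditions : sequence of (day, uptake, reconstruction), optional
        Restrict rendering to a subset of scan conditions.  Patient truths
        and the noise stream of every rendered condition are unaffected by
        the restriction (each condition has its own RNG substream).
    """
    if conditions is None:
        conditions = ALL_CONDITIONS
    conditions = [(int(d), int(u), str(r)) for d, u, r in conditions]
    for cond in conditions:
        if cond not in ALL_CONDITIONS:
            raise ValueError(f"unknown scan condition {cond}")

    root = np.random.SeedSequence(spec.seed)
    patients = []
    for pid, patient_ss in enumerate(root.spawn(spec.n_patients), start=1):
        streams = patient_ss.spawn(1 + len(ALL_CONDITIONS))
        truth_rng = np.random.default_rng(streams[0])
        day1, day2 = _sample_patient_lesions(spec, truth_rng)
        lesions = {1: day1, 2: day2}
        labels = {d: _rasterise(lesions[d], spec.grid) for d in DAYS}
        truth = {
            d: LabeledLesions(labels[d], spec.grid, connectivity=26) for d in DAYS
        }
        images = {}
        for k, cond in enumerate(ALL_CONDITIONS):
            if cond not in conditions:
                continue
            day, uptake, recon = cond
            rng = np.random.default_rng(streams[1 + k])
            images[cond] = _render(spec, lesions[day], labels[day], uptake, recon, rng)
        patients.append(PatientPhantom(pid, lesions, truth, images))
    return PhantomStudy(spec, tuple(patients))


def emulate_observer(image: SuvImage, truth: LabeledLesions,
                     threshold_bias: float = 1.0,
                     base_threshold: float = 4.0) -> BinaryMask:
    """Programmatic stand-in for an expert reference delineation.

    Applies a global fixed-SUV threshold (``base_threshold * threshold_bias``,
    the default base being the whole-body SUV 4.0 seed an observer would
    start from) and keeps only connected components that overlap the true
    lesion field — emulating manual removal of physiological uptake.  A
    bias above 1 tightens, below 1 loosens the contour; the returned mask
    volume is monotone non-increasing in the bias.
    """
    if threshold_bias <= 0:
        raise ValueError("threshold_bias must be positive")
    image.grid.require_match(truth.grid)
    thresholded = BinaryMask(image.values >= base_threshold * threshold_bias, image.grid)
    if not truth.labels.any():
        return BinaryMask(np.zeros(image.grid.shape, dtype=bool), image.grid)
    comps = label_components(thresholded, connectivity=truth.connectivity)
    keep_ids = np.unique(comps.labels[(truth.labels > 0) & (comps.labels > 0)])
    keep = np.isin(comps.labels, keep_ids[keep_ids > 0])
    return BinaryMask(keep, image.grid)
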