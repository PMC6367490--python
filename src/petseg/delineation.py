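"""Standard PET-based semi-automatic lesion delineation operators.

Four threshold operators are provided, the workhorses of clinical
metabolic-volume software:

``SUV25`` / ``SUV40``
    whole-body fixed SUV thresholds at 2.5 and 4.0 g/mL;
``41MAX``
    adaptive per-lesion threshold at 41% of the lesion's maximum SUV,
    ignoring background activity;
``A50P``
    contrast-corrected per-lesion threshold at 50% of the peak SUV above
    the local background, T = 0.5 * (SUVpeak - BG) + BG, able to segment
    lesions whose uptake is below twice the local background.

Two sub-procedures feed A50P: ``suv_peak`` (the highest mean SUV of a 1 mL
sphere positioned inside the lesion) and ``local_background`` (the mean SUV
of a single-voxel 3-D shell 2.5 cm outside the lesion's 70%-of-SUVmax
isocontour, excluding shell voxels with SUV above 2.5).

All threshold comparisons are inclusive (``>=``), which makes recovery of a
noiseless uniform lesion exact.  Per-lesion masks are restricted to the
connected component containing the lesion's max (41MAX) or peak (A50P)
voxel so that a mask cannot leak into a neighbouring avid structure inside
its margin box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_model import (
    BinaryMask,
    LabeledLesions,
    SuvImage,
    connectivity_structure,
    label_components,
)

__all__ = [
    "DelineationConfig",
    "LesionContext",
    "STANDARD_METHODS",
    "CONSENSUS_METHODS",
    "ALL_METHODS",
    "segment_fixed_threshold",
    "detect_candidates",
    "lesion_context",
    "suv_peak",
    "segment_41max",
    "local_background",
    "segment_a50p",
    "run_method",
]

STANDARD_METHODS = ("SUV25", "SUV40", "41MAX", "A50P")
CONSENSUS_METHODS = ("MV2", "MV3")
ALL_METHODS = STANDARD_METHODS + CONSENSUS_METHODS


@dataclass(frozen=True)
class DelineationConfig:
    """Tunable parameters of the delineation operators (units in names)."""

    detection_threshold: float = 2.5   # SUV seed threshold for candidate lesions
    min_lesion_ml: float = 0.1         # candidates smaller than this are dropped
    margin_mm: float = 20.0            # physical margin around each candidate box
    connectivity: int = 26
    shell_distance_mm: float = 25.0    # local-background shell offset
    shell_exclusion_suv: float = 2.5   # shell voxels strictly above this are dropped
    isocontour_fraction: float = 0.70  # isocontour for the shell reference surface
    peak_sphere_ml: float = 1.0        # SUVpeak sphere volume
    a50p_fraction: float = 0.50
    fortyone_fraction: float = 0.41
    suv25_threshold: float = 2.5
    suv40_threshold: float = 4.0


@dataclass(frozen=True)
class LesionContext:
    """Sub-grid around one candidate lesion plus its summary uptake values."""

    lesion_id: int
    slices: tuple[slice, slice, slice]   # margin box in full-image indices
    lesion_local: np.ndarray             # bool, candidate voxels within the box
    suv_max: float
    max_index: tuple[int, int, int]      # full-image index of the lesion's max voxel


def segment_fixed_threshold(image: SuvImage, threshold: float) -> BinaryMask:
    """Whole-body fixed SUV threshold: voxel included iff SUV >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return BinaryMask(image.values >= threshold, image.grid)


def detect_candidates(image: SuvImage, config: DelineationConfig = DelineationConfig()) -> LabeledLesions:
    """Seed candidate lesions: components of the detection threshold, size-filtered.

    Components smaller than ``min_lesion_ml`` are removed and the survivors
    relabelled 1..N in stable scan order.  Zero candidates is a valid result.
    """
    mask = segment_fixed_threshold(image, config.detection_threshold)
    comps = label_components(mask, config.connectivity)
    if comps.n_lesions == 0:
        return comps
    counts = np.bincount(comps.labels.ravel(), minlength=comps.n_lesions + 1)
    min_vox = config.min_lesion_ml / image.grid.voxel_volume_ml
    keep = np.flatnonzero(counts >= min_vox)
    keep = keep[keep > 0]
    remap = np.zeros(comps.n_lesions + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return LabeledLesions(remap[comps.labels], image.grid, config.connectivity, int(keep.size))


def _bbox_slices(mask: np.ndarray, margin_vox, shape) -> tuple[slice, slice, slice]:
    idx = np.nonzero(mask)
    lo = [max(int(i.min()) - m, 0) for i, m in zip(idx, margin_vox)]
    hi = [min(int(i.max()) + m + 1, s) for i, m, s in zip(idx, margin_vox, shape)]
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def lesion_context(image: SuvImage, candidates: LabeledLesions, lesion_id: int,
                   config: DelineationConfig = DelineationConfig()) -> LesionContext:
    """Bounding region (candidate box + physical margin) of one candidate."""
    lesion = candidates.labels == lesion_id
    if not lesion.any():
        raise ValueError(f"lesion id {lesion_id} is empty")
    margin_vox = [int(np.ceil(config.margin_mm / s)) for s in image.grid.spacing]
    slices = _bbox_slices(lesion, margin_vox, image.grid.shape)
    local = lesion[slices]
    vals = image.values[slices]
    masked = np.where(local, vals, -np.inf)
    flat = int(np.argmax(masked))
    local_idx = np.unravel_index(flat, local.shape)
    max_index = tuple(int(s.start + i) for s, i in zip(slices, local_idx))
    return LesionContext(lesion_id, slices, local, float(vals[local_idx]), max_index)


# ---------------------------------------------------------------------------
# SUVpeak

def _sphere_offsets(spacing, radius_mm: float) -> np.ndarray:
    """Voxel-index offsets whose centres lie within radius_mm of the origin."""
    spacing = np.asarray(spacing, dtype=float)
    half = np.floor(radius_mm / spacing).astype(int)
    rng = [np.arange(-h, h + 1) for h in half]
    grids = np.meshgrid(*rng, indexing="ij")
    offs = np.stack([g.ravel() for g in grids], axis=1)
    d2 = ((offs * spacing) ** 2).sum(axis=1)
    return offs[d2 <= radius_mm**2]


def peak_sphere_radius_mm(volume_ml: float) -> float:
    """Radius of a sphere of the given volume: (3 V / 4 pi)^(1/3), V in mm^3."""
    return float((3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def _suv_peak_with_position(image: SuvImage, lesion_mask: np.ndarray,
                            config: DelineationConfig) -> tuple[float, tuple[int, int, int]]:
    """Max over lesion-voxel centres of the in-sphere mean SUV, and its argmax.

    The sphere is the set of voxels whose centres lie within the 1 mL radius
    of the centre voxel; at the image boundary only in-image voxels enter
    the mean.  Implemented as a normalised convolution over the lesion's
    bounding box, mathematically identical to the exhaustive centre scan.
    """
    if not lesion_mask.any():
        raise ValueError("lesion is empty")
    radius = peak_sphere_radius_mm(config.peak_sphere_ml)
    spacing = image.grid.spacing
    offs = _sphere_offsets(spacing, radius)
    half = [int(np.abs(offs[:, k]).max()) for k in range(3)]
    box = _bbox_slices(lesion_mask, half, image.grid.shape)
    sub = image.values[box]
    kernel = np.zeros([2 * h + 1 for h in half])
    kernel[tuple((offs + half).T)] = 1.0
    sums = ndimage.convolve(sub, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones_like(sub), kernel, mode="constant", cval=0.0)
    means = sums / counts
    local = lesion_mask[box]
    means = np.where(local, means, -np.inf)
    flat = int(np.argmax(means))
    idx = np.unravel_index(flat, means.shape)
    pos = tuple(int(s.start + i) for s, i in zip(box, idx))
    return float(means[idx]), pos


def suv_peak(image: SuvImage, candidates: LabeledLesions, lesion_id: int,
             config: DelineationConfig = DelineationConfig()) -> float:
    """Peak SUV of one lesion: highest mean SUV of a 1 mL sphere whose centre
    voxel lies inside the lesion."""
    lesion = candidates.labels == lesion_id
    value, _ = _suv_peak_with_position(image, lesion, config)
    return value


# ---------------------------------------------------------------------------
# Per-lesion threshold masks

def _component_containing(mask: np.ndarray, seed_index, connectivity: int) -> np.ndarray:
    labels, _ = ndimage.label(mask, structure=connectivity_structure(connectivity))
    lab = labels[tuple(seed_index)]
    if lab == 0:
        return np.zeros_like(mask)
    return labels == lab


def segment_41max(image: SuvImage, context: LesionContext,
                  config: DelineationConfig = DelineationConfig()) -> BinaryMask:
    """Adaptive 41%-of-SUVmax threshold, restricted to the component holding
    the lesion's max voxel; background activity plays no role."""
    if context.suv_max <= 0:
        raise ValueError("lesion SUVmax must be positive")
    region = image.values[context.slices]
    above = region >= config.fortyone_fraction * context.suv_max
    seed = tuple(i - s.start for i, s in zip(context.max_index, context.slices))
    comp = _component_containing(above, seed, config.connectivity)
    out = np.zeros(image.grid.shape, dtype=bool)
    out[context.slices] = comp
    return BinaryMask(out, image.grid)


def local_background(image: SuvImage, context: LesionContext,
                     config: DelineationConfig = DelineationConfig(),
                     candidates: LabeledLesions | None = None) -> float:
    """Local background activity around one lesion.

    A single-voxel-thick 3-D shell is taken at 25 mm (Euclidean, in physical
    mm) outside the lesion's 70%-of-SUVmax isocontour; shell voxels with SUV
    strictly above 2.5 are excluded, as are voxels belonging to any other
    candidate lesion, and the mean SUV of the remainder is returned.  If the
    exclusions empty the shell, the unexcluded shell mean is used and a
    warning issued (aborting a whole-body run on one pathological lesion
    would be worse than a biased background).
    """
    region = image.values[context.slices]
    iso_local = region >= config.isocontour_fraction * context.suv_max
    seed = tuple(i - s.start for i, s in zip(context.max_index, context.slices))
    iso_local = _component_containing(iso_local, seed, config.connectivity)

    # shell lives well outside the margin box: work on a box grown past the shell
    iso_full = np.zeros(image.grid.shape, dtype=bool)
    iso_full[context.slices] = iso_local
    spacing = image.grid.spacing
    pad_vox = [int(np.ceil((config.shell_distance_mm + 2 * s) / s)) for s in spacing]
    box = _bbox_slices(iso_full, pad_vox, image.grid.shape)
    iso_box = iso_full[box]

    dist = ndimage.distance_transform_edt(~iso_box, sampling=spacing)
    shell = (dist >= config.shell_distance_mm) & (
        dist < config.shell_distance_mm + min(spacing)
    )
    if candidates is not None:
        others = candidates.labels[box]
        shell &= ~((others > 0) & (others != context.lesion_id))
    if not shell.any():
        warnings.warn(
            f"lesion {context.lesion_id}: background shell lies outside the image; "
            "using non-lesion voxels of the margin box",
            stacklevel=2,
        )
        fallback = ~iso_box
        return float(image.values[box][fallback].mean())
    vals = image.values[box][shell]
    kept = vals[vals <= config.shell_exclusion_suv]
    if kept.size == 0:
        warnings.warn(
            f"lesion {context.lesion_id}: SUV>{config.shell_exclusion_suv} exclusion "
            "emptied the background shell; using the unexcluded shell mean",
            stacklevel=2,
        )
        return float(vals.mean())
    return float(kept.mean())


def segment_a50p(image: SuvImage, context: LesionContext,
                 config: DelineationConfig = DelineationConfig(),
                 candidates: LabeledLesions | None = None) -> BinaryMask:
    """Contrast-corrected 50%-of-peak threshold.

    T = a50p_fraction * (SUVpeak - BG) + BG with the 1 mL-sphere peak and the
    shell background; since T < SUVpeak whenever SUVpeak > BG the operator
    still segments lesions with uptake below twice the local background.  An
    inverted contrast (SUVpeak <= BG) yields an empty mask with a warning.
    """
    peak, peak_pos = _suv_peak_with_position(image, _context_lesion_full(image, context), config)
    background = local_background(image, context, config, candidates)
    if peak <= background:
        warnings.warn(
            f"lesion {context.lesion_id}: SUVpeak {peak:.3g} <= background "
            f"{background:.3g}; returning empty mask",
            stacklevel=2,
        )
        return BinaryMask(np.zeros(image.grid.shape, dtype=bool), image.grid)
    threshold = config.a50p_fraction * (peak - background) + background
    region = image.values[context.slices]
    above = region >= threshold
    seed = tuple(i - s.start for i, s in zip(peak_pos, context.slices))
    comp = _component_containing(above, seed, config.connectivity)
    out = np.zeros(image.grid.shape, dtype=bool)
    out[context.slices] = comp
    return BinaryMask(out, image.grid)


def _context_lesion_full(image: SuvImage, context: LesionContext) -> np.ndarray:
    full = np.zeros(image.grid.shape, dtype=bool)
    full[context.slices] = context.lesion_local
    return full


def run_method(image: SuvImage, method: str, candidates: LabeledLesions,
               config: DelineationConfig = DelineationConfig()) -> BinaryMask:
    """Dispatch one of the four standard operators over the whole body.

    SUV25/SUV40 are global thresholds; 41MAX/A50P are the union over
    candidate lesions of their per-lesion masks.  With no candidates the
    adaptive methods return an empty mask.
    """
    if method == "SUV25":
        return segment_fixed_threshold(image, config.suv25_threshold)
    if method == "SUV40":
        return segment_fixed_threshold(image, config.suv40_threshold)
    if method not in ("41MAX", "A50P"):
        raise ValueError(f"unknown delineation method {method!r}")
    out = np.zeros(image.grid.shape, dtype=bool)
    for lid in candidates.lesion_ids():
        ctx = lesion_context(image, candidates, lid, config)
        if method == "41MAX":
            mask = segment_41max(image, ctx, config)
        else:
            mask = segment_a50p(image, ctx, config, candidates)
        out |= mask.values
    return BinaryMask(out, image.grid)
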