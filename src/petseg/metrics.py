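"""Per-lesion and whole-body tumour-load metrics, and overlap scoring.

Per lesion: MATV (metabolic active tumour volume, mL), SUVmean, SUVmax,
SUVpeak and TLG (total lesion glycolysis, grams) = MATV x SUVmean.
Per patient and condition: TMATV = sum of MATV over all lesions (mL) and
TTB = total tumour burden = whole-body sum of TLG (grams).

Delineation accuracy is scored with the Jaccard index
JI(A, B) = |A n B| / |A u B| between whole-body masks: 1.0 is perfect
coincidence, 0.0 no intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .delineation import DelineationConfig, _suv_peak_with_position
from .image_model import BinaryMask, LabeledLesions, SuvImage

__all__ = [
    "LesionRecord",
    "PatientMeasurement",
    "lesion_metrics",
    "patient_totals",
    "jaccard",
    "measurements_frame",
]


@dataclass(frozen=True)
class LesionRecord:
    """Quantitative summary of one delineated lesion."""

    lesion_id: int
    matv_ml: float
    suv_mean: float
    suv_max: float
    suv_peak: float
    tlg_g: float


@dataclass(frozen=True)
class PatientMeasurement:
    """Whole-body totals for one patient / day / uptake / reconstruction / method."""

    patient: int
    day: int
    uptake: int
    reconstruction: str
    method: str
    tmatv_ml: float
    ttb_g: float
    lesions: tuple[LesionRecord, ...] = field(default_factory=tuple)


def lesion_metrics(image: SuvImage, lesions: LabeledLesions,
                   config: DelineationConfig = DelineationConfig(),
                   include_peak: bool = True) -> list[LesionRecord]:
    """Per-component MATV, SUVmean/max/peak and TLG.

    MATV is the voxel count times the voxel volume; SUVmean averages all
    in-mask voxels; TLG is their product.  Empty ids are skipped.
    """
    image.grid.require_match(lesions.grid)
    vv = image.grid.voxel_volume_ml
    records = []
    for lid in lesions.lesion_ids():
        sel = lesions.labels == lid
        n = int(sel.sum())
        if n == 0:
            continue
        vals = image.values[sel]
        matv = n * vv
        mean = float(vals.mean())
        if include_peak:
            peak, _ = _suv_peak_with_position(image, sel, config)
        else:
            peak = float("nan")
        records.append(
            LesionRecord(lid, matv, mean, float(vals.max()), peak, matv * mean)
        )
    return records


def patient_totals(records, patient: int, day: int, uptake: int,
                   reconstruction: str, method: str) -> PatientMeasurement:
    """Sum lesion records into TMATV (mL) and TTB (g); empty list gives zeros."""
    tmatv = float(sum(r.matv_ml for r in records))
    ttb = float(sum(r.tlg_g for r in records))
    return PatientMeasurement(
        patient, day, uptake, reconstruction, method, tmatv, ttb, tuple(records)
    )


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """Jaccard index |A n B| / |A u B| by voxel counting on a shared grid.

    Two empty masks have no meaningful overlap; the index is defined as 0.0
    and a warning is issued.
    """
    a.grid.require_match(b.grid)
    inter = int(np.logical_and(a.values, b.values).sum())
    union = int(np.logical_or(a.values, b.values).sum())
    if union == 0:
        warnings.warn("Jaccard of two empty masks is undefined; returning 0.0",
                      stacklevel=2)
        return 0.0
    return inter / union


def measurements_frame(measurements) -> pd.DataFrame:
    """Long-format table of PatientMeasurement rows (one per possibility)."""
    rows = [
        {
            "patient": m.patient,
            "day": m.day,
            "uptake": m.uptake,
            "reconstruction": m.reconstruction,
            "method": m.method,
            "tmatv_ml": m.tmatv_ml,
            "ttb_g": m.ttb_g,
            "n_lesions": len(m.lesions),
        }
        for m in measurements
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient", "day", "uptake", "reconstruction", "method",
            "tmatv_ml", "ttb_g", "n_lesions",
        ],
    )
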