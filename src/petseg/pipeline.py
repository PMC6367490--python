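"""End-to-end experiment: phantom -> delineations -> metrics -> repeatability.

One config drives the whole study: generate the paired-scan phantom cohort,
apply the six delineation methods to every scan x reconstruction (the "48
possibilities" per complete patient: 2 days x 2 uptake intervals x 2
reconstructions x 6 methods), compute per-lesion and whole-body metrics,
score each method against the reference delineation with the Jaccard index
(by default only on the 60-min, EARL-like images), and summarise test-retest
repeatability per condition.  Identical config + seed gives byte-identical
output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import majority_vote
from .delineation import (
    ALL_METHODS,
    CONSENSUS_METHODS,
    STANDARD_METHODS,
    DelineationConfig,
    detect_candidates,
    run_method,
)
from .image_model import BinaryMask, label_components, write_volume
from .metrics import jaccard, lesion_metrics, measurements_frame, patient_totals
from .phantom import ALL_CONDITIONS, PhantomSpec, emulate_observer, generate_study
from .repeatability import build_pairs, export_long_table, summarize

log = logging.getLogger("petseg")

__all__ = ["RunConfig", "RunResult", "run_experiment", "load_config", "delineate_image"]


@dataclass(frozen=True)
class RunConfig:
    """Full experiment configuration (YAML-serialisable)."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    delineation: DelineationConfig = field(default_factory=DelineationConfig)
    methods: tuple[str, ...] = ALL_METHODS
    output_dir: str = "petseg_run"
    #: reference delineation for Jaccard scoring: phantom ground truth or the
    #: observer emulator (biased SUV40 restricted to true components)
    reference: str = "truth"
    observer_bias: float = 1.0
    #: (uptake, reconstruction) conditions on which Jaccard is evaluated
    jaccard_conditions: tuple[tuple[int, str], ...] = ((60, "earl"),)
    #: scans absent from the study, as (patient, day, uptake) triples
    missing_scans: tuple[tuple[int, int, int], ...] = ()
    write_masks: bool = False
    include_lesion_peak: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if set(self.methods) & set(CONSENSUS_METHODS) and not set(STANDARD_METHODS) <= set(self.methods):
            raise ValueError("MV2/MV3 require all four standard methods")
        if self.reference not in ("truth", "observer"):
            raise ValueError("reference must be 'truth' or 'observer'")


@dataclass(frozen=True)
class RunResult:
    output_dir: Path
    measurements: pd.DataFrame
    lesions: pd.DataFrame
    jaccard: pd.DataFrame
    jaccard_summary: pd.DataFrame
    repeatability_summary: pd.DataFrame
    pairs: pd.DataFrame
    manifest: dict


def delineate_image(image, methods, config: DelineationConfig):
    """All requested method masks for one image; MVs from the four standard."""
    candidates = detect_candidates(image, config)
    standard = {m: run_method(image, m, candidates, config) for m in STANDARD_METHODS}
    masks = {m: standard[m] for m in methods if m in STANDARD_METHODS}
    four = [standard[m] for m in STANDARD_METHODS]
    if "MV2" in methods:
        masks["MV2"] = majority_vote(four, 2)
    if "MV3" in methods:
        masks["MV3"] = majority_vote(four, 3)
    return masks, candidates


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_experiment(config: RunConfig) -> RunResult:
    """Run the whole study and write all tables under ``config.output_dir``.

    Per-condition failures are logged and the run continues, mirroring a
    study that retains patients with one unusable scan.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    missing = {tuple(m) for m in config.missing_scans}
    study = generate_study(config.phantom)

    measurements, lesion_rows, jacc_rows, issues = [], [], [], []
    jaccard_on = {(int(u), str(r)) for u, r in config.jaccard_conditions}

    for patient in study.patients:
        for (day, uptake, recon) in ALL_CONDITIONS:
            if (patient.patient, day, uptake) in missing:
                continue
            image = patient.images[(day, uptake, recon)]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    masks, _ = delineate_image(image, config.methods, config.delineation)
            except Exception as exc:  # pragma: no cover - defensive
                log.error("patient %d %s: delineation failed: %s",
                          patient.patient, (day, uptake, recon), exc)
                issues.append(f"patient {patient.patient} {(day, uptake, recon)}: {exc}")
                continue
            if config.reference == "truth":
                reference = patient.truth[day].foreground()
            else:
                reference = emulate_observer(image, patient.truth[day], config.observer_bias)
            for method, mask in masks.items():
                comps = label_components(mask, config.delineation.connectivity)
                records = lesion_metrics(image, comps, config.delineation,
                                         include_peak=config.include_lesion_peak)
                pm = patient_totals(records, patient.patient, day, uptake, recon, method)
                measurements.append(pm)
                for r in records:
                    lesion_rows.append({
                        "patient": patient.patient, "day": day, "uptake": uptake,
                        "reconstruction": recon, "method": method,
                        "lesion_id": r.lesion_id, "matv_ml": r.matv_ml,
                        "suv_mean": r.suv_mean, "suv_max": r.suv_max,
                        "suv_peak": r.suv_peak, "tlg_g": r.tlg_g,
                    })
                if (uptake, recon) in jaccard_on:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        ji = jaccard(mask, reference)
                    jacc_rows.append({
                        "patient": patient.patient, "day": day, "uptake": uptake,
                        "reconstruction": recon, "method": method, "jaccard": ji,
                    })
                if config.write_masks:
                    mask_dir = out / "masks"
                    mask_dir.mkdir(parents=True, exist_ok=True)
                    name = f"p{patient.patient:02d}_d{day}_u{uptake}_{recon}_{method}.nii.gz"
                    write_volume(mask, mask_dir / name)

    meas_df = measurements_frame(measurements)
    lesions_df = pd.DataFrame(lesion_rows, columns=[
        "patient", "day", "uptake", "reconstruction", "method", "lesion_id",
        "matv_ml", "suv_mean", "suv_max", "suv_peak", "tlg_g"])
    jacc_df = pd.DataFrame(jacc_rows, columns=[
        "patient", "day", "uptake", "reconstruction", "method", "jaccard"])

    if len(jacc_df):
        jacc_summary = (
            jacc_df.groupby(["method", "day"])["jaccard"]
            .agg(mean_ji="mean",
                 iqr_low=lambda s: s.quantile(0.25),
                 iqr_high=lambda s: s.quantile(0.75),
                 n="count")
            .reset_index()
        )
    else:
        jacc_summary = pd.DataFrame(
            columns=["method", "day", "mean_ji", "iqr_low", "iqr_high", "n"])

    pairs = build_pairs(meas_df)
    summary = summarize(pairs)

    fmt = "%.10g"
    meas_df.to_csv(out / "measurements.csv", index=False, float_format=fmt)
    lesions_df.to_csv(out / "lesions.csv", index=False, float_format=fmt)
    jacc_df.to_csv(out / "jaccard.csv", index=False, float_format=fmt)
    jacc_summary.to_csv(out / "jaccard_summary.csv", index=False, float_format=fmt)
    summary.to_csv(out / "repeatability_summary.csv", index=False, float_format=fmt)
    export_long_table(pairs, out / "repeatability_long.csv")

    manifest = {
        "petseg_version": __version__,
        "seed": config.phantom.seed,
        "config_hash": _config_hash(config),
        "n_patients": config.phantom.n_patients,
        "n_measurement_rows": len(meas_df),
        "n_jaccard_rows": len(jacc_df),
        "issues": issues,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunResult(out, meas_df, lesions_df, jacc_df, jacc_summary, summary,
                     pairs, manifest)


def _dataclass_from_mapping(cls, mapping):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
    }
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file with `phantom`/`delineation` blocks."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    phantom = _dataclass_from_mapping(PhantomSpec, raw.pop("phantom", {}) or {})
    delin = _dataclass_from_mapping(DelineationConfig, raw.pop("delineation", {}) or {})
    if "methods" in raw and raw["methods"] is not None:
        raw["methods"] = tuple(raw["methods"])
    if "jaccard_conditions" in raw:
        raw["jaccard_conditions"] = tuple(
            (int(u), str(r)) for u, r in raw["jaccard_conditions"])
    if "missing_scans" in raw:
        raw["missing_scans"] = tuple(tuple(int(x) for x in m) for m in raw["missing_scans"])
    return _dataclass_from_mapping(RunConfig, {"phantom": phantom, "delineation": delin, **raw})
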