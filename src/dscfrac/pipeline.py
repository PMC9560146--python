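"""End-to-end orchestration: phantom/NIfTI inputs → CBV → metrics → cohort report.

Runs are deterministic: every random procedure (bootstrap CIs, phantom
noise) consumes only the seeds recorded in the report, and CSV/JSON
outputs serialize floats at fixed precision so identical configurations
are bytewise identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acquisition import AcquisitionParams
from .cbv import DscSeries, compute_cbv_maps
from .metrics import (
    THRESHOLDS,
    PatientPerfusionRecord,
    compute_patient_record,
    records_to_frame,
    transfer_mask,
)
from . import stats as cs

log = logging.getLogger("dscfrac")

__all__ = ["ConfigError", "DataError", "RunConfig", "CaseManifest",
           "run_case", "run_cohort", "write_report"]

_FLOAT_PRECISION = 6


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (exit code 2)."""


class DataError(RuntimeError):
    """Missing or malformed input data (exit code 3)."""


@dataclass
class RunConfig:
    output_dir: Path | None = None
    thresholds: tuple[float, ...] = THRESHOLDS
    exclude_necrosis: bool = False
    bootstrap_b: int = 2000
    seed: int = 0
    cutoff_convention: str = "midpoint"
    log_level: str = "INFO"
    acquisition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        th = tuple(float(x) for x in self.thresholds)
        if any(x <= 0 for x in th) or list(th) != sorted(th):
            raise ConfigError("thresholds must be positive and ascending")
        self.thresholds = th
        if self.cutoff_convention != "midpoint":
            raise ConfigError(
                f"unknown cutoff convention {self.cutoff_convention!r}"
            )
        if self.output_dir is not None:
            self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls(**payload)

    def make_acquisition(self) -> AcquisitionParams:
        return AcquisitionParams(**self.acquisition)


@dataclass
class CaseManifest:
    """File paths for one case (all NIfTI on a shared or transferable grid)."""

    patient_id: str
    series: Path
    brain: Path
    lesion: Path
    wm_rois: tuple[Path, Path, Path]
    necrosis: Path | None = None
    timepoint: str = "CRT1"
    group: str | None = None
    truth: Path | None = None

    def validate(self, require_necrosis: bool = False) -> None:
        paths = [self.series, self.brain, self.lesion, *self.wm_rois]
        if require_necrosis:
            if self.necrosis is None:
                raise ConfigError(
                    f"{self.patient_id}: exclude_necrosis requested but no "
                    "necrosis mask is listed"
                )
        if self.necrosis is not None:
            paths.append(self.necrosis)
        for p in paths:
            if not Path(p).exists():
                raise DataError(f"{self.patient_id}: missing input file {p}")


def _load_nifti(path: Path):
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def _load_mask(path: Path, target_affine, target_shape) -> np.ndarray:
    data, affine = _load_nifti(path)
    mask = data > 0
    if data.shape == tuple(target_shape) and np.allclose(affine, target_affine):
        return mask
    return transfer_mask(mask, affine, target_affine, target_shape)


def run_case(manifest: CaseManifest, config: RunConfig) -> PatientPerfusionRecord:
    """Per-case pipeline: load → CBV (leakage-corrected) → metrics record."""
    manifest.validate(require_necrosis=config.exclude_necrosis)
    try:
        data, affine = _load_nifti(manifest.series)
        acq = config.make_acquisition()
        series = DscSeries(data=data.astype(float), acq=acq, affine=affine)
        shape = series.shape3d
        brain = _load_mask(manifest.brain, affine, shape)
        lesion = _load_mask(manifest.lesion, affine, shape)
        necrosis = (
            _load_mask(manifest.necrosis, affine, shape)
            if manifest.necrosis is not None
            else None
        )
        wm_rois = [_load_mask(p, affine, shape) for p in manifest.wm_rois]
        _unc, corrected, _k2 = compute_cbv_maps(series, brain, lesion)
        record = compute_patient_record(
            corrected.data,
            lesion,
            necrosis,
            wm_rois,
            affine,
            patient_id=manifest.patient_id,
            timepoint=manifest.timepoint,
            thresholds=config.thresholds,
            group=manifest.group,
        )
    except (ConfigError, DataError):
        raise
    except Exception as exc:
        log.error("case %s failed: %s", manifest.patient_id, exc)
        raise DataError(f"case {manifest.patient_id}: {exc}") from exc
    return record


def _round(obj):
    if isinstance(obj, float):
        return round(obj, _FLOAT_PRECISION)
    if isinstance(obj, dict):
        return {k: _round(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), _FLOAT_PRECISION)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_cohort(
    records: list[PatientPerfusionRecord],
    config: RunConfig | None = None,
    groups: dict[str, str] | None = None,
) -> dict:
    """Cohort statistics over per-case records.

    ``groups`` maps patient_id to "PsP"/"TP" when the records carry no
    label. Single-group cohorts yield descriptive output only.
    """
    if config is None:
        config = RunConfig()
    records = sorted(records, key=lambda r: r.patient_id)
    labels = []
    for r in records:
        g = r.group if r.group is not None else (groups or {}).get(r.patient_id)
        labels.append(g)
    if any(g is None for g in labels):
        raise ConfigError("every record needs a group label (PsP or TP)")
    labels = np.array(labels)
    report: dict = {
        "n_cases": len(records),
        "groups": {g: int((labels == g).sum()) for g in np.unique(labels)},
        "seed": config.seed,
        "bootstrap_b": config.bootstrap_b,
        "thresholds": list(config.thresholds),
    }

    key = 2.0
    field_getters = {
        "rcbvmax_hotspot": lambda r: r.rcbvmax_hotspot,
        "rcbvmax_volume": lambda r: r.rcbvmax_volume,
        "pct_rcbv_gt2": lambda r: r.pct_above[key],
        "pct_rcbv_gt2_necrosis_excluded":
            lambda r: r.pct_above_necrosis_excluded[key],
    }
    desc: dict = {}
    for name, get in field_getters.items():
        try:
            vals = np.array([get(r) for r in records], dtype=float)
        except KeyError:
            continue
        if not np.all(np.isfinite(vals)):
            continue
        block = {}
        for g in np.unique(labels):
            gv = vals[labels == g]
            if gv.size >= 3:
                med, q1, q3 = cs.median_iqr(gv)
                block[g] = {"median": med, "q1": q1, "q3": q3, "n": int(gv.size)}
        desc[name] = block
    report["descriptives"] = desc

    two_groups = {"PsP", "TP"} <= set(np.unique(labels)) and all(
        (labels == g).sum() >= 2 for g in ("PsP", "TP")
    )
    if not two_groups:
        report["warning"] = (
            "fewer than 2 cases per group: descriptive output only"
        )
        log.warning(report["warning"])
        return _round(report)

    psp_sel, tp_sel = labels == "PsP", labels == "TP"
    comparisons = {}
    for name, get in field_getters.items():
        try:
            vals = np.array([get(r) for r in records], dtype=float)
        except KeyError:
            continue
        if not np.all(np.isfinite(vals)):
            continue
        u, p = cs.mann_whitney(vals[psp_sel], vals[tp_sel])
        comparisons[name] = {"U": u, "p": p}
    report["mann_whitney"] = comparisons

    # discrimination of pseudoprogression by %rCBV>2 (lower is positive)
    roc_block = {}
    for name in ("pct_rcbv_gt2", "pct_rcbv_gt2_necrosis_excluded"):
        try:
            scores = np.array([field_getters[name](r) for r in records])
        except KeyError:
            continue
        roc = cs.roc_analysis(
            scores, np.where(psp_sel, "PsP", "TP"), pos_label="PsP",
            lower_is_positive=True, n_boot=config.bootstrap_b,
            ci_seed=config.seed,
        )
        cut = cs.youden_cutoff(
            scores, np.where(psp_sel, "PsP", "TP"), pos_label="PsP",
            lower_is_positive=True,
        )
        roc_block[name] = {
            "auc": roc.auc,
            "auc_ci": [roc.ci_low, roc.ci_high],
            "cutoff": cut.cutoff,
            "sensitivity": cut.sensitivity,
            "sensitivity_pct": round(cut.sensitivity * 100),
            "specificity": cut.specificity,
            "specificity_pct": round(cut.specificity * 100),
            "youden_j": cut.youden_j,
        }
    report["roc"] = roc_block

    try:
        pct_maps = [r.pct_above for r in records]
        sweep = cs.threshold_sweep(
            pct_maps, labels, pos_label="PsP", lower_is_positive=True,
            n_boot=config.bootstrap_b, ci_seed=config.seed,
        )
        report["threshold_sweep"] = sweep.round(_FLOAT_PRECISION).to_dict(
            orient="records"
        )
    except KeyError:
        pass

    return _round(report)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
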