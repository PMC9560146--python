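"""Lesion perfusion metrics: hot-spot and volume rCBVmax, %rCBV>x.

Two normalizations of the same CBV map are implemented. The hot-spot
method places small circular ROIs (fixed 50 mm², the midpoint of the
conventional 40-60 mm² range) inside the enhancing lesion and takes the
best disc-mean; instead of an operator's visual search, every admissible
disc centre is tried exhaustively, which makes the estimate deterministic
and an upper envelope of what a reader could find. The volume method uses
the voxelwise maximum of the whole segmented lesion. Both are divided by
the mean CBV of three contralateral white-matter reference ROIs.

The fractional statistic %rCBV>x is the percentage of lesion voxels whose
normalized CBV strictly exceeds x; the central necrotic core is included
by default and can be excluded via ``exclude_necrosis``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "THRESHOLDS",
    "CircularRoi",
    "WmReferenceSet",
    "PatientPerfusionRecord",
    "DegenerateLesionError",
    "disc_footprint",
    "wm_reference",
    "hotspot_rcbvmax",
    "volume_rcbvmax",
    "fraction_above",
    "exclude_necrosis",
    "transfer_mask",
    "compute_patient_record",
    "records_to_frame",
    "records_to_csv",
    "records_from_csv",
]

#: the seven tested normalized-CBV thresholds
THRESHOLDS: tuple[float, ...] = (1.5, 1.75, 2.0, 2.25, 2.5, 2.75, 3.0)


class DegenerateLesionError(RuntimeError):
    """Lesion cannot host a single admissible hot-spot disc."""


@dataclass(frozen=True)
class CircularRoi:
    """One in-plane circular hot-spot ROI.

    ``center`` is the (i, j, k) voxel index of the disc centre; ``area``
    is the nominal geometric disc area in mm²; membership is by
    pixel-centre-in-disc.
    """

    center: tuple[int, int, int]
    radius_mm: float
    area_mm2: float
    mean_cbv: float

    def __post_init__(self) -> None:
        if not 40.0 <= self.area_mm2 <= 60.0:
            raise ValueError(f"ROI area must be in [40, 60] mm², got {self.area_mm2}")


@dataclass(frozen=True)
class WmReferenceSet:
    """Three white-matter ROI means and their combined reference value."""

    roi_means: tuple[float, float, float]
    reference: float


@dataclass
class PatientPerfusionRecord:
    """Per-patient, per-timepoint perfusion metrics."""

    patient_id: str
    timepoint: str
    rcbvmax_hotspot: float
    rcbvmax_volume: float
    pct_above: dict[float, float]
    pct_above_necrosis_excluded: dict[float, float]
    group: str | None = None

    def __post_init__(self) -> None:
        for d in (self.pct_above, self.pct_above_necrosis_excluded):
            vals = [d[x] for x in sorted(d)]
            if any(not 0.0 <= v <= 100.0 for v in vals):
                raise ValueError("percentages must lie in [0, 100]")
            if any(a < b - 1e-9 for a, b in zip(vals, vals[1:])):
                raise ValueError("%rCBV>x must be non-increasing in x")
        if self.rcbvmax_hotspot > self.rcbvmax_volume + 1e-9:
            raise ValueError(
                "hot-spot rCBVmax cannot exceed volume rCBVmax on the same map"
            )


def disc_footprint(voxel_size_xy: tuple[float, float], area_mm2: float = 50.0) -> np.ndarray:
    """Boolean in-plane footprint of a disc of the given area.

    A pixel belongs to the disc when its centre lies within
    radius = sqrt(area/pi) of the central pixel.
    """
    dx, dy = voxel_size_xy
    r = float(np.sqrt(area_mm2 / np.pi))
    ni = int(np.floor(r / dx))
    nj = int(np.floor(r / dy))
    ii, jj = np.mgrid[-ni : ni + 1, -nj : nj + 1]
    return (ii * dx) ** 2 + (jj * dy) ** 2 <= r**2


def wm_reference(cbv_data: np.ndarray, wm_rois: list[np.ndarray]) -> WmReferenceSet:
    """Mean of the three per-ROI mean CBVs; must be positive."""
    if len(wm_rois) != 3:
        raise ValueError(f"exactly three reference ROIs required, got {len(wm_rois)}")
    means = []
    for k, roi in enumerate(wm_rois, start=1):
        roi = np.asarray(roi, dtype=bool)
        vals = np.asarray(cbv_data)[roi]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"reference ROI {k} is empty (or all-invalid)")
        means.append(float(vals.mean()))
    ref = float(np.mean(means))
    if ref <= 0:
        raise ValueError(f"white-matter reference must be positive, got {ref}")
    return WmReferenceSet(roi_means=tuple(means), reference=ref)


def _voxel_size_xy(affine: np.ndarray) -> tuple[float, float]:
    a = np.asarray(affine, dtype=float)
    return (float(np.linalg.norm(a[:3, 0])), float(np.linalg.norm(a[:3, 1])))


def hotspot_rcbvmax(
    cbv_data: np.ndarray,
    lesion_mask: np.ndarray,
    wm_reference_value: float,
    affine: np.ndarray | None = None,
    voxel_size_xy: tuple[float, float] | None = None,
    n_rois: int = 4,
    area_mm2: float = 50.0,
) -> tuple[float, list[CircularRoi]]:
    """Exhaustive hot-spot search: best disc-mean CBV over the lesion.

    Candidate centres are every lesion voxel whose disc lies fully inside
    the lesion on its slice; up to ``n_rois`` non-overlapping discs are
    kept (ranked by mean) and the best disc mean divided by the reference
    is returned.
    """
    if wm_reference_value <= 0:
        raise ValueError("white-matter reference must be positive")
    if voxel_size_xy is None:
        if affine is None:
            raise ValueError("provide either affine or voxel_size_xy")
        voxel_size_xy = _voxel_size_xy(affine)
    cbv = np.asarray(cbv_data, dtype=float)
    mask = np.asarray(lesion_mask, dtype=bool)
    foot = disc_footprint(voxel_size_xy, area_mm2)
    npix = int(foot.sum())
    radius = float(np.sqrt(area_mm2 / np.pi))

    candidates: list[tuple[float, int, int, int]] = []
    finite = np.isfinite(cbv)
    for z in range(mask.shape[2]):
        m2 = mask[:, :, z] & finite[:, :, z]
        if not m2.any():
            continue
        admissible = ndimage.binary_erosion(m2, structure=foot)
        if not admissible.any():
            continue
        sums = ndimage.correlate(
            np.where(m2, cbv[:, :, z], 0.0), foot.astype(float), mode="constant"
        )
        means = sums / npix
        for i, j in zip(*np.nonzero(admissible)):
            candidates.append((float(means[i, j]), int(i), int(j), z))
    if not candidates:
        raise DegenerateLesionError(
            f"no lesion slice can host a {area_mm2:.0f} mm² disc"
        )
    candidates.sort(key=lambda c: (-c[0], c[3], c[1], c[2]))

    fi, fj = np.nonzero(foot)
    fi = fi - foot.shape[0] // 2
    fj = fj - foot.shape[1] // 2
    used: set[tuple[int, int, int]] = set()
    chosen: list[CircularRoi] = []
    for mean, i, j, z in candidates:
        pix = {(int(i + a), int(j + b), z) for a, b in zip(fi, fj)}
        if pix & used:
            continue
        used |= pix
        chosen.append(
            CircularRoi(center=(i, j, z), radius_mm=radius, area_mm2=area_mm2,
                        mean_cbv=mean)
        )
        if len(chosen) == n_rois:
            break
    best = max(roi.mean_cbv for roi in chosen)
    return best / wm_reference_value, chosen


def volume_rcbvmax(
    cbv_data: np.ndarray, lesion_mask: np.ndarray, wm_reference_value: float
) -> float:
    """Maximum voxel CBV over the segmented volume, normalized."""
    if wm_reference_value <= 0:
        raise ValueError("white-matter reference must be positive")
    vals = np.asarray(cbv_data, dtype=float)[np.asarray(lesion_mask, dtype=bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("lesion mask is empty (or all-invalid)")
    return float(vals.max()) / wm_reference_value


def fraction_above(
    cbv_data: np.ndarray,
    lesion_mask: np.ndarray,
    wm_reference_value: float,
    x: float,
) -> float:
    """%rCBV>x: percent of lesion voxels with CBV/reference strictly > x."""
    if x <= 0:
        raise ValueError("threshold x must be positive")
    if wm_reference_value <= 0:
        raise ValueError("white-matter reference must be positive")
    vals = np.asarray(cbv_data, dtype=float)[np.asarray(lesion_mask, dtype=bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("lesion mask is empty (or all-invalid)")
    return 100.0 * float((vals / wm_reference_value > x).sum()) / vals.size


def exclude_necrosis(
    lesion_mask: np.ndarray, necrosis_mask: np.ndarray
) -> np.ndarray:
    """Remove the necrotic core from the segmented volume (set difference)."""
    lesion = np.asarray(lesion_mask, dtype=bool)
    necrosis = np.asarray(necrosis_mask, dtype=bool)
    outside = int((necrosis & ~lesion).sum())
    if outside:
        warnings.warn(
            f"{outside} necrosis voxels lie outside the lesion; using the "
            "intersection",
            stacklevel=2,
        )
    reduced = lesion & ~necrosis
    if not reduced.any():
        raise ValueError("necrosis covers the entire lesion; record unusable")
    return reduced


def transfer_mask(
    mask: np.ndarray,
    source_affine: np.ndarray,
    target_affine: np.ndarray,
    target_shape: tuple[int, int, int],
) -> np.ndarray:
    """Nearest-neighbour resampling of a binary mask onto a target grid."""
    src = np.asarray(source_affine, dtype=float)
    tgt = np.asarray(target_affine, dtype=float)
    for name, a in (("source", src), ("target", tgt)):
        if abs(np.linalg.det(a)) < 1e-12:
            raise ValueError(f"{name} affine is not invertible")
    # composition target voxel -> world -> source voxel
    m = np.linalg.inv(src) @ tgt
    out = ndimage.affine_transform(
        np.asarray(mask, dtype=float),
        m[:3, :3],
        offset=m[:3, 3],
        output_shape=tuple(target_shape),
        order=0,
        mode="constant",
        cval=0.0,
    )
    return out > 0.5


def compute_patient_record(
    cbv_data: np.ndarray,
    lesion_mask: np.ndarray,
    necrosis_mask: np.ndarray | None,
    wm_rois: list[np.ndarray],
    affine: np.ndarray,
    patient_id: str,
    timepoint: str = "CRT1",
    thresholds: tuple[float, ...] = THRESHOLDS,
    group: str | None = None,
) -> PatientPerfusionRecord:
    """All per-patient metrics from one CBV map and its masks.

    Hot-spot candidates are restricted to the enhancing lesion (necrosis
    removed) since hot-spots are read off enhancing tissue; the volume
    method and %rCBV>x use the full segmented volume by default, with
    necrosis-excluded variants computed alongside.
    """
    lesion = np.asarray(lesion_mask, dtype=bool)
    if necrosis_mask is not None and np.asarray(necrosis_mask).any():
        enhancing = exclude_necrosis(lesion, necrosis_mask)
    else:
        enhancing = lesion
    ref = wm_reference(cbv_data, wm_rois)
    hotspot, _rois = hotspot_rcbvmax(
        cbv_data, enhancing, ref.reference, affine=affine
    )
    volume = volume_rcbvmax(cbv_data, lesion, ref.reference)
    pct = {
        float(x): fraction_above(cbv_data, lesion, ref.reference, x)
        for x in thresholds
    }
    pct_ne = {
        float(x): fraction_above(cbv_data, enhancing, ref.reference, x)
        for x in thresholds
    }
    return PatientPerfusionRecord(
        patient_id=patient_id,
        timepoint=timepoint,
        rcbvmax_hotspot=hotspot,
        rcbvmax_volume=volume,
        pct_above=pct,
        pct_above_necrosis_excluded=pct_ne,
        group=group,
    )


def records_to_frame(records: list[PatientPerfusionRecord]) -> pd.DataFrame:
    """Long-format table: patient_id, timepoint, group, method, metric, threshold, value."""
    rows = []
    for r in records:
        base = {"patient_id": r.patient_id, "timepoint": r.timepoint, "group": r.group}
        rows.append({**base, "method": "hotspot", "metric": "rcbvmax",
                     "threshold": np.nan, "value": r.rcbvmax_hotspot})
        rows.append({**base, "method": "volume", "metric": "rcbvmax",
                     "threshold": np.nan, "value": r.rcbvmax_volume})
        for x, v in sorted(r.pct_above.items()):
            rows.append({**base, "method": "volume", "metric": "pct_above",
                         "threshold": x, "value": v})
        for x, v in sorted(r.pct_above_necrosis_excluded.items()):
            rows.append({**base, "method": "volume",
                         "metric": "pct_above_necrosis_excluded",
                         "threshold": x, "value": v})
    return pd.DataFrame(rows)


def records_to_csv(records: list[PatientPerfusionRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def records_from_csv(path) -> list[PatientPerfusionRecord]:
    """Inverse of :func:`records_to_csv` (lossless round trip)."""
    df = pd.read_csv(path)
    out = []
    for (pid, tp), g in df.groupby(["patient_id", "timepoint"], sort=False):
        group = g["group"].dropna()
        grp = None if group.empty else str(group.iloc[0])
        hs = g.query("metric == 'rcbvmax' and method == 'hotspot'")["value"].iloc[0]
        vol = g.query("metric == 'rcbvmax' and method == 'volume'")["value"].iloc[0]
        pct = {
            float(row.threshold): float(row.value)
            for row in g.query("metric == 'pct_above'").itertuples()
        }
        pct_ne = {
            float(row.threshold): float(row.value)
            for row in g.query("metric == 'pct_above_necrosis_excluded'").itertuples()
        }
        out.append(
            PatientPerfusionRecord(
                patient_id=str(pid), timepoint=str(tp),
                rcbvmax_hotspot=float(hs), rcbvmax_volume=float(vol),
                pct_above=pct, pct_above_necrosis_excluded=pct_ne, group=grp,
            )
        )
    return out
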