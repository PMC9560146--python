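"""Signal → ΔR2* → cerebral blood volume, with unidirectional leakage correction.

The DSC signal drop during bolus passage is converted voxelwise to the
change in transverse relaxation rate, ΔR2*(t) = -ln(S(t)/S0)/TE, and CBV
(arbitrary units) is the trapezoidal time-integral of ΔR2*. In enhancing
tumour, contrast extravasation adds a T1-dominant term that biases the
integral low; the unidirectional (Boxerman-type) linear model

    ΔR2*_voxel(t) ≈ K1 · ΔR̄2*(t) - K2 · ∫0^t ΔR̄2*(τ) dτ

is fit per voxel against the whole-brain reference curve ΔR̄2* by ordinary
least squares over the post-baseline frames (closed-form 2x2 normal
equations), and the corrected curve adds back K2 times the running
reference integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .acquisition import AcquisitionParams

__all__ = [
    "DscSeries",
    "DeltaR2Series",
    "LeakageFit",
    "CbvMap",
    "BolusNotFoundError",
    "SingularDesignError",
    "estimate_baseline_window",
    "compute_delta_r2star",
    "whole_brain_reference_curve",
    "fit_unidirectional_leakage",
    "leakage_corrected_curve",
    "integrate_cbv",
    "compute_cbv_maps",
]


class BolusNotFoundError(RuntimeError):
    """The series never shows a detectable bolus signal drop."""


class SingularDesignError(RuntimeError):
    """Reference curve and its running integral are collinear (or zero)."""


@dataclass
class DscSeries:
    """A 4D DSC signal series (x, y, z, t) with acquisition metadata."""

    data: np.ndarray
    acq: AcquisitionParams
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"series must be 4D, got shape {self.data.shape}")
        if self.data.shape[-1] != self.acq.n_timepoints:
            raise ValueError(
                f"series has {self.data.shape[-1]} frames but acquisition "
                f"declares {self.acq.n_timepoints}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class DeltaR2Series:
    """Voxelwise ΔR2*(t) in 1/s, with the baseline map it was derived from."""

    data: np.ndarray
    s0_map: np.ndarray
    baseline_window: slice
    valid_mask: np.ndarray
    acq: AcquisitionParams


@dataclass(frozen=True)
class LeakageFit:
    """Two-parameter unidirectional leakage fit for one voxel curve.

    k1 scales the reference bolus (the intravascular component); k2 is
    the leakage rate constant (1/s). A negative k1 is physically
    meaningless and is reported as-is for flagging, never clamped.
    """

    k1: float
    k2: float
    residual_rms: float

    @property
    def physical(self) -> bool:
        return self.k1 >= 0


@dataclass
class CbvMap:
    """3D CBV map (arbitrary units)."""

    data: np.ndarray
    corrected: bool
    affine: np.ndarray
    integration_window: slice
    k2_map: np.ndarray | None = None


def estimate_baseline_window(series: DscSeries, brain_mask: np.ndarray) -> slice:
    """Locate the pre-bolus baseline frames from the brain-mean signal.

    With the first 8 frames as a provisional baseline, bolus arrival is
    the first frame whose brain-mean signal falls below (mean - 5*SD);
    the returned window stops 3 frames before arrival as a safety margin.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    curve = series.data[brain_mask].mean(axis=0)
    prov = curve[:8]
    thresh = prov.mean() - 5.0 * prov.std()
    below = np.nonzero(curve < thresh)[0]
    if below.size == 0:
        raise BolusNotFoundError(
            "no bolus detected: brain-mean signal never drops below "
            f"baseline mean - 5 SD ({thresh:.3g})"
        )
    t_arrival = int(below[0])
    stop = t_arrival - 3
    if stop < 4:
        raise BolusNotFoundError(
            f"bolus arrives at frame {t_arrival}; fewer than 4 usable "
            "baseline frames remain"
        )
    return slice(0, stop)


def compute_delta_r2star(
    series: DscSeries,
    baseline_window: slice,
    mask: np.ndarray | None = None,
) -> DeltaR2Series:
    """Convert signal to ΔR2*(t) = -ln(S/S0)/TE voxelwise.

    Voxels with non-positive signal anywhere in the time course (or
    non-positive S0) are flagged invalid and carry NaN curves; signal
    rises above baseline (T1 leakage) yield negative ΔR2*, preserved.
    """
    s = series.data
    s0 = s[..., baseline_window].mean(axis=-1)
    valid = (s0 > 0) & (s > 0).all(axis=-1)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    dr2 = np.full_like(s, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        dr2[valid] = -np.log(s[valid] / s0[valid, None]) / series.acq.te
    return DeltaR2Series(
        data=dr2,
        s0_map=s0,
        baseline_window=baseline_window,
        valid_mask=valid,
        acq=series.acq,
    )


def whole_brain_reference_curve(
    dr2: DeltaR2Series, brain_mask: np.ndarray, lesion_mask: np.ndarray
) -> np.ndarray:
    """Mean ΔR2* over valid, non-enhancing brain voxels, per frame."""
    ref_set = (
        np.asarray(brain_mask, dtype=bool)
        & ~np.asarray(lesion_mask, dtype=bool)
        & dr2.valid_mask
    )
    if not ref_set.any():
        raise ValueError("reference set (brain minus lesion) is empty")
    return dr2.data[ref_set].mean(axis=0)


def _leakage_design(
    reference_curve: np.ndarray, baseline_window: slice, tr: float
) -> tuple[np.ndarray, np.ndarray, slice]:
    ref = np.asarray(reference_curve, dtype=float)
    cum_ref = cumulative_trapezoid(ref, dx=tr, initial=0.0)
    post = slice(baseline_window.stop, len(ref))
    X = np.column_stack([ref[post], -cum_ref[post]])
    g = X.T @ X
    # relative determinant guards both the zero-reference and the
    # collinear case
    norm = np.outer(np.sqrt(np.diag(g)), np.sqrt(np.diag(g)))
    if not np.all(np.diag(g) > 0) or np.linalg.det(g / norm) < 1e-12:
        raise SingularDesignError(
            "reference curve and its running integral are collinear or zero; "
            "the 2x2 leakage design is singular"
        )
    return X, cum_ref, post


def fit_unidirectional_leakage(
    voxel_curve: np.ndarray,
    reference_curve: np.ndarray,
    baseline_window: slice,
    tr: float = 1.0,
) -> LeakageFit:
    """OLS fit of (K1, K2) in the unidirectional leakage model."""
    X, _, post = _leakage_design(reference_curve, baseline_window, tr)
    y = np.asarray(voxel_curve, dtype=float)[post]
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    return LeakageFit(
        k1=float(beta[0]),
        k2=float(beta[1]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def leakage_corrected_curve(
    voxel_curve: np.ndarray,
    reference_curve: np.ndarray,
    k2: float,
    tr: float = 1.0,
) -> np.ndarray:
    """Add back the leakage term: corrected = measured + K2 * ∫ reference."""
    cum_ref = cumulative_trapezoid(
        np.asarray(reference_curve, dtype=float), dx=tr, initial=0.0
    )
    return np.asarray(voxel_curve, dtype=float) + k2 * cum_ref


def _fit_leakage_stack(
    curves: np.ndarray,
    reference_curve: np.ndarray,
    baseline_window: slice,
    tr: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (K1, K2) OLS over an (n_voxels, T) stack of curves."""
    X, _, post = _leakage_design(reference_curve, baseline_window, tr)
    beta = np.linalg.solve(X.T @ X, X.T @ curves[:, post].T)
    return beta[0], beta[1]


def integrate_cbv(
    curve: np.ndarray, integration_window: slice, tr: float
) -> float | np.ndarray:
    """Trapezoidal ΔR2* integral over the window (last axis for stacks)."""
    curve = np.asarray(curve, dtype=float)
    seg = curve[..., integration_window]
    if seg.shape[-1] < 2:
        raise ValueError("integration window must span at least 2 frames")
    out = np.trapezoid(seg, dx=tr, axis=-1)
    return float(out) if out.ndim == 0 else out


def compute_cbv_maps(
    series: DscSeries,
    brain_mask: np.ndarray,
    lesion_mask: np.ndarray,
    correct_leakage: bool = True,
    baseline_window: slice | None = None,
    integration_window: slice | None = None,
) -> tuple[CbvMap, CbvMap | None, np.ndarray | None]:
    """Full voxelwise pipeline: baseline → ΔR2* → leakage fit → integral.

    Returns (uncorrected map, corrected map, K2 map); the latter two are
    None when ``correct_leakage`` is False. The integration window
    defaults to bolus arrival through the last frame (recirculation is
    not truncated). Invalid voxels (non-positive signal) carry NaN.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    if baseline_window is None:
        baseline_window = estimate_baseline_window(series, brain_mask)
    dr2 = compute_delta_r2star(series, baseline_window, mask=brain_mask)
    t_arrival = baseline_window.stop + 3
    if integration_window is None:
        integration_window = slice(t_arrival, series.acq.n_timepoints)
    tr = series.acq.tr

    valid = dr2.valid_mask & brain_mask
    curves = dr2.data[valid]

    unc = np.full(series.shape3d, np.nan)
    unc[valid] = integrate_cbv(curves, integration_window, tr)
    uncorrected = CbvMap(
        data=unc,
        corrected=False,
        affine=series.affine,
        integration_window=integration_window,
    )
    if not correct_leakage:
        return uncorrected, None, None

    ref = whole_brain_reference_curve(dr2, brain_mask, lesion_mask)
    k1s, k2s = _fit_leakage_stack(curves, ref, baseline_window, tr)
    cum_ref = cumulative_trapezoid(ref, dx=tr, initial=0.0)
    corrected_curves = curves + k2s[:, None] * cum_ref
    cor = np.full(series.shape3d, np.nan)
    cor[valid] = integrate_cbv(corrected_curves, integration_window, tr)
    k2_map = np.full(series.shape3d, np.nan)
    k2_map[valid] = k2s
    corrected = CbvMap(
        data=cor,
        corrected=True,
        affine=series.affine,
        integration_window=integration_window,
        k2_map=k2_map,
    )
    return uncorrected, corrected, k2_map
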