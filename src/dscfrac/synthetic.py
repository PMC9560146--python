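"""Digital DSC perfusion phantoms and packaged cohort fixtures.

Phantoms carry complete ground truth (per-voxel normalized CBV, leakage
rate, all masks) so that every downstream quantity — ΔR2* conversion,
leakage correction, rCBVmax, %rCBV>x — can be checked against construction.

A phantom is an ellipsoidal "brain" of reference tissue (normalized CBV 1)
containing a spherical enhancing lesion whose voxels split into a
hypervascular fraction ``f`` (normalized CBV > 2) and a low-perfusion
remainder (< 2), optionally around a near-avascular necrotic core.
Enhancing voxels leak contrast unidirectionally: their ΔR2* curve is the
bolus response minus ``k2`` times the running integral of the reference
bolus, the T1-dominant extravasation signature that leakage correction
must remove.

The canonical cohort fixtures are packaged per-patient %rCBV>2 values
(11 pseudoprogression, 14 true progression) whose medians, quartiles and
pairwise concordance structure reproduce the published group summaries;
every constraint is re-verified by brute force in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.stats import truncnorm

from .acquisition import AcquisitionParams
from .cbv import DscSeries

__all__ = [
    "PSP_LIKE",
    "TP_LIKE",
    "PhantomSpec",
    "PhantomTruth",
    "CanonicalFixture",
    "gamma_variate_curve",
    "signal_from_delta_r2star",
    "build_phantom",
    "generate_phantom_cohort",
    "generate_canonical_fixture",
    "write_phantom",
]

PSP_LIKE = "PSP_LIKE"
TP_LIKE = "TP_LIKE"

#: default first-pass bolus model (arrival 10 frames after start, in s)
DEFAULT_BOLUS = {"t0_frames": 10.0, "amplitude": 2.2, "alpha": 3.0, "beta": 1.5}

#: baseline signal level in arbitrary scanner units
BASELINE_SIGNAL = 100.0


def gamma_variate_curve(
    t: np.ndarray, t0: float, amplitude: float, alpha: float, beta: float
) -> np.ndarray:
    """First-pass bolus concentration model.

    c(t) = amplitude * (t - t0)**alpha * exp(-(t - t0)/beta) for t > t0,
    0 before arrival. Peak at t0 + alpha*beta; total integral
    amplitude * beta**(alpha+1) * Gamma(alpha+1).
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("time grid must be non-empty and strictly increasing")
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    x = t - t0
    out = np.zeros_like(t)
    pos = x > 0
    out[pos] = amplitude * x[pos] ** alpha * np.exp(-x[pos] / beta)
    return out


def signal_from_delta_r2star(
    delta_r2star: np.ndarray, s0: float | np.ndarray, te: float
) -> np.ndarray:
    """Gradient-echo DSC signal for a given ΔR2* time course.

    S(t) = S0 * exp(-TE * ΔR2*(t)); exact inverse of the ΔR2* conversion
    in the noise-free case.
    """
    if te <= 0:
        raise ValueError("te must be positive")
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 <= 0):
        raise ValueError("baseline signal s0 must be positive")
    return s0 * np.exp(-te * np.asarray(delta_r2star, dtype=float))


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth parameters of a simulated case.

    ``lesion_fraction_hyper`` is the fraction of *all* lesion voxels
    (necrotic core included, matching the primary necrosis-included
    analysis) whose true normalized CBV exceeds 2. ``noise_sigma`` is the
    Gaussian signal SD relative to baseline (0.02 = baseline SNR 50).
    """

    phenotype: str = TP_LIKE
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    lesion_fraction_hyper: float = 0.5
    necrosis_fraction: float = 0.15
    rcbv_hyper_range: tuple[float, float] = (2.25, 4.5)
    rcbv_low_range: tuple[float, float] = (0.25, 1.75)
    k2_leakage: float = 0.02
    noise_sigma: float = 0.02
    lesion_radius_mm: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phenotype not in (PSP_LIKE, TP_LIKE):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if not 0.0 <= self.lesion_fraction_hyper <= 1.0:
            raise ValueError("lesion_fraction_hyper must be in [0, 1]")
        if not 0.0 <= self.necrosis_fraction < 1.0:
            raise ValueError("necrosis_fraction must be in [0, 1)")
        if self.rcbv_hyper_range[0] <= 2.0:
            raise ValueError("rcbv_hyper_range must lie strictly above 2")
        if self.rcbv_low_range[1] >= 2.0:
            raise ValueError("rcbv_low_range must lie strictly below 2")
        for lo, hi in (self.rcbv_hyper_range, self.rcbv_low_range):
            if not 0 <= lo <= hi:
                raise ValueError("rCBV ranges must satisfy 0 <= lo <= hi")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class PhantomTruth:
    """Everything known by construction about a phantom."""

    f_true: float
    true_cbv_map: np.ndarray  # per-voxel true normalized CBV ratio
    k2_map: np.ndarray  # per-voxel true leakage rate (1/s)
    masks: dict[str, np.ndarray]  # lesion, necrosis, wm_roi_1..3, brain
    hotspot_feasible: bool
    spec: PhantomSpec
    reference_curve: np.ndarray  # noise-free bolus ΔR2* of reference tissue

    @property
    def wm_roi_masks(self) -> list[np.ndarray]:
        return [self.masks[f"wm_roi_{i}"] for i in (1, 2, 3)]


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def build_phantom(
    spec: PhantomSpec, acq: AcquisitionParams | None = None
) -> tuple[DscSeries, PhantomTruth]:
    """Simulate a DSC series with known ground truth.

    Deterministic given ``spec.seed``. The signal model per voxel is
    S(t) = S0 exp(-TE ΔR2*(t)) + N(0, sigma), with
    ΔR2*(t) = ratio * C(t) - k2 * ∫C for enhancing lesion voxels and
    ΔR2*(t) = ratio * C(t) elsewhere, C being the reference-tissue bolus.
    """
    if acq is None:
        acq = AcquisitionParams()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = acq.voxel_size

    center = ((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2)
    brain = _ellipsoid(spec.grid_shape, center, (0.44 * nx, 0.44 * ny, 0.47 * nz))

    lesion_center = (center[0] + 0.22 * nx, center[1], center[2])
    r = spec.lesion_radius_mm
    lesion = _ellipsoid(spec.grid_shape, lesion_center, (r / dx, r / dy, r / dz))
    lesion &= brain
    r_nec = r * spec.necrosis_fraction ** (1.0 / 3.0)
    necrosis = _ellipsoid(
        spec.grid_shape, lesion_center, (r_nec / dx, r_nec / dy, r_nec / dz)
    )
    necrosis &= lesion
    enhancing = lesion & ~necrosis

    n_lesion = int(lesion.sum())
    n_enh = int(enhancing.sum())
    if n_lesion == 0:
        raise ValueError("lesion mask is empty for this grid/radius")

    # three 50 mm^2 reference discs mirrored into the contralateral
    # hemisphere at the lesion's superior/middle/inferior slices
    from .metrics import disc_footprint

    foot = disc_footprint((dx, dy), area_mm2=50.0)
    fi, fj = np.nonzero(foot)
    fi = fi - foot.shape[0] // 2
    fj = fj - foot.shape[1] // 2
    zs = np.nonzero(lesion.any(axis=(0, 1)))[0]
    roi_slices = (int(zs.min()), int(zs[len(zs) // 2]), int(zs.max()))
    mirror_i = int(round(2 * center[0] - lesion_center[0]))
    roi_j = int(round(center[1]))
    wm_rois = {}
    for k, z in enumerate(roi_slices, start=1):
        m = np.zeros(spec.grid_shape, dtype=bool)
        m[mirror_i + fi, roi_j + fj, z] = True
        if not (m <= brain).all() or (m & lesion).any():
            raise ValueError("reference ROI falls outside brain or inside lesion")
        wm_rois[f"wm_roi_{k}"] = m

    # true normalized CBV per voxel
    ratio = np.zeros(spec.grid_shape, dtype=float)
    ratio[brain] = 1.0
    ratio[necrosis] = 0.05
    n_hyper = int(round(spec.lesion_fraction_hyper * n_lesion))
    if n_hyper > n_enh:
        raise ValueError(
            f"hypervascular fraction {spec.lesion_fraction_hyper} needs "
            f"{n_hyper} voxels but only {n_enh} enhancing voxels exist"
        )
    enh_idx = np.flatnonzero(enhancing.ravel())
    hyper_idx = rng.choice(enh_idx, size=n_hyper, replace=False)
    low_idx = np.setdiff1d(enh_idx, hyper_idx, assume_unique=False)
    flat = ratio.ravel()
    flat[hyper_idx] = rng.uniform(*spec.rcbv_hyper_range, size=n_hyper)
    flat[low_idx] = rng.uniform(*spec.rcbv_low_range, size=low_idx.size)
    ratio = flat.reshape(spec.grid_shape)

    k2_map = np.where(enhancing, spec.k2_leakage, 0.0)

    t = acq.time_grid
    bolus = dict(DEFAULT_BOLUS)
    ref_curve = gamma_variate_curve(
        t, bolus["t0_frames"] * acq.tr, bolus["amplitude"], bolus["alpha"], bolus["beta"]
    )
    cum_ref = cumulative_trapezoid(ref_curve, dx=acq.tr, initial=0.0)

    dr2 = ratio[..., None] * ref_curve - k2_map[..., None] * cum_ref
    signal = np.zeros(spec.grid_shape + (acq.n_timepoints,), dtype=float)
    signal[brain] = signal_from_delta_r2star(dr2[brain], BASELINE_SIGNAL, acq.te)
    if spec.noise_sigma > 0:
        signal[brain] += rng.normal(
            0.0, spec.noise_sigma * BASELINE_SIGNAL, size=signal[brain].shape
        )

    # can the lesion host at least one 40 mm^2 disc fully inside it?
    from scipy.ndimage import binary_erosion

    foot_min = disc_footprint((dx, dy), area_mm2=40.0)
    feasible = any(
        binary_erosion(enhancing[:, :, z], structure=foot_min).any()
        for z in range(nz)
    )

    f_true = float((ratio > 2.0)[lesion].sum() / n_lesion)
    masks = {"brain": brain, "lesion": lesion, "necrosis": necrosis, **wm_rois}
    series = DscSeries(data=signal, acq=acq, affine=acq.affine)
    truth = PhantomTruth(
        f_true=f_true,
        true_cbv_map=ratio,
        k2_map=k2_map,
        masks=masks,
        hotspot_feasible=feasible,
        spec=spec,
        reference_curve=ref_curve,
    )
    return series, truth


def generate_phantom_cohort(
    n_psp: int,
    n_tp: int,
    psp_f_dist: tuple[float, float] = (0.22, 0.14),
    tp_f_dist: tuple[float, float] = (0.52, 0.17),
    acq: AcquisitionParams | None = None,
    seed: int = 0,
    f_bounds: tuple[float, float] = (0.02, 0.95),
    **spec_overrides,
) -> list[tuple[DscSeries, PhantomTruth]]:
    """Simulate a cohort with phenotype-dependent hypervascular fractions.

    Each case draws its true fraction ``f`` from a truncated normal
    (mean, sd) on ``f_bounds``; pseudoprogression-like cases default to
    mean 0.22, progression-like to mean 0.52 (calibrated to the published
    group medians of %rCBV>2). Per-case seeds derive from ``seed``.
    """
    if n_psp < 1 or n_tp < 1:
        raise ValueError("n_psp and n_tp must each be >= 1")
    for mean, sd in (psp_f_dist, tp_f_dist):
        if sd <= 0:
            raise ValueError("f distribution sd must be positive")
    master = np.random.default_rng(seed)
    case_seeds = master.integers(0, 2**31 - 1, size=n_psp + n_tp)
    lo, hi = f_bounds
    out = []
    phenos = [PSP_LIKE] * n_psp + [TP_LIKE] * n_tp
    dists = [psp_f_dist] * n_psp + [tp_f_dist] * n_tp
    for pheno, (mean, sd), cs in zip(phenos, dists, case_seeds):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        case_rng = np.random.default_rng(cs)
        # a drawn fraction can exceed what the enhancing rim can host
        # (necrotic voxels cannot be hypervascular); such draws are
        # rejected and redrawn, i.e. f is conditioned on feasibility
        for _attempt in range(100):
            f = float(truncnorm.rvs(a, b, loc=mean, scale=sd,
                                    random_state=case_rng))
            spec = PhantomSpec(
                phenotype=pheno,
                lesion_fraction_hyper=f,
                seed=int(cs),
                **spec_overrides,
            )
            try:
                out.append(build_phantom(spec, acq=acq))
                break
            except ValueError as exc:
                if "enhancing" not in str(exc):
                    raise
        else:
            raise ValueError(
                "could not draw a feasible hypervascular fraction in 100 tries"
            )
    return out


# ---------------------------------------------------------------------------
# canonical per-patient fixtures
# ---------------------------------------------------------------------------

# %rCBV>2 (percent) on the early follow-up MRI, necrosis included.
_FIXTURE_PSP = (5.0, 8.0, 9.9, 14.0, 18.0, 22.1, 26.0, 30.0, 37.4, 40.0, 41.0)
_FIXTURE_TP_A = (
    20.0, 29.0, 39.5, 39.6, 42.0, 45.0, 50.0,
    53.6, 58.0, 60.0, 64.6, 66.0, 70.0, 75.0,
)
# necrosis-excluded variant: same pseudoprogression arm, two progression
# cases shift below 40 (necrotic lesions whose fraction rises less)
_FIXTURE_TP_B = (
    20.0, 29.0, 36.0, 36.5, 39.6, 45.0, 50.0,
    53.6, 58.0, 60.0, 64.6, 66.0, 70.0, 75.0,
)


@dataclass(frozen=True)
class CanonicalFixture:
    """Packaged per-patient %rCBV>2 values reproducing the cohort summaries.

    Variant "A": early follow-up, necrosis included (11 PsP vs 14 TP).
    Variant "B": early follow-up, necrosis excluded (same PsP arm).
    """

    variant: str
    psp: tuple[float, ...]
    tp: tuple[float, ...]

    def values(self, group: str) -> np.ndarray:
        if group not in ("PsP", "TP"):
            raise ValueError(f"unknown group {group!r}")
        return np.asarray(self.psp if group == "PsP" else self.tp)

    @property
    def scores(self) -> np.ndarray:
        return np.concatenate([self.values("PsP"), self.values("TP")])

    @property
    def labels(self) -> np.ndarray:
        return np.array(["PsP"] * len(self.psp) + ["TP"] * len(self.tp))

    def to_frame(self) -> pd.DataFrame:
        ids = [f"{g}{i + 1:02d}" for g, arm in (("psp", self.psp), ("tp", self.tp))
               for i in range(len(arm))]
        return pd.DataFrame(
            {
                "patient_id": ids,
                "group": self.labels,
                "variant": self.variant,
                "pct_rcbv_gt2": self.scores,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_records(self):
        """Per-patient records carrying only %rCBV>2 (imaging bypassed)."""
        from .metrics import PatientPerfusionRecord

        out = []
        for row in self.to_frame().itertuples():
            out.append(
                PatientPerfusionRecord(
                    patient_id=row.patient_id,
                    timepoint="CRT1",
                    rcbvmax_hotspot=float("nan"),
                    rcbvmax_volume=float("nan"),
                    pct_above={2.0: float(row.pct_rcbv_gt2)},
                    pct_above_necrosis_excluded={},
                    group=row.group,
                )
            )
        return out


def generate_canonical_fixture(variant: str = "A") -> CanonicalFixture:
    """Return the packaged cohort fixture for variant "A" or "B"."""
    if variant == "A":
        return CanonicalFixture("A", _FIXTURE_PSP, _FIXTURE_TP_A)
    if variant == "B":
        return CanonicalFixture("B", _FIXTURE_PSP, _FIXTURE_TP_B)
    raise ValueError(f"unknown fixture variant {variant!r}")


def write_phantom(
    series: DscSeries, truth: PhantomTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write a phantom as NIfTI-1 files plus a JSON ground-truth sidecar."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    aff = series.affine
    img = nib.Nifti1Image(series.data.astype(np.float32), aff)
    paths["series"] = out_dir / "dsc_series.nii.gz"
    nib.save(img, paths["series"])
    for name, mask in truth.masks.items():
        p = out_dir / f"mask_{name}.nii.gz"
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff), p)
        paths[name] = p
    p = out_dir / "true_cbv.nii.gz"
    nib.save(nib.Nifti1Image(truth.true_cbv_map.astype(np.float32), aff), p)
    paths["true_cbv"] = p
    sidecar = {
        "f_true": truth.f_true,
        "hotspot_feasible": truth.hotspot_feasible,
        "spec": {
            "phenotype": truth.spec.phenotype,
            "grid_shape": list(truth.spec.grid_shape),
            "lesion_fraction_hyper": truth.spec.lesion_fraction_hyper,
            "necrosis_fraction": truth.spec.necrosis_fraction,
            "rcbv_hyper_range": list(truth.spec.rcbv_hyper_range),
            "rcbv_low_range": list(truth.spec.rcbv_low_range),
            "k2_leakage": truth.spec.k2_leakage,
            "noise_sigma": truth.spec.noise_sigma,
            "seed": truth.spec.seed,
        },
        "acquisition": {
            "te": series.acq.te,
            "tr": series.acq.tr,
            "n_timepoints": series.acq.n_timepoints,
            "voxel_size": list(series.acq.voxel_size),
            "baseline_points": series.acq.baseline_points,
        },
    }
    paths["truth"] = out_dir / "truth.json"
    paths["truth"].write_text(json.dumps(sidecar, indent=2))
    return paths
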