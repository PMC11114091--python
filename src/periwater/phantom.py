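"""Synthetic single-shell DWI phantoms and longitudinal stroke cohorts.

The phantom is a mirror-symmetric "brain" on an isotropic 2 mm grid: an
ellipsoidal white-matter compartment, paired midline-adjacent ventricles,
and a single ellipsoidal subcortical lesion confined to one hemisphere.
Ground-truth free-water and tissue-FA fields carry a lesion effect that
decays geometrically over concentric 2 mm distance rings and follows
per-timepoint trajectories (free-water rising monotonically over the year
after stroke; tissue FA dipping at the 1-month visit). Signals are produced
by the same bi-tensor forward model the fitting stage estimates, with
Rician (magnitude-MR) noise.

Cohorts can be simulated at two levels: full imaging phantoms per scan, or
directly at the ROI-measure level (normalized lesion/shell means drawn with
between- and within-subject variability), which is what the statistics
layer consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import shells as shell_ops
from .fwmodel import D_WATER, cylinder_tensor
from .gradients import GradientTable

log = logging.getLogger(__name__)

TIMEPOINTS = ("TP1", "TP2", "TP3", "TP4")
DAY_WINDOWS = ((3, 5), (30, 40), (85, 95), (340, 380))

# Lesion-effect defaults: relative ipsi-vs-contra differences and their
# per-timepoint trajectories (acute, 1 month, 3 months, 12 months), with the
# shell-to-shell attenuation of the effect per 2 mm ring.
FW_LESION_DELTA = 0.41
FW_MULTIPLIERS = (1.0, 1.11 / 0.41, 2.08 / 0.41, 2.51 / 0.41)
FW_DECAY = (0.591, 0.181, 0.209, 0.435)
FAT_LESION_DELTA = -0.343
FAT_MULTIPLIERS = (1.0, 37.3 / 34.3, 25.9 / 34.3, 18.3 / 34.3)
FAT_DECAY = (0.29, 0.545, 0.62, 0.64)


class PhantomSpecError(ValueError):
    """Raised when a phantom specification violates its invariants."""


def _as_tuple4(value, name: str) -> tuple[float, float, float, float]:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (len(TIMEPOINTS),))
    return tuple(float(v) for v in arr)


@dataclass(frozen=True)
class EffectProfile:
    """Ground-truth lesion effect sizes and their spatio-temporal shape.

    ``fw_lesion_delta`` is the relative free-water elevation inside the
    lesion at the first timepoint (e.g. 0.41 = +41%); ``fat_lesion_delta``
    the (negative) relative tissue-FA change. Multipliers scale each delta
    per timepoint; ``*_decay`` attenuates it multiplicatively per 2 mm
    distance ring (scalar or one value per timepoint).
    """

    fw_lesion_delta: float = FW_LESION_DELTA
    fat_lesion_delta: float = FAT_LESION_DELTA
    fw_multipliers: tuple = FW_MULTIPLIERS
    fat_multipliers: tuple = FAT_MULTIPLIERS
    fw_decay: tuple = FW_DECAY
    fat_decay: tuple = FAT_DECAY

    def __post_init__(self) -> None:
        for name in ("fw_multipliers", "fat_multipliers"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) != len(TIMEPOINTS):
                raise PhantomSpecError(
                    f"{name} must have one entry per timepoint ({len(TIMEPOINTS)})"
                )
            object.__setattr__(self, name, vals)
        for name in ("fw_decay", "fat_decay"):
            vals = _as_tuple4(getattr(self, name), name)
            if any(not (0.0 < v <= 1.0) for v in vals):
                raise PhantomSpecError(f"{name} values must lie in (0, 1]")
            object.__setattr__(self, name, vals)

    def delta(self, measure: str, tp_index: int, shell_k: int) -> float:
        """Relative effect for shell ring ``shell_k`` (0 = lesion itself)."""
        if measure == "fw":
            base, mult, decay = self.fw_lesion_delta, self.fw_multipliers, self.fw_decay
        elif measure == "fat":
            base, mult, decay = self.fat_lesion_delta, self.fat_multipliers, self.fat_decay
        else:
            raise ValueError(f"unknown measure {measure!r}")
        return base * mult[tp_index] * decay[tp_index] ** shell_k


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and baseline tissue parameters of the synthetic brain.

    The left-right axis is axis 0 and must have odd length so the midline
    is a voxel plane. Baseline values describe healthy white matter; they
    are configurable defaults, not literature claims.
    """

    grid_shape: tuple = (31, 31, 31)
    voxel_size_mm: float = 2.0
    lesion_center: tuple = (7, 15, 15)
    lesion_radii_mm: tuple = (5.0, 6.0, 6.0)
    wm_margin_mm: float = 2.0
    ventricle_offset_mm: float = 6.0
    ventricle_radii_mm: tuple = (4.0, 8.0, 6.0)
    baseline_fw: float = 0.15
    baseline_fat: float = 0.55
    baseline_md: float = 0.7e-3  # tissue mean diffusivity, mm^2/s
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3:
            raise PhantomSpecError("grid_shape must be 3-D")
        if self.grid_shape[0] % 2 == 0:
            raise PhantomSpecError("left-right axis (0) must have odd length")
        if not 0.0 <= self.baseline_fw < 1.0:
            raise PhantomSpecError("baseline_fw must lie in [0, 1)")
        if not 0.0 <= self.baseline_fat <= 1.0:
            raise PhantomSpecError("baseline_fat must lie in [0, 1]")

    @property
    def midline_index(self) -> int:
        return self.grid_shape[0] // 2


@dataclass
class PhantomMasks:
    """Binary anatomy masks plus the hemisphere map (-1 / 0 midline / +1)."""

    brain: np.ndarray
    wm: np.ndarray
    ventricles: np.ndarray
    lesion: np.ndarray
    hemispheres: np.ndarray


@dataclass
class TruthMaps:
    """Voxelwise ground truth: free-water fraction and tissue tensor field."""

    fw: np.ndarray
    fat: np.ndarray
    md: np.ndarray
    tensors: np.ndarray  # (..., 3, 3)
    masks: PhantomMasks

    @property
    def f_t(self) -> np.ndarray:
        return 1.0 - self.fw


def _ellipsoid(shape, center, radii_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii_vox):
        acc = acc + ((g - c) / max(r, 1e-9)) ** 2
    return acc <= 1.0


def build_phantom(spec: PhantomSpec) -> PhantomMasks:
    """Construct the mirror-symmetric anatomy and the lesion mask.

    White matter and ventricles are symmetric about the midline plane by
    construction; the lesion must lie strictly inside one hemisphere and
    inside white matter.
    """
    shape = tuple(spec.grid_shape)
    vox = spec.voxel_size_mm
    center = tuple((s - 1) / 2.0 for s in shape)
    brain_radii = tuple((s - 1) / 2.0 - 0.5 for s in shape)
    brain = _ellipsoid(shape, center, brain_radii)

    margin_vox = spec.wm_margin_mm / vox
    wm_outer = _ellipsoid(shape, center, tuple(r - margin_vox for r in brain_radii))

    voff = spec.ventricle_offset_mm / vox
    vrad = tuple(r / vox for r in spec.ventricle_radii_mm)
    vent_one = _ellipsoid(shape, (center[0] - voff, center[1], center[2]), vrad)
    ventricles = vent_one | np.flip(vent_one, axis=0)

    wm = wm_outer & ~ventricles

    lrad = tuple(r / vox for r in spec.lesion_radii_mm)
    lesion = _ellipsoid(shape, spec.lesion_center, lrad)
    if not lesion.any():
        raise PhantomSpecError("lesion mask is empty")

    mid = spec.midline_index
    xs = np.nonzero(lesion)[0]
    if xs.min() <= mid <= xs.max() or (xs < mid).any() and (xs > mid).any():
        raise PhantomSpecError("lesion must lie strictly inside one hemisphere")
    if (lesion & ~wm).any():
        raise PhantomSpecError("lesion must lie inside the white-matter compartment")

    hemispheres = np.zeros(shape, dtype=int)
    idx = np.arange(shape[0])
    hemispheres[idx < mid] = -1
    hemispheres[idx > mid] = 1
    return PhantomMasks(brain=brain, wm=wm, ventricles=ventricles, lesion=lesion,
                        hemispheres=hemispheres)


def _fiber_axes(shape) -> np.ndarray:
    """Smoothly varying principal axis: normalized gradient of a smooth field."""
    i, j, k = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    gx = 0.35 * np.cos(0.21 * i + 0.3) + 0.15
    gy = 0.30 * np.cos(0.17 * j + 1.1) + 0.10
    gz = 0.40 * np.cos(0.23 * k + 2.0) + 0.12
    axes = np.stack([gx, gy, gz], axis=-1)
    norms = np.linalg.norm(axes, axis=-1, keepdims=True)
    axes = np.where(norms > 1e-9, axes / np.clip(norms, 1e-9, None), [1.0, 0.0, 0.0])
    return axes


def make_truth_maps(
    spec: PhantomSpec,
    effect: EffectProfile | None = None,
    timepoint: int = 0,
    masks: PhantomMasks | None = None,
    n_shells: int = shell_ops.DEFAULT_N_SHELLS,
) -> TruthMaps:
    """Ground-truth free-water and tissue-tensor fields at one timepoint.

    The lesion effect is applied inside the lesion and, attenuated by the
    per-ring decay, in each ipsilateral 2 mm distance ring (computed with
    the same 6-connected morphology as the analysis shells). The
    contralateral hemisphere holds baseline values exactly. Tissue tensors
    are cylindrically symmetric with eigenvalues solving the FA formula
    exactly at fixed mean diffusivity; ventricles are nearly isotropic,
    free-water dominated voxels.
    """
    if masks is None:
        masks = build_phantom(spec)
    if effect is None:
        effect = EffectProfile()
    if not 0 <= timepoint < len(TIMEPOINTS):
        raise ValueError(f"timepoint index out of range: {timepoint}")
    shape = tuple(spec.grid_shape)

    fw = np.zeros(shape)
    fat = np.zeros(shape)
    md = np.full(shape, spec.baseline_md)
    fw[masks.brain] = spec.baseline_fw
    fat[masks.brain] = spec.baseline_fat
    # non-WM brain rim (cortical ribbon stand-in): wetter, less anisotropic
    rim = masks.brain & ~masks.wm & ~masks.ventricles
    fw[rim] = 0.25
    fat[rim] = 0.30
    fw[masks.ventricles] = 0.95
    fat[masks.ventricles] = 0.05
    md[masks.ventricles] = 1.2e-3

    lesion_side = np.sign(masks.hemispheres[masks.lesion].sum())
    ipsi = masks.hemispheres == lesion_side
    rings = shell_ops.build_shells(masks.lesion, n_shells)
    regions = [masks.lesion] + [r & ipsi for r in rings]
    for k, region in enumerate(regions):
        d_fw = effect.delta("fw", timepoint, k)
        d_fat = effect.delta("fat", timepoint, k)
        fw[region] = np.clip(fw[region] * (1.0 + d_fw), 0.0, 0.99)
        fat[region] = np.clip(fat[region] * (1.0 + d_fat), 0.0, 0.99)

    tensors = cylinder_tensor(fat, md, _fiber_axes(shape))
    return TruthMaps(fw=fw, fat=fat, md=md, tensors=tensors, masks=masks)


def simulate_dwi(
    truth: TruthMaps,
    table: GradientTable,
    s0: float = 1000.0,
    snr: float | None = 30.0,
    seed: int = 0,
    d_w: float = D_WATER,
) -> np.ndarray:
    """Forward-simulate the 4-D DWI volume from ground-truth maps.

    The noiseless attenuation per voxel and volume is the bi-tensor model;
    Rician noise is applied as the magnitude of ``(A s0 + n1, n2)`` with
    independent Gaussian channels of standard deviation ``sigma = s0/snr``.
    Pass ``snr=None`` (or ``inf``) for noise-free data.
    """
    if snr is not None and not snr > 0 and not np.isinf(snr):
        raise ValueError("snr must be positive (or None/inf for noiseless)")
    brain = truth.masks.brain
    g = table.bvecs
    b = table.bvals
    f_t = truth.f_t[brain]
    tens = truth.tensors[brain]
    q = np.einsum("ij,njk,ik->ni", g, tens, g)  # (nvox, nvol)
    att = f_t[:, None] * np.exp(-b[None, :] * q) + (1.0 - f_t)[:, None] * np.exp(
        -b[None, :] * d_w
    )
    signal = np.zeros(brain.shape + (len(table),))
    signal[brain] = s0 * att
    if snr is None or np.isinf(snr):
        return signal
    sigma = s0 / snr
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


# ---------------------------------------------------------------------------
# longitudinal cohort


class CohortDesignError(ValueError):
    """Raised when a cohort design is internally inconsistent."""


@dataclass(frozen=True)
class CohortDesign:
    """Longitudinal study layout: visits, retention, covariates, effects.

    Defaults reproduce the reference study structure: 27 enrolled subjects
    with per-visit retention 26/21/19/19 over four visits at 3-5, 30-40,
    85-95 and 340-380 days after stroke, monotone dropout, and 72% of
    followed lesions shrinking by the 3-month visit. Measure variability is
    given per measure on the normalized (relative-difference) scale.
    """

    n_subjects: int = 27
    timepoints: tuple = TIMEPOINTS
    day_windows: tuple = DAY_WINDOWS
    missingness: tuple = (26, 21, 19, 19)
    effect: EffectProfile = field(default_factory=EffectProfile)
    between_subject_sd: dict = field(
        default_factory=lambda: {"fw": 0.15, "fat": 0.03}
    )
    within_subject_sd: dict = field(
        default_factory=lambda: {"fw": 0.30, "fat": 0.06}
    )
    shrink_fraction: float = 0.72
    n_shells: int = shell_ops.DEFAULT_N_SHELLS
    baseline_fw: float = 0.15
    baseline_fat: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.missingness) != len(self.timepoints):
            raise CohortDesignError("one retention count per timepoint required")
        if max(self.missingness) > self.n_subjects:
            raise CohortDesignError(
                f"retention {max(self.missingness)} exceeds n_subjects={self.n_subjects}"
            )
        if any(b > a for a, b in zip(self.missingness, self.missingness[1:])):
            raise CohortDesignError(
                "monotone dropout requires non-increasing retention counts"
            )
        if not 0.0 <= self.shrink_fraction <= 1.0:
            raise CohortDesignError("shrink_fraction must lie in [0, 1]")


# lesion-volume trajectories relative to baseline (shrinking vs growing)
_SHRINK_TRAJ = (1.0, 0.82, 0.68, 0.60)
_GROW_TRAJ = (1.0, 1.12, 1.22, 1.25)


def simulate_cohort(design: CohortDesign) -> "CohortSim":
    """Draw the subject table for a longitudinal cohort.

    Retention counts are met exactly with monotone dropout (a subject who
    misses a visit misses all later ones). Among the subjects followed to
    the 3-month visit, ``round(shrink_fraction * m)`` have shrinking
    lesions by construction. All draws are functions of ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_subjects
    order = rng.permutation(n)  # order[i] = dropout rank of subject i
    # subject attends visit t iff their rank is below the retention count
    attends = {s: [order[s] < m for m in design.missingness] for s in range(n)}

    tp3 = min(2, len(design.timepoints) - 1)
    followed = [s for s in range(n) if attends[s][tp3]]
    n_shrink = int(round(design.shrink_fraction * len(followed)))
    shrinkers = set(np.asarray(followed)[rng.permutation(len(followed))[:n_shrink]])

    subjects = []
    for s in range(n):
        male = bool(rng.random() < 16 / 27)
        nihss0 = float(np.round(np.exp(rng.normal(np.log(4.5), 0.55))))
        subjects.append(
            {
                "subject_id": f"sub-{s + 1:02d}",
                "age": float(np.clip(rng.normal(66.73, 11.57), 30, 95)),
                "sex": "M" if male else "F",
                "lesion_side": "L" if rng.random() < 12 / 27 else "R",
                "baseline_volume_ml": float(np.exp(rng.normal(np.log(6.5), 0.65))),
                "nihss0": nihss0,
                "shrinks": s in shrinkers,
            }
        )

    recovery = (1.0, 0.65, 0.45, 0.35)  # clinical improvement trajectory
    rows = []
    for s, subj in enumerate(subjects):
        traj = _SHRINK_TRAJ if subj["shrinks"] else _GROW_TRAJ
        for t, tp in enumerate(design.timepoints):
            if not attends[s][t]:
                continue
            lo, hi = design.day_windows[t]
            nihss_t = max(0.0, np.round(subj["nihss0"] * recovery[t] + rng.normal(0, 0.5)))
            vol = subj["baseline_volume_ml"] * traj[t] * (1.0 + rng.normal(0, 0.02))
            rows.append(
                {
                    "subject_id": subj["subject_id"],
                    "timepoint": tp,
                    "days_since_stroke": int(rng.integers(lo, hi + 1)),
                    "age": round(subj["age"], 1),
                    "sex": subj["sex"],
                    "lesion_side": subj["lesion_side"],
                    "lesion_volume_ml": round(vol, 3),
                    "nihss": nihss_t,
                    "uefm": float(np.clip(np.round(66 - 2.4 * nihss_t + rng.normal(0, 3)), 4, 66)),
                    "nhp": round(float(np.clip(22 + 3.0 * nihss_t + rng.normal(0, 3), 15, 90)), 1),
                    "grip_rel": round(float(np.clip(1.0 - 0.055 * nihss_t + rng.normal(0, 0.08), 0.05, 1.3)), 3),
                }
            )
    table = pd.DataFrame(rows)
    return CohortSim(design=design, subject_table=table)


@dataclass
class CohortSim:
    """A drawn cohort: subject table plus scan-level generators."""

    design: CohortDesign
    subject_table: pd.DataFrame

    def scan_list(self) -> list[tuple[str, str]]:
        return list(
            self.subject_table[["subject_id", "timepoint"]].itertuples(index=False, name=None)
        )

    def phantom_spec_for(self, subject_id: str, timepoint: str,
                         base_spec: PhantomSpec | None = None) -> PhantomSpec:
        """Per-scan phantom geometry: lesion radius tracks the subject's
        relative lesion-volume trajectory (the phantom brain is scaled down,
        so absolute milliliters are not transferred onto the grid)."""
        spec = base_spec or PhantomSpec()
        sub = self.subject_table[self.subject_table["subject_id"] == subject_id]
        row = sub[sub["timepoint"] == timepoint]
        if row.empty:
            raise KeyError(f"no scan for {subject_id}/{timepoint}")
        tp0 = self.design.timepoints[0]
        base_rows = sub[sub["timepoint"] == tp0]
        v0 = float(base_rows["lesion_volume_ml"].iloc[0]) if len(base_rows) else float(
            row["lesion_volume_ml"].iloc[0]
        )
        vol_ml = float(row["lesion_volume_ml"].iloc[0])
        scale = (vol_ml / v0) ** (1.0 / 3.0)
        radii = tuple(max(r * scale, spec.voxel_size_mm) for r in spec.lesion_radii_mm)
        tp_index = list(self.design.timepoints).index(timepoint)
        sub_index = int(subject_id.split("-")[1])
        return replace(
            spec,
            lesion_radii_mm=radii,
            seed=int((self.design.seed * 1000 + sub_index * 10 + tp_index) % (2**31)),
        )


def simulate_measures(design: CohortDesign, null: bool = False) -> pd.DataFrame:
    """Draw a cohort's ROI-measure table directly from the design.

    Each present scan contributes one row per location (lesion + shells)
    and measure, with
    ``normalized = truth_delta + subject_effect + residual`` where the
    subject effect is N(0, between_subject_sd) per subject and measure and
    the residual N(0, within_subject_sd). ``null=True`` zeroes the truth
    deltas (symmetric-hemispheres null). Contralateral/ipsilateral means
    consistent with the normalized value are synthesized from the baseline
    parameters. Reproducible from ``design.seed`` alone.
    """
    cohort = simulate_cohort(design)
    rng = np.random.default_rng(design.seed + 1)
    labels = shell_ops.shell_labels(design.n_shells)
    baselines = {"fw": design.baseline_fw, "fat": design.baseline_fat}
    subj_ids = cohort.subject_table["subject_id"].unique()
    b_effects = {
        (sid, m): rng.normal(0.0, design.between_subject_sd[m])
        for sid in subj_ids
        for m in ("fw", "fat")
    }
    rows = []
    for rec in cohort.subject_table.itertuples(index=False):
        t = list(design.timepoints).index(rec.timepoint)
        for k, loc in enumerate(labels):
            for m in ("fw", "fat"):
                truth = 0.0 if null else design.effect.delta(m, t, k)
                value = truth + b_effects[(rec.subject_id, m)] + rng.normal(
                    0.0, design.within_subject_sd[m]
                )
                contra = baselines[m]
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "timepoint": rec.timepoint,
                        "location": loc,
                        "measure": m,
                        "ipsi_mean": contra * (1.0 + value),
                        "contra_mean": contra,
                        "normalized": value,
                        "n_ipsi": 0,
                        "n_contra": 0,
                    }
                )
    return pd.DataFrame(rows)
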