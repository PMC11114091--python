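"""Perilesional shell ROIs and contralaterally normalized measure extraction.

The lesion mask is mirrored across the brain midline, cleaned of ventricle
voxels, and both lesion masks are grown into eight concentric 1-voxel-wide
(2 mm at the default spacing) tissue shells by iterative 6-connected
dilation. Corresponding ipsi/contralateral shells are made disjoint, shells
are restricted to eroded white matter, and ROI means of the free-water and
tissue-FA maps are normalized as (ipsilateral - contralateral)/contralateral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

log = logging.getLogger(__name__)

#: face-adjacent (city-block) structuring element: one dilation = one voxel
STRUCT_6 = ndimage.generate_binary_structure(3, 1)

DEFAULT_N_SHELLS = 8

#: ROI labels in analysis order: lesion, then shells by outer distance in mm
def shell_labels(n_shells: int = DEFAULT_N_SHELLS, voxel_size_mm: float = 2.0):
    return ["lesion"] + [f"{int(round((k + 1) * voxel_size_mm))}mm" for k in range(n_shells)]


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        if not np.isin(np.unique(mask), (0, 1)).all():
            raise ValueError("mask must be binary")
        mask = mask.astype(bool)
    return mask


def flip_mask(mask: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mirror a mask across the grid midline of ``axis``.

    Requires an odd dimension along the flip axis so a one-voxel midline
    plane exists and the reflection is an exact involution on the grid.
    Real-data users whose images are not midline-aligned must mirror in a
    symmetric standard space instead and supply the transformed mask.
    """
    mask = _as_bool(mask)
    if mask.shape[axis] % 2 == 0:
        raise ValueError(
            f"axis {axis} has even length {mask.shape[axis]}: no voxel midline "
            "plane exists; flip in a midline-aligned space and supply the result"
        )
    return np.flip(mask, axis=axis)


def subtract_ventricles(flipped_lesion: np.ndarray, ventricles: np.ndarray) -> np.ndarray:
    """Remove ventricle (CSF) voxels from the mirrored lesion mask."""
    flipped_lesion = _as_bool(flipped_lesion)
    ventricles = _as_bool(ventricles)
    if flipped_lesion.shape != ventricles.shape:
        raise ValueError("masks must share a grid")
    out = flipped_lesion & ~ventricles
    if not out.any() and flipped_lesion.any():
        log.warning("flipped lesion lies entirely within the ventricle mask")
    return out


def erode_mask(mask: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Erode with the 6-connected element; ``iterations`` voxels of margin."""
    mask = _as_bool(mask)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mask.copy()
    out = ndimage.binary_erosion(mask, structure=STRUCT_6, iterations=iterations)
    if mask.any() and not out.any():
        log.warning("erosion (%d iterations) emptied the mask", iterations)
    return out


def build_shells(seed_mask: np.ndarray, n_shells: int = DEFAULT_N_SHELLS) -> list[np.ndarray]:
    """Concentric 1-voxel-wide rings around ``seed_mask``.

    Shell k (1-based) is ``dilate^k(seed) \\ dilate^(k-1)(seed)`` under
    6-connected dilation, i.e. the voxels at city-block distance exactly k
    from the seed. Shells are pairwise disjoint and disjoint from the seed.
    """
    seed_mask = _as_bool(seed_mask)
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    shells = []
    prev = seed_mask
    for _ in range(n_shells):
        grown = ndimage.binary_dilation(prev, structure=STRUCT_6)
        shells.append(grown & ~prev)
        prev = grown
    return shells


def remove_bilateral_overlap(
    ipsi_shells: list[np.ndarray], contra_shells: list[np.ndarray]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Remove, from both sides, the voxels shared by corresponding shells."""
    if len(ipsi_shells) != len(contra_shells):
        raise ValueError("shell lists must have equal length")
    ipsi_out, contra_out = [], []
    for ipsi, contra in zip(ipsi_shells, contra_shells):
        both = ipsi & contra
        ipsi_out.append(ipsi & ~both)
        contra_out.append(contra & ~both)
    return ipsi_out, contra_out


def filter_with_wm(shells: list[np.ndarray], wm_mask: np.ndarray) -> list[np.ndarray]:
    """Restrict each shell to the (eroded) white-matter mask."""
    wm_mask = _as_bool(wm_mask)
    out = []
    for k, shell in enumerate(shells):
        filtered = shell & wm_mask
        if shell.any() and not filtered.any():
            log.warning("shell %d is empty after white-matter filtering", k + 1)
        out.append(filtered)
    return out


@dataclass
class ShellSet:
    """Lesion ROI plus paired ipsi/contralateral perilesional shells.

    ``ipsi_shells[k]``/``contra_shells[k]`` are the 1-voxel-wide rings whose
    outer boundary lies ``(k+1) * voxel_size_mm`` from the respective lesion
    mask, after bilateral-overlap removal and white-matter filtering.
    """

    lesion: np.ndarray
    flipped_lesion: np.ndarray  # ventricle-subtracted mirror of the lesion
    ipsi_shells: list[np.ndarray]
    contra_shells: list[np.ndarray]
    voxel_size_mm: float = 2.0
    wm_filtered: bool = True

    @property
    def n_shells(self) -> int:
        return len(self.ipsi_shells)

    @property
    def labels(self) -> list[str]:
        return shell_labels(self.n_shells, self.voxel_size_mm)


def build_shellset(
    lesion: np.ndarray,
    wm: np.ndarray,
    ventricles: np.ndarray,
    axis: int = 0,
    n_shells: int = DEFAULT_N_SHELLS,
    wm_erode_iterations: int = 2,
    voxel_size_mm: float = 2.0,
) -> ShellSet:
    """Run the full ROI construction for one lesion.

    Order of operations: mirror the lesion, subtract ventricles from the
    mirrored mask, grow shells around both masks, remove bilateral overlap,
    then filter the shells (not the lesion ROIs) with eroded white matter.
    """
    lesion = _as_bool(lesion)
    flipped = subtract_ventricles(flip_mask(lesion, axis=axis), ventricles)
    ipsi = build_shells(lesion, n_shells)
    if flipped.any():
        contra = build_shells(flipped, n_shells)
    else:
        log.warning("empty flipped lesion: contralateral shells are empty")
        contra = [np.zeros_like(lesion) for _ in range(n_shells)]
    ipsi, contra = remove_bilateral_overlap(ipsi, contra)
    wm_eroded = erode_mask(wm, wm_erode_iterations)
    ipsi = filter_with_wm(ipsi, wm_eroded)
    contra = filter_with_wm(contra, wm_eroded)
    return ShellSet(
        lesion=lesion,
        flipped_lesion=flipped,
        ipsi_shells=ipsi,
        contra_shells=contra,
        voxel_size_mm=voxel_size_mm,
        wm_filtered=True,
    )


def _roi_mean(data: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    n = int(mask.sum())
    if n == 0:
        return np.nan, 0
    return float(data[mask].mean()), n


def extract_measures(
    maps: dict[str, np.ndarray],
    shellset: ShellSet,
    subject: str = "",
    timepoint: str = "",
) -> pd.DataFrame:
    """ROI means and contralateral normalization for each measure.

    ``maps`` maps measure names (e.g. ``fw``, ``fat``) to voxel maps. Returns
    one row per location x measure with columns ``ipsi_mean``, ``contra_mean``,
    ``normalized`` = ipsi/contra - 1, and the ROI voxel counts. Empty ROIs
    (or a zero contralateral mean) yield NaN, never an infinity.
    """
    roi_pairs = [(shellset.lesion, shellset.flipped_lesion)]
    roi_pairs += list(zip(shellset.ipsi_shells, shellset.contra_shells))
    rows = []
    for label, (ipsi_mask, contra_mask) in zip(shellset.labels, roi_pairs):
        for measure, data in maps.items():
            if data.shape != ipsi_mask.shape:
                raise ValueError(f"map {measure!r} does not share the mask grid")
            ipsi_mean, n_ipsi = _roi_mean(data, ipsi_mask)
            contra_mean, n_contra = _roi_mean(data, contra_mask)
            if n_ipsi == 0 or n_contra == 0:
                log.warning(
                    "empty ROI for %s/%s/%s (ipsi n=%d, contra n=%d)",
                    subject, label, measure, n_ipsi, n_contra,
                )
            if n_contra == 0 or n_ipsi == 0 or contra_mean == 0:
                normalized = np.nan
            else:
                normalized = ipsi_mean / contra_mean - 1.0
            rows.append(
                {
                    "subject_id": subject,
                    "timepoint": timepoint,
                    "location": label,
                    "measure": measure,
                    "ipsi_mean": ipsi_mean,
                    "contra_mean": contra_mean,
                    "normalized": normalized,
                    "n_ipsi": n_ipsi,
                    "n_contra": n_contra,
                }
            )
    return pd.DataFrame(rows)
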