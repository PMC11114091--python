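"""Diffusion gradient tables (b-values and unit directions).

Single-shell acquisitions are described by a :class:`GradientTable`: one
b-value and unit direction per volume, with the b=0 volumes carrying a zero
direction vector, following the FSL ``bvals``/``bvecs`` convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

#: directions needed to identify a symmetric 3x3 diffusion tensor
MIN_DIRECTIONS = 6

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class InvalidAcquisitionError(ValueError):
    """Raised when a gradient scheme cannot identify the diffusion tensor."""


@dataclass(frozen=True)
class GradientTable:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    b=0 volumes carry a zero vector; all other directions must have unit norm.
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must have shape (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) length mismatch"
            )
        norms = np.linalg.norm(bvecs, axis=1)
        nonzero = bvals > 0
        if np.any(np.abs(norms[nonzero] - 1.0) > 1e-6):
            raise ValueError("nonzero-b directions must have unit norm (within 1e-6)")
        if np.any(norms[~nonzero] > 1e-12):
            raise ValueError("b=0 volumes must carry a zero direction vector")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_b0(self) -> int:
        return int(np.count_nonzero(self.b0_mask))

    @property
    def n_directions(self) -> int:
        return len(self) - self.n_b0

    @property
    def directions(self) -> np.ndarray:
        """Unit directions of the diffusion-weighted volumes only."""
        return self.bvecs[~self.b0_mask]

    @property
    def shell_bvals(self) -> np.ndarray:
        return self.bvals[~self.b0_mask]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform points on the unit sphere (spiral lattice)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q


def make_gradient_table(
    n_directions: int,
    b_value: float = 1500.0,
    n_b0: int = 1,
    seed: int = 0,
) -> GradientTable:
    """Build a single-shell gradient table with uniform directions.

    Directions come from a spherical-Fibonacci lattice, rotated by a seeded
    random rotation so different seeds give different (but reproducible)
    orientations. The b=0 volumes are placed first.

    Parameters
    ----------
    n_directions:
        Number of diffusion-weighted directions; at least 6, otherwise the
        tensor is not identifiable.
    b_value:
        Shell b-value in s/mm^2.
    n_b0:
        Number of non-diffusion-weighted (b=0) volumes.
    seed:
        RNG seed controlling the lattice orientation.
    """
    if n_directions < MIN_DIRECTIONS:
        raise InvalidAcquisitionError(
            f"need at least {MIN_DIRECTIONS} non-collinear directions to identify "
            f"a diffusion tensor, got {n_directions}"
        )
    if n_b0 < 0:
        raise ValueError("n_b0 must be non-negative")
    rng = np.random.default_rng(seed)
    dirs = _fibonacci_sphere(n_directions) @ _random_rotation(rng).T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    # spiral lattices are non-collinear by construction; verify anyway
    dots = np.abs(dirs @ dirs.T)
    np.fill_diagonal(dots, 0.0)
    if np.any(dots > 1.0 - 1e-9):
        raise InvalidAcquisitionError("generated directions contain a collinear pair")
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b_value))])
    bvecs = np.concatenate([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals, bvecs)


def read_fsl_gradients(bval_path, bvec_path) -> GradientTable:
    """Read FSL-dialect ``bvals`` (1 x n) and ``bvecs`` (3 x n) text files.

    Directions whose norm deviates from 1 by more than 1e-3 are re-normalized
    with a warning; b=0 entries are forced to the zero vector.
    """
    bvals = np.loadtxt(bval_path, dtype=float).reshape(-1)
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim != 2 or bvecs.shape[0] != 3:
        raise ValueError(
            f"bvec file must have exactly 3 rows (x, y, z), got shape {bvecs.shape}"
        )
    bvecs = bvecs.T
    if bvals.shape[0] != bvecs.shape[0]:
        raise ValueError(
            f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) length mismatch"
        )
    nonzero = bvals > 0
    norms = np.linalg.norm(bvecs, axis=1)
    bad = nonzero & (np.abs(norms - 1.0) > 1e-3)
    if np.any(bad):
        log.warning("re-normalizing %d gradient vectors with non-unit norm", bad.sum())
    renorm = nonzero & (norms > 0)
    bvecs[renorm] /= norms[renorm, None]
    bvecs[~nonzero] = 0.0
    return GradientTable(bvals, bvecs)


def write_fsl_gradients(table: GradientTable, bval_path, bvec_path) -> None:
    """Write FSL-dialect gradient files (space-separated, bvecs as 3 rows)."""
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:.6g}" for b in table.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in table.bvecs.T:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
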