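"""Encapsulation of the effective-atom cloud in a 3D Gaussian envelope.

The molecule is centered at the mean effective-atom position and rotated
into its principal-axis frame (eigenvectors of the position covariance,
largest variance along x). Per axis, sigma follows the three-sigma rule:
the farthest effective atom along that axis lies at exactly 3 sigma, with
no padding margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

__all__ = ["GaussianEnvelope", "orient", "fit_sigmas", "fit_envelope"]

_DEGENERACY_RTOL = 1e-12


@dataclass(frozen=True)
class GaussianEnvelope:
    """Center, principal-axis rotation, and (sigma_x, sigma_y, sigma_z) in Å."""

    center: np.ndarray          # (3,) input-frame centroid
    rotation: np.ndarray        # (3, 3), rows = principal axes; det = +1
    sigmas: tuple[float, float, float]  # sigma_x >= sigma_y >= sigma_z > 0

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        sx, sy, sz = self.sigmas
        if not (sx >= sy >= sz > 0):
            raise ValueError(f"sigmas must satisfy sx >= sy >= sz > 0, got {self.sigmas}")

    def to_frame(self, positions: np.ndarray) -> np.ndarray:
        """Map input-frame positions into the centered principal-axis frame."""
        return (np.asarray(positions, dtype=float) - self.center) @ self.rotation.T


def orient(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and rotate positions into the principal-axis frame.

    Returns ``(oriented, rotation, center)`` with ``oriented = (P - center) @ R.T``.
    Axes are ordered by decreasing variance (x first). Sign convention: each
    axis is flipped so the atom farthest from the center along it has a
    non-negative coordinate; if that leaves an improper rotation, the z axis
    is flipped back to restore det = +1.

    Raises
    ------
    GeometryError
        Fewer than 3 points, or a collinear/degenerate cloud.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError(f"expected (N, 3) positions, got {pos.shape}")
    n = pos.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 effective atoms, got {n}")

    center = pos.mean(axis=0)
    centered = pos - center
    cov = centered.T @ centered / n
    evals, evecs = np.linalg.eigh(cov)        # ascending
    order = np.argsort(evals)[::-1]           # descending variance -> x, y, z
    evals = evals[order]
    axes = evecs[:, order].T                  # rows are principal axes

    if evals[1] <= _DEGENERACY_RTOL * max(evals[0], 1.0):
        raise GeometryError("effective atoms are (near-)collinear; envelope undefined")

    oriented = centered @ axes.T
    for a in range(3):
        i = int(np.argmax(np.abs(oriented[:, a])))
        if oriented[i, a] < 0:
            axes[a] = -axes[a]
            oriented[:, a] = -oriented[:, a]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
        oriented[:, 2] = -oriented[:, 2]
    return oriented, axes, center


def fit_sigmas(oriented: np.ndarray) -> tuple[float, float, float]:
    """Three-sigma rule per axis: sigma_a = max_i |coordinate_a| / 3.

    Raises
    ------
    GeometryError
        If any axis extent is zero (planar or degenerate cloud).
    """
    arr = np.asarray(oriented, dtype=float)
    extents = np.abs(arr).max(axis=0)
    if np.any(extents <= 0.0):
        raise GeometryError(f"degenerate (planar) cloud: axis extents {extents}")
    sx, sy, sz = extents / 3.0
    return float(sx), float(sy), float(sz)


def fit_envelope(positions: np.ndarray) -> tuple[np.ndarray, GaussianEnvelope]:
    """Orient a cloud and fit its Gaussian envelope in one step.

    Returns ``(oriented_positions, envelope)``.
    """
    oriented, rotation, center = orient(positions)
    extents = np.abs(oriented).max(axis=0)
    # Variance ordering (orient) can disagree with extent ordering on rare
    # clouds; the envelope contract is sigma_x >= sigma_y >= sigma_z.
    if not (extents[0] >= extents[1] >= extents[2]):
        order = np.argsort(extents)[::-1]
        rotation = rotation[order]
        oriented = oriented[:, order]
        if np.linalg.det(rotation) < 0:
            rotation[2] = -rotation[2]
            oriented[:, 2] = -oriented[:, 2]
    sigmas = fit_sigmas(oriented)
    return oriented, GaussianEnvelope(center=center, rotation=rotation, sigmas=sigmas)
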