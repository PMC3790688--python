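"""Quasi-static spherical forward model: dipole grid -> scalp potentials.

The head is a homogeneous conducting sphere of radius ``head_radius_mm``
with electrodes on its surface; candidate sources live on a cubic voxel
lattice inside a concentric "brain" sphere.  The potential of a current
dipole inside a homogeneous sphere has the classical Legendre expansion

    V(e) = 1/(4 pi sigma R^2) * sum_n (2n+1)/n * f^(n-1)
           * [ n q_r P_n(cos g) + q_t sin g P_n'(cos g) ]

with f the fractional source eccentricity, g the angle between source
and electrode, and q_r / q_t the radial / tangential moment components
in the source-electrode plane.  For a dipole at the centre only the
n = 1 term survives and the series reduces to the textbook
3 (q . e_hat) / (4 pi sigma R^2), which anchors the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import Montage


@dataclass
class SourceGrid:
    """Cubic voxel lattice (mm) inside the brain sphere."""

    points_mm: np.ndarray  # (n_voxels, 3)
    spacing_mm: float
    brain_radius_mm: float
    head_radius_mm: float

    @property
    def n_voxels(self) -> int:
        return len(self.points_mm)

    def nearest_voxel(self, point_mm) -> int:
        d = np.linalg.norm(self.points_mm - np.asarray(point_mm), axis=1)
        return int(np.argmin(d))

    def adjacency(self) -> np.ndarray:
        """Boolean 6-neighbourhood adjacency on the lattice."""
        d = np.linalg.norm(
            self.points_mm[:, None, :] - self.points_mm[None, :, :], axis=2
        )
        adj = (d > 1e-9) & (d < self.spacing_mm * 1.01)
        return adj

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian used as the spatial-smoothness penalty."""
        adj = self.adjacency()
        deg = adj.sum(axis=1)
        return np.diag(deg.astype(float)) - adj.astype(float)


def make_grid(
    spacing_mm: float = 14.0,
    brain_radius_mm: float = 75.0,
    head_radius_mm: float = 100.0,
) -> SourceGrid:
    """Cubic lattice of voxel centres with |r| <= brain radius.

    The defaults give a few hundred voxels so a full statistical map
    runs in seconds; a 7-mm spacing reproduces the dense configuration.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    if brain_radius_mm >= head_radius_mm:
        raise ValueError("brain sphere must sit inside the head sphere")
    half = int(np.floor(brain_radius_mm / spacing_mm))
    axis = np.arange(-half, half + 1) * spacing_mm
    xx, yy, zz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    inside = np.linalg.norm(pts, axis=1) <= brain_radius_mm
    return SourceGrid(pts[inside], spacing_mm, brain_radius_mm, head_radius_mm)


@dataclass
class GainMatrix:
    """Sensors x (voxels*3) linear forward operator.

    Columns are ordered voxel-major: columns ``3v .. 3v+2`` are the x, y,
    z dipole components of voxel ``v``.  Units are volts per (A m) scaled
    by the conductivity; only relative structure matters downstream.
    """

    matrix: np.ndarray
    grid: SourceGrid
    channels: list[str]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def dipole_field(self, voxel: int, moment) -> np.ndarray:
        """Scalp pattern of one dipole (moment is a 3-vector)."""
        cols = self.matrix[:, 3 * voxel : 3 * voxel + 3]
        return cols @ np.asarray(moment, dtype=float)


def make_leadfield(
    montage: Montage,
    grid: SourceGrid,
    channels: list[str] | None = None,
    sigma: float = 0.33,
    n_terms: int = 80,
) -> GainMatrix:
    """Legendre-series leadfield for every channel over the voxel grid.

    ``channels`` defaults to the montage's scalp channels (the
    informative set used for source analysis).
    """
    if channels is None:
        channels = montage.scalp_names
    radii = np.linalg.norm(grid.points_mm, axis=1)
    if np.any(radii >= grid.head_radius_mm):
        raise ValueError("voxel outside the head sphere")

    R = grid.head_radius_mm * 1e-3  # meters
    elec = montage.positions[montage.indices(channels)]  # unit vectors
    src = grid.points_mm * 1e-3
    f = np.linalg.norm(src, axis=1) / R  # eccentricity in [0, 1)
    # source radial unit vectors; a central dipole has no defined radial
    # direction, any unit vector works because only n=1 survives there
    r0 = np.where(f[:, None] > 1e-12, src / np.maximum(f[:, None] * R, 1e-300), 0.0)
    r0[f <= 1e-12] = np.array([0.0, 0.0, 1.0])

    c = elec @ r0.T  # (E, V) cos gamma
    c = np.clip(c, -1.0, 1.0)
    sin_g = np.sqrt(np.clip(1.0 - c * c, 0.0, None))

    # accumulate a = sum (2n+1) f^(n-1) P_n(c)           (radial weight)
    #            b = sum (2n+1)/n f^(n-1) sin_g P_n'(c)  (tangential weight)
    p_prev = np.ones_like(c)  # P_0
    p_cur = c.copy()  # P_1
    t_prev = np.zeros_like(c)  # sin_g * P_0'
    t_cur = sin_g.copy()  # sin_g * P_1'
    fpow = np.ones(grid.n_voxels)
    a = 3.0 * fpow * p_cur  # n = 1 terms
    b = 3.0 * fpow * t_cur
    for n in range(1, n_terms):
        # recurrences advance P_n, sin_g*P_n' from (n) to (n+1)
        p_next = ((2 * n + 1) * c * p_cur - n * p_prev) / (n + 1)
        t_next = ((2 * n + 1) * (sin_g * p_cur + c * t_cur) - n * t_prev) / (n + 1)
        p_prev, p_cur = p_cur, p_next
        t_prev, t_cur = t_cur, t_next
        fpow = fpow * f
        m = n + 1
        a = a + (2 * m + 1) * fpow * p_cur
        b = b + (2 * m + 1) / m * fpow * t_cur

    scale = 1.0 / (4.0 * np.pi * sigma * R * R)
    # tangential unit vector from source toward electrode
    # t_hat = (e_hat - c r0) / sin_g, guarded where sin_g ~ 0
    gain = np.empty((len(channels), grid.n_voxels, 3))
    for v in range(grid.n_voxels):
        rv = r0[v]
        tv = elec - c[:, v][:, None] * rv[None, :]
        norm = np.linalg.norm(tv, axis=1)
        safe = norm > 1e-12
        tv[safe] /= norm[safe][:, None]
        tv[~safe] = 0.0
        gain[:, v, :] = scale * (a[:, v][:, None] * rv[None, :] + b[:, v][:, None] * tv)
    matrix = gain.reshape(len(channels), grid.n_voxels * 3)
    if not np.all(np.isfinite(matrix)):
        raise FloatingPointError("non-finite leadfield entries")
    return GainMatrix(matrix, grid, list(channels))
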