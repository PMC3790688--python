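"""Simplified distributed inverse and voxelwise statistical maps.

The inverse is Tikhonov-regularized least squares with an added
discrete-Laplacian smoothness penalty on the voxel lattice — a
"smoothest current density compatible with the scalp data" estimator in
the spirit of distributed EEG source analysis, on a spherical head
model rather than an anatomical atlas.  Group maps are one-sample
Hotelling T² tests of the 3-component current vectors against zero
(F-transformed), and paired-condition contrasts are Hotelling tests of
the per-participant difference vectors; multiplicity is handled with
Bonferroni over voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .erp import ErpSet, WindowSpec
from .forward import GainMatrix, SourceGrid


@dataclass
class InverseOperator:
    """Linear map sensors -> voxels x 3 current density."""

    k: np.ndarray  # (3 n_voxels, n_sensors)
    channels: list[str]
    grid: SourceGrid
    lam: float
    smooth_weight: float

    def apply(self, sensor_vec: np.ndarray) -> np.ndarray:
        """Current-density estimate, shape (n_voxels, 3)."""
        return (self.k @ np.asarray(sensor_vec, dtype=float)).reshape(-1, 3)


def inverse_operator(
    gain: GainMatrix,
    lam: float,
    smooth_weight: float = 1.0,
    grid: SourceGrid | None = None,
) -> InverseOperator:
    """(GᵀG + lam² I + w L⊗I₃)⁻¹ Gᵀ with L the voxel-graph Laplacian."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    grid = grid or gain.grid
    g = gain.matrix
    lap3 = np.kron(grid.laplacian(), np.eye(3))
    # scale the penalty blocks to the gain's magnitude so lam is unitless
    gscale = np.mean(np.sum(g**2, axis=0))
    m = g.T @ g + (lam**2) * gscale * np.eye(g.shape[1]) + smooth_weight * gscale * lap3
    try:
        k = np.linalg.solve(m, g.T)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"singular normal equations: {err}") from err
    return InverseOperator(k, list(gain.channels), grid, lam, smooth_weight)


def gcv_lambda(
    gain: GainMatrix,
    sensor_vec: np.ndarray,
    smooth_weight: float = 1.0,
    lambdas: np.ndarray | None = None,
) -> float:
    """Generalized cross-validation choice of the ridge parameter.

    GCV(lam) = n ||(I - A) y||² / tr(I - A)² with A the data-space
    influence matrix; evaluated on (typically) the group-average scalp
    vector.
    """
    y = np.asarray(sensor_vec, dtype=float)
    if lambdas is None:
        lambdas = np.logspace(-3, 1, 25)
    best_lam, best_score = None, np.inf
    for lam in lambdas:
        inv = inverse_operator(gain, lam, smooth_weight)
        a = gain.matrix @ inv.k
        resid = y - a @ y
        denom = (len(y) - np.trace(a)) ** 2
        if denom <= 0:
            continue
        score = len(y) * float(resid @ resid) / denom
        if score < best_score:
            best_lam, best_score = float(lam), score
    return best_lam


@dataclass
class SourceSolution:
    """participants x conditions x voxels x 3 current-density estimates."""

    data: np.ndarray
    participants: list
    conditions: list[str]
    grid: SourceGrid
    lam: float
    smooth_weight: float

    def condition_index(self, condition: str) -> int:
        try:
            return self.conditions.index(condition)
        except ValueError:
            raise KeyError(f"unknown condition {condition!r}") from None


def localize_window(
    erps: ErpSet, window: WindowSpec, inv: InverseOperator
) -> SourceSolution:
    """Apply the inverse to each participant x condition window average."""
    ch = erps.channel_indices(inv.channels)
    ts = erps.sample_window(window.t_start_ms, window.t_end_ms)
    if ts.size == 0:
        raise ValueError("window contains no samples")
    scalp = erps.data[:, :, ch][:, :, :, ts].mean(axis=3)  # part x cond x sens
    n_p, n_c, _ = scalp.shape
    sols = np.empty((n_p, n_c, inv.grid.n_voxels, 3))
    for i in range(n_p):
        for j in range(n_c):
            sols[i, j] = inv.apply(scalp[i, j])
    return SourceSolution(
        sols, list(erps.participants), list(erps.conditions), inv.grid,
        inv.lam, inv.smooth_weight,
    )


@dataclass
class Spm:
    """Voxelwise statistical parametric map with Bonferroni threshold."""

    statistic: np.ndarray  # Hotelling T² per voxel
    f: np.ndarray
    df: tuple[int, int]
    p: np.ndarray  # uncorrected
    p_corrected: np.ndarray
    sig: np.ndarray
    alpha: float
    grid: SourceGrid
    correction: str = "bonferroni"

    def to_frame(self) -> pd.DataFrame:
        pts = self.grid.points_mm
        return pd.DataFrame(
            dict(
                x_mm=pts[:, 0],
                y_mm=pts[:, 1],
                z_mm=pts[:, 2],
                t2=self.statistic,
                f=self.f,
                p=self.p,
                p_corrected=self.p_corrected,
                sig=self.sig.astype(bool),
            )
        )


def _hotelling_map(x: np.ndarray, grid: SourceGrid, alpha: float) -> Spm:
    """One-sample Hotelling T² against zero per voxel; x is n x V x 3."""
    n, n_vox, p_dim = x.shape
    if n <= p_dim:
        raise ValueError(f"need more than {p_dim} participants, got {n}")
    mean = x.mean(axis=0)
    centered = x - mean[None]
    t2 = np.full(n_vox, np.nan)
    for v in range(n_vox):
        s = centered[:, v, :].T @ centered[:, v, :] / (n - 1)
        try:
            sol = np.linalg.solve(s, mean[v])
        except np.linalg.LinAlgError:
            continue  # singular covariance: voxel untestable
        t2[v] = n * float(mean[v] @ sol)
    df = (p_dim, n - p_dim)
    with np.errstate(invalid="ignore"):
        f = t2 * (n - p_dim) / (p_dim * (n - 1))
    p = np.where(np.isnan(f), np.nan, stats.f.sf(f, *df))
    p_corr = np.minimum(p * n_vox, 1.0)
    sig = np.where(np.isnan(p_corr), False, p_corr < alpha)
    return Spm(t2, f, df, p, p_corr, sig.astype(bool), alpha, grid)


def spm_hotelling(
    solutions: SourceSolution, condition: str, alpha: float = 0.01
) -> Spm:
    """Voxel-by-voxel Hotelling T² of one condition's currents vs zero."""
    j = solutions.condition_index(condition)
    return _hotelling_map(solutions.data[:, j], solutions.grid, alpha)


def spm_condition_contrast(
    solutions: SourceSolution,
    condition_a: str,
    condition_b: str,
    alpha: float = 0.01,
) -> Spm:
    """Paired contrast: Hotelling T² on the A-B difference vectors.

    Equivalent to the 2-level within-factor multivariate ANOVA, and
    symmetric in the two conditions.
    """
    ja = solutions.condition_index(condition_a)
    jb = solutions.condition_index(condition_b)
    diff = solutions.data[:, ja] - solutions.data[:, jb]
    return _hotelling_map(diff, solutions.grid, alpha)
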