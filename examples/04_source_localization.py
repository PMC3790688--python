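"""Distributed source analysis of the 170-190 ms window.

Builds the spherical-head leadfield on a coarse voxel grid, estimates
each participant x condition current-density distribution from the
window-averaged scalp ERPs, and maps where the rivalry changed-vs-same
contrast is significant (Hotelling T² on the paired 3-vector
differences, Bonferroni-corrected over voxels).  The fusion contrast is
the negative control and should stay empty.
"""

import numpy as np

from rivalerp import (
    EffectParams,
    EpochSpec,
    WindowSpec,
    average_erps,
    default_montage,
    inverse_operator,
    localize_window,
    make_grid,
    make_leadfield,
    spm_condition_contrast,
    spm_hotelling,
)
from rivalerp.simulate import simulate_study_epochs

montage = default_montage()
# coarse grid: 3 x 19 source components for 59 sensors, so the gain
# matrix has full column rank and the inverse is nearly leak-free
grid = make_grid(spacing_mm=50.0)
gain = make_leadfield(montage, grid)
print(f"grid: {grid.n_voxels} voxels at {grid.spacing_mm:g} mm")

effects = EffectParams(n1_extra_negativity_uV=3.0)
epochs = simulate_study_epochs(
    n_participants=11, n_blocks=6, effects=effects, noise_sd_uV=2.0, seed=3,
    espec=EpochSpec(tmin_ms=-100.0, tmax_ms=500.0),
)
erps = average_erps(epochs)

window = WindowSpec(list(gain.channels), 170.0, 190.0)
inv = inverse_operator(gain, 0.02, smooth_weight=0.0)
sols = localize_window(erps, window, inv)

spm = spm_hotelling(sols, "rivalry_changed")
contrast = spm_condition_contrast(sols, "rivalry_changed", "rivalry_same")
fusion = spm_condition_contrast(sols, "fusion_changed", "fusion_same")
print(f"activity vs zero: {int(spm.sig.sum())} significant voxels "
      f"(F df = {spm.df})")
print(f"rivalry changed vs same: {int(contrast.sig.sum())} significant voxels")
print(f"fusion changed vs same (control): {int(fusion.sig.sum())} significant voxels")
if contrast.sig.any():
    peak = int(np.nanargmax(contrast.f))
    x, y_, z = grid.points_mm[peak]
    print(f"peak contrast voxel at ({x:.0f}, {y_:.0f}, {z:.0f}) mm, "
          f"F = {np.nanmax(contrast.f):.1f}")
# The broad posterior scalp topography of the injected N1 effect maps to
# a deep posterior-inferior equivalent source on this coarse grid; the
# fusion contrast carries no outcome-dependent signal and stays empty.
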