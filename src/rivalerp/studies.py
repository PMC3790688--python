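"""Simulation studies: Type-I calibration and effect-recovery power.

These routines run many replicates of the synthetic-data -> averaging ->
statistics chain at a reduced channel count (the full 10-electrode
parieto-occipital/occipital ROI plus two central channels) and a
shortened epoch, so that hundreds of replicates finish in minutes while
exercising exactly the operations used on full-size data.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .design import BehaviorParams, make_design, simulate_behavior
from .erp import (
    RoiSpec,
    WindowSpec,
    average_erps,
    permutation_tmap,
    pointwise_tmap,
    roi_count,
    window_anova,
    window_mean,
)
from .montage import Montage, default_montage
from .preprocessing import EpochSpec
from .simulate import EffectParams, effect_difference_wave, simulate_epochs


def reduced_montage(montage: Montage | None = None) -> Montage:
    """ROI electrodes plus a central pair; enough for both t-map regions."""
    montage = montage or default_montage()
    return montage.subset(montage.channels_in_rows(["PO", "O"]) + ["FCz", "Cz"])


#: group-mean outcome probabilities without between-participant spread,
#: so repeated small groups keep every condition cell occupied
FIXED_BEHAVIOR = BehaviorParams(
    sd_change_rivalry=0.0, sd_noresponse_rivalry=0.0, sd_correct_fusion=0.0
)

SHORT_EPOCH = EpochSpec(tmin_ms=-100.0, tmax_ms=300.0)


def _simulate_group(
    rng: np.random.Generator,
    effects: EffectParams,
    montage: Montage,
    n_participants: int,
    trials_per_block: int,
    noise_sd: float,
    espec: EpochSpec,
):
    eps = {}
    for p in range(n_participants):
        trials = simulate_behavior(
            make_design(1, trials_per_block, seed=rng), FIXED_BEHAVIOR, seed=rng
        )
        eps[p] = simulate_epochs(
            trials, effects, montage, noise_sd_uV=noise_sd, seed=rng, espec=espec
        )
    return average_erps(eps)


def type1_calibration(
    n_null_datasets: int = 200,
    n_effect_datasets: int = 100,
    n_participants: int = 11,
    trials_per_block: int = 40,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> dict:
    """False-positive rates of the ROI cell tests on null synthetic data.

    Null datasets carry no outcome-dependent effect; the pointwise and
    sign-flip permutation t-maps should each flag ~1 % of the 850 ROI
    cells at alpha .01.  Effect-bearing datasets exercise the fusion
    negative control: fusion responses never depend on the outcome, so
    the fusion-condition map must stay null even when the rivalry
    effects are present.
    """
    montage = reduced_montage()
    roi = RoiSpec.default(montage)
    rng = np.random.default_rng(seed)
    null_effects = EffectParams().null()

    point_sig = perm_sig = n_cells_total = 0
    for _ in range(n_null_datasets):
        erps = _simulate_group(
            rng, null_effects, montage, n_participants, trials_per_block,
            noise_sd, SHORT_EPOCH,
        )
        tmap = pointwise_tmap(erps, "rivalry_changed", "rivalry_same", roi.alpha)
        perm = permutation_tmap(erps, "rivalry_changed", "rivalry_same",
                                alpha=roi.alpha)
        c, n = roi_count(tmap, roi)
        point_sig += c
        perm_sig += roi_count(perm, roi).count
        n_cells_total += n

    fusion_sig = fusion_cells = 0
    for _ in range(n_effect_datasets):
        erps = _simulate_group(
            rng, EffectParams(), montage, n_participants, trials_per_block,
            noise_sd, SHORT_EPOCH,
        )
        fmap = pointwise_tmap(erps, "fusion_changed", "fusion_same", roi.alpha)
        c, n = roi_count(fmap, roi)
        fusion_sig += c
        fusion_cells += n

    return {
        "pointwise_sig_fraction": point_sig / n_cells_total,
        "permutation_sig_fraction": perm_sig / n_cells_total,
        "fusion_sig_fraction": fusion_sig / fusion_cells,
        "n_roi_cells": n_cells_total,
        "n_fusion_cells": fusion_cells,
        "alpha": roi.alpha,
    }


def binomial_band(p: float, n: int, z: float = 2.5758) -> tuple[float, float]:
    """Two-sided 99 % normal-approximation band for a binomial fraction."""
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half


def n1_recovery_study(
    n_replicates: int = 100,
    n_participants: int = 11,
    trials_per_block: int = 40,
    noise_sd: float = 5.0,
    effect_sd_multiple: float = 3.0,
    seed: int = 0,
) -> dict:
    """Power and bias of the 170-190 ms posterior-window ANOVA.

    The N1 deepening is injected at ``effect_sd_multiple`` times the
    ERP-noise SD of the participant-level changed-minus-same window
    mean (computed from the noise level and the expected per-condition
    trial counts), then recovered through averaging, window means, and
    the repeated-measures ANOVA.
    """
    montage = reduced_montage()
    window = WindowSpec.n1_window()
    n_samples = 10  # [170, 190) at 2 ms
    n_elec = len(window.electrodes)
    n_riv = trials_per_block // 2
    exp_changed = n_riv * FIXED_BEHAVIOR.p_change_rivalry
    exp_same = n_riv * FIXED_BEHAVIOR.p_same_rivalry
    sd_diff = noise_sd * np.sqrt(
        (1 / exp_changed + 1 / exp_same) / (n_elec * n_samples)
    )

    # window-mean of the injected difference per unit of N1 amplitude
    unit = EffectParams(n1_extra_negativity_uV=1.0, lp_reduction_uV=0.0,
                        s2_lp_reduction_uV=0.0)
    times = np.arange(
        int(SHORT_EPOCH.tmin_ms / 2), int(SHORT_EPOCH.tmax_ms / 2) + 1
    ) * 2.0
    wave = effect_difference_wave(times, unit, montage)
    ch = montage.indices(window.electrodes)
    ts = (times >= window.t_start_ms) & (times < window.t_end_ms)
    unit_window_effect = wave[np.ix_(ch, np.flatnonzero(ts))].mean()  # negative

    amplitude = effect_sd_multiple * sd_diff / abs(unit_window_effect)
    effects = replace(
        unit, n1_extra_negativity_uV=amplitude, s2_lp_reduction_uV=1.0
    )
    expected_diff = amplitude * unit_window_effect

    rng = np.random.default_rng(seed)
    rejections = 0
    recovered = []
    for _ in range(n_replicates):
        erps = _simulate_group(
            rng, effects, montage, n_participants, trials_per_block,
            noise_sd, SHORT_EPOCH,
        )
        res = window_anova(erps, window)
        if res.p < 0.05:
            rejections += 1
        wm = window_mean(erps, window)
        recovered.append(
            (wm["rivalry_changed"] - wm["rivalry_same"]).mean()
        )
    recovered = np.asarray(recovered)
    return {
        "rejection_rate": rejections / n_replicates,
        "injected_amplitude_uV": amplitude,
        "expected_window_diff_uV": expected_diff,
        "recovered_window_diff_uV": float(recovered.mean()),
        "recovery_se_uV": float(recovered.std(ddof=1) / np.sqrt(n_replicates)),
        "n_replicates": n_replicates,
    }
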