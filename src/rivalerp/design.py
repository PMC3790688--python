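"""Trial design and behavioral-outcome simulation for intermittent rivalry.

Each trial is S1 (1000 ms) - gap (200 ms) - S2 (1000 ms) - mask (1000 ms)
- ITI (2000 ms), i.e. successive S1 onsets are 5200 ms apart.  Half the
trials in every block show rival gratings (orthogonal orientations in
the two eyes); the other half show fused gratings (identical
orientations), with a physical orientation change after the gap on half
of the fusion trials.  On rivalry trials the participant reports whether
the consciously seen orientation changed across the gap; on fusion
trials the report can be scored for accuracy against the physical
change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# trial segment durations, ms
S1_MS = 1000.0
GAP_MS = 200.0
S2_MS = 1000.0
MASK_MS = 1000.0
ITI_MS = 2000.0
TRIAL_MS = S1_MS + GAP_MS + S2_MS + MASK_MS + ITI_MS  # 5200
S2_ONSET_MS = S1_MS + GAP_MS  # 1200 after S1 onset

TRIAL_COLUMNS = [
    "trial_id",
    "block",
    "condition",
    "eye_left_orientation",
    "eye_right_orientation",
    "s2_physical_change",
    "s1_onset_ms",
    "outcome",
    "response_correct",
]


@dataclass
class BehaviorParams:
    """Outcome probabilities and their between-participant spread.

    The means are the group-level values; per-participant probabilities
    are drawn from moment-matched Beta hyperpriors so that simulated
    groups reproduce both the mean and the between-participant SD.
    """

    p_change_rivalry: float = 0.37
    p_same_rivalry: float = 0.57
    p_noresponse_rivalry: float = 0.06
    p_correct_fusion: float = 0.94
    sd_change_rivalry: float = 0.14
    sd_noresponse_rivalry: float = 0.10
    sd_correct_fusion: float = 0.07

    def __post_init__(self) -> None:
        probs = [
            self.p_change_rivalry,
            self.p_same_rivalry,
            self.p_noresponse_rivalry,
            self.p_correct_fusion,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        total = (
            self.p_change_rivalry + self.p_same_rivalry + self.p_noresponse_rivalry
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"rivalry outcome probabilities sum to {total}, not 1")

    def draw_participant(self, rng: np.random.Generator) -> "BehaviorParams":
        """Sample one participant's probabilities from the hyperprior."""
        p_change = _beta_draw(rng, self.p_change_rivalry, self.sd_change_rivalry)
        p_nr = _beta_draw(
            rng, self.p_noresponse_rivalry, self.sd_noresponse_rivalry
        )
        # renormalize the rare draws whose two components exceed 1
        if p_change + p_nr >= 1.0:
            scale = 0.999 / (p_change + p_nr)
            p_change *= scale
            p_nr *= scale
        p_corr = _beta_draw(rng, self.p_correct_fusion, self.sd_correct_fusion)
        return BehaviorParams(
            p_change_rivalry=p_change,
            p_same_rivalry=1.0 - p_change - p_nr,
            p_noresponse_rivalry=p_nr,
            p_correct_fusion=p_corr,
            sd_change_rivalry=0.0,
            sd_noresponse_rivalry=0.0,
            sd_correct_fusion=0.0,
        )


def _beta_draw(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd <= 0 or mean in (0.0, 1.0):
        return mean
    var = sd * sd
    nu = mean * (1 - mean) / var - 1.0
    if nu <= 0:  # SD too large for a Beta; fall back to the mean
        return mean
    return float(rng.beta(mean * nu, (1 - mean) * nu))


def make_design(
    n_blocks: int = 16,
    trials_per_block: int = 40,
    seed: int | np.random.Generator = 0,
    first_condition: str = "rivalry",
) -> pd.DataFrame:
    """Build the counterbalanced trial table.

    Per block: equal rivalry and fusion counts; rivalry trials split
    exactly in half by which eye sees vertical; fusion trials split
    exactly in half by pre-gap orientation and (as evenly as possible)
    by whether the orientation changes physically after the gap.  Trial
    order is freshly randomized per block, except that the condition of
    the first trial alternates block by block starting from
    ``first_condition``.
    """
    if trials_per_block % 4:
        raise ValueError(
            f"trials_per_block must be divisible by 4, got {trials_per_block}"
        )
    if first_condition not in ("rivalry", "fusion"):
        raise ValueError("first_condition must be 'rivalry' or 'fusion'")
    rng = np.random.default_rng(seed)

    rows = []
    trial_id = 0
    for block in range(1, n_blocks + 1):
        half = trials_per_block // 2
        block_rows = []
        # rivalry: which eye sees vertical, exactly balanced
        left_vertical = [True] * (half // 2) + [False] * (half - half // 2)
        for lv in left_vertical:
            block_rows.append(
                dict(
                    condition="rivalry",
                    eye_left_orientation="vertical" if lv else "horizontal",
                    eye_right_orientation="horizontal" if lv else "vertical",
                    s2_physical_change=False,
                )
            )
        # fusion: orientation balanced; physical change balanced
        orientations = ["horizontal"] * (half // 2) + ["vertical"] * (half - half // 2)
        changes = [True] * (half // 2) + [False] * (half - half // 2)
        rng.shuffle(changes)
        for ori, chg in zip(orientations, changes):
            block_rows.append(
                dict(
                    condition="fusion",
                    eye_left_orientation=ori,
                    eye_right_orientation=ori,
                    s2_physical_change=chg,
                )
            )
        order = rng.permutation(len(block_rows))
        block_rows = [block_rows[i] for i in order]
        want_first = (
            first_condition
            if block % 2 == 1
            else ("fusion" if first_condition == "rivalry" else "rivalry")
        )
        first_idx = next(
            i for i, r in enumerate(block_rows) if r["condition"] == want_first
        )
        block_rows.insert(0, block_rows.pop(first_idx))
        for r in block_rows:
            r["trial_id"] = trial_id
            r["block"] = block
            r["s1_onset_ms"] = trial_id * TRIAL_MS
            r["outcome"] = pd.NA
            r["response_correct"] = pd.NA
            rows.append(r)
            trial_id += 1

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_behavior(
    trials: pd.DataFrame,
    behavior: BehaviorParams | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Fill the outcome columns of a trial table.

    Rivalry outcomes are i.i.d. draws from the
    changed/same/no-response multinomial; fusion responses are correct
    with ``p_correct_fusion`` and the recorded outcome is the (possibly
    wrong) report of whether the orientation changed.
    """
    behavior = behavior or BehaviorParams()
    rng = np.random.default_rng(seed)
    out = trials.copy()

    rivalry = out["condition"] == "rivalry"
    n_riv = int(rivalry.sum())
    draws = rng.choice(
        ["changed", "same", "no_response"],
        size=n_riv,
        p=[
            behavior.p_change_rivalry,
            behavior.p_same_rivalry,
            behavior.p_noresponse_rivalry,
        ],
    )
    out.loc[rivalry, "outcome"] = draws
    out.loc[rivalry, "response_correct"] = pd.NA

    fusion = ~rivalry
    n_fus = int(fusion.sum())
    correct = rng.random(n_fus) < behavior.p_correct_fusion
    changed = out.loc[fusion, "s2_physical_change"].to_numpy(dtype=bool)
    reported_change = np.where(correct, changed, ~changed)
    out.loc[fusion, "outcome"] = np.where(reported_change, "changed", "same")
    out.loc[fusion, "response_correct"] = correct
    return out


def erp_condition(trials: pd.DataFrame) -> pd.Series:
    """Map each trial to its ERP averaging condition (or <NA> if excluded).

    Rivalry no-response trials and fusion trials with an incorrect
    response are excluded from averaging.
    """
    cond = pd.Series(pd.NA, index=trials.index, dtype="object")
    riv = trials["condition"] == "rivalry"
    cond[riv & (trials["outcome"] == "changed")] = "rivalry_changed"
    cond[riv & (trials["outcome"] == "same")] = "rivalry_same"
    fus_ok = (~riv) & (trials["response_correct"] == True)  # noqa: E712
    cond[fus_ok & trials["s2_physical_change"]] = "fusion_changed"
    cond[fus_ok & ~trials["s2_physical_change"].astype(bool)] = "fusion_same"
    return cond
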