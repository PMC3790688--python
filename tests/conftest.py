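import numpy as np
import pandas as pd
import pytest

from rivalerp.design import BehaviorParams, make_design, simulate_behavior
from rivalerp.erp import ErpSet
from rivalerp.montage import default_montage


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def small_montage(montage):
    """Reduced channel set for repeated simulations: the full 10-channel
    parieto-occipital/occipital ROI plus a central electrode pair, EOG,
    and the earlobes."""
    names = (
        montage.channels_in_rows(["PO", "O"])
        + ["FCz", "Cz"]
        + montage.eog_names
        + montage.earlobe_names
    )
    return montage.subset(names)


@pytest.fixture(scope="session")
def fixed_behavior():
    """Group-mean outcome probabilities without between-participant spread
    (keeps every condition cell occupied in small simulations)."""
    return BehaviorParams(
        sd_change_rivalry=0.0, sd_noresponse_rivalry=0.0, sd_correct_fusion=0.0
    )


@pytest.fixture()
def labelled_trials(fixed_behavior):
    design = make_design(1, 8, seed=3)
    return simulate_behavior(design, fixed_behavior, seed=3)


def make_erpset(
    rng: np.random.Generator,
    n_participants: int = 11,
    channels: list[str] | None = None,
    times_ms: np.ndarray | None = None,
    conditions=("rivalry_changed", "rivalry_same"),
    scale: float = 1.0,
) -> ErpSet:
    """Random participant-level ERPs for direct statistical tests."""
    channels = channels or ["POz", "Oz", "O1"]
    if times_ms is None:
        times_ms = np.arange(-50, 151) * 2.0
    data = scale * rng.standard_normal(
        (n_participants, len(conditions), len(channels), len(times_ms))
    )
    counts = pd.DataFrame(
        {c: [10] * n_participants for c in conditions},
        index=list(range(n_participants)),
    )
    return ErpSet(
        data,
        list(range(n_participants)),
        list(conditions),
        list(channels),
        times_ms,
        counts,
    )
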