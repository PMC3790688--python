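"""Condition-averaged ERPs and the statistical battery.

Group statistics operate on participant-level condition averages:
pointwise paired t-maps (uncorrected, thresholded at p = .01), a
significance-count chi-square against the nominal Type-I expectation, a
sign-flip permutation analogue of the t-map (full enumeration of the
2^n flips for small groups), window-averaged voltages over electrode
clusters, and repeated-measures ANOVAs with partial eta squared.

Sample-window convention: electrode x time regions take samples in
[t_start, t_end) ms on the sample grid, so at 500 Hz the 80-250 ms ROI
over 10 parieto-occipital/occipital electrodes has exactly 10 x 85 =
850 cells, and the 170-190 / 380-420 ms windows have 10 and 20 samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .montage import Montage
from .preprocessing import EpochSet

CONDITIONS = ("rivalry_changed", "rivalry_same", "fusion_changed", "fusion_same")

#: default 6-electrode clusters for window averages
PO_CLUSTER = ["PO3", "POz", "PO4", "O1", "Oz", "O2"]
CENTRAL_CLUSTER = ["FC1", "FCz", "FC2", "C1", "Cz", "C2"]


@dataclass
class ErpSet:
    """Per-participant, per-condition channel x time averages (µV)."""

    data: np.ndarray  # participants x conditions x channels x samples
    participants: list
    conditions: list[str]
    channels: list[str]
    times_ms: np.ndarray
    n_trials: pd.DataFrame  # participants x conditions trial counts

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        expect = (
            len(self.participants),
            len(self.conditions),
            len(self.channels),
            len(self.times_ms),
        )
        if self.data.shape != expect:
            raise ValueError(f"ERP data shape {self.data.shape} != {expect}")

    def condition_index(self, condition: str) -> int:
        try:
            return self.conditions.index(condition)
        except ValueError:
            raise KeyError(f"unknown condition {condition!r}") from None

    def channel_indices(self, names) -> np.ndarray:
        idx = []
        for n in names:
            try:
                idx.append(self.channels.index(n))
            except ValueError:
                raise KeyError(f"unknown electrode {n!r}") from None
        return np.asarray(idx, dtype=int)

    def sample_window(self, start_ms: float, stop_ms: float) -> np.ndarray:
        return np.flatnonzero((self.times_ms >= start_ms) & (self.times_ms < stop_ms))


def average_erps(
    epochs_by_participant: dict,
    conditions: tuple[str, ...] = CONDITIONS,
) -> ErpSet:
    """Average kept epochs per participant x condition.

    Epoch metadata must carry an ``erp_condition`` column (rivalry
    no-response and incorrect-fusion trials are <NA> there and are never
    averaged).  A participant with an empty condition cell is excluded
    with a warning, mirroring the exclusion of participants with too few
    change trials.
    """
    participants, stacks, counts = [], [], []
    excluded = []
    channels = times = None
    for pid, ep in epochs_by_participant.items():
        kept = ep.kept()
        if channels is None:
            channels, times = kept.channels, kept.times_ms
        cond_col = kept.metadata["erp_condition"]
        per_cond, per_count = [], {}
        ok = True
        for cond in conditions:
            match = (cond_col == cond).fillna(False)
            idx = np.flatnonzero(match.to_numpy(dtype=bool))
            per_count[cond] = len(idx)
            if len(idx) == 0:
                ok = False
                continue
            per_cond.append(kept.data[idx].mean(axis=0))
        if not ok:
            excluded.append(pid)
            continue
        participants.append(pid)
        stacks.append(np.stack(per_cond))
        counts.append(per_count)
    if excluded:
        warnings.warn(
            f"excluded participants with empty condition cells: {excluded}",
            stacklevel=2,
        )
    if not participants:
        raise ValueError("no participant has trials in every condition")
    n_trials = pd.DataFrame(counts, index=participants)
    return ErpSet(
        np.stack(stacks), participants, list(conditions), channels, times, n_trials
    )


# ---------------------------------------------------------------------------
# region / window specifications


@dataclass
class RoiSpec:
    """Spatiotemporal region of interest (half-open time window)."""

    electrodes: list[str] = field(default_factory=list)
    t_start_ms: float = 80.0
    t_end_ms: float = 250.0
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def default(cls, montage: Montage) -> "RoiSpec":
        """The 10 parieto-occipital/occipital electrodes, 80-250 ms."""
        return cls(electrodes=montage.channels_in_rows(["PO", "O"]))


@dataclass
class WindowSpec:
    """Electrode cluster and time window for scalar voltage averages."""

    electrodes: list[str]
    t_start_ms: float
    t_end_ms: float

    @classmethod
    def n1_window(cls, electrodes=None) -> "WindowSpec":
        return cls(list(electrodes or PO_CLUSTER), 170.0, 190.0)

    @classmethod
    def late_positivity_window(cls, electrodes=None) -> "WindowSpec":
        return cls(list(electrodes or CENTRAL_CLUSTER), 380.0, 420.0)


@dataclass
class StatMap:
    """Electrode x time grid of paired-t statistics."""

    t: np.ndarray
    df: int
    p: np.ndarray
    sig: np.ndarray
    alpha: float
    channels: list[str]
    times_ms: np.ndarray
    method: str = "pointwise_t"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ch in enumerate(self.channels):
            for j, tm in enumerate(self.times_ms):
                rows.append(
                    dict(
                        electrode=ch,
                        time_ms=tm,
                        t=self.t[i, j],
                        p=self.p[i, j],
                        sig=bool(self.sig[i, j]),
                    )
                )
        return pd.DataFrame(rows)


def _paired_differences(erps: ErpSet, condition_a: str, condition_b: str):
    if len(erps.participants) < 2:
        raise ValueError("paired tests need at least 2 participants")
    ia, ib = erps.condition_index(condition_a), erps.condition_index(condition_b)
    return erps.data[:, ia] - erps.data[:, ib]  # participants x ch x samples


def pointwise_tmap(
    erps: ErpSet, condition_a: str, condition_b: str, alpha: float = 0.01
) -> StatMap:
    """Paired two-sided t at every (electrode, sample) cell; df = n - 1."""
    d = _paired_differences(erps, condition_a, condition_b)
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero_var = sd == 0
    if np.any(zero_var & (mean != 0)):
        warnings.warn(
            "zero-variance cells with nonzero mean: t undefined, "
            "flagged not significant",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, 0.0, mean / (sd / np.sqrt(n)))
    df = n - 1
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(zero_var, 1.0, p)
    return StatMap(t, df, p, p < alpha, alpha, list(erps.channels), erps.times_ms)


class RoiCount(NamedTuple):
    count: int
    n_cells: int


def roi_count(stat_map: StatMap, roi: RoiSpec) -> RoiCount:
    """Number of significant cells in the ROI, plus the grid size."""
    if not roi.electrodes:
        raise ValueError("empty ROI electrode list")
    ch_idx = []
    for name in roi.electrodes:
        try:
            ch_idx.append(stat_map.channels.index(name))
        except ValueError:
            raise KeyError(f"ROI electrode {name!r} not in map") from None
    t_idx = np.flatnonzero(
        (stat_map.times_ms >= roi.t_start_ms) & (stat_map.times_ms < roi.t_end_ms)
    )
    if t_idx.size == 0:
        raise ValueError("ROI window contains no samples")
    cells = stat_map.sig[np.ix_(ch_idx, t_idx)]
    return RoiCount(int(cells.sum()), int(cells.size))


def count_chisq(observed: int, n_tests: int, alpha: float):
    """1-df goodness-of-fit chi-square on {significant, not significant}.

    Expectations are n alpha and n (1 - alpha); invariant to swapping
    the two cells; zero iff observed equals expected.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 <= observed <= n_tests:
        raise ValueError("need 0 <= observed <= n_tests")
    e_sig = n_tests * alpha
    e_ns = n_tests * (1 - alpha)
    chi2 = (observed - e_sig) ** 2 / e_sig + ((n_tests - observed) - e_ns) ** 2 / e_ns
    p = float(stats.chi2.sf(chi2, 1))
    return float(chi2), 1, p


def permutation_tmap(
    erps: ErpSet,
    condition_a: str,
    condition_b: str,
    n_perm: int = 2048,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.01,
) -> StatMap:
    """Sign-flip permutation version of the pointwise t-map.

    Each participant's condition difference is independently negated:
    all 2^n flips are enumerated when n <= 12 (2048 flips at n = 11,
    seed-free and exact), otherwise ``n_perm`` random flips are drawn.
    Two-sided p is the fraction of flips whose |t| reaches the observed
    |t|; the identity flip is always included, so p >= 1/n_flips.
    """
    d = _paired_differences(erps, condition_a, condition_b)
    n = d.shape[0]
    shape = d.shape[1:]
    flat = d.reshape(n, -1)

    if n <= 12:
        k = 2**n
        bits = (np.arange(k)[:, None] >> np.arange(n)[None, :]) & 1
        signs = 1.0 - 2.0 * bits  # k x n of ±1; row of all +1 is index 0
        obs_row = 0
    else:
        if n_perm < 100:
            warnings.warn("fewer than 100 permutations", stacklevel=2)
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        signs[0] = 1.0  # force the identity into the reference set
        obs_row = 0

    sums = signs @ flat  # flips x cells
    ss = (flat**2).sum(axis=0)  # invariant under sign flips
    mean = sums / n
    var = (ss[None, :] - n * mean**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = np.where(var <= 0, 0.0, mean / np.sqrt(var / n))
    t_obs = t_all[obs_row]
    p = (np.abs(t_all) >= np.abs(t_obs)[None, :]).mean(axis=0)
    return StatMap(
        t_obs.reshape(shape),
        n - 1,
        p.reshape(shape),
        (p < alpha).reshape(shape),
        alpha,
        list(erps.channels),
        erps.times_ms,
        method="signflip_permutation",
    )


# ---------------------------------------------------------------------------
# window averages and repeated-measures ANOVA


def window_mean(erps: ErpSet, window: WindowSpec) -> pd.DataFrame:
    """Mean voltage over the window's samples and cluster electrodes.

    Returns a participants x conditions table of scalars (µV).
    """
    ch = erps.channel_indices(window.electrodes)
    ts = erps.sample_window(window.t_start_ms, window.t_end_ms)
    if ts.size == 0:
        raise ValueError("window contains no samples")
    vals = erps.data[:, :, ch][:, :, :, ts].mean(axis=(2, 3))
    return pd.DataFrame(vals, index=erps.participants, columns=erps.conditions)


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float


def rm_anova(
    table: pd.DataFrame,
    dv: str = "value",
    within: list[str] | None = None,
    subject: str = "participant",
) -> list[AnovaResult]:
    """Repeated-measures ANOVA (one or two within-subject factors).

    ``table`` is long-form with one observation per subject x cell; a
    missing or duplicated cell raises (no imputation).  Each effect is
    tested against its own subject-by-effect interaction and reported
    with partial eta squared = SS_effect / (SS_effect + SS_error).  For
    a single 2-level factor, F is exactly the squared paired t.
    """
    within = within or ["condition"]
    if not 1 <= len(within) <= 2:
        raise ValueError("supports one or two within-subject factors")
    cells = table.groupby([subject] + within, observed=True)[dv].count()
    if (cells != 1).any():
        raise ValueError("design must have exactly one observation per cell")

    subjects = sorted(table[subject].unique())
    levels = [sorted(table[f].unique()) for f in within]
    shape = (len(subjects), *[len(lv) for lv in levels])
    y = np.full(shape, np.nan)
    sub_idx = {s: i for i, s in enumerate(subjects)}
    lvl_idx = [{l: i for i, l in enumerate(lv)} for lv in levels]
    for _, row in table.iterrows():
        pos = (sub_idx[row[subject]], *[lvl_idx[k][row[f]] for k, f in enumerate(within)])
        y[pos] = row[dv]
    if np.isnan(y).any():
        raise ValueError("missing cells in the within-subject design")

    n = len(subjects)
    results = []
    if len(within) == 1:
        a = shape[1]
        grand = y.mean()
        a_means = y.mean(axis=0)
        s_means = y.mean(axis=1)
        ss_a = n * ((a_means - grand) ** 2).sum()
        resid = y - a_means[None, :] - s_means[:, None] + grand
        ss_err = (resid**2).sum()
        df_a, df_e = a - 1, (a - 1) * (n - 1)
        results.append(_anova_term(within[0], ss_a, df_a, ss_err, df_e))
    else:
        a, b = shape[1], shape[2]
        grand = y.mean()
        s_m = y.mean(axis=(1, 2))
        a_m = y.mean(axis=(0, 2))
        b_m = y.mean(axis=(0, 1))
        sa_m = y.mean(axis=2)  # subject x A
        sb_m = y.mean(axis=1)  # subject x B
        ab_m = y.mean(axis=0)  # A x B

        ss_a = n * b * ((a_m - grand) ** 2).sum()
        ss_b = n * a * ((b_m - grand) ** 2).sum()
        ss_ab = n * ((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2).sum()
        ss_sa = b * (
            (sa_m - s_m[:, None] - a_m[None, :] + grand) ** 2
        ).sum()
        ss_sb = a * (
            (sb_m - s_m[:, None] - b_m[None, :] + grand) ** 2
        ).sum()
        resid = (
            y
            - sa_m[:, :, None]
            - sb_m[:, None, :]
            - ab_m[None, :, :]
            + s_m[:, None, None]
            + a_m[None, :, None]
            + b_m[None, None, :]
            - grand
        )
        ss_sab = (resid**2).sum()
        results.append(_anova_term(within[0], ss_a, a - 1, ss_sa, (a - 1) * (n - 1)))
        results.append(_anova_term(within[1], ss_b, b - 1, ss_sb, (b - 1) * (n - 1)))
        results.append(
            _anova_term(
                f"{within[0]}*{within[1]}",
                ss_ab,
                (a - 1) * (b - 1),
                ss_sab,
                (a - 1) * (b - 1) * (n - 1),
            )
        )
    return results


def _anova_term(name, ss_eff, df_eff, ss_err, df_err) -> AnovaResult:
    if ss_err == 0:
        f = 0.0 if ss_eff == 0 else np.inf
    else:
        f = (ss_eff / df_eff) / (ss_err / df_err)
    p = float(stats.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
    pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return AnovaResult(name, float(f), int(df_eff), int(df_err), p, float(pes))


def window_anova(
    erps: ErpSet,
    window: WindowSpec,
    conditions: tuple[str, str] = ("rivalry_changed", "rivalry_same"),
) -> AnovaResult:
    """One-factor (changed vs same) rm-ANOVA on the window-mean voltage."""
    wm = window_mean(erps, window)
    long = (
        wm[list(conditions)]
        .reset_index(names="participant")
        .melt(id_vars="participant", var_name="condition", value_name="value")
    )
    return rm_anova(long, dv="value", within=["condition"])[0]
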