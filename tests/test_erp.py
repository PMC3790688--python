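"""ERP averaging and the statistical battery, against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rivalerp.design import make_design, simulate_behavior
from rivalerp.erp import (
    RoiSpec,
    WindowSpec,
    average_erps,
    count_chisq,
    permutation_tmap,
    pointwise_tmap,
    rm_anova,
    roi_count,
    window_anova,
    window_mean,
)
from rivalerp.simulate import EffectParams, simulate_epochs

from conftest import make_erpset


# ---------------------------------------------------------------------------
# averaging


class TestAverageErps:
    def _epochs(self, small_montage, data, conds):
        from rivalerp.preprocessing import EpochSet

        md = pd.DataFrame({"erp_condition": conds})
        times = np.arange(-50, 151) * 2.0
        return EpochSet(
            data, times, list(small_montage.names), list(small_montage.roles),
            500.0, md,
        )

    def test_identical_epochs_average_to_themselves(self, small_montage):
        rng = np.random.default_rng(0)
        one = rng.standard_normal((len(small_montage), 201))
        conds = ["rivalry_changed", "rivalry_changed", "rivalry_same",
                 "fusion_changed", "fusion_same"]
        data = np.stack([one] * 5)
        ep = self._epochs(small_montage, data, conds)
        erps = average_erps({0: ep})
        assert np.allclose(erps.data[0, 0], one)
        assert erps.n_trials.loc[0, "rivalry_changed"] == 2

    def test_opposite_epochs_cancel(self, small_montage):
        v = np.ones((len(small_montage), 201))
        data = np.stack([v, -v, v, v, v])
        conds = ["rivalry_changed"] * 2 + ["rivalry_same", "fusion_changed",
                                           "fusion_same"]
        erps = average_erps({0: self._epochs(small_montage, data, conds)})
        assert np.allclose(erps.data[0, 0], 0.0)

    def test_averaging_shrinks_noise_as_sqrt_n(self, small_montage):
        rng = np.random.default_rng(1)
        sigma, n = 4.0, 50
        data = sigma * rng.standard_normal((n + 3, len(small_montage), 201))
        conds = ["rivalry_changed"] * n + ["rivalry_same", "fusion_changed",
                                           "fusion_same"]
        erps = average_erps({0: self._epochs(small_montage, data, conds)})
        sd = erps.data[0, 0].std()
        assert abs(sd - sigma / np.sqrt(n)) < 0.15 * sigma / np.sqrt(n)

    def test_empty_cell_excludes_participant(self, small_montage):
        rng = np.random.default_rng(2)
        good = self._epochs(
            small_montage,
            rng.standard_normal((4, len(small_montage), 201)),
            ["rivalry_changed", "rivalry_same", "fusion_changed", "fusion_same"],
        )
        bad = self._epochs(
            small_montage,
            rng.standard_normal((3, len(small_montage), 201)),
            ["rivalry_changed", "rivalry_same", "fusion_changed"],
        )
        with pytest.warns(UserWarning, match="excluded"):
            erps = average_erps({0: good, 1: bad})
        assert erps.participants == [0]


# ---------------------------------------------------------------------------
# t-maps and ROI counting


class TestPointwiseTmap:
    def test_identical_conditions_give_zero_t(self):
        erps = make_erpset(np.random.default_rng(0))
        erps.data[:, 1] = erps.data[:, 0]
        m = pointwise_tmap(erps, "rivalry_changed", "rivalry_same")
        assert np.allclose(m.t, 0.0)
        assert np.allclose(m.p, 1.0)
        assert not m.sig.any()
        assert m.df == 10

    def test_constant_positive_difference_gives_positive_t(self):
        erps = make_erpset(np.random.default_rng(1))
        erps.data[:, 0] = erps.data[:, 1] + 2.0 + 0.1 * np.random.default_rng(2).standard_normal(erps.data[:, 0].shape)
        m = pointwise_tmap(erps, "rivalry_changed", "rivalry_same")
        assert (m.t > 0).all()

    def test_matches_scipy_paired_ttest(self):
        from scipy import stats

        erps = make_erpset(np.random.default_rng(3))
        m = pointwise_tmap(erps, "rivalry_changed", "rivalry_same")
        ref = stats.ttest_rel(erps.data[:, 0], erps.data[:, 1], axis=0)
        assert np.allclose(m.t, ref.statistic)
        assert np.allclose(m.p, ref.pvalue)


class TestRoiCount:
    def test_default_roi_has_850_cells(self, montage):
        rng = np.random.default_rng(0)
        erps = make_erpset(
            rng,
            channels=list(montage.scalp_names),
            times_ms=np.arange(-50, 1001) * 2.0,
        )
        m = pointwise_tmap(erps, "rivalry_changed", "rivalry_same")
        roi = RoiSpec.default(montage)
        count, n_cells = roi_count(m, roi)
        assert n_cells == 850  # 10 electrodes x 85 samples
        assert n_cells * roi.alpha == pytest.approx(8.5)

    def test_null_and_saturated_maps(self, montage):
        erps = make_erpset(
            np.random.default_rng(1),
            channels=list(montage.scalp_names),
            times_ms=np.arange(-50, 1001) * 2.0,
        )
        m = pointwise_tmap(erps, "rivalry_changed", "rivalry_same")
        roi = RoiSpec.default(montage)
        m.sig[:] = False
        assert roi_count(m, roi).count == 0
        m.sig[:] = True
        assert roi_count(m, roi) == (850, 850)

    def test_unknown_electrode_rejected(self):
        erps = make_erpset(np.random.default_rng(2))
        m = pointwise_tmap(erps, "rivalry_changed", "rivalry_same")
        with pytest.raises(KeyError):
            roi_count(m, RoiSpec(electrodes=["XX1"]))


class TestCountChisq:
    def test_reported_value_for_34_of_850(self):
        chi2, df, p = count_chisq(34, 850, 0.01)
        assert chi2 == pytest.approx(77.27, abs=0.005)
        assert df == 1
        assert p < 1e-4

    def test_direct_two_cell_evaluation(self):
        chi2, _, _ = count_chisq(17, 850, 0.01)
        assert chi2 == pytest.approx(8.586, abs=0.001)

    def test_zero_when_observed_equals_expected(self):
        chi2, _, p = count_chisq(50, 100, 0.5)
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        n=st.integers(10, 2000),
        o=st.integers(0, 2000),
        alpha=st.floats(0.001, 0.5),
    )
    def test_swap_invariance(self, n, o, alpha):
        """Exchanging the roles of the two cells leaves chi-square fixed,
        and chi-square is zero iff observed equals expected."""
        o = min(o, n)
        chi2, _, _ = count_chisq(o, n, alpha)
        swapped, _, _ = count_chisq(n - o, n, 1 - alpha)
        assert chi2 == pytest.approx(swapped, rel=1e-12, abs=1e-12)
        if abs(o - n * alpha) > 1e-9:
            assert chi2 > 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            count_chisq(5, 10, 1.5)
        with pytest.raises(ValueError):
            count_chisq(11, 10, 0.01)


class TestPermutationTmap:
    def test_identical_conditions_give_p_one(self):
        erps = make_erpset(np.random.default_rng(0), n_participants=6)
        erps.data[:, 1] = erps.data[:, 0]
        m = permutation_tmap(erps, "rivalry_changed", "rivalry_same")
        assert np.allclose(m.p, 1.0)
        assert not m.sig.any()

    def test_distribution_symmetric_under_global_flip(self):
        erps = make_erpset(np.random.default_rng(1), n_participants=8)
        ab = permutation_tmap(erps, "rivalry_changed", "rivalry_same")
        ba = permutation_tmap(erps, "rivalry_same", "rivalry_changed")
        assert np.allclose(ab.t, -ba.t)
        assert np.allclose(ab.p, ba.p)

    def test_full_enumeration_p_floor(self):
        """With n participants fully enumerated, the smallest two-sided p
        is 2/2^n (the observed assignment and its global negation)."""
        rng = np.random.default_rng(2)
        erps = make_erpset(rng, n_participants=8, channels=["POz"],
                           times_ms=np.arange(5) * 2.0)
        erps.data[:, 0] = erps.data[:, 1] + 5.0 + 0.01 * rng.standard_normal(
            erps.data[:, 0].shape
        )
        m = permutation_tmap(erps, "rivalry_changed", "rivalry_same")
        assert np.allclose(m.p, 2 / 2**8)

    def test_agrees_with_bruteforce_enumeration(self):
        """Independent oracle: explicit loop over all sign assignments."""
        rng = np.random.default_rng(3)
        n = 6
        erps = make_erpset(rng, n_participants=n, channels=["POz"],
                           times_ms=np.arange(3) * 2.0)
        d = erps.data[:, 0, 0, :] - erps.data[:, 1, 0, :]

        def t_of(x):
            return x.mean(0) / (x.std(0, ddof=1) / np.sqrt(len(x)))

        t_obs = t_of(d)
        ps = []
        for cell in range(d.shape[1]):
            count = 0
            for signs in itertools.product([1, -1], repeat=n):
                td = t_of(np.asarray(signs)[:, None] * d[:, [cell]])[0]
                if abs(td) >= abs(t_obs[cell]):
                    count += 1
            ps.append(count / 2**n)
        m = permutation_tmap(erps, "rivalry_changed", "rivalry_same")
        assert np.allclose(m.p[0], ps)
        assert np.allclose(m.t[0], t_obs)


# ---------------------------------------------------------------------------
# window means and rm-ANOVA


class TestWindowMean:
    def test_constant_erp(self):
        erps = make_erpset(np.random.default_rng(0))
        erps.data[:] = 2.0
        wm = window_mean(erps, WindowSpec(["POz", "Oz"], 170.0, 190.0))
        assert np.allclose(wm.to_numpy(), 2.0)

    def test_single_cell_window_picks_the_sample(self):
        erps = make_erpset(np.random.default_rng(1))
        w = WindowSpec(["POz"], 100.0, 102.0)  # one sample, half-open
        wm = window_mean(erps, w)
        j = int(np.flatnonzero(erps.times_ms == 100.0)[0])
        assert np.allclose(
            wm.to_numpy(), erps.data[:, :, erps.channels.index("POz"), j]
        )

    def test_window_sample_counts_follow_half_open_rule(self):
        erps = make_erpset(np.random.default_rng(2),
                           times_ms=np.arange(-50, 251) * 2.0)
        assert len(erps.sample_window(170.0, 190.0)) == 10
        assert len(erps.sample_window(380.0, 420.0)) == 20
        assert len(erps.sample_window(80.0, 250.0)) == 85


def brute_force_rm_anova(y):
    """Cell-means sums-of-squares oracle from first principles.

    ``y`` is subjects x A (one factor) or subjects x A x B (two).
    Returns {effect: (ss_eff, df_eff, ss_err, df_err)} via explicit
    loops over the definitional sums, no shared code with the package.
    """
    n = y.shape[0]
    g = y.mean()
    out = {}
    if y.ndim == 2:
        a = y.shape[1]
        ss_a = sum(n * (y[:, i].mean() - g) ** 2 for i in range(a))
        ss_err = 0.0
        for s in range(n):
            for i in range(a):
                ss_err += (y[s, i] - y[:, i].mean() - y[s, :].mean() + g) ** 2
        out["A"] = (ss_a, a - 1, ss_err, (a - 1) * (n - 1))
        return out
    a, b = y.shape[1], y.shape[2]
    ss_a = sum(n * b * (y[:, i, :].mean() - g) ** 2 for i in range(a))
    ss_b = sum(n * a * (y[:, :, j].mean() - g) ** 2 for j in range(b))
    ss_ab = 0.0
    for i in range(a):
        for j in range(b):
            ss_ab += n * (
                y[:, i, j].mean() - y[:, i, :].mean() - y[:, :, j].mean() + g
            ) ** 2
    ss_sa = 0.0
    for s in range(n):
        for i in range(a):
            ss_sa += b * (
                y[s, i, :].mean() - y[s].mean() - y[:, i, :].mean() + g
            ) ** 2
    ss_sb = 0.0
    for s in range(n):
        for j in range(b):
            ss_sb += a * (
                y[s, :, j].mean() - y[s].mean() - y[:, :, j].mean() + g
            ) ** 2
    ss_sab = 0.0
    for s in range(n):
        for i in range(a):
            for j in range(b):
                ss_sab += (
                    y[s, i, j]
                    - y[s, i, :].mean()
                    - y[s, :, j].mean()
                    - y[:, i, j].mean()
                    + y[s].mean()
                    + y[:, i, :].mean()
                    + y[:, :, j].mean()
                    - g
                ) ** 2
    out["A"] = (ss_a, a - 1, ss_sa, (a - 1) * (n - 1))
    out["B"] = (ss_b, b - 1, ss_sb, (b - 1) * (n - 1))
    out["A*B"] = (ss_ab, (a - 1) * (b - 1), ss_sab, (a - 1) * (b - 1) * (n - 1))
    return out


def _long_table(y):
    rows = []
    for s in range(y.shape[0]):
        if y.ndim == 2:
            for i in range(y.shape[1]):
                rows.append(dict(participant=s, A=f"a{i}", value=y[s, i]))
        else:
            for i in range(y.shape[1]):
                for j in range(y.shape[2]):
                    rows.append(
                        dict(participant=s, A=f"a{i}", B=f"b{j}", value=y[s, i, j])
                    )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_hand_computed_three_participant_table(self):
        # {(1,2),(2,4),(3,3)}: SS_cond = 1.5, SS_err = 1.0 -> F(1,2) = 3
        y = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 3.0]])
        res = rm_anova(_long_table(y), within=["A"])[0]
        assert res.F == pytest.approx(3.0)
        assert (res.df_num, res.df_den) == (1, 2)
        assert res.partial_eta_sq == pytest.approx(0.6)

    def test_f_equals_squared_paired_t_for_two_levels(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        y = rng.standard_normal((11, 2))
        res = rm_anova(_long_table(y), within=["A"])[0]
        t = stats.ttest_rel(y[:, 0], y[:, 1])
        assert res.F == pytest.approx(t.statistic**2, rel=1e-12)
        assert res.p == pytest.approx(t.pvalue, rel=1e-12)
        assert (res.df_num, res.df_den) == (1, 10)

    def test_identical_columns_give_zero_f(self):
        y = np.tile(np.arange(4.0)[:, None], (1, 3))
        res = rm_anova(_long_table(y), within=["A"])[0]
        assert res.F == 0.0
        assert res.partial_eta_sq == 0.0

    @pytest.mark.parametrize("shape", [(4, 2), (4, 3), (3, 2, 2), (4, 3, 3), (6, 2, 3)])
    def test_matches_bruteforce_ss_oracle(self, shape):
        rng = np.random.default_rng(sum(shape))
        y = rng.standard_normal(shape) * 3 + 1
        oracle = brute_force_rm_anova(y)
        within = ["A"] if y.ndim == 2 else ["A", "B"]
        results = {r.effect: r for r in rm_anova(_long_table(y), within=within)}
        for eff, (ss_e, df_e, ss_r, df_r) in oracle.items():
            key = eff if y.ndim == 2 else {"A": "A", "B": "B", "A*B": "A*B"}[eff]
            r = results[key]
            f_oracle = (ss_e / df_e) / (ss_r / df_r)
            assert r.F == pytest.approx(f_oracle, rel=1e-10)
            assert r.partial_eta_sq == pytest.approx(ss_e / (ss_e + ss_r), rel=1e-10)
            assert (r.df_num, r.df_den) == (df_e, df_r)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        y = rng.standard_normal((8, 2, 3))
        table = _long_table(y)
        ours = {r.effect: r for r in rm_anova(table, within=["A", "B"])}
        theirs = pg.rm_anova(
            data=table, dv="value", within=["A", "B"], subject="participant",
            detailed=True,
        )
        for _, row in theirs.iterrows():
            name = {"A": "A", "B": "B", "A * B": "A*B"}[row["Source"]]
            assert ours[name].F == pytest.approx(row["F"], rel=1e-8)
            assert ours[name].p == pytest.approx(row["p_unc"], rel=1e-6)

    def test_missing_cell_rejected(self):
        y = np.arange(6.0).reshape(3, 2)
        table = _long_table(y).drop(index=0)
        with pytest.raises(ValueError, match="one observation per cell|missing"):
            rm_anova(table, within=["A"])

    def test_duplicate_cell_rejected(self):
        y = np.arange(6.0).reshape(3, 2)
        table = _long_table(y)
        table = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="one observation"):
            rm_anova(table, within=["A"])


def test_window_anova_detects_injected_effect_only_in_its_window(small_montage):
    """The N1 deepening drives the 170-190 ms posterior window but not an
    early pre-effect window; fusion shows nothing anywhere."""
    trials = simulate_behavior(make_design(2, 40, seed=0), seed=0)
    effects = EffectParams(n1_extra_negativity_uV=3.0, lp_reduction_uV=0.0)
    eps = {
        p: simulate_epochs(trials, effects, small_montage, noise_sd_uV=4.0,
                           seed=100 + p)
        for p in range(11)
    }
    erps = average_erps(eps)
    hit = window_anova(erps, WindowSpec.n1_window())
    assert hit.p < 0.05
    miss = window_anova(erps, WindowSpec(["POz", "Oz"], 20.0, 60.0))
    assert miss.p > 0.01
    fusion = window_anova(
        erps, WindowSpec.n1_window(), ("fusion_changed", "fusion_same")
    )
    assert fusion.p > 0.01
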