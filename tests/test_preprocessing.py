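"""Re-referencing, FIR filtering, epoching, baseline, artifact rejection."""

import numpy as np
import pytest

from rivalerp.montage import Montage
from rivalerp.preprocessing import (
    EpochSet,
    EpochSpec,
    FilterSpec,
    RejectionSpec,
    baseline_correct,
    design_fir,
    epoch,
    filter_apply,
    filter_response_db,
    reject_artifacts,
    rereference,
)
from rivalerp.recording import RawRecording


@pytest.fixture()
def mini_montage():
    return Montage(
        ["Cz", "Oz", "VEOGU", "A1", "A2"],
        ["scalp", "scalp", "eog", "earlobe", "earlobe"],
        np.array(
            [
                [0, 0, 1.0],
                [0, -1.0, 0],
                [0.3, 0.9, 0.2] / np.linalg.norm([0.3, 0.9, 0.2]),
                [-1.0, 0, 0],
                [1.0, 0, 0],
            ]
        ),
    )


def _raw(mini_montage, data, events=()):
    return RawRecording(np.asarray(data, float), 500.0, mini_montage, list(events))


class TestRereference:
    def test_zero_earlobes_leave_data_unchanged(self, mini_montage):
        data = np.vstack([np.arange(10.0)] * 3 + [np.zeros(10)] * 2)
        out = rereference(_raw(mini_montage, data))
        assert np.array_equal(out.data, data)
        assert out.reference_state == "linked_earlobes"

    def test_common_earlobe_signal_subtracted_everywhere(self, mini_montage):
        c = np.sin(np.arange(20.0))
        data = np.vstack([np.zeros(20)] * 3 + [c, c])
        out = rereference(_raw(mini_montage, data))
        assert np.allclose(out.data[:3], -c)
        # earlobes themselves sum to zero after linked-mean subtraction
        assert np.allclose(out.data[3] + out.data[4], 0.0)

    def test_double_rereference_rejected(self, mini_montage):
        raw = _raw(mini_montage, np.zeros((5, 10)))
        once = rereference(raw)
        with pytest.raises(ValueError, match="already"):
            rereference(once)

    def test_missing_earlobes_rejected(self):
        m = Montage(["Cz", "A1"], ["scalp", "earlobe"], [[0, 0, 1.0], [-1, 0, 0]])
        with pytest.raises(ValueError, match="earlobe"):
            rereference(RawRecording(np.zeros((2, 5)), 500.0, m))


class TestFirDesign:
    def test_passband_and_stopband_contract(self):
        h = design_fir(FilterSpec())
        db = filter_response_db(h, [0.0, 10.0, 100.0], 500.0)
        assert abs(db[1]) <= 0.5  # 10 Hz within ±0.5 dB of unity
        assert db[0] <= -50.0  # DC attenuated
        assert db[2] <= -50.0  # beyond the high edge

    def test_exact_linear_phase_symmetry(self):
        h = design_fir(FilterSpec())
        assert np.array_equal(h, h[::-1])

    def test_coefficients_sum_near_zero(self):
        assert abs(design_fir(FilterSpec()).sum()) < 1e-2

    def test_even_taps_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            FilterSpec(n_taps=1856)

    def test_band_limits_validated(self):
        with pytest.raises(ValueError):
            FilterSpec(low_hz=40.0, high_hz=35.0)


class TestFilterApply:
    def test_impulse_centered_at_impulse_sample(self, mini_montage):
        spec = FilterSpec(n_taps=201)
        h = design_fir(spec)
        n, k = 1000, 500
        data = np.zeros((5, n))
        data[0, k] = 1.0
        out = filter_apply(_raw(mini_montage, data), h)
        assert np.allclose(out.data[0, k - 100 : k + 101], h, atol=1e-12)
        assert out.unusable_edge == 100

    def test_dc_offset_removed(self, mini_montage):
        h = design_fir(FilterSpec(n_taps=1857))
        data = np.full((5, 4000), 100.0)
        out = filter_apply(_raw(mini_montage, data), h)
        mid = out.data[0, 1900:2100]
        assert np.max(np.abs(mid)) < 0.5  # ~60 dB below 100 µV

    def test_passband_sine_amplitude_matches_response(self, mini_montage):
        spec = FilterSpec()
        h = design_fir(spec)
        fs, f0 = 500.0, 10.0
        t = np.arange(8000) / fs
        data = np.tile(np.sin(2 * np.pi * f0 * t), (5, 1))
        out = filter_apply(_raw(mini_montage, data), h)
        steady = out.data[0, 3000:5000]
        gain = np.max(np.abs(steady))
        expected = 10 ** (filter_response_db(h, f0, fs)[0] / 20)
        assert abs(gain - expected) < 0.01

    def test_shift_equivariance(self, mini_montage):
        rng = np.random.default_rng(0)
        h = design_fir(FilterSpec(n_taps=101))
        x = rng.standard_normal(600)
        k = 7
        a = np.zeros((5, 800))
        b = np.zeros((5, 800))
        a[0, :600] = x
        b[0, k : 600 + k] = x
        fa = filter_apply(_raw(mini_montage, a), h).data[0]
        fb = filter_apply(_raw(mini_montage, b), h).data[0]
        assert np.allclose(fa[60:500], fb[60 + k : 500 + k], atol=1e-10)

    def test_short_record_rejected(self, mini_montage):
        with pytest.raises(ValueError, match="shorter"):
            filter_apply(_raw(mini_montage, np.zeros((5, 100))), design_fir(FilterSpec()))


class TestEpoching:
    def test_window_has_1051_samples_at_500hz(self, mini_montage):
        raw = _raw(mini_montage, np.zeros((5, 3000)), [(500, 1, "S1_rivalry_changed")])
        ep = epoch(raw, EpochSpec())
        assert ep.data.shape == (1, 5, 1051)
        assert ep.times_ms[0] == -100.0
        assert ep.times_ms[-1] == 2000.0

    def test_boundary_epoch_dropped(self, mini_montage):
        raw = _raw(
            mini_montage,
            np.zeros((5, 3000)),
            [(0, 1, "S1_rivalry_changed"), (600, 2, "S1_rivalry_same")],
        )
        ep = epoch(raw, EpochSpec())
        assert ep.n_trials == 1
        assert ep.rejection_report["n_boundary_dropped"] == 1

    def test_epochs_in_event_order(self, mini_montage):
        data = np.zeros((5, 4000))
        data[0, 500] = 1.0
        data[0, 1500] = 2.0
        raw = _raw(
            mini_montage,
            data,
            [(500, 1, "S1_rivalry_changed"), (1500, 2, "S1_rivalry_same")],
        )
        ep = epoch(raw, EpochSpec())
        assert ep.n_trials == 2
        assert ep.data[0, 0, 50] == 1.0  # t=0 sample of first epoch
        assert ep.data[1, 0, 50] == 2.0

    def test_no_events_rejected(self, mini_montage):
        with pytest.raises(ValueError, match="no locking events"):
            epoch(_raw(mini_montage, np.zeros((5, 3000))), EpochSpec())


class TestBaseline:
    def _epochs(self, data):
        times = np.arange(-50, 151) * 2.0
        import pandas as pd

        return EpochSet(
            data,
            times,
            ["Cz"],
            ["scalp"],
            500.0,
            pd.DataFrame({"i": range(len(data))}),
        )

    def test_constant_epoch_becomes_zero(self):
        ep = self._epochs(np.full((1, 1, 201), 5.0))
        assert np.allclose(baseline_correct(ep).data, 0.0)

    def test_ramp_baseline_mean_zero(self):
        ramp = np.arange(201.0)[None, None, :]
        out = baseline_correct(self._epochs(ramp))
        assert abs(out.data[0, 0, :51].mean()) < 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        ep = self._epochs(rng.standard_normal((3, 1, 201)))
        once = baseline_correct(ep)
        twice = baseline_correct(once)
        assert np.allclose(once.data, twice.data)


class TestRejection:
    def _epochs(self, mini_montage, data):
        import pandas as pd

        times = np.arange(-50, 151) * 2.0
        return EpochSet(
            data,
            times,
            list(mini_montage.names),
            list(mini_montage.roles),
            500.0,
            pd.DataFrame({"i": range(len(data))}),
        )

    def test_clean_epochs_kept(self, mini_montage):
        ep = self._epochs(mini_montage, np.zeros((4, 5, 201)))
        assert reject_artifacts(ep).keep_mask.all()

    def test_eog_spike_rejected(self, mini_montage):
        data = np.zeros((2, 5, 201))
        data[1, 2, 100] = 200.0  # 200 µV spike on the EOG channel
        out = reject_artifacts(self._epochs(mini_montage, data))
        assert list(out.keep_mask) == [True, False]
        assert out.rejection_report["n_rejected_eog"] == 1

    def test_scalp_threshold_between_bounds(self, mini_montage):
        data = np.zeros((1, 5, 201))
        data[0, 0, 100] = 100.0  # 100 µV scalp excursion: > 60, < 150
        out = reject_artifacts(self._epochs(mini_montage, data))
        assert out.keep_mask.all()
        data[0, 0, 100] = 160.0
        out = reject_artifacts(self._epochs(mini_montage, data))
        assert not out.keep_mask.any()

    def test_infinite_thresholds_keep_everything(self, mini_montage):
        rng = np.random.default_rng(0)
        data = 500 * rng.standard_normal((6, 5, 201))
        ep = self._epochs(mini_montage, data)
        out = reject_artifacts(ep, RejectionSpec(np.inf, np.inf))
        assert np.array_equal(out.keep_mask, ep.keep_mask)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotonicity_in_thresholds(self, mini_montage, seed):
        rng = np.random.default_rng(seed)
        ep = self._epochs(mini_montage, 80 * rng.standard_normal((20, 5, 201)))
        kept = [
            reject_artifacts(ep, RejectionSpec(e, s)).keep_mask.sum()
            for e, s in [(30, 80), (60, 150), (120, 300), (1e6, 1e6)]
        ]
        assert kept == sorted(kept)
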