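import numpy as np
import pandas as pd
import pytest

from adtfnet import (EpochedEEG, PipelineConfig, paired_t_with_d,
                     peak_measures, preprocess_epochs, rm_anova_2x2,
                     simulate_n170_cohort)


@pytest.fixture
def cfg():
    return PipelineConfig()


def make_epochs(rng, n_ch=3, n_trials=6, amp=10.0, names=("a", "b", "c")):
    return EpochedEEG(rng.normal(0, amp, (n_ch, 300, n_trials)), 250.0,
                      names, tmin_ms=-200.0)


class TestPreprocess:
    def test_excursion_rejected(self, cfg, rng):
        eeg = make_epochs(rng, amp=5.0)
        eeg.data[1, 50, 2] = 100.0  # one bad trial
        out = preprocess_epochs(eeg, cfg)
        assert out.n_trials == eeg.n_trials - 1

    def test_constant_channel_zero_after_baseline(self, cfg):
        data = np.zeros((2, 300, 1))
        data[0] = 5.0
        data[1] = np.linspace(0, 1, 300)[None, :, None][0]
        eeg = EpochedEEG(data, 250.0, ("flat", "ramp"), tmin_ms=-200.0)
        out = preprocess_epochs(eeg, cfg)
        assert np.allclose(out.data[0], 0.0)

    def test_survivor_count_matches_brute_force(self, cfg, rng):
        eeg = make_epochs(rng, n_trials=40, amp=18.0)
        out = preprocess_epochs(eeg, cfg)
        brute = sum(
            1 for r in range(40)
            if np.abs(eeg.data[:, :, r]).max() <= cfg.reject_threshold)
        assert out.n_trials == brute

    def test_eog_trials_rejected_and_channel_dropped(self, cfg, rng):
        eeg = make_epochs(rng, amp=5.0, names=("a", "b", "EOG"))
        eeg.data[2, 10, 0] = 90.0  # blink on trial 0 only
        out = preprocess_epochs(eeg, cfg, eog=("EOG",))
        assert out.ch_names == ("a", "b")
        assert out.n_trials == eeg.n_trials - 1

    def test_all_rejected_raises(self, cfg):
        eeg = EpochedEEG(np.full((2, 300, 3), 80.0), 250.0, ("a", "b"),
                         tmin_ms=-200.0)
        with pytest.raises(RuntimeError, match="rejected"):
            preprocess_epochs(eeg, cfg)


class TestPeakMeasures:
    def _erp(self, wave):
        data = np.zeros((1, 300, 1))
        data[0, :, 0] = wave
        return EpochedEEG(data, 250.0, ("P8",), tmin_ms=-200.0)

    def test_constructed_trough(self):
        erp = self._erp(np.zeros(300))
        t_idx = int((172.0 - (-200.0)) / 4.0)
        erp.data[0, t_idx, 0] = -6.2
        m = peak_measures(erp, "P8", window=(160, 180))
        assert m.peak_amplitude == pytest.approx(-6.2)
        assert m.peak_latency == pytest.approx(172.0)

    def test_monotone_segment_latency_at_window_start(self):
        erp = self._erp(np.linspace(-5, 5, 300))
        m = peak_measures(erp, "P8", window=(160, 180))
        assert m.peak_latency == pytest.approx(160.0)

    def test_tie_breaks_to_earliest(self):
        erp = self._erp(np.zeros(300))
        for t_ms in (168.0, 176.0):
            erp.data[0, int((t_ms + 200.0) / 4.0), 0] = -3.0
        m = peak_measures(erp, "P8", window=(160, 180))
        assert m.peak_latency == pytest.approx(168.0)

    def test_missing_channel(self):
        with pytest.raises(KeyError):
            peak_measures(self._erp(np.zeros(300)), "Cz")


class TestPairedT:
    def test_identical_samples(self):
        t, p, d = paired_t_with_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and d == 0.0

    def test_constant_nonzero_difference_is_error(self):
        with pytest.raises(ZeroDivisionError):
            paired_t_with_d([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])

    def test_matches_hand_computation(self):
        x = np.array([51.0, 45.0, 33.0, 57.0, 49.0, 38.0])
        y = np.array([42.0, 41.0, 35.0, 45.0, 38.0, 40.0])
        diff = x - y
        t_hand = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        d_hand = diff.mean() / diff.std(ddof=1)
        t, p, d = paired_t_with_d(x, y)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert d == pytest.approx(d_hand, abs=1e-10)
        assert 0 < p < 1


class TestRmAnova:
    def _table(self, values):
        rows = []
        for s, per_subject in enumerate(values):
            for (ref, stim), v in per_subject.items():
                rows.append(dict(subject=f"s{s}", reference=ref,
                                 stimulus=stim, value=v))
        return pd.DataFrame(rows)

    def test_identical_values_give_zero_f(self):
        cells = {(r, s): 1.0 for r in ("AR", "REST")
                 for s in ("face", "letter")}
        out = rm_anova_2x2(self._table([cells] * 5))
        assert np.allclose(out["F"], 0.0)

    def test_pure_additive_effects(self):
        out_rows = []
        for s in range(6):
            cells = {}
            for ri, r in enumerate(("AR", "REST")):
                for si, st in enumerate(("face", "letter")):
                    cells[(r, st)] = 10.0 + s + 3.0 * ri + 5.0 * si
            out_rows.append(cells)
        out = rm_anova_2x2(self._table(out_rows)).set_index("Source")
        assert out.loc["reference", "partial_eta_sq"] == pytest.approx(1.0)
        assert out.loc["stimulus", "partial_eta_sq"] == pytest.approx(1.0)
        assert out.loc["reference * stimulus", "F"] == pytest.approx(0.0,
                                                                     abs=1e-8)

    def test_matches_hand_sums_of_squares(self, rng):
        """Independent oracle: explicit SS decomposition of the 2x2
        fully-repeated design on a 4-subject toy table."""
        vals = rng.normal(10, 2, size=(4, 2, 2))  # subject x ref x stim
        rows = []
        for s in range(4):
            for ri, r in enumerate(("AR", "REST")):
                for si, st in enumerate(("face", "letter")):
                    rows.append(dict(subject=f"s{s}", reference=r,
                                     stimulus=st, value=vals[s, ri, si]))
        out = rm_anova_2x2(pd.DataFrame(rows)).set_index("Source")

        grand = vals.mean()
        n_s = 4
        # main effect A (reference)
        a_means = vals.mean(axis=(0, 2))
        ss_a = n_s * 2 * ((a_means - grand) ** 2).sum()
        sa_means = vals.mean(axis=2)  # subject x ref
        s_means = vals.mean(axis=(1, 2))
        ss_as = 2 * ((sa_means - s_means[:, None] - a_means[None, :]
                      + grand) ** 2).sum()
        f_a = (ss_a / 1) / (ss_as / (n_s - 1))
        eta_a = ss_a / (ss_a + ss_as)
        assert out.loc["reference", "F"] == pytest.approx(f_a, abs=1e-8)
        assert out.loc["reference", "partial_eta_sq"] == pytest.approx(
            eta_a, abs=1e-8)
        # interaction
        ab_means = vals.mean(axis=0)
        b_means = vals.mean(axis=(0, 1))
        ss_ab = n_s * ((ab_means - a_means[:, None] - b_means[None, :]
                        + grand) ** 2).sum()
        resid = (vals - sa_means[:, :, None]
                 - vals.mean(axis=1)[:, None, :] + s_means[:, None, None]
                 - ab_means[None] + a_means[None, :, None]
                 + b_means[None, None, :] - grand)
        ss_abs = (resid ** 2).sum()
        f_ab = (ss_ab / 1) / (ss_abs / (n_s - 1))
        assert out.loc["reference * stimulus", "F"] == pytest.approx(
            f_ab, abs=1e-8)

    def test_incomplete_design_rejected(self):
        cells = {(r, s): 1.0 for r in ("AR", "REST")
                 for s in ("face", "letter")}
        table = self._table([cells] * 4).iloc[:-1]
        with pytest.raises(ValueError, match="balanced"):
            rm_anova_2x2(table)


class TestCohortLatencyRecovery:
    def test_reference_offset_detected(self):
        """The generator's built-in AR-minus-REST latency offset is
        recovered by the peak-latency paired t (direction REST earlier)."""
        subjects, _ = simulate_n170_cohort(n_subjects=15, n_trials=40, seed=11)
        ar = [peak_measures(s["face"]["AR"], "P8").peak_latency
              for s in subjects]
        rest = [peak_measures(s["face"]["REST"], "P8").peak_latency
                for s in subjects]
        t, p, d = paired_t_with_d(ar, rest)
        assert t > 0 and np.mean(ar) > np.mean(rest)
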