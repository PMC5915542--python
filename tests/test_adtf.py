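import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from adtfnet import (ADTFTensor, EpochedEEG, band_grid, empirical_edge_pvalues,
                     fit_mvaar_kalman, integrated_adtf, network_from_adtf,
                     normalized_adtf, phase_randomize, simulate_sources,
                     surrogate_null, threshold_network, threshold_single,
                     transfer_function)
from adtfnet.mvar import TransferFunction
from tests.test_mvar import stationary_model


def tf_from_h(H, freqs):
    return TransferFunction(H=H, freqs=np.asarray(freqs, dtype=float),
                            sfreq=250.0,
                            ch_names=tuple(f"c{i}" for i in range(H.shape[-1])))


class TestNormalizedADTF:
    def test_diagonal_h_gives_identity_pattern(self):
        H = np.tile((np.eye(3) * (1 + 2j))[None, None], (2, 4, 1, 1))
        iota = normalized_adtf(tf_from_h(H, [4.0, 5.0])).iota2
        assert np.allclose(iota, np.tile(np.eye(3)[None, None], (2, 4, 1, 1)))

    def test_rows_sum_to_one_and_bounded(self, rng):
        H = rng.normal(size=(3, 10, 4, 4)) + 1j * rng.normal(size=(3, 10, 4, 4))
        iota = normalized_adtf(tf_from_h(H, [4.0, 5.0, 6.0])).iota2
        assert np.abs(iota.sum(axis=-1) - 1.0).max() < 1e-8
        assert iota.min() >= 0.0 and iota.max() <= 1.0

    def test_true_system_flows_one_way_in_band(self):
        """The analytic H of the causal system yields zero reverse ADTF and
        strictly positive forward ADTF at every band frequency."""
        A1 = np.array([[0.9, 0.0], [0.0, 0.0]])
        A2 = np.array([[-0.9, 0.0], [0.5, 0.0]])
        H = transfer_function(stationary_model([A1, A2]), band_grid(4, 10),
                              250.0)
        iota = normalized_adtf(H).iota2
        assert np.abs(iota[..., 0, 1]).max() == 0.0   # S2 -> S1 absent
        assert iota[..., 1, 0].min() > 0.0            # S1 -> S2 present

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(hnp.arrays(np.float64, (2, 3, 3, 3),
                      elements=st.floats(-5, 5, allow_nan=False)),
           hnp.arrays(np.float64, (2, 3, 3, 3),
                      elements=st.floats(-5, 5, allow_nan=False)))
    def test_row_normalization_property(self, re, im):
        """For any finite H without an all-zero row, ADTF values lie in
        [0, 1] and every (receiver, frequency, time) row sums to one."""
        H = re + 1j * im
        rowsums = (np.abs(H) ** 2).sum(axis=-1)
        if np.any(rowsums == 0):
            return
        iota = normalized_adtf(tf_from_h(H, [4.0, 5.0])).iota2
        assert iota.min() >= 0.0 and iota.max() <= 1.0 + 1e-12
        assert np.abs(iota.sum(axis=-1) - 1.0).max() < 1e-8

    def test_zero_row_rejected(self):
        H = np.zeros((1, 1, 2, 2), dtype=complex)
        H[..., 1, 1] = 1.0
        with pytest.raises(ValueError, match="zero"):
            normalized_adtf(tf_from_h(H, [4.0]))


class TestIntegratedADTF:
    def _tensor(self, iota, freqs):
        return ADTFTensor(iota2=iota, freqs=np.asarray(freqs, dtype=float),
                          ch_names=("a", "b"))

    def test_constant_band_mean_is_constant(self):
        iota = np.full((3, 5, 2, 2), 0.25)
        out = integrated_adtf(self._tensor(iota, [4.0, 5.0, 6.0]), 4, 6)
        assert np.allclose(out.theta2, 0.25)

    def test_single_frequency_band(self, rng):
        iota = rng.uniform(size=(3, 5, 2, 2))
        out = integrated_adtf(self._tensor(iota, [4.0, 5.0, 6.0]), 5, 5)
        assert np.allclose(out.theta2, iota[1])

    def test_empty_band_rejected(self, rng):
        iota = rng.uniform(size=(2, 5, 2, 2))
        with pytest.raises(ValueError, match="band|frequencies"):
            integrated_adtf(self._tensor(iota, [4.0, 5.0]), 7.0, 9.0)


class TestPhaseRandomize:
    def test_amplitude_spectrum_preserved(self, rng):
        x = rng.normal(size=(4, 251))
        surr = phase_randomize(x, seed=3)
        assert np.abs(np.abs(np.fft.rfft(surr)) -
                      np.abs(np.fft.rfft(x))).max() < 1e-10

    def test_seed_reproducibility(self, rng):
        x = rng.normal(size=(2, 100))
        assert np.array_equal(phase_randomize(x, seed=5),
                              phase_randomize(x, seed=5))
        assert not np.allclose(phase_randomize(x, seed=5),
                               phase_randomize(x, seed=6))

    def test_destroys_cross_channel_coupling(self, rng):
        """A near-deterministically lag-coupled pair decorrelates in the
        surrogates (mean |r| at the coupling lag drops toward zero)."""
        x1 = rng.normal(size=2000)
        x2 = np.roll(x1, 2) + 0.1 * rng.normal(size=2000)
        x = np.vstack([x1, x2])
        r0 = np.corrcoef(x1[:-2], x2[2:])[0, 1]
        assert abs(r0) > 0.9
        rs = []
        for seed in range(50):
            s = phase_randomize(x, seed=seed)
            rs.append(np.corrcoef(s[0, :-2], s[1, 2:])[0, 1])
        assert np.abs(np.mean(rs)) < 0.2
        assert np.mean(np.abs(rs)) < 0.2


class TestSurrogateNull:
    def test_single_surrogate(self):
        S = simulate_sources(300, seed=0)
        null = surrogate_null(S, p=2, n_surrogates=1, seed=0, fs=250.0)
        assert null.shape == (1, 300, 2, 2)

    def test_null_covers_uncoupled_observations(self, rng):
        """On independent channels the observed flow behaves like a draw
        from its own surrogate null for the large majority of cells."""
        inside = []
        for seed in range(5):
            g = np.random.default_rng(seed)
            x = g.normal(size=(3, 400))
            eeg = EpochedEEG(x, 250.0, ("a", "b", "c"))
            model = fit_mvaar_kalman(eeg, p=2, uc=1e-3)
            H = transfer_function(model, band_grid(4, 10), 250.0)
            theta = integrated_adtf(normalized_adtf(H), 4, 10).theta2
            null = surrogate_null(eeg, p=2, n_surrogates=100, seed=seed)
            lo = np.quantile(null, 0.025, axis=0)
            hi = np.quantile(null, 0.975, axis=0)
            off = ~np.eye(3, dtype=bool)
            # evaluate after the Kalman warm-up (initialization-dominated
            # estimates carry no calibration information)
            ok = ((theta >= lo) & (theta <= hi))[100:, :, :][:, off]
            inside.append(ok.mean())
        assert np.mean(inside) > 0.9

    def test_true_edge_exceeds_null(self):
        """The causal system's forward edge clears the null's 95th
        percentile at most timepoints."""
        S = simulate_sources(1200, seed=4)
        model = fit_mvaar_kalman(S, p=2, uc=1e-3)
        H = transfer_function(model, band_grid(4, 10), 250.0)
        theta = integrated_adtf(normalized_adtf(H), 4, 10).theta2
        null = surrogate_null(S, p=2, n_surrogates=100, seed=4, fs=250.0)
        q95 = np.quantile(null, 0.95, axis=0)
        assert (theta[2:, 1, 0] > q95[2:, 1, 0]).mean() > 0.5


class TestThresholding:
    def test_identical_observed_and_null_not_significant(self, rng):
        obs = rng.uniform(0.1, 0.5, size=(4, 3, 3))
        null = np.tile(obs[None], (50, 1, 1, 1))
        net = threshold_single(obs, null, ("a", "b", "c"),
                               [0.0, 4.0, 8.0, 12.0], alpha=0.05)
        assert not net.sig_mask.any()

    def test_mask_monotone_in_alpha(self, rng):
        obs = rng.uniform(0.1, 0.9, size=(6, 3, 3))
        null = rng.uniform(0.0, 0.6, size=(100, 6, 3, 3))
        times = np.arange(6) * 4.0
        strict = threshold_single(obs, null, ("a", "b", "c"), times,
                                  alpha=0.01)
        loose = threshold_single(obs, null, ("a", "b", "c"), times,
                                 alpha=0.05)
        assert not (strict.sig_mask & ~loose.sig_mask).any()

    def test_empirical_pvalues_match_rank_definition(self, rng):
        obs = rng.uniform(size=(2, 2, 2))
        null = rng.uniform(size=(40, 2, 2, 2))
        p = empirical_edge_pvalues(obs, null)
        brute = np.empty_like(obs)
        for t in range(2):
            for i in range(2):
                for j in range(2):
                    brute[t, i, j] = (1 + (null[:, t, i, j] >=
                                           obs[t, i, j]).sum()) / 41
        assert np.allclose(p, brute)

    def test_network_invariants(self, rng):
        w = rng.uniform(size=(3, 4, 4))
        m = np.ones((3, 4, 4), dtype=bool)
        net = network_from_adtf(w, tuple("abcd"), np.arange(3) * 4.0,
                                sig_mask=m)
        idx = np.arange(4)
        assert np.all(net.weights[:, idx, idx] == 0)
        assert not net.sig_mask[:, idx, idx].any()
        assert not (net.sig_mask & ~(net.weights > 0)).any()


class TestGroupThreshold:
    """Across-subject Wilcoxon thresholding, checked against the exact
    signed-rank tail: with all n subjects showing a positive offset and no
    ties, the one-sided p is 2^-n, Bonferroni-scaled by the 342 directed
    edges of a 19-node network."""

    def _stacks(self, n_subj, rng, offset_edge=(1, 0), offset=0.5):
        T, n = 1, 19
        obs, nulls = [], []
        for s in range(n_subj):
            base = rng.uniform(0.1, 0.2, size=(T, n, n))
            null = np.tile(base[None], (20, 1, 1, 1))
            o = base.copy()
            # distinct per-subject increments avoid rank ties
            o[0, offset_edge[0], offset_edge[1]] += offset * (1 + 0.01 * s)
            obs.append(o)
            nulls.append(null)
        return obs, nulls

    def test_exact_tail_sixteen_subjects_significant_at_001(self, rng):
        obs, nulls = self._stacks(16, rng)
        net = threshold_network(obs, nulls, tuple(f"n{i}" for i in range(19)),
                                [0.0], alpha=0.01)
        # exact one-sided tail: 2^-16 * 342 = 0.0052 < 0.01
        assert net.sig_mask[0, 1, 0]
        assert net.sig_mask.sum() == 1

    def test_exact_tail_twelve_subjects_not_significant(self, rng):
        # 2^-12 * 342 = 0.084 exceeds even alpha = 0.05
        obs, nulls = self._stacks(12, rng)
        net = threshold_network(obs, nulls, tuple(f"n{i}" for i in range(19)),
                                [0.0], alpha=0.05)
        assert not net.sig_mask.any()

    def test_scipy_exact_tail_agreement(self):
        d = 0.5 * (1 + 0.01 * np.arange(16))
        p = stats.wilcoxon(d, alternative="greater").pvalue
        assert p == pytest.approx(2.0**-16, rel=1e-10)

    def test_too_few_subjects_rejected(self, rng):
        obs, nulls = self._stacks(4, rng)
        with pytest.raises(ValueError, match="6 subjects"):
            threshold_network(obs, nulls, tuple(f"n{i}" for i in range(19)),
                              [0.0])
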