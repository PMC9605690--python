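import numpy as np
import pytest

from dnpop.events import (
    Event,
    correlation_analysis,
    event_triggered_average,
    extract_isolated_events,
    lagged_correlation,
    ward_ordering,
)
from dnpop.signals import make_crf_kernel


def label_series(spans, n, fs=100.0):
    labels = np.full(n, "resting")
    for s, e in spans:
        labels[int(s * fs) : int(e * fs)] = "walking"
    return labels, np.arange(n) / fs


class TestEventExtraction:
    def test_empty_labels_empty_set(self):
        labels, times = label_series([], 1000)
        assert extract_isolated_events(labels, times, "walking") == []

    def test_event_too_close_to_previous_excluded(self):
        # second epoch starts 0.5 s after the first ends
        labels, times = label_series([(2.0, 4.0), (4.5, 6.0)], 1000)
        evs = extract_isolated_events(labels, times, "walking")
        assert len(evs) == 1
        assert evs[0].onset == pytest.approx(2.0)

    def test_isolated_events_kept(self):
        labels, times = label_series([(2.0, 3.0), (4.5, 6.0)], 1000)
        evs = extract_isolated_events(labels, times, "walking")
        assert len(evs) == 2

    def test_block_truncated_by_epoch_end(self):
        labels, times = label_series([(2.0, 4.0)], 1000)
        ev = extract_isolated_events(labels, times, "walking")[0]
        assert ev.block == (pytest.approx(1.0), pytest.approx(4.0))

    def test_long_epoch_block_capped_at_4s(self):
        labels, times = label_series([(2.0, 9.0)], 1000)
        ev = extract_isolated_events(labels, times, "walking")[0]
        assert ev.block[1] == pytest.approx(6.0)

    def test_onset_without_pre_window_excluded(self):
        labels, times = label_series([(0.2, 3.0)], 1000)
        assert extract_isolated_events(labels, times, "walking") == []


class TestEventTriggeredAverage:
    def test_identical_blocks_average_to_block(self):
        fs = 16.4
        n = 2000
        times = np.arange(n) / fs
        sig = np.zeros((1, n))
        onsets = [20.0, 40.0, 60.0]
        pulse = np.sin(np.linspace(0, np.pi, 30))
        for o in onsets:
            k = int(round(o * fs))
            sig[0, k : k + 30] = pulse
        events = [Event("walking", o, o + 10.0, 0) for o in onsets]
        out = event_triggered_average(sig, times, events, mode="trace")
        at = np.searchsorted(out["time"], 0.0)
        assert np.allclose(out["mean"][0, at : at + 30], pulse, atol=1e-6)
        assert out["n"][at] == 3

    def test_noisy_crf_response_recovered(self):
        rng = np.random.default_rng(0)
        fs = 16.4
        k = make_crf_kernel(dt=1 / fs, t_max=4.0)
        shape = k.samples[: int(4 * fs)] / k.samples.max()
        n_events = 100
        spacing = 8.0
        n = int((n_events + 2) * spacing * fs)
        times = np.arange(n) / fs
        sig = np.zeros(n)
        onsets = []
        for i in range(n_events):
            o = (i + 1) * spacing
            onsets.append(o)
            idx = int(round(o * fs))
            sig[idx : idx + shape.size] += shape
        sigma = 0.2
        sig = sig + sigma * rng.standard_normal(n)
        events = [Event("walking", o, o + 4.0, 0) for o in onsets]
        out = event_triggered_average(sig[None, :], times, events, mode="trace")
        at = np.searchsorted(out["time"], 0.0)
        est = out["mean"][0, at : at + shape.size]
        assert np.abs(est - shape).max() < 3 * sigma / np.sqrt(n_events) * 3

    def test_white_noise_average_near_zero(self):
        rng = np.random.default_rng(1)
        fs = 16.4
        n = 20000
        sig = rng.standard_normal((1, n))
        times = np.arange(n) / fs
        events = [Event("walking", float(o), float(o) + 4.0, 0) for o in range(20, 1100, 10)]
        out = event_triggered_average(sig, times, events, mode="trace")
        bound = 4.0 / np.sqrt(out["n"].min())
        assert np.abs(out["mean"]).max() < bound

    def test_pixel_mode_discard_rule(self):
        fs = 16.4
        n = 40000
        sig = np.zeros((2, n))
        times = np.arange(n) / fs
        events = [Event("walking", float(o), float(o) + 4.0, 0) for o in range(20, 20 + 49 * 10, 10)]
        out = event_triggered_average(sig, times, events, mode="pixel")
        assert len(events) == 49
        assert out["discarded"]
        events.append(Event("walking", 2000.0, 2004.0, 0))
        out = event_triggered_average(sig, times, events, mode="pixel")
        assert not out["discarded"]

    def test_pixel_mode_rebaselines_blocks(self):
        fs = 16.4
        n = 4000
        times = np.arange(n) / fs
        sig = np.full((1, n), 7.0)  # constant offset must vanish
        events = [Event("walking", 50.0, 54.0, 0), Event("walking", 100.0, 104.0, 0)]
        out = event_triggered_average(sig, times, events, mode="pixel")
        assert np.allclose(out["mean"][0][out["n"] > 0], 0.0, atol=1e-9)


class TestCorrelations:
    def test_self_correlation_peaks_at_zero_lag(self):
        rng = np.random.default_rng(2)
        from scipy.ndimage import gaussian_filter1d

        x = gaussian_filter1d(rng.standard_normal(3000), 5.0)
        lags, rs, best = lagged_correlation(x, x, 20)
        assert best == 0
        assert rs[lags == 0] == pytest.approx(1.0)

    def test_shifted_copy_recovered(self):
        rng = np.random.default_rng(3)
        from scipy.ndimage import gaussian_filter1d

        x = gaussian_filter1d(rng.standard_normal(5000), 5.0)
        y = np.roll(x, 3)
        lags, rs, best = lagged_correlation(x, y, 10)
        assert best == 3

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(4)
        mats = [rng.standard_normal((2, 5000))]
        corr = correlation_analysis(mats)["neuron_corr"]
        assert abs(corr[0, 1]) < 0.05

    def test_trial_averaged_matrix_properties(self, small_fly):
        corr = correlation_analysis([t.traces.values for t in small_fly.trials])["neuron_corr"]
        assert np.allclose(corr, corr.T, atol=1e-12)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.nanmax(np.abs(corr)) <= 1.0 + 1e-12


class TestWardClustering:
    def _block_corr(self, seed=5):
        rng = np.random.default_rng(seed)
        from scipy.ndimage import gaussian_filter1d

        base1 = gaussian_filter1d(rng.standard_normal(4000), 10.0)
        base2 = -0.6 * base1 + gaussian_filter1d(rng.standard_normal(4000), 10.0) * 0.5
        traces = np.vstack(
            [base1 + 0.3 * rng.standard_normal(4000) for _ in range(4)]
            + [base2 + 0.3 * rng.standard_normal(4000) for _ in range(4)]
        )
        return np.corrcoef(traces)

    def test_perfectly_correlated_pair_merges_first(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(500)
        traces = np.vstack([x, x, rng.standard_normal(500)])
        out = ward_ordering(np.corrcoef(traces))
        assert out["linkage"][0, 2] == pytest.approx(0.0, abs=1e-9)
        assert set(out["linkage"][0, :2].astype(int)) == {0, 1}

    def test_anticorrelated_groups_separate_in_leaf_order(self):
        out = ward_ordering(self._block_corr())
        order = list(out["leaf_order"])
        groups = [0 if i < 4 else 1 for i in order]
        # contiguous blocks: exactly one switch point
        assert sum(a != b for a, b in zip(groups, groups[1:])) == 1

    def test_merge_heights_non_decreasing(self):
        out = ward_ordering(self._block_corr(7))
        heights = out["linkage"][:, 2]
        assert (np.diff(heights) >= -1e-9).all()

    def test_label_equivariance_under_permutation(self):
        corr = self._block_corr(8)
        perm = np.array([3, 1, 6, 0, 7, 2, 5, 4])
        out1 = ward_ordering(corr)
        out2 = ward_ordering(corr[np.ix_(perm, perm)])
        # permuted input yields the same partition at the 2-cluster level
        from scipy.cluster.hierarchy import fcluster

        c1 = fcluster(out1["linkage"], 2, criterion="maxclust")
        c2 = fcluster(out2["linkage"], 2, criterion="maxclust")
        remapped = np.empty(8, dtype=int)
        remapped[perm] = c2
        same = (remapped == c1).all() or ((3 - remapped) == c1).all()
        assert same

    def test_masked_entries_imputed_with_warning(self):
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = np.nan
        with pytest.warns(UserWarning):
            out = ward_ordering(corr)
        assert out["linkage"].shape == (2, 4)
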