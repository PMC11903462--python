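"""Window extraction, offset labeling, normalization, noise, splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scistats

from eegnda.errors import ConfigurationError, SizingError
from eegnda.sampling import (
    NoiseSpec,
    WindowSpec,
    add_gaussian_noise,
    label_index,
    normalize,
    sample_windows,
    split,
)
from eegnda.synthdata import EEGRecording, EventTimeline


class TestNormalize:
    def test_zscore_definition(self, toy_recording):
        rec, _ = toy_recording
        out, (mu, sd) = normalize(rec)
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data.std(axis=1), 1.0, atol=1e-12)

    def test_constant_channel_maps_to_zero(self):
        data = np.vstack([np.full(100, 3.7), np.arange(100.0)])
        out, (mu, sd) = normalize(EEGRecording(data, 500.0))
        assert (out.data[0] == 0).all()
        assert sd[0] == 0

    def test_stored_stats_match_elementwise_formula(self, toy_recording):
        rec, _ = toy_recording
        idx = np.arange(0, 2000)
        _, (mu, sd) = normalize(rec, stats_from=idx)
        held_out = EEGRecording(rec.data[:, 2000:], 500.0)
        out, _ = normalize(held_out, stats=(mu, sd))
        expected = (rec.data[:, 2000:] - mu[:, None]) / sd[:, None]
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_empty_stats_from_rejected(self, toy_recording):
        rec, _ = toy_recording
        with pytest.raises(ConfigurationError):
            normalize(rec, stats_from=np.array([], dtype=int))


class TestLabelIndex:
    @pytest.mark.parametrize(
        "start,n,offset,expected",
        [
            (0, 100, 0.0, 0),
            (0, 100, 1.0, 99),
            (0, 101, 0.5, 50),
            (7, 100, 0.5, 7 + 49),  # floor(0.5 * 99) = 49
        ],
    )
    def test_examples(self, start, n, offset, expected):
        assert label_index(start, n, offset) == expected

    @given(
        start=st.integers(0, 10**6),
        n=st.integers(1, 10**4),
        offset=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_always_inside_window(self, start, n, offset):
        idx = label_index(start, n, offset)
        assert start <= idx <= start + n - 1

    def test_offset_out_of_range(self):
        with pytest.raises(ConfigurationError):
            label_index(0, 10, 1.5)


class TestSampleWindows:
    def test_bounds_and_determinism(self, toy_recording):
        rec, tl = toy_recording
        spec = WindowSpec(n_samples=200, offset=0.5, count=500, seed=3)
        a = sample_windows(rec, tl, spec)
        b = sample_windows(rec, tl, spec)
        assert (a.starts >= 0).all() and (a.starts <= rec.n_samples - 200).all()
        np.testing.assert_array_equal(a.starts, b.starts)
        np.testing.assert_array_equal(a.data, b.data)
        c = sample_windows(rec, tl, WindowSpec(200, 0.5, 500, seed=4))
        assert (a.starts != c.starts).any()

    def test_labels_read_at_offset_index(self, toy_recording):
        rec, tl = toy_recording
        for offset in (0.0, 0.5, 1.0):
            batch = sample_windows(rec, tl, WindowSpec(301, offset, 200, seed=5))
            idx = batch.starts + int(np.floor(offset * 300))
            np.testing.assert_array_equal(batch.labels, tl.triggers[:, idx].T)

    def test_start_distribution_uniform(self, toy_recording):
        rec, tl = toy_recording
        batch = sample_windows(rec, tl, WindowSpec(100, 0.5, 10000, seed=0))
        hi = rec.n_samples - 100
        # KS test against the uniform CDF on [0, hi]
        p = scistats.kstest(batch.starts / hi, "uniform").pvalue
        assert p > 1e-4

    def test_window_data_matches_recording(self, toy_recording):
        rec, tl = toy_recording
        batch = sample_windows(rec, tl, WindowSpec(50, 0.0, 10, seed=1))
        s = int(batch.starts[3])
        np.testing.assert_allclose(
            batch.data[3], rec.data[:, s : s + 50].astype(np.float32)
        )

    def test_positive_enrichment_raises_positive_fraction(self, toy_recording):
        rec, tl = toy_recording
        spec = WindowSpec(100, 0.5, 200, seed=2)
        plain = sample_windows(rec, tl, spec)
        enriched = sample_windows(rec, tl, spec, min_positive_fraction=0.5)
        frac = lambda b: (b.labels.any(axis=1)).mean()  # noqa: E731
        assert frac(enriched) >= 0.5 > frac(plain)

    def test_oversized_window_rejected(self, toy_recording):
        rec, tl = toy_recording
        with pytest.raises(SizingError):
            sample_windows(rec, tl, WindowSpec(rec.n_samples + 1, 0.5, 10, seed=0))


class TestOffsetSemantics:
    """Offset semantics on a hand-constructed timeline."""

    def _setup(self):
        n = 2000
        triggers = np.zeros((6, n), dtype=np.int8)
        triggers[0, 1000:1150] = 1  # one 150-sample run
        rec = EEGRecording(np.zeros((2, n)), 500.0)
        return rec, EventTimeline(triggers)

    def test_window_inside_run_has_same_label_at_all_offsets(self):
        rec, tl = self._setup()
        # window of 100 samples fully inside [1000, 1150)
        for offset in (0.0, 0.5, 1.0):
            assert tl.triggers[0, label_index(1020, 100, offset)] == 1

    def test_offset_one_labels_positive_only_if_end_inside_run(self):
        rec, tl = self._setup()
        start = 900  # window [900, 1100): end sample 1099 inside the run
        assert tl.triggers[0, label_index(start, 200, 1.0)] == 1
        assert tl.triggers[0, label_index(start, 200, 0.0)] == 0
        start = 700  # window [700, 900): end sample 899 before onset
        assert tl.triggers[0, label_index(start, 200, 1.0)] == 0

    def test_dilution_fraction_non_increasing_in_n(self):
        """Expected in-window fraction of labeled-action samples shrinks
        (weakly) as N grows: the natural-noise dilution."""
        rec, tl = self._setup()
        fractions = []
        for n in (150, 300, 600, 1200):
            batch = sample_windows(rec, tl, WindowSpec(n, 0.5, 4000, seed=9))
            pos = batch.labels[:, 0] == 1
            if not pos.any():
                fractions.append(0.0)
                continue
            frac = []
            for s in batch.starts[pos]:
                frac.append(tl.triggers[0, s : s + n].mean())
            fractions.append(np.mean(frac))
        assert all(a >= b - 1e-9 for a, b in zip(fractions, fractions[1:]))


class TestNoise:
    def test_sigma_zero_is_identity(self, toy_recording):
        rec, tl = toy_recording
        batch = sample_windows(rec, tl, WindowSpec(100, 0.5, 50, seed=0))
        out = add_gaussian_noise(batch, NoiseSpec(0.0, seed=1))
        np.testing.assert_array_equal(out.data, batch.data)

    def test_moments_match_spec(self, toy_recording):
        rec, tl = toy_recording
        batch = sample_windows(rec, tl, WindowSpec(500, 0.5, 500, seed=0))
        out = add_gaussian_noise(batch, NoiseSpec(0.2, seed=1))
        delta = (out.data - batch.data).ravel()
        assert delta.size >= 10**6
        assert abs(delta.mean()) < 3 * 0.2 / np.sqrt(delta.size)
        assert abs(delta.std() - 0.2) < 1e-3

    @pytest.mark.parametrize("sigma", [0.001, 0.01, 0.1, 0.2])
    def test_study_sigmas_accepted(self, sigma):
        NoiseSpec(sigma)

    def test_labels_and_starts_untouched(self, toy_recording):
        rec, tl = toy_recording
        batch = sample_windows(rec, tl, WindowSpec(100, 0.5, 50, seed=0))
        out = add_gaussian_noise(batch, NoiseSpec(0.5, seed=2))
        np.testing.assert_array_equal(out.labels, batch.labels)
        np.testing.assert_array_equal(out.starts, batch.starts)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ConfigurationError):
            NoiseSpec(-0.1)


class TestSplit:
    def test_split_sizes_82_9_9(self, toy_recording):
        rec, tl = toy_recording
        batch = sample_windows(rec, tl, WindowSpec(100, 0.5, 1000, seed=0))
        tr, va, te = split(batch, (0.82, 0.09, 0.09), seed=0)
        assert (len(tr), len(va), len(te)) == (820, 90, 90)

    def test_partition_disjoint_and_complete(self, toy_recording):
        rec, tl = toy_recording
        batch = sample_windows(rec, tl, WindowSpec(100, 0.5, 333, seed=0))
        parts = split(batch, seed=1)
        ids = np.concatenate([p.starts for p in parts])
        assert sum(len(p) for p in parts) == 333
        assert sorted(ids.tolist()) == sorted(batch.starts.tolist())

    def test_same_seed_same_partition(self, toy_recording):
        rec, tl = toy_recording
        batch = sample_windows(rec, tl, WindowSpec(100, 0.5, 200, seed=0))
        a = split(batch, seed=5)
        b = split(batch, seed=5)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.starts, pb.starts)

    def test_time_blocked_folds_are_contiguous(self, toy_recording):
        rec, tl = toy_recording
        batch = sample_windows(rec, tl, WindowSpec(100, 0.5, 400, seed=0))
        tr, va, te = split(batch, mode="time-blocked")
        assert tr.starts.max() < va.starts.min() <= va.starts.max() < te.starts.min()

    def test_too_few_windows_rejected(self, toy_recording):
        rec, tl = toy_recording
        batch = sample_windows(rec, tl, WindowSpec(100, 0.5, 2, seed=0))
        with pytest.raises(SizingError):
            split(batch)

    def test_bad_fractions_rejected(self, toy_recording):
        rec, tl = toy_recording
        batch = sample_windows(rec, tl, WindowSpec(100, 0.5, 10, seed=0))
        with pytest.raises(ConfigurationError):
            split(batch, (0.5, 0.3, 0.3))
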