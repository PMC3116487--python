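import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from maldianova.design import build_design
from maldianova.preprocessing import (
    IntensityMatrix, PeakSet, align_shift, apply_shift,
    average_technical_replicates, compute_reference_peaks, cwt_pick_peaks,
    log_transform, median_smooth, preprocess_dataset, quantify_peaks,
    stabilize_variance, tophat_baseline, variance_diagnostic)
from maldianova.simulate import NoiseParams, default_families, simulate_dataset
from maldianova.spectrum import Spectrum, Stage


def spec(x, stage=Stage.RAW, sid="s"):
    x = np.asarray(x, dtype=float)
    return Spectrum(sid, np.linspace(700, 10000, len(x)), x, stage)


# ----------------------------------------------------------- oracles

def brute_median(x, window):
    """Shrinking-window sliding median, the slow obvious way."""
    half = window // 2
    return np.array([np.median(x[max(0, i - half):i + half + 1])
                     for i in range(len(x))])


def brute_opening(x, width):
    """Erosion then dilation with a flat structuring element."""
    half = width // 2
    n = len(x)
    def erode(v):
        return np.array([v[max(0, i - half):i + half + 1].min()
                         for i in range(n)])
    def dilate(v):
        return np.array([v[max(0, i - half):i + half + 1].max()
                         for i in range(n)])
    return dilate(erode(x))


class TestLogTransform:
    def test_zeros_stay_zero(self):
        out = log_transform(spec(np.zeros(10)))
        np.testing.assert_array_equal(out.intensities, np.zeros(10))
        assert out.stage == Stage.LOGGED

    def test_analytic_value(self):
        out = log_transform(spec([np.e - 1]))
        assert out.intensities[0] == pytest.approx(1.0)

    def test_monotone_order_preserved(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 50)
        out = log_transform(spec(x))
        np.testing.assert_array_equal(np.argsort(out.intensities),
                                      np.argsort(x))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(spec([-1.0, 2.0]))

    def test_stage_must_be_raw(self):
        with pytest.raises(ValueError):
            log_transform(spec([1.0, 2.0], Stage.LOGGED))


class TestMedianSmooth:
    def test_constant_unchanged(self):
        out = median_smooth(spec(np.full(30, 3.0), Stage.LOGGED))
        np.testing.assert_array_equal(out.intensities, np.full(30, 3.0))

    def test_spike_removed_ramp_intact(self):
        x = np.linspace(0, 10, 50)
        x[25] += 100.0
        out = median_smooth(spec(x, Stage.LOGGED), window=9)
        np.testing.assert_allclose(out.intensities,
                                   brute_median(x, 9), rtol=0, atol=0)
        assert out.intensities[25] < 10.0

    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(9, 40))
        out = median_smooth(spec(x, Stage.LOGGED), window=9)
        np.testing.assert_array_equal(out.intensities, brute_median(x, 9))

    def test_monotone_input_stays_monotone(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.uniform(0, 1, 60))
        out = median_smooth(spec(x, Stage.LOGGED))
        assert np.all(np.diff(out.intensities) >= 0)

    @pytest.mark.parametrize("window", [4, 1, 101])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ValueError):
            median_smooth(spec(np.zeros(50), Stage.LOGGED), window=window)


class TestTophat:
    def test_constant_becomes_zero(self):
        out = tophat_baseline(spec(np.full(400, 7.0), Stage.SMOOTHED))
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-12)

    def test_matches_brute_force_opening(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 5, 200)
        out = tophat_baseline(spec(x, Stage.SMOOTHED), struct_width=21)
        np.testing.assert_allclose(out.intensities,
                                   x - brute_opening(x, 21), atol=1e-12)

    def test_narrow_peaks_on_linear_baseline_preserved(self):
        idx = np.arange(1000)
        baseline = 10 + 0.01 * idx
        peaks = np.zeros(1000)
        for c in (300, 700):
            peaks += 50 * np.exp(-0.5 * ((idx - c) / 4.0) ** 2)
        out = tophat_baseline(spec(baseline + peaks, Stage.SMOOTHED),
                              struct_width=151)
        for c in (300, 700):
            assert out.intensities[c] == pytest.approx(50.0, rel=0.01)
        flat = np.r_[out.intensities[:100], out.intensities[900:]]
        assert np.all(flat < 1.0)

    def test_bounds_zero_to_input(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 5, 300)
        out = tophat_baseline(spec(x, Stage.SMOOTHED), struct_width=31)
        assert np.all(out.intensities >= -1e-12)
        assert np.all(out.intensities <= x + 1e-12)

    def test_opening_is_idempotent(self):
        from scipy.ndimage import grey_opening
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 5, 300)
        once = grey_opening(x, size=31, mode="nearest")
        twice = grey_opening(once, size=31, mode="nearest")
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            tophat_baseline(spec(np.zeros(100), Stage.SMOOTHED),
                            struct_width=150)


class TestCwtPicking:
    def test_flat_spectrum_yields_nothing(self):
        assert len(cwt_pick_peaks(np.zeros(500))) == 0

    def test_five_planted_gaussians_at_snr20(self):
        rng = np.random.default_rng(0)
        idx = np.arange(2000)
        truth = [200, 400, 600, 660, 800]
        x = sum(20 * np.exp(-0.5 * ((idx - c) / 3.0) ** 2) for c in truth)
        ps = cwt_pick_peaks(x + rng.normal(0, 1, 2000))
        assert len(ps) == 5
        assert np.all(np.abs(ps.apex_indices - np.array(truth)) <= 1)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        idx = np.arange(1500)
        x = sum(15 * np.exp(-0.5 * ((idx - c) / 3.0) ** 2)
                for c in (300, 900)) + rng.normal(0, 1, 1500)
        a = cwt_pick_peaks(x)
        b = cwt_pick_peaks(2.0 * x)
        np.testing.assert_array_equal(a.apex_indices, b.apex_indices)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cwt_pick_peaks(np.zeros(10))


class TestReferencePeaks:
    def test_single_spectrum_is_its_own_reference(self):
        idx = np.arange(1500)
        x = sum(15 * np.exp(-0.5 * ((idx - c) / 3.0) ** 2)
                for c in (300, 900))
        s = spec(x, Stage.BASELINED)
        ref = compute_reference_peaks([s])
        np.testing.assert_array_equal(ref.apex_indices,
                                      cwt_pick_peaks(s).apex_indices)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_reference_peaks([spec(np.zeros(200), Stage.BASELINED),
                                     spec(np.zeros(300), Stage.BASELINED)])


class TestAlignment:
    def _ps(self, apices, sid="s"):
        return PeakSet(sid, np.asarray(apices), np.ones(len(apices)))

    def test_identical_peaksets_give_zero_shift(self):
        ref = self._ps([100, 200, 300])
        sh = align_shift(self._ps([100, 200, 300]), ref)
        assert sh.shift == 0 and sh.n_matched == 3 and not sh.zero_match

    def test_uniform_displacement_recovered(self):
        ref = self._ps([100, 200, 300])
        sh = align_shift(self._ps([107, 207, 307]), ref)
        assert sh.shift == 7

    def test_no_match_flags_zero(self):
        ref = self._ps([100])
        sh = align_shift(self._ps([500]), ref, window=30)
        assert sh.shift == 0 and sh.n_matched == 0 and sh.zero_match

    def test_apply_zero_shift_is_identity(self):
        s = spec(np.arange(50.0), Stage.BASELINED)
        out = apply_shift(s, 0)
        np.testing.assert_array_equal(out.intensities, s.intensities)
        assert out.stage == Stage.ALIGNED

    def test_shift_round_trip(self):
        idx = np.arange(1500)
        x = sum(15 * np.exp(-0.5 * ((idx - c) / 3.0) ** 2)
                for c in (300, 900))
        ref = cwt_pick_peaks(x)
        shifted = np.roll(x, 7)                  # planted drift +7
        sh = align_shift(cwt_pick_peaks(shifted), ref)
        assert sh.shift == 7
        back = apply_shift(spec(shifted, Stage.BASELINED), sh.shift)
        residual = align_shift(cwt_pick_peaks(back.intensities), ref)
        assert residual.shift == 0

    def test_shift_composition(self):
        x = np.sin(np.arange(300) / 7.0) + 2
        a = apply_shift(spec(x, Stage.SMOOTHED), 3).intensities
        ab = apply_shift(spec(a, Stage.SMOOTHED), 4).intensities
        direct = apply_shift(spec(x, Stage.SMOOTHED), 7).intensities
        np.testing.assert_array_equal(ab[10:-10], direct[10:-10])


class TestQuantify:
    def _aligned(self, x):
        return spec(x, Stage.ALIGNED)

    def test_delta_peak_at_apex(self):
        x = np.zeros(100)
        x[40] = 9.0
        ref = PeakSet("r", [40], [1.0])
        assert quantify_peaks(self._aligned(x), ref)[0] == 9.0

    def test_apex_off_by_three_still_captured(self):
        x = np.zeros(100)
        x[43] = 9.0
        ref = PeakSet("r", [40], [1.0])
        assert quantify_peaks(self._aligned(x), ref, q=4)[0] == 9.0

    def test_q_zero_reads_exact_index(self):
        x = np.arange(100.0)
        ref = PeakSet("r", [40], [1.0])
        assert quantify_peaks(self._aligned(x), ref, q=0)[0] == 40.0

    def test_window_clipped_at_edges(self):
        x = np.arange(10.0)
        ref = PeakSet("r", [0, 9], [1.0, 1.0])
        np.testing.assert_array_equal(
            quantify_peaks(self._aligned(x), ref, q=4), [4.0, 9.0])


def _matrix(values, columns=None):
    values = np.asarray(values, dtype=float)
    columns = columns or [f"p{i}" for i in range(values.shape[1])]
    mz = pd.Index(np.arange(values.shape[0], dtype=float) + 1000, name="mz")
    return IntensityMatrix(pd.DataFrame(values, index=mz, columns=columns),
                           np.arange(values.shape[0]))


class TestStabilizeVariance:
    def test_log_of_point_nine_is_zero(self):
        out = stabilize_variance(_matrix([[0.9]]))
        assert out.data.iloc[0, 0] == pytest.approx(0.0)

    def test_offset_is_additive(self):
        base = stabilize_variance(_matrix([[1.0, 2.0], [3.0, 4.0]]))
        shifted = stabilize_variance(_matrix([[1.0, 2.0], [3.0, 4.0]]),
                                     offset=5.0)
        np.testing.assert_allclose(shifted.data.to_numpy(),
                                   base.data.to_numpy() + 5.0)

    def test_transform_log_records_steps(self):
        out = stabilize_variance(_matrix([[1.0]]), offset=2.0)
        assert any("log" in t for t in out.transforms)
        assert any("offset" in t for t in out.transforms)

    def test_nonpositive_after_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            stabilize_variance(_matrix([[-0.5]]))


def _replicate_sim(sigma, n_groups=400, n_rep=4, seed=0, log_first=False):
    """Log-normal technical replicates around spread-out mean heights."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(5, 9, (30, n_groups))
    draws = np.exp(base[..., None]
                   + sigma * rng.standard_normal((30, n_groups, n_rep)))
    if log_first:
        draws = np.log(draws)
    cols, groups = {}, {}
    for g in range(n_groups):
        for r in range(n_rep):
            pid = f"g{g}r{r}"
            cols[pid] = draws[:, g, r]
            groups[pid] = f"g{g}"
    return _matrix(np.column_stack(list(cols.values())),
                   list(cols)), groups


class TestVarianceDiagnostic:
    def test_identical_replicates_give_zero_spread(self):
        m = _matrix(np.tile(np.array([[1.0], [5.0]]), (1, 4)))
        d = variance_diagnostic(m, {c: "g" for c in m.data.columns})
        assert np.all(d.spreads == 0) and d.slope == pytest.approx(0.0)

    def test_homoscedastic_noise_flat_slope(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(2, 9, (50, 200))[:, :, None] \
            + 0.5 * rng.standard_normal((50, 200, 4))
        cols = {f"g{g}r{r}": vals[:, g, r] for g in range(200)
                for r in range(4)}
        m = _matrix(np.column_stack(list(cols.values())), list(cols))
        d = variance_diagnostic(m, {c: c[:c.index("r")] for c in cols})
        assert abs(d.slope) < 0.05

    def test_multiplicative_noise_positive_slope(self):
        m, groups = _replicate_sim(0.5)
        d = variance_diagnostic(m, groups)
        assert d.slope > 0.2

    def test_stabilization_flattens_multiplicative_noise(self):
        m, groups = _replicate_sim(0.5, log_first=True)
        d = variance_diagnostic(stabilize_variance(m), groups)
        assert abs(d.slope) < 0.05

    def test_requires_a_replicated_group(self):
        m = _matrix([[1.0], [2.0]])
        with pytest.raises(ValueError):
            variance_diagnostic(m, {"p0": "g0"})


class TestReplicateAveraging:
    def _sheet(self, mapping):
        return pd.DataFrame({
            "spectrum_id": list(mapping),
            "sample_id": list(mapping.values()),
        })

    def test_single_replicate_identity(self):
        m = _matrix([[1.0, 2.0]], ["a1", "b1"])
        out = average_technical_replicates(
            m, self._sheet({"a1": "a", "b1": "b"}))
        np.testing.assert_array_equal(out.data.to_numpy(), [[1.0, 2.0]])
        assert out.level == "sample-averaged"

    def test_identical_replicates_average_to_themselves(self):
        m = _matrix([[3.0, 3.0]], ["a1", "a2"])
        out = average_technical_replicates(
            m, self._sheet({"a1": "a", "a2": "a"}))
        assert out.data.shape == (1, 1)
        assert out.data.iloc[0, 0] == 3.0

    def test_unmapped_profile_rejected(self):
        m = _matrix([[1.0, 2.0]], ["a1", "zz"])
        with pytest.raises(KeyError):
            average_technical_replicates(m, self._sheet({"a1": "a"}))


class TestFullChain:
    def test_pipeline_deterministic(self, small_dataset):
        rep1, samp1, _ = preprocess_dataset(small_dataset.spectra,
                                            small_dataset.sample_sheet)
        rep2, samp2, _ = preprocess_dataset(small_dataset.spectra,
                                            small_dataset.sample_sheet)
        assert rep1.data.equals(rep2.data)
        assert samp1.data.equals(samp2.data)

    def test_replicates_collapse_to_samples(self, small_dataset):
        rep, samp, _ = preprocess_dataset(small_dataset.spectra,
                                          small_dataset.sample_sheet)
        sheet = small_dataset.sample_sheet
        assert rep.n_profiles == len(sheet)
        assert samp.n_profiles == sheet["sample_id"].nunique()
        assert samp.level == "sample-averaged"

    def test_planted_shifts_recovered_in_pipeline(self):
        fams = default_families(3000, 3, 3, 6, seed=1)
        d = build_design(["B6"], ["SD"], [3], {("B6", "SD", 3): (40, 10)})
        ds0 = simulate_dataset(d, fams, axis_length=3000, seed=11,
                               noise=NoiseParams(max_index_shift=0))
        ds = simulate_dataset(d, fams, axis_length=3000, seed=11,
                              noise=NoiseParams(max_index_shift=15))
        base0 = [tophat_baseline(median_smooth(log_transform(s)))
                 for s in ds0.spectra]
        ref = compute_reference_peaks(base0)
        hits = 0
        for s in ds.spectra:
            b = tophat_baseline(median_smooth(log_transform(s)))
            sh = align_shift(cwt_pick_peaks(b), ref)
            hits += sh.shift == ds.truth.index_shifts[s.spectrum_id]
        assert hits >= 0.95 * len(ds.spectra)
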