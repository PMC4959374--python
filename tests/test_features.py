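"""Windowing, the 19 statistics, Welch band power, asymmetry and Z-index."""

import numpy as np
import pytest

from adlike import (
    EPOC_MONTAGE,
    STAT_NAMES,
    WindowSpec,
    ZIndexInputs,
    assemble_features,
    asymmetry_stats,
    feature_names,
    slide_windows,
    valence_pair_correlation,
    welch_band_power,
    welch_log_psd,
    window_statistics,
    z_index,
)
from adlike.errors import DegenerateWindowError, MontageError, UndefinedIndexError
from adlike.features import PSD_EPSILON

FS = 128.0
S = {name: i for i, name in enumerate(STAT_NAMES)}


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

class TestSlideWindows:
    @pytest.mark.parametrize(
        "duration,expected",
        [
            (30.0, [(0, 10, False), (6, 16, False), (12, 22, False), (18, 28, False), (24, 30, True)]),
            (10.0, [(0, 10, False)]),
            (16.0, [(0, 10, False), (6, 16, False)]),
        ],
    )
    def test_window_layout(self, duration, expected):
        wins = slide_windows(duration, WindowSpec())
        assert [(s, e, p) for s, e, p in wins] == [(float(a), float(b), p) for a, b, p in expected]

    def test_thirty_second_ad_yields_five_windows(self):
        assert len(slide_windows(30.0)) == 5

    def test_short_clip_single_truncated_window_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            wins = slide_windows(7.0)
        assert wins == [(0.0, 7.0, True)]

    def test_count_formula(self):
        spec = WindowSpec()
        for duration in np.arange(10.0, 61.0, 1.0):
            n = len(slide_windows(duration, spec))
            assert n == int(np.ceil((duration - spec.length_s) / spec.hop_s)) + 1


# ---------------------------------------------------------------------------
# The 19 statistics
# ---------------------------------------------------------------------------

def reference_statistics(series):
    """Independent straight-line recomputation of all 19 formulas."""
    x = [float(v) for v in series]
    n = len(x)
    mean = sum(x) / n
    dev = [v - mean for v in x]
    var = sum(d * d for d in dev) / (n - 1)
    sd = var ** 0.5
    m2 = sum(d * d for d in dev) / n
    m3 = sum(d ** 3 for d in dev) / n
    m4 = sum(d ** 4 for d in dev) / n
    skew = m3 / m2 ** 1.5 if m2 > 0 else 0.0
    kurt = m4 / m2 ** 2 - 3.0 if m2 > 0 else 0.0
    q1, med, q3 = (float(np.percentile(x, q)) for q in (25, 50, 75))
    rms = (sum(v * v for v in x) / n) ** 0.5
    mad = sum(abs(d) for d in dev) / n
    d1 = [x[i + 1] - x[i] for i in range(n - 1)]
    line_length = sum(abs(d) for d in d1) / len(d1)
    zc = sum(1 for i in range(n - 1) if x[i] * x[i + 1] < 0)
    var_x = m2
    var_d = sum(v * v for v in d1) / len(d1) - (sum(d1) / len(d1)) ** 2
    mob = (var_d / var_x) ** 0.5 if var_x > 0 else 0.0
    d2 = [x[i + 2] - 2 * x[i + 1] + x[i] for i in range(n - 2)]
    var_dd = sum(v * v for v in d2) / len(d2) - (sum(d2) / len(d2)) ** 2
    mob_d = (var_dd / var_d) ** 0.5 if var_d > 0 else 0.0
    comp = mob_d / mob if mob > 0 else 0.0
    energy = sum(v * v for v in x)
    return [mean, sd, var, min(x), max(x), max(x) - min(x), med, q1, q3, q3 - q1,
            skew, kurt, rms, mad, line_length, zc, mob, comp, energy]


class TestWindowStatistics:
    def test_matches_reference_on_simple_and_random_series(self, rng):
        for series in ([1.0, 2.0, 3.0, 4.0], rng.normal(size=64), rng.normal(size=257)):
            got = window_statistics(np.asarray(series))
            np.testing.assert_allclose(got, reference_statistics(series), rtol=1e-10, atol=1e-12)

    def test_constant_series(self):
        got = window_statistics(np.full(32, 3.5))
        assert got[S["mean"]] == 3.5
        assert got[S["sd"]] == 0.0
        assert got[S["range"]] == 0.0
        assert got[S["zero_crossings"]] == 0.0
        assert got[S["skewness"]] == 0.0

    def test_symmetric_series_zero_skewness(self):
        x = np.concatenate([np.arange(10.0), -np.arange(10.0)])
        assert abs(window_statistics(x)[S["skewness"]]) < 1e-9

    @pytest.mark.parametrize("k", [0.5, 3.0])
    def test_scaling_homogeneity(self, rng, k):
        """Each statistic scales by k to its homogeneity degree."""
        x = rng.normal(size=128)
        base = window_statistics(x)
        scaled = window_statistics(k * x)
        degree1 = ["mean", "sd", "min", "max", "range", "median", "q1", "q3",
                   "iqr", "rms", "mad", "line_length"]
        invariant = ["skewness", "kurtosis", "zero_crossings",
                     "hjorth_mobility", "hjorth_complexity"]
        for name in degree1:
            assert scaled[S[name]] == pytest.approx(k * base[S[name]], rel=1e-9)
        for name in invariant:
            assert scaled[S[name]] == pytest.approx(base[S[name]], rel=1e-9, abs=1e-12)
        assert scaled[S["var"]] == pytest.approx(k**2 * base[S["var"]], rel=1e-9)
        assert scaled[S["energy"]] == pytest.approx(k**2 * base[S["energy"]], rel=1e-9)

    def test_clean_mask_reproduces_unmasked_statistics(self, rng):
        x = rng.normal(size=100)
        np.testing.assert_array_equal(
            window_statistics(x, np.zeros(100, dtype=bool)), window_statistics(x)
        )

    def test_masked_samples_excluded(self, rng):
        x = rng.normal(size=100)
        x[40:50] = 1e6  # contaminated
        mask = np.zeros(100, dtype=bool)
        mask[40:50] = True
        got = window_statistics(x, mask)
        assert abs(got[S["max"]]) < 1e3

    def test_too_few_clean_samples_rejected(self):
        with pytest.raises(DegenerateWindowError):
            window_statistics(np.arange(5.0), np.array([False, True, True, True, True]))


# ---------------------------------------------------------------------------
# Welch band power
# ---------------------------------------------------------------------------

class TestWelchLogPSD:
    def test_alpha_tone_dominates_other_bands(self):
        """Oracle: a 10 Hz tone's energy sits in alpha; the log band power
        exceeds every other band by >= 2 natural-log units."""
        t = np.arange(1280) / FS
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        logp, degenerate = welch_log_psd(x, FS)
        assert not degenerate
        alpha = logp[0, 1]
        others = [logp[0, i] for i in (0, 2, 3)]
        assert all(alpha - o >= 2.0 for o in others)

    def test_white_noise_power_proportional_to_bandwidth(self):
        """Monte-Carlo (fixed seed, 100 repetitions): integrated band
        power tracks the number of band bins within 25 % relative."""
        rng = np.random.default_rng(99)
        acc = np.zeros(4)
        for _ in range(100):
            acc += welch_band_power(rng.normal(size=1280), FS)
        freqs = np.fft.rfftfreq(128, 1 / FS)
        nbins = np.array([
            int(np.sum((freqs >= lo) & (freqs <= hi)))
            for lo, hi in [(3, 7), (8, 13), (14, 29), (30, 47)]
        ])
        expected = acc.sum() * nbins / nbins.sum()
        np.testing.assert_allclose(acc, expected, rtol=0.25)

    def test_window_identical_to_baseline_cancels(self, rng):
        x = rng.normal(size=(14, 1280))
        base_bp = welch_band_power(x, FS)
        logp, degenerate = welch_log_psd(x, FS, baseline_band_power=base_bp)
        assert degenerate
        np.testing.assert_array_equal(logp, np.log(PSD_EPSILON))

    def test_all_zero_window_floors_and_flags(self):
        logp, degenerate = welch_log_psd(np.zeros((14, 1280)), FS)
        assert degenerate
        np.testing.assert_array_equal(logp, np.log(PSD_EPSILON))


# ---------------------------------------------------------------------------
# Asymmetry block
# ---------------------------------------------------------------------------

def _band_windows(rng, n=640):
    return {b: rng.normal(size=(14, n)) for b in ("theta", "alpha", "beta", "gamma")}


class TestAsymmetry:
    def test_block_shape_is_7_by_19(self, rng):
        assert asymmetry_stats(_band_windows(rng)).shape == (7, 19)

    def test_identical_hemispheres_give_zero_series_statistics(self, rng):
        bw = _band_windows(rng)
        labels = tuple(EPOC_MONTAGE)
        for b in bw:
            for left, right in (("AF3", "AF4"), ("F7", "F8"), ("F3", "F4"), ("FC5", "FC6"),
                                ("T7", "T8"), ("P7", "P8"), ("O1", "O2")):
                bw[b][labels.index(right)] = bw[b][labels.index(left)]
        got = asymmetry_stats(bw)
        np.testing.assert_allclose(got[:, S["mean"]], 0.0, atol=1e-12)
        np.testing.assert_allclose(got[:, S["sd"]], 0.0, atol=1e-12)
        np.testing.assert_allclose(got[:, S["energy"]], 0.0, atol=1e-12)

    def test_hemisphere_swap_parity(self, rng):
        """Swapping left/right negates sign-odd statistics and leaves
        sign-even ones unchanged (brute-force recomputation after swap)."""
        bw = _band_windows(rng)
        base = asymmetry_stats(bw)
        swapped_labels = []
        mapping = dict()
        for left, right in (("AF3", "AF4"), ("F7", "F8"), ("F3", "F4"), ("FC5", "FC6"),
                            ("T7", "T8"), ("P7", "P8"), ("O1", "O2")):
            mapping[left], mapping[right] = right, left
        labels = tuple(mapping.get(ch, ch) for ch in EPOC_MONTAGE)
        swapped = asymmetry_stats(bw, channel_labels=labels)
        for name in ("mean", "median", "skewness"):
            np.testing.assert_allclose(swapped[:, S[name]], -base[:, S[name]], atol=1e-9)
        for name in ("sd", "var", "range", "rms", "energy", "kurtosis", "line_length",
                     "zero_crossings"):
            np.testing.assert_allclose(swapped[:, S[name]], base[:, S[name]], rtol=1e-9)
        np.testing.assert_allclose(swapped[:, S["min"]], -base[:, S["max"]], atol=1e-9)

    def test_missing_electrode_raises_montage_error(self, rng):
        bw = {b: w[:13] for b, w in _band_windows(rng).items()}
        with pytest.raises(MontageError, match="AF4"):
            asymmetry_stats(bw, channel_labels=EPOC_MONTAGE[:13])


# ---------------------------------------------------------------------------
# Z-index and valence correlation
# ---------------------------------------------------------------------------

class TestZIndex:
    def test_null_deviation(self):
        assert z_index(ZIndexInputs(x_bar=1.0, mu=1.0, sigma=2.0, n=9)) == 0.0

    def test_direct_evaluation(self):
        assert z_index(ZIndexInputs(x_bar=2.0, mu=1.0, sigma=2.0, n=16)) == pytest.approx(2.0)

    def test_preconditions_enforced(self):
        with pytest.raises(UndefinedIndexError):
            ZIndexInputs(x_bar=0.0, mu=1.0, sigma=1.0, n=1)
        with pytest.raises(UndefinedIndexError):
            ZIndexInputs(x_bar=0.0, mu=1.0, sigma=0.0, n=4)


class TestValenceCorrelation:
    def test_perfect_correlation_and_anticorrelation(self, rng):
        z = rng.normal(size=(10, 14))
        labels = tuple(EPOC_MONTAGE)
        for left, right in (("AF3", "AF4"), ("F7", "F8"), ("F3", "F4"), ("FC5", "FC6"),
                            ("T7", "T8"), ("P7", "P8"), ("O1", "O2")):
            z[:, labels.index(right)] = z[:, labels.index(left)]
        ratings = np.array([5, 5, 5, 4, 4, 1, 1, 2, 2, 1])
        out = valence_pair_correlation(z, ratings)
        for group in ("pleasant", "unpleasant"):
            assert all(r == pytest.approx(1.0) for r in out[group].values())
        z2 = z.copy()
        for left, right in (("AF3", "AF4"),):
            z2[:, labels.index(right)] = -z2[:, labels.index(left)]
        out2 = valence_pair_correlation(z2, ratings)
        assert out2["pleasant"]["AF3-AF4"] == pytest.approx(-1.0)

    def test_independent_z_bounded_correlation(self):
        """50 videos per valence group of independent Z values:
        |r| < 0.4 (Monte-Carlo bound at this n)."""
        rng = np.random.default_rng(7)
        z = rng.normal(size=(100, 14))
        ratings = np.concatenate([np.full(50, 5), np.full(50, 1)])
        out = valence_pair_correlation(z, ratings)
        for group in ("pleasant", "unpleasant"):
            assert all(abs(r) < 0.4 for r in out[group].values())

    def test_small_group_flagged_absent(self, rng):
        out = valence_pair_correlation(rng.normal(size=(4, 14)), np.array([5, 4, 4, 3]))
        assert out["unpleasant"] is None
        assert out["pleasant"] is not None


# ---------------------------------------------------------------------------
# Assembly and schema
# ---------------------------------------------------------------------------

class TestAssembly:
    def test_block_sizes(self):
        names = feature_names()
        assert sum(n.startswith("stat.") for n in names) == 1064
        assert sum(n.startswith("asym.") for n in names) == 133
        assert sum(n.startswith("psd.") for n in names) == 56
        assert sum(n.startswith("z.") for n in names) == 14
        assert len(names) == 1267
        assert len(set(names)) == len(names)

    def test_assembled_vector_matches_schema_order(self, rng):
        stat = rng.normal(size=(14, 4, 19))
        psd = rng.normal(size=(14, 4))
        asym = rng.normal(size=(7, 19))
        z = rng.normal(size=14)
        vec = assemble_features(stat, psd, asym, z)
        assert vec.shape == (1267,)
        np.testing.assert_array_equal(vec[:1064], stat.reshape(-1))
        np.testing.assert_array_equal(vec[1064:1120], psd.reshape(-1))
        np.testing.assert_array_equal(vec[1120:1253], asym.reshape(-1))
        np.testing.assert_array_equal(vec[1253:], z)

    def test_block_shape_mismatch_named(self, rng):
        from adlike.errors import ValidationError
        with pytest.raises(ValidationError, match="asym"):
            assemble_features(rng.normal(size=(14, 4, 19)), rng.normal(size=(14, 4)),
                              rng.normal(size=(6, 19)), rng.normal(size=14))

    def test_schema_is_deterministic(self):
        assert feature_names() == feature_names()
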