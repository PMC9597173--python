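"""Distance-resolved correlation functions, smoothing and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methkin import corrfuncs
from methkin.corrfuncs import (
    CorrelationFunction,
    classify_pairs,
    distance_correlation,
    feature_association,
    loess_smooth,
    mean_magnitude,
    site_interval_ids,
)


def brute_force_corr(positions, values, d_max):
    """O(n^2) double-loop oracle with the same symmetrized estimator."""
    n = len(positions)
    pairs = {d: [] for d in range(2, d_max + 1)}
    for i in range(n):
        for j in range(i + 1, n):
            d = positions[j] - positions[i]
            if 2 <= d <= d_max:
                pairs[d].append((values[i], values[j]))
    out = {}
    for d, pp in pairs.items():
        if len(pp) < 2:
            out[d] = (np.nan, len(pp))
            continue
        x = [a for a, b in pp] + [b for a, b in pp]
        y = [b for a, b in pp] + [a for a, b in pp]
        sx = np.std(x)
        if sx == 0 or np.std(y) == 0:
            out[d] = (np.nan, len(pp))
        else:
            out[d] = (stats.pearsonr(x, y)[0], len(pp))
    return out


class TestDistanceCorrelation:
    def test_matches_double_loop_oracle(self, rng):
        positions = np.unique(rng.integers(0, 600, 100))
        positions = positions[np.concatenate([[True], np.diff(positions) >= 2])]
        values = rng.standard_normal(len(positions))
        cf = distance_correlation(positions, values, d_max=80, min_pairs=2)
        oracle = brute_force_corr(positions, values, 80)
        for i, d in enumerate(cf.d):
            r_o, n_o = oracle[d]
            assert cf.n_pairs[i] == n_o
            if np.isnan(r_o):
                assert np.isnan(cf.r[i])
            else:
                assert cf.r[i] == pytest.approx(r_o, abs=1e-12)

    def test_identical_values_masked_everywhere(self):
        pos = np.arange(0, 200, 2)
        cf = distance_correlation(pos, np.full(len(pos), 3.7), d_max=50,
                                  min_pairs=2)
        assert np.isnan(cf.r).all()

    def test_sign_flip_symmetry(self, rng):
        pos = np.cumsum(rng.integers(2, 8, 300))
        v = rng.standard_normal(300)
        a = distance_correlation(pos, v, d_max=100, min_pairs=2)
        b = distance_correlation(pos, -v, d_max=100, min_pairs=2)
        np.testing.assert_allclose(a.r, b.r, atol=1e-12)

    def test_reported_r_bounded(self, rng):
        pos = np.cumsum(rng.integers(2, 12, 2_000))
        v = rng.standard_normal(2_000)
        cf = distance_correlation(pos, v, d_max=300, min_pairs=5)
        ok = np.isfinite(cf.r)
        assert (np.abs(cf.r[ok]) <= 1.0 + 1e-12).all()

    def test_nan_values_excluded(self, rng):
        pos = np.arange(0, 1000, 5)
        v = rng.standard_normal(len(pos))
        v[::3] = np.nan
        cf = distance_correlation(pos, v, d_max=100, min_pairs=1)
        sub = np.isfinite(v)
        oracle = distance_correlation(pos[sub], v[sub], d_max=100, min_pairs=1)
        np.testing.assert_allclose(cf.r, oracle.r, equal_nan=True)

    def test_min_pairs_floor(self, rng):
        pos = np.cumsum(rng.integers(2, 40, 500))
        v = rng.standard_normal(500)
        cf = distance_correlation(pos, v, d_max=200, min_pairs=30)
        sparse = cf.n_pairs < 30
        assert np.isnan(cf.r[sparse]).all()

    def test_subsampling_stays_within_sampling_noise(self, rng):
        pos = np.cumsum(rng.integers(2, 6, 8_000))
        latent = np.cumsum(rng.standard_normal(8_000)) * 0.02
        v = latent + rng.standard_normal(8_000)
        full = distance_correlation(pos, v, d_max=50, min_pairs=20)
        half_idx = np.sort(rng.choice(8_000, 4_000, replace=False))
        half = distance_correlation(pos[half_idx], v[half_idx], d_max=50,
                                    min_pairs=20)
        both = np.isfinite(full.r) & np.isfinite(half.r)
        z = (full.r[both] - half.r[both]) * np.sqrt(half.n_pairs[both])
        assert np.abs(z).max() < 6


class TestLoessSmooth:
    def test_constant_track_preserved(self):
        cf = CorrelationFunction(np.arange(2, 200), np.full(198, 0.42),
                                 np.full(198, 100))
        sm = loess_smooth(cf)
        np.testing.assert_allclose(sm, 0.42, atol=1e-9)

    def test_noisy_exponential_within_noise_envelope(self, rng):
        d = np.arange(2, 1001)
        truth = 0.3 * np.exp(-d / 150.0)
        noisy = truth + 0.02 * rng.standard_normal(len(d))
        cf = CorrelationFunction(d, noisy, np.full(len(d), 500))
        sm = loess_smooth(cf, span=100.0)
        # smoothing should track the noise-free curve well inside one noise SD
        assert np.nanmax(np.abs(sm - truth)) < 0.02

    def test_too_few_points_warns_and_masks(self):
        cf = CorrelationFunction(np.arange(2, 12),
                                 np.full(10, np.nan), np.zeros(10))
        cf.r[3] = 0.5
        with pytest.warns(UserWarning):
            sm = loess_smooth(cf)
        assert np.isnan(sm).all()

    def test_invalid_span(self):
        cf = CorrelationFunction(np.arange(2, 10), np.zeros(8), np.zeros(8))
        with pytest.raises(ValueError):
            loess_smooth(cf, span=0)


class TestMeanMagnitude:
    def test_constant_half(self):
        cf = CorrelationFunction(np.arange(2, 1001), np.full(999, 0.5),
                                 np.full(999, 99))
        assert mean_magnitude(cf) == pytest.approx(0.5)

    def test_harmonic_track_matches_direct_sum(self):
        d = np.arange(2, 1001)
        cf = CorrelationFunction(d, 1.0 / d, np.full(999, 99))
        direct = sum(1.0 / dd for dd in range(2, 1001)) / 999
        assert mean_magnitude(cf) == pytest.approx(direct, rel=1e-12)

    def test_uncovered_range_rejected(self):
        cf = CorrelationFunction(np.arange(2, 10), np.zeros(8), np.zeros(8))
        with pytest.raises(ValueError):
            mean_magnitude(cf, d_lo=2000, d_hi=3000)


class TestPairClassification:
    def test_single_interval_all_within(self):
        pos = np.array([5, 10, 15, 20])
        ids = site_interval_ids(pos, np.array([[0, 30]]))
        i_idx, j_idx = np.triu_indices(4, k=1)
        assert classify_pairs(ids, i_idx, j_idx, "within").all()
        assert not classify_pairs(ids, i_idx, j_idx, "across").any()

    def test_two_intervals_enumeration_oracle(self):
        pos = np.array([0, 4, 8, 100, 104, 108])
        ids = site_interval_ids(pos, np.array([[0, 10], [100, 110]]))
        i_idx, j_idx = np.triu_indices(6, k=1)
        within = classify_pairs(ids, i_idx, j_idx, "within")
        across = classify_pairs(ids, i_idx, j_idx, "across")
        assert within.sum() == 6   # C(3,2) per interval
        assert across.sum() == 9   # 3 x 3 cross pairs

    def test_outside_sites_excluded(self):
        pos = np.array([0, 4, 50, 100])
        ids = site_interval_ids(pos, np.array([[0, 10], [95, 110]]))
        assert ids.tolist() == [0, 0, -1, 1]
        i_idx, j_idx = np.triu_indices(4, k=1)
        keep = classify_pairs(ids, i_idx, j_idx, "within") | classify_pairs(
            ids, i_idx, j_idx, "across")
        touching_outside = (ids[i_idx] < 0) | (ids[j_idx] < 0)
        assert not (keep & touching_outside).any()

    def test_across_pairs_depleted_at_short_distance(self, rng):
        """Short-range pairs mostly fall inside one contiguous interval."""
        pos = np.sort(rng.choice(20_000, 2_000, replace=False)).astype(np.int64)
        pos += 2 * np.arange(2_000)  # enforce >= 2 bp spacing
        intervals = np.array([[s, s + 500] for s in range(0, 28_000, 1_000)])
        ids = site_interval_ids(pos, intervals)
        v = rng.standard_normal(2_000)
        within = distance_correlation(pos, v, d_max=400, min_pairs=1,
                                      interval_ids=ids, scope="within")
        across = distance_correlation(pos, v, d_max=400, min_pairs=1,
                                      interval_ids=ids, scope="across")
        short = within.d <= 100
        assert within.n_pairs[short].sum() > 10 * across.n_pairs[short].sum()


class TestFeatureAssociation:
    def test_perfectly_linear_gives_unit_correlation(self):
        table = pd.DataFrame({
            "magnitude": [0.1, 0.2, 0.3, 0.4],
            "s": [1.0, 2.0, 3.0, 4.0],
            "r": [8, 6, 4, 2],
            "q": [0.9, 0.8, 0.7, 0.6],
        })
        res = feature_association(table).set_index("feature")
        assert res.loc["s", "pearson_r"] == pytest.approx(1.0)
        assert res.loc["r", "pearson_r"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        table = pd.DataFrame({
            "magnitude": rng.random(8),
            "s": rng.random(8), "r": rng.random(8), "q": rng.random(8),
        })
        res = feature_association(table).set_index("feature")
        for col in ("s", "r", "q"):
            x = table[col].to_numpy()
            y = table["magnitude"].to_numpy()
            xc, yc = x - x.mean(), y - y.mean()
            manual = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
            assert res.loc[col, "pearson_r"] == pytest.approx(manual, rel=1e-12)

    def test_too_few_regions_rejected(self):
        table = pd.DataFrame({"magnitude": [0.1, 0.2], "s": [1, 2],
                              "r": [1, 2], "q": [1, 2]})
        with pytest.raises(ValueError):
            feature_association(table)
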