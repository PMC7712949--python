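"""Feature families: wavelet statistics, Hoeffding's D, permutation entropy."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from conftest import hoeffding_brute, make_epoch
from eegmodwt.features import (
    FeatureConfig,
    _hoeffding_all_pairs,
    build_feature_table,
    extract_epoch_features,
    feature_count,
    hoeffding_d,
    permutation_entropy,
    retained_layers_for,
    wavelet_iqr,
    wavelet_pcc,
    wavelet_variance,
)
from eegmodwt.modwt import modwt_decompose


class TestWaveletVariance:
    def test_zero_coefficients(self):
        assert wavelet_variance(np.zeros(10), Lj=4) == 0.0

    def test_hand_computed_boundary_exclusion(self):
        w = np.array([9, 9, 9, 1, -1, 2, -2, 1, -1, 2], dtype=float)
        # boundary coefficients t < 3 (the three 9s) excluded; Mj = 10-4+1 = 7
        assert wavelet_variance(w, Lj=4) == pytest.approx(16 / 7)

    def test_matches_direct_sum(self, rng):
        w = rng.standard_normal(100)
        Lj = 8
        direct = sum(w[t] ** 2 for t in range(Lj - 1, 100)) / (100 - Lj + 1)
        assert wavelet_variance(w, Lj) == pytest.approx(direct, rel=1e-12)

    def test_white_noise_haar_level1(self, rng):
        """Level-1 Haar wavelet variance of white noise is sigma^2/2."""
        sigma = 1.7
        x = sigma * rng.standard_normal(100_000)
        d = modwt_decompose(x, "haar", J=1)
        v = wavelet_variance(d.W[0], int(d.Lj[0]))
        se = np.sqrt(2.0) * (sigma**2 / 2) / np.sqrt(100_000)  # MC standard error
        assert abs(v - sigma**2 / 2) < 3 * se

    def test_all_boundary_rejected(self):
        with pytest.raises(ValueError):
            wavelet_variance(np.ones(5), Lj=7)


class TestWaveletPcc:
    def test_self_and_negated(self, rng):
        w = rng.standard_normal(50)
        assert wavelet_pcc(w, w, Lj=4) == pytest.approx(1.0)
        assert wavelet_pcc(w, -w, Lj=4) == pytest.approx(-1.0)

    def test_independent_series_near_zero(self, rng):
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        assert abs(wavelet_pcc(x, y, Lj=1)) < 0.05

    def test_constant_series_is_nan(self):
        assert np.isnan(wavelet_pcc(np.ones(20), np.arange(20.0), Lj=2))


class TestWaveletIqr:
    def test_constant_coefficients(self):
        assert wavelet_iqr(np.full(20, 2.5), Lj=3) == 0.0

    def test_linear_interpolation_rule(self):
        # values 1..8 retained: P75 = 6.25, P25 = 2.75
        assert wavelet_iqr(np.arange(1.0, 9.0), Lj=1) == pytest.approx(3.5)

    def test_scale_homogeneity(self, rng):
        w = rng.standard_normal(60)
        assert wavelet_iqr(-3.0 * w, Lj=5) == pytest.approx(3.0 * wavelet_iqr(w, Lj=5))


class TestHoeffdingD:
    def test_monotone_dependence_is_one(self):
        assert hoeffding_d([1, 2, 3, 4, 5], [10, 20, 30, 40, 50]) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        """200 random instances incl. ties, n = 5..50, to 1e-12."""
        for _ in range(200):
            n = int(rng.integers(5, 51))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n) + 0.5 * x
            if rng.random() < 0.4:  # discretize to force ties
                x = np.round(x)
                y = np.round(y)
            assert hoeffding_d(x, y) == pytest.approx(hoeffding_brute(x, y), abs=1e-12)

    def test_near_zero_under_independence(self, rng):
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        assert abs(hoeffding_d(x, y)) < 0.01

    def test_rank_invariance_under_monotone_transforms(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        d0 = hoeffding_d(x, y)
        d1 = hoeffding_d(np.exp(x), y**3 + 5 * y)
        assert d0 == pytest.approx(d1, abs=1e-12)

    def test_batched_matches_pairwise(self, rng):
        data = rng.standard_normal((8, 60))
        mat = _hoeffding_all_pairs(data)
        for a in range(8):
            for b in range(a + 1, 8):
                assert mat[a, b] == pytest.approx(hoeffding_d(data[a], data[b]), abs=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            hoeffding_d([1, 2, 3, 4], [1, 2, 3, 4])


class TestPermutationEntropy:
    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_monotone_series_is_zero(self, m):
        assert permutation_entropy(np.arange(100.0), m=m) == pytest.approx(0.0, abs=1e-12)

    def test_alternating_series_m2_approaches_one(self):
        x = np.tile([0.0, 1.0], 500)
        assert permutation_entropy(x, m=2) == pytest.approx(1.0, abs=1e-3)

    def test_matches_exhaustive_enumeration_on_permutations(self):
        """All 120 permutations of (1..5), m=3: entropy from explicit
        ordinal-pattern counting."""
        for perm in permutations(range(1, 6)):
            x = np.array(perm, dtype=float)
            pats = {}
            for t in range(3):
                key = tuple(np.argsort(x[t : t + 3], kind="stable"))
                pats[key] = pats.get(key, 0) + 1
            p = np.array(list(pats.values())) / 3.0
            expected = -(p * np.log(p)).sum() / np.log(6.0)
            assert permutation_entropy(x, m=3) == pytest.approx(expected, abs=1e-12)

    def test_equidistributed_patterns_reach_one(self):
        # concatenation in which each of the 6 m=3 patterns appears equally often
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200_000)
        assert permutation_entropy(x, m=3) == pytest.approx(1.0, abs=0.01)

    def test_bounds_and_errors(self):
        with pytest.raises(ValueError):
            permutation_entropy([1.0, 2.0], m=3)
        with pytest.raises(ValueError):
            permutation_entropy(np.arange(10.0), m=1)


class TestEpochFeatures:
    @pytest.mark.parametrize(
        "filt,layers,expected",
        [
            ("la8", [5, 6, 7], 832),
            ("d4", [5, 6, 7, 8], 1104),
            ("haar", [5, 6, 7, 8, 9, 10], 1648),
        ],
    )
    def test_feature_counts_for_10s_epoch(self, rng, filt, layers, expected):
        """272*j + 16 features from a 16 x 1250 epoch."""
        epoch = make_epoch(rng.standard_normal((16, 1250)))
        feats = extract_epoch_features(epoch, filt, retained_layers=layers)
        assert len(feats) == expected == feature_count(16, len(layers))

    def test_default_retained_layers_exclude_shallowest_four(self):
        assert retained_layers_for(1250, "la8") == [5, 6, 7]
        assert retained_layers_for(1250, "d4") == [5, 6, 7, 8]
        assert retained_layers_for(1250, "haar") == [5, 6, 7, 8, 9, 10]

    def test_deep_exclusion_orientation(self):
        cfg = FeatureConfig(exclude_from="deep")
        assert retained_layers_for(1250, "la8", cfg) == [1, 2, 3]

    def test_zero_epoch_gives_zero_dispersion_features(self):
        epoch = make_epoch(np.zeros((3, 1250)))
        feats = extract_epoch_features(epoch, "haar", retained_layers=[5])
        for name, v in feats.items():
            if name.startswith(("VA_", "IQR_")):
                assert v == 0.0

    def test_feature_values_and_ranges(self, rng):
        epoch = make_epoch(rng.standard_normal((4, 1250)))
        feats = extract_epoch_features(epoch, "la8", retained_layers=[5])
        assert all(np.isfinite(v) for v in feats.values())
        for name, v in feats.items():
            if name.startswith("PCC_"):
                assert -1.0 <= v <= 1.0
            elif name.startswith(("VA_", "IQR_")):
                assert v >= 0.0
            elif name.startswith("PE_"):
                assert 0.0 <= v <= 1.0


class TestFeatureTable:
    def test_table_shape_and_metadata(self, rng):
        epochs = [
            make_epoch(rng.standard_normal((4, 1250)), subject_id=f"S{i // 2}", label="AD" if i % 2 else "NC", epoch_index=i)
            for i in range(6)
        ]
        table = build_feature_table(epochs, "la8", retained_layers=[5, 6])
        assert table.shape == (6, feature_count(4, 2) + 2)
        assert list(table.columns[:2]) == ["subject_id", "label"]
        assert not table.drop(columns=["subject_id", "label"]).isna().any().any()

    def test_constant_channel_imputed_with_column_median(self, rng):
        data = [rng.standard_normal((3, 1250)) for _ in range(4)]
        data[0][2] = 0.0  # one epoch with a flat channel -> undefined PCC
        epochs = [make_epoch(d, subject_id=f"S{i}", epoch_index=i) for i, d in enumerate(data)]
        table = build_feature_table(epochs, "haar", retained_layers=[5])
        col = table["PCC_ch1_ch3_layer5"]
        assert np.isfinite(col).all()
        assert col.iloc[0] == pytest.approx(np.median(col.iloc[1:]))

    def test_inconsistent_shapes_rejected(self, rng):
        epochs = [
            make_epoch(rng.standard_normal((3, 1250))),
            make_epoch(rng.standard_normal((4, 1250))),
        ]
        with pytest.raises(ValueError, match="inconsistent"):
            build_feature_table(epochs, "haar", retained_layers=[5])
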