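"""Feature extraction: PCA, Haar multiresolution transform, weighted PCA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gmmsort import (
    WaveformSet,
    haar_reconstruct,
    haar_wd,
    pca_transform,
    weighted_pca,
)


def make_wfs(values, fs=24000.0, n_channels=1):
    return WaveformSet(
        waveforms=np.asarray(values, dtype=float),
        sampling_rate=fs,
        n_channels=n_channels,
    )


class TestPCA:
    def test_line_in_2d_puts_all_variance_on_pc1(self, rng):
        t = rng.normal(0, 1, 200)
        wfs = make_wfs(np.column_stack([t, 2 * t]))
        fm = pca_transform(wfs)
        ev = fm.method_params["eigenvalues"]
        assert ev[1] == pytest.approx(0.0, abs=1e-12 * ev[0])
        assert fm.values[:, 0].var(ddof=1) == pytest.approx(ev[0], rel=1e-8)

    def test_total_variance_conserved(self, rng):
        x = rng.normal(0, 1, (150, 32))
        fm = pca_transform(make_wfs(x))
        xc = x - x.mean(axis=0)
        total = xc.var(axis=0, ddof=1).sum()
        assert fm.method_params["eigenvalues"].sum() == pytest.approx(total, rel=1e-10)

    def test_scores_match_eigendecomposition_oracle(self, rng):
        x = rng.normal(0, 1, (100, 32))
        fm = pca_transform(make_wfs(x))
        # independent oracle: direct eigendecomposition of the covariance
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(xc.T))
        order = np.argsort(evals)[::-1]
        oracle = xc @ evecs[:, order]
        for c in range(x.shape[1]):
            dots = np.abs([np.dot(fm.values[:, c], oracle[:, c])])
            norm = np.linalg.norm(fm.values[:, c]) * np.linalg.norm(oracle[:, c])
            assert dots[0] == pytest.approx(norm, rel=1e-8)  # equal up to sign

    def test_scores_uncorrelated(self, rng):
        x = rng.normal(0, 1, (200, 16))
        fm = pca_transform(make_wfs(x))
        cov = np.cov(fm.values.T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(cov)).max()

    def test_loadings_orthonormal(self, rng):
        fm = pca_transform(make_wfs(rng.normal(0, 1, (60, 8))))
        A = fm.method_params["loadings"]
        assert np.allclose(A.T @ A, np.eye(8), atol=1e-10)


class TestHaar:
    def test_constant_waveform_details_zero(self):
        wfs = make_wfs(np.full((3, 16), 2.0))
        fm = haar_wd(wfs, levels=4)
        details = [i for i, f in enumerate(fm.feature_ids) if f.scale > 0]
        approx = [i for i, f in enumerate(fm.feature_ids) if f.scale < 0]
        assert np.allclose(fm.values[:, details], 0.0, atol=1e-12)
        energy = (fm.values[:, approx] ** 2).sum(axis=1)
        assert energy == pytest.approx([16 * 4.0] * 3)

    def test_hand_computed_example(self):
        wfs = make_wfs([[1.0, 1.0, -1.0, -1.0]])
        fm = haar_wd(wfs, levels=2)
        by_label = dict(zip(fm.labels, fm.values[0]))
        assert by_label["wd_c0_d1_k0"] == pytest.approx(0.0)
        assert by_label["wd_c0_d1_k1"] == pytest.approx(0.0)
        assert by_label["wd_c0_d2_k0"] == pytest.approx(2.0)
        assert by_label["wd_c0_a2_k0"] == pytest.approx(0.0)

    def test_energy_conserved_and_invertible(self, rng):
        x = rng.normal(0, 1, (50, 64))
        fm = haar_wd(make_wfs(x), levels=4)
        assert fm.values.shape == x.shape  # full decomposition, n coefficients
        assert np.allclose(
            (fm.values**2).sum(axis=1), (x**2).sum(axis=1), rtol=1e-9
        )
        rec = haar_reconstruct(fm)
        assert np.abs(rec - x).max() < 1e-10

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_orthonormality_property(self, seed):
        x = np.random.default_rng(seed).normal(0, 1, (4, 64))
        fm = haar_wd(make_wfs(x), levels=4)
        assert np.allclose((fm.values**2).sum(), (x**2).sum(), rtol=1e-9)
        assert np.abs(haar_reconstruct(fm) - x).max() < 1e-10

    def test_multichannel_equals_concatenated_single_channels(self, rng):
        x = rng.normal(0, 1, (20, 4 * 32))
        fm4 = haar_wd(
            WaveformSet(x, sampling_rate=30000.0, n_channels=4), levels=4
        )
        per = [
            haar_wd(make_wfs(x[:, 32 * c : 32 * (c + 1)]), levels=4).values
            for c in range(4)
        ]
        assert np.allclose(fm4.values, np.hstack(per))

    def test_padding_flags_when_not_divisible(self, rng):
        x = rng.normal(0, 1, (5, 20))  # 20 not divisible by 16
        fm = haar_wd(make_wfs(x), levels=4)
        assert any(f.padded for f in fm.feature_ids)
        # unpadded coefficients (level-1 details over the first samples) intact
        first = [f for f in fm.feature_ids if f.scale == 1 and f.shift == 0][0]
        assert not first.padded

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            haar_wd(make_wfs(np.zeros((2, 8))), levels=4)


class TestWeightedPCA:
    def test_equal_weights_equals_pca_of_zscores(self, rng):
        x = rng.normal(0, 1, (100, 64)) * rng.uniform(0.5, 5.0, 64)
        fm = haar_wd(make_wfs(x), levels=4)
        w_eq = weighted_pca(fm, np.full(fm.n_features, 3.7))
        z = (fm.values - fm.values.mean(0)) / fm.values.std(0, ddof=1)
        ref = pca_transform(make_wfs(z))
        # a uniform weight rescales the scores but leaves the directions alone
        assert np.allclose(np.abs(w_eq.values), 3.7 * np.abs(ref.values), atol=1e-8)

    def test_dominant_weight_aligns_pc1(self, rng):
        fm = haar_wd(make_wfs(rng.normal(0, 1, (200, 16)), fs=1000.0), levels=2)
        w = np.full(fm.n_features, 1e-3)
        w[5] = 100.0
        out = weighted_pca(fm, w)
        loadings = out.method_params["loadings"]
        cos = np.abs(loadings[5, 0]) / np.linalg.norm(loadings[:, 0])
        assert cos > 0.99

    def test_zero_variance_columns_dropped(self, rng):
        x = rng.normal(0, 1, (50, 16))
        x[:, 3] = 1.0  # constant column survives the transform as constant approx?
        fm = haar_wd(make_wfs(x), levels=2)
        fm.values[:, 2] = 0.0  # force a degenerate coefficient
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out = weighted_pca(fm, np.ones(fm.n_features))
        assert out.n_features == fm.n_features - 1

    def test_all_zero_weights_rejected(self, rng):
        fm = haar_wd(make_wfs(rng.normal(0, 1, (30, 16)), fs=1000.0), levels=2)
        with pytest.raises(ValueError, match="no informative"):
            weighted_pca(fm, np.zeros(fm.n_features))

    def test_column_permutation_equivariance(self, rng):
        x = rng.normal(0, 1, (80, 12)) * rng.uniform(0.5, 2.0, 12)
        from gmmsort.features import FeatureMatrix, FeatureId

        ids = [FeatureId(method="wd", scale=1, shift=i) for i in range(12)]
        fm = FeatureMatrix(x, ids)
        w = rng.uniform(0.1, 2.0, 12)
        perm = rng.permutation(12)
        fm_p = FeatureMatrix(x[:, perm], [ids[i] for i in perm])
        a = weighted_pca(fm, w)
        b = weighted_pca(fm_p, w[perm])
        assert np.allclose(np.abs(a.values), np.abs(b.values), atol=1e-8)


class TestWaveformSet:
    def test_shape_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            WaveformSet(np.zeros((3, 10)), sampling_rate=1000.0, n_channels=4)

    def test_nonfinite_rejected(self):
        w = np.zeros((2, 8))
        w[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            WaveformSet(w, sampling_rate=1000.0)
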