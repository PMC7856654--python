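"""SNR formula, differential maps, SVD projection and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sensmap.analytic import meg_sphere_field
from sensmap.sensors import fibonacci_sphere
from sensmap.snr import (
    SnrConfig,
    differential_snr,
    heatmap_by_column,
    snr_map,
    summarize_by_bins,
    svd_project,
)


class TestSnrFormula:
    def test_signal_equals_noise_is_zero_db(self):
        # N = 1, a*b = s: ratio 1 -> 0 dB
        b = np.array([[0.5]])          # uV/nAm
        s2 = np.array([25.0])          # (a*b)^2 = 25 with a = 10
        assert snr_map(b, s2, SnrConfig(10.0))[0] == pytest.approx(0.0)

    def test_hand_arithmetic_10_db(self):
        # a = 10 nAm, b = 1 uV/nAm, s^2 = 10 uV^2 -> 10 log10(100/10) = 10 dB
        assert snr_map(np.array([[1.0]]), np.array([10.0]),
                       SnrConfig(10.0))[0] == pytest.approx(10.0)

    def test_amplitude_doubling_adds_6_db(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=(7, 5))
        s2 = rng.uniform(1, 4, size=7)
        d = snr_map(b, s2, SnrConfig(20.0)) - snr_map(b, s2, SnrConfig(10.0))
        np.testing.assert_allclose(d, 20 * np.log10(2), rtol=1e-12)

    def test_joint_scaling_invariance(self):
        rng = np.random.default_rng(1)
        b = rng.normal(size=(5, 4))
        s2 = rng.uniform(0.5, 2, size=5)
        c = 3.7
        np.testing.assert_allclose(
            snr_map(c * b, c ** 2 * s2), snr_map(b, s2), rtol=1e-12
        )

    def test_increasing_one_noise_variance_decreases_snr(self):
        rng = np.random.default_rng(2)
        b = rng.normal(size=(4, 6))
        s2 = np.ones(4)
        base = snr_map(b, s2)
        s2b = s2.copy()
        s2b[2] *= 4.0
        assert np.all(snr_map(b, s2b) < base)

    def test_zero_column_gives_neg_inf_sentinel(self):
        b = np.array([[1.0, 0.0], [2.0, 0.0]])
        out = snr_map(b, np.array([1.0, 1.0]))
        assert np.isfinite(out[0]) and out[1] == -np.inf

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            snr_map(np.ones((2, 2)), np.array([1.0, 0.0]))


class TestDifferential:
    def test_values_and_antisymmetry(self):
        meg = np.array([12.0, 3.0])
        eeg = np.array([5.0, 3.0])
        d = differential_snr(meg, eeg)
        np.testing.assert_allclose(d, [7.0, 0.0])
        np.testing.assert_allclose(differential_snr(eeg, meg), -d)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            differential_snr(np.ones(3), np.ones(2))


class TestSvdProjection:
    def test_orthogonal_columns_already_svd(self):
        L = np.diag([3.0, 2.0, 1.0])
        L = np.vstack([L, np.zeros((2, 3))])
        p = svd_project(L, np.ones((4, 3)))
        np.testing.assert_allclose(p.singular_values, [3.0, 2.0, 1.0])
        # V is a signed permutation of identity, sign-fixed positive
        np.testing.assert_allclose(np.abs(p.v), np.eye(3), atol=1e-12)
        assert np.all(p.v[np.argmax(np.abs(p.v), axis=0), np.arange(3)] > 0)

    def test_rank_two_third_singular_value_zero(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 8))
        L = np.column_stack([a, b, a + b])
        p = svd_project(L, np.ones((4, 3)))
        assert p.singular_values[2] == pytest.approx(0.0, abs=1e-12)

    def test_projection_reconstructs_leadfield(self):
        rng = np.random.default_rng(3)
        L = rng.normal(size=(12, 3))
        E = rng.normal(size=(6, 3))
        p = svd_project(L, E)
        np.testing.assert_allclose(p.meg @ p.v.T, L, atol=1e-10)
        np.testing.assert_allclose(p.eeg @ p.v.T, E, atol=1e-10)

    def test_sphere_leadfield_identifies_radial_direction(self):
        # Sarvas-generated n x 3 leadfields: V's last column is radial
        coils = fibonacci_sphere(271, 120.0, seed=4)
        orient = coils / np.linalg.norm(coils, axis=1, keepdims=True)
        rng = np.random.default_rng(5)
        for _ in range(10):
            pos = rng.normal(size=3)
            pos = pos / np.linalg.norm(pos) * rng.uniform(0.3, 0.8) * 78.0
            L = np.empty((271, 3))
            for k in range(3):
                e = np.zeros(3)
                e[k] = 1.0
                for c in range(271):
                    L[c, k] = meg_sphere_field([0, 0, 0], pos, e, coils[c]) @ orient[c]
            p = svd_project(L, np.ones((4, 3)))
            radial = pos / np.linalg.norm(pos)
            assert abs(p.radial_direction @ radial) >= 0.95

    def test_energy_conserved_under_projection_with_uniform_noise(self):
        # orthogonal V preserves sum_k b^2 / s^2 when noise is channel-constant
        rng = np.random.default_rng(6)
        L = rng.normal(size=(10, 3))
        p = svd_project(L, np.ones((4, 3)))
        s2 = np.full(10, 2.5)
        raw = np.sum(L ** 2 / s2[:, None])
        proj = np.sum(p.meg ** 2 / s2[:, None])
        assert proj == pytest.approx(raw, rel=1e-12)

    def test_whitened_variant_conserves_noise_weighted_energy(self):
        # with heterogeneous noise, whitening before the SVD makes the
        # component split conserve sum_k b^2 / s^2 exactly
        rng = np.random.default_rng(8)
        L = rng.normal(size=(10, 3))
        s2 = rng.uniform(0.5, 5.0, size=10)
        p = svd_project(L, np.ones((4, 3)), meg_noise_std=np.sqrt(s2))
        raw = np.sum(L ** 2 / s2[:, None])
        proj = np.sum(p.meg ** 2 / s2[:, None])
        assert proj == pytest.approx(raw, rel=1e-12)

    def test_rank_zero_rejected(self):
        with pytest.raises(ValueError, match="rank-0"):
            svd_project(np.zeros((5, 3)), np.zeros((4, 3)))


class TestSummaries:
    def test_hand_built_two_bin_example(self):
        vals = np.array([1.0, 2, 3, 4, 5, 10, 20, 30, 40, 50])
        cov = np.array([0.1] * 5 + [0.9] * 5)
        s = summarize_by_bins(vals, cov, n_bins=2, covariate_range=(0.0, 1.0))
        np.testing.assert_allclose(s.five_number[0], [1, 2, 3, 4, 5])
        np.testing.assert_allclose(s.five_number[1], [10, 20, 30, 40, 50])
        assert s.counts.tolist() == [5, 5]

    def test_constant_values(self):
        s = summarize_by_bins(np.full(9, 4.2), np.linspace(0, 1, 9), n_bins=3)
        nz = s.counts > 0
        np.testing.assert_allclose(s.five_number[nz], 4.2)

    def test_neg_inf_excluded_from_summaries_but_counted(self):
        vals = np.array([-np.inf, 1.0, 2.0, 3.0])
        s = summarize_by_bins(vals, np.zeros(4), n_bins=1, covariate_range=(0, 1))
        assert s.counts[0] == 4
        np.testing.assert_allclose(s.five_number[0], [1, 1.5, 2, 2.5, 3])


class TestHeatmap:
    def test_hand_placed_points(self):
        snr = np.array([0.5, 0.5, 1.5, 1.5, 1.5, 0.5])
        cov = np.array([0.5, 0.5, 0.5, 1.5, 2.5, 2.5])
        hm = heatmap_by_column(snr, cov, snr_bins=2, covariate_bins=3,
                               snr_range=(0.0, 2.0), covariate_range=(0.0, 3.0))
        expected = np.array([[2 / 3, 0.0, 0.5],
                             [1 / 3, 1.0, 0.5]])
        np.testing.assert_allclose(hm.matrix, expected)

    def test_columns_sum_to_one_or_zero(self):
        rng = np.random.default_rng(7)
        hm = heatmap_by_column(rng.normal(size=300), rng.uniform(0, 1, 300),
                               snr_bins=10, covariate_bins=5)
        sums = hm.matrix.sum(axis=0)
        assert np.all((np.abs(sums - 1) < 1e-12) | (sums == 0))

    def test_single_cell_mass(self):
        hm = heatmap_by_column([1.0, 1.0], [0.5, 0.5], snr_bins=2,
                               covariate_bins=2, snr_range=(0, 2),
                               covariate_range=(0, 2))
        assert hm.matrix.max() == 1.0
        assert hm.matrix.sum() == 1.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-50, 50), min_size=1, max_size=60),
    st.floats(0.1, 10.0),
)
def test_snr_homogeneity_property(values, scale):
    """Scaling leadfield and noise std together never changes any SNR."""
    b = np.array(values)[None, :]
    s2 = np.array([2.0])
    np.testing.assert_allclose(
        snr_map(scale * b, scale ** 2 * s2), snr_map(b, s2),
        rtol=1e-9, atol=1e-9,
    )
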