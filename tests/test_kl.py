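"""Spectral densities, KL divergence, likelihood weighting and denoising."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleoxrf.core import EnergyCalibration, SpectralMap, Spectrum
from paleoxrf.kl import (
    KLTissueModel,
    SpectralDensity,
    denoised_density,
    divergence_map,
    kl_divergence,
    likelihood_weights,
    log_ratio,
    spectral_density,
    weight_histogram,
)

# Hand-derived reference values (direct evaluation of the divergence sum):
# t=[3,1] -> t_hat=(0.75, 0.25); s=[1,3]+1=[2,4] -> s_hat=(1/3, 2/3)
KL_31_13 = 0.75 * np.log(0.75 / (1 / 3)) + 0.25 * np.log(0.25 / (2 / 3))


class TestSpectralDensity:
    @pytest.mark.parametrize("counts,expected", [
        ([2, 2, 2, 2], [0.25, 0.25, 0.25, 0.25]),
        ([0, 10], [0.0, 1.0]),
        ([3, 1], [0.75, 0.25]),
    ])
    def test_normalization(self, counts, expected):
        assert np.allclose(spectral_density(np.array(counts)).probabilities,
                           expected)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            spectral_density(np.zeros(4))

    def test_density_invariants_enforced(self):
        with pytest.raises(ValueError):
            SpectralDensity(np.array([0.5, 0.4]))     # does not sum to 1
        with pytest.raises(ValueError):
            SpectralDensity(np.array([1.2, -0.2]))    # negative entry


class TestKLDivergence:
    def test_identity_is_zero_without_pseudocount(self):
        t = np.array([5, 3, 2, 7])
        assert kl_divergence(t, t, pseudocount=0) == pytest.approx(0.0, abs=1e-14)

    def test_hand_derived_examples(self):
        assert kl_divergence([3, 1], [1, 3], 1) == pytest.approx(KL_31_13, abs=1e-12)
        assert kl_divergence([0, 4], [4, 0], 1) == pytest.approx(np.log(6), abs=1e-12)

    def test_pseudocount_applies_to_evaluated_only(self):
        # reference untouched: zero reference channels contribute nothing
        val = kl_divergence([0, 4], [0, 4], 1)
        assert val == pytest.approx(np.log((4 + 2) / (4 + 1)), abs=1e-12)

    def test_scale_invariance_of_reference(self):
        t = np.array([4, 1, 3])
        s = np.array([2, 2, 2])
        assert kl_divergence(t * 7, s, 0) == pytest.approx(
            kl_divergence(t, s, 0), abs=1e-12)

    def test_asymmetry(self):
        assert kl_divergence([5, 1], [1, 3], 1) != pytest.approx(
            kl_divergence([1, 3], [5, 1], 1))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            kl_divergence([1, 2], [1, 2, 3])

    @given(st.lists(st.integers(0, 200), min_size=2, max_size=40),
           st.lists(st.integers(0, 200), min_size=2, max_size=40))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_nonnegative_for_any_spectra(self, t, s):
        n = min(len(t), len(s))
        t, s = np.array(t[:n]), np.array(s[:n])
        if t.sum() == 0:
            return
        assert kl_divergence(t, s, 1) >= 0.0


class TestDivergenceMap:
    def test_uniform_map_is_zero_with_pseudocount_zero(self):
        cal = EnergyCalibration(0.0, 0.1, 4)
        cube = np.tile(np.array([3, 1, 2, 4], np.uint32), (3, 5, 1))
        div = divergence_map(SpectralMap(cube, cal), (1, 2), pseudocount=0)
        assert np.allclose(div.values, 0.0, atol=1e-12)

    def test_two_pixel_map_reduces_to_single_divergence(self):
        cal = EnergyCalibration(0.0, 0.1, 2)
        cube = np.array([[[3, 1]], [[1, 3]]], dtype=np.uint32)
        div = divergence_map(SpectralMap(cube, cal), (0, 0), pseudocount=1)
        # reference evaluated against itself with the pseudocount applied
        assert div.values[0, 0] == pytest.approx(
            kl_divergence([3, 1], [3, 1], 1), abs=1e-12)
        assert div.values[1, 0] == pytest.approx(KL_31_13, abs=1e-12)

    def test_zero_count_pixels_flagged_invalid(self):
        cal = EnergyCalibration(0.0, 0.1, 2)
        cube = np.array([[[3, 1], [0, 0]]], dtype=np.uint32)
        div = divergence_map(SpectralMap(cube, cal), (0, 0))
        assert not div.valid[0, 1]
        assert np.isinf(div.values[0, 1])

    def test_empty_reference_errors(self):
        cal = EnergyCalibration(0.0, 0.1, 2)
        cube = np.array([[[3, 1], [0, 0]]], dtype=np.uint32)
        with pytest.raises(ValueError):
            divergence_map(SpectralMap(cube, cal), (0, 1))

    def test_within_class_below_between_class(self, fish_cube, fish_phantom,
                                              reference_pixels):
        div = divergence_map(fish_cube, reference_pixels["bone"])
        labels = fish_phantom.labels
        bone = fish_phantom.class_index("bone")
        matrix = fish_phantom.class_index("matrix")
        assert div.values[labels == bone].mean() < \
            div.values[labels == matrix].mean()


class TestWeights:
    def test_exp_transform_examples(self):
        from paleoxrf.kl import DivergenceImage, WeightImage

        values = np.array([[0.0, np.log(1 / 0.8), 1.0]])
        div_img = DivergenceImage(values, (0, 0), 1)
        w = likelihood_weights(div_img, 0.8)
        assert w.weights[0, 0] == pytest.approx(1.0)
        assert w.weights[0, 1] == pytest.approx(0.8)
        assert w.weights[0, 2] == pytest.approx(np.exp(-1.0), abs=1e-12)
        # w = exp(-1) ~ 0.368 is excluded at λ = 0.8; w = 1 retained
        assert w.retained[0, 0] and not w.retained[0, 2]
        # the λ = w boundary is inclusive
        boundary = WeightImage(np.array([[0.8]]), 0.8, np.ones((1, 1), bool))
        assert boundary.retained[0, 0]

    def test_threshold_domain(self):
        from paleoxrf.kl import DivergenceImage

        div = DivergenceImage(np.zeros((1, 1)), (0, 0), 1)
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                likelihood_weights(div, bad)

    def test_invalid_pixels_get_zero_weight(self):
        cal = EnergyCalibration(0.0, 0.1, 2)
        cube = np.array([[[3, 1], [0, 0]]], dtype=np.uint32)
        w = likelihood_weights(divergence_map(SpectralMap(cube, cal), (0, 0)))
        assert w.weights[0, 1] == 0.0 and not w.retained[0, 1]


class TestDenoised:
    def _map(self, cube):
        cal = EnergyCalibration(0.0, 0.1, cube.shape[2])
        return SpectralMap(cube.astype(np.uint32), cal)

    def test_single_retained_pixel_returns_its_density(self):
        cube = np.array([[[8, 2], [1, 1]]])
        m = self._map(cube)
        w = likelihood_weights(divergence_map(m, (0, 0)), 0.9)
        assert w.retained.sum() == 1
        den = denoised_density(m, w)
        assert np.allclose(den.probabilities, [0.8, 0.2])

    def test_identical_retained_pixels_fixed_point(self):
        cube = np.tile(np.array([6, 2, 2]), (2, 3, 1))
        m = self._map(cube)
        w = likelihood_weights(divergence_map(m, (0, 0)), 0.8)
        den = denoised_density(m, w)
        assert np.allclose(den.probabilities, [0.6, 0.2, 0.2])

    def test_convex_combination_bounds(self, fish_cube, reference_pixels):
        res = KLTissueModel(fish_cube, reference_pixels["bone"]).fit(0.8)
        cube = fish_cube.counts_cube[res.weights.retained].astype(float)
        dens = cube / cube.sum(axis=1, keepdims=True)
        p = res.denoised.probabilities
        assert np.all(p >= dens.min(axis=0) - 1e-12)
        assert np.all(p <= dens.max(axis=0) + 1e-12)

    def test_empty_retained_set_advises(self):
        from paleoxrf.kl import WeightImage

        m = self._map(np.array([[[8, 2], [1, 1]]]))
        w = WeightImage(np.array([[0.5, 0.3]]), 0.8, np.ones((1, 2), bool))
        with pytest.raises(ValueError, match="threshold"):
            denoised_density(m, w)


class TestHistogram:
    def test_all_weights_one_single_top_bin(self):
        cal = EnergyCalibration(0.0, 0.1, 2)
        cube = np.tile(np.array([3, 1], np.uint32), (2, 2, 1))
        w = likelihood_weights(divergence_map(SpectralMap(cube, cal), (0, 0), 0))
        edges, counts, thr = weight_histogram(w, 10)
        assert counts.sum() == 4 and counts[-1] == 4
        assert thr == 0.8

    def test_two_values_two_bins(self):
        from paleoxrf.kl import DivergenceImage

        div = DivergenceImage(np.array([[np.log(1 / 0.45), np.log(10 / 9)]]),
                              (0, 0), 1)
        w = likelihood_weights(div)
        edges, counts, _ = weight_histogram(w, 2)   # weights 0.45 and 0.9
        assert counts.tolist() == [1, 1]

    def test_phantom_histogram_bimodal(self, fish_cube, fish_phantom,
                                       reference_pixels):
        """Bone reference: same-tissue weights cluster high, the rest low."""
        w = likelihood_weights(divergence_map(fish_cube,
                                              reference_pixels["bone"]))
        edges, counts, _ = weight_histogram(w, 20)
        centers = (edges[:-1] + edges[1:]) / 2
        n_bone = (fish_phantom.labels ==
                  fish_phantom.class_index("bone")).sum()
        assert counts[centers > 0.8].sum() >= 0.9 * n_bone
        assert counts[centers < 0.5].sum() >= 0.5 * fish_phantom.labels.size
        # valley between the low mode and the same-tissue mode
        valley = counts[(centers > 0.45) & (centers < 0.7)].sum()
        assert valley < 0.05 * counts.sum()


class TestLogRatio:
    def test_identity_zero(self):
        d = SpectralDensity(np.array([0.5, 0.5]))
        assert np.allclose(log_ratio(d, d), 0.0)

    def test_direct_evaluation(self):
        d1 = SpectralDensity(np.array([0.8, 0.2]))
        d2 = SpectralDensity(np.array([0.2, 0.8]))
        assert np.allclose(log_ratio(d1, d2), [np.log(4), -np.log(4)])

    def test_zero_channel_conventions(self):
        d1 = SpectralDensity(np.array([0.0, 0.5, 0.5, 0.0]))
        d2 = SpectralDensity(np.array([0.0, 0.25, 0.25, 0.5]))
        r = log_ratio(d1, d2)
        assert r[0] == 0.0                      # both zero
        assert np.isposinf(log_ratio(d2, d1)[3])  # only d2 nonzero there
        assert np.isneginf(r[3])

    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=16))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_antisymmetry(self, raw):
        p = np.array(raw)
        a = SpectralDensity(p / p.sum())
        q = np.array(raw[::-1])
        b = SpectralDensity(q / q.sum())
        assert np.allclose(log_ratio(a, b), -log_ratio(b, a))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            log_ratio(SpectralDensity(np.array([1.0])),
                      SpectralDensity(np.array([0.5, 0.5])))


def test_model_results_summary(fish_cube, reference_pixels):
    res = KLTissueModel(fish_cube, reference_pixels["muscle"]).fit(0.8)
    text = res.summary()
    assert "retained" in text and "threshold" in text
    assert res.n_retained > 0
    assert res.denoised.probabilities.sum() == pytest.approx(1.0)
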