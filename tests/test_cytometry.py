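"""Cytometry statistics: stoichiometry, arcsinh normalization, mixture
fits, separation, blank widths and linearity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclim import (arcsinh_transform, blank_width_ratio,
                    expected_labeled_epitopes, fit_arcsinh_scale,
                    fit_loglog_linearity, fit_two_gaussians, separation)
from cyclim.cytometry import ArcsinhScale, fit_two_gaussians_hist
from cyclim.errors import DegenerateScaleError, InputError


class TestExpectedEpitopes:
    @pytest.mark.parametrize("pct,expected", [
        (100.0, 57_000.0), (33.0, 18_810.0), (10.0, 5700.0), (3.30, 1881.0),
        (1.00, 570.0), (0.330, 188.1), (0.100, 57.0), (0.0330, 18.81),
        (0.0100, 5.7), (0.0, 0.0),
    ])
    def test_titration_column(self, pct, expected):
        assert expected_labeled_epitopes(pct) == pytest.approx(expected)

    @pytest.mark.parametrize("pct,printed", [(33.0, 19_000.0), (0.330, 190.0),
                                             (0.0330, 19.0)])
    def test_two_significant_figure_style(self, pct, printed):
        assert expected_labeled_epitopes(pct, round_2sf=True) == printed

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            expected_labeled_epitopes(120.0)


class TestArcsinhScale:
    def test_fit_pins_blank_to_zero_and_top_to_two(self):
        rng = np.random.default_rng(4)
        blank = rng.normal(50.0, 20.0, 5000)
        top = rng.normal(50_000.0, 8000.0, 5000)
        scale = fit_arcsinh_scale(blank, top)
        assert abs(arcsinh_transform(blank, scale).mean()) < 1e-9
        assert abs(arcsinh_transform(top, scale).mean() - 2.0) < 1e-9

    def test_rescaled_intensities_rescale_a_only(self):
        rng = np.random.default_rng(5)
        blank = rng.normal(10.0, 3.0, 2000)
        top = rng.normal(5000.0, 400.0, 2000)
        scale = fit_arcsinh_scale(blank, top)
        c = 12.5
        rescaled = fit_arcsinh_scale(c * blank, c * top)
        assert rescaled.a == pytest.approx(scale.a / c, rel=1e-6)
        assert rescaled.b == pytest.approx(scale.b, abs=1e-6)
        np.testing.assert_allclose(arcsinh_transform(c * blank, rescaled),
                                   arcsinh_transform(blank, scale), atol=1e-9)

    def test_inverted_populations_rejected(self):
        with pytest.raises(DegenerateScaleError):
            fit_arcsinh_scale(np.array([10.0, 11.0]), np.array([1.0, 2.0]))

    def test_transform_basics(self):
        scale = ArcsinhScale(a=1.0, b=0.0)
        assert arcsinh_transform(0.0, scale) == 0.0
        # asymptotically log10(2aI)
        big = 1e8
        assert abs(arcsinh_transform(big, scale)
                   - np.log10(2 * big)) < 1e-9

    @given(st.floats(min_value=0.01, max_value=100.0),
           st.floats(min_value=-50.0, max_value=50.0))
    @settings(max_examples=30, deadline=None)
    def test_transform_strictly_increasing(self, a, b):
        scale = ArcsinhScale(a=a, b=b)
        grid = np.linspace(-1e4, 1e4, 200)
        y = arcsinh_transform(grid, scale)
        assert np.all(np.diff(y) > 0)


class TestSeparation:
    @pytest.mark.parametrize("args,expected", [
        ((0, 1, 0, 1), 0.0),
        ((0, 1, 2, 1), np.sqrt(2)),
        ((0, 3, 4, 4), 0.8),
    ])
    def test_closed_forms(self, args, expected):
        assert separation(*args) == pytest.approx(expected)

    @given(st.floats(-10, 10), st.floats(0.1, 5), st.floats(-10, 10),
           st.floats(0.1, 5), st.floats(0.1, 4), st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_affine_invariant(self, mu1, s1, mu2, s2, scale,
                                            shift):
        s = separation(mu1, s1, mu2, s2)
        assert separation(mu2, s2, mu1, s1) == pytest.approx(s)
        assert separation(scale * mu1 + shift, scale * s1,
                          scale * mu2 + shift,
                          scale * s2) == pytest.approx(s, rel=1e-9)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(InputError):
            separation(0, 0, 1, 1)


class TestTwoGaussianFit:
    def test_recovers_root_two_separation(self):
        rng = np.random.default_rng(10)
        y = np.concatenate([rng.normal(0, 1, 5000), rng.normal(2, 1, 5000)])
        fit = fit_two_gaussians(y, seed=0)
        assert abs(fit.s - np.sqrt(2)) / np.sqrt(2) < 0.05

    def test_identical_components_give_near_zero_separation(self):
        rng = np.random.default_rng(11)
        y = rng.normal(1.0, 0.5, 5000)
        fit = fit_two_gaussians(y, seed=0)
        assert fit.degenerate or fit.s < 0.5

    def test_matches_reference_mixture_fit(self):
        # independent cross-check against scikit-learn's EM
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(12)
        y = np.concatenate([rng.normal(0, 1, 3000), rng.normal(3, 0.8, 3000)])
        ours = fit_two_gaussians(y, seed=0)
        gm = GaussianMixture(2, random_state=0, tol=1e-8, max_iter=2000)
        gm.fit(y[:, None])
        mus = np.sort(gm.means_.ravel())
        sds = np.sqrt(gm.covariances_.ravel())[np.argsort(gm.means_.ravel())]
        s_ref = abs(mus[1] - mus[0]) / np.hypot(sds[0], sds[1])
        assert ours.s == pytest.approx(s_ref, rel=0.02)

    def test_recovery_at_resolvability_floor(self):
        # s = 1.3 is about the weakest separation that published double
        # Gaussian fits still resolve; over 20 replicates the median
        # relative error stays below 5%
        true_s = 1.3
        delta = true_s * np.sqrt(2)
        errs = []
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            y = np.concatenate([rng.normal(0, 1, 5000),
                                rng.normal(delta, 1, 5000)])
            fit = fit_two_gaussians(y, seed=rep)
            errs.append(abs(fit.s - true_s) / true_s)
        assert np.median(errs) < 0.05

    def test_histogram_mode_agrees_with_em(self):
        rng = np.random.default_rng(13)
        y = np.concatenate([rng.normal(0, 1, 4000), rng.normal(3, 1, 4000)])
        em = fit_two_gaussians(y, seed=0)
        hist = fit_two_gaussians_hist(y, bins=80)
        assert hist.s == pytest.approx(em.s, rel=0.1)

    def test_tiny_sample_rejected(self):
        with pytest.raises(InputError):
            fit_two_gaussians(np.zeros(10))


class TestBlankWidth:
    def test_identical_samples_ratio_one(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, 1000)
        assert blank_width_ratio(x, x) == 1.0

    def test_known_sds_ratio(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 2.0, 200_000)
        b = rng.normal(0, 1.0, 200_000)
        assert blank_width_ratio(a, b) == pytest.approx(0.5, rel=0.01)

    def test_fourteen_point_five_fold_narrower_blank(self):
        # imaging-vs-flow style comparison: instrument A's blank is 14.5x
        # narrower, so the ratio of widths recovers 14.5
        rng = np.random.default_rng(16)
        sigma_b = 0.04
        a = rng.normal(0, sigma_b, 10_000)
        b = rng.normal(0, 14.5 * sigma_b, 10_000)
        assert blank_width_ratio(a, b) == pytest.approx(14.5, rel=0.05)

    def test_robust_width_option(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0, 1.0, 50_000)
        spoiled = np.concatenate([a, [1e6]])
        assert blank_width_ratio(a, spoiled, width="mad") == pytest.approx(
            1.0, rel=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            blank_width_ratio(np.ones(10), np.arange(10.0))


class TestLinearity:
    def test_exact_proportionality_gives_unit_slope(self):
        levels = np.array([1e-4, 1e-3, 1e-2, 1e-1, 1.0])
        samples = [np.full(10, 500.0 * lv) for lv in levels]
        fit = fit_loglog_linearity(levels, samples)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_quadratic_data_gives_slope_two(self):
        levels = np.array([0.01, 0.1, 1.0, 10.0])
        samples = [np.full(5, 3.0 * lv**2) for lv in levels]
        assert fit_loglog_linearity(levels, samples).slope == pytest.approx(2.0)

    def test_nonpositive_level_mean_excluded_with_warning(self):
        levels = np.array([0.0, 0.01, 0.1, 1.0])
        samples = [np.zeros(5)] + [np.full(5, lv) for lv in levels[1:]]
        with pytest.warns(UserWarning):
            fit = fit_loglog_linearity(levels, samples)
        assert fit.slope == pytest.approx(1.0)

    def test_too_few_levels_rejected(self):
        with pytest.raises(InputError):
            fit_loglog_linearity(np.array([0.1, 1.0]),
                                 [np.ones(3), np.ones(3)])
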