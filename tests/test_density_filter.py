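"""Cross-validated KDE bandwidth selection and first-valley thresholding."""

import numpy as np
import pytest

from eggflow import (
    DegenerateSampleError,
    NoValleyError,
    first_valley,
    mode_filter,
    select_bandwidth,
)
from eggflow.density_filter import KDEFit
from eggflow.io_lpfc import STATUS_DEBRIS

from conftest import make_sample


def mixture(n, seed, w1=0.3, mu1=90.0, sd1=15.0, mu2=410.0, sd2=40.0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n1 = rng.binomial(n, w1)
    return np.concatenate(
        [rng.normal(mu1, sd1, n1), rng.normal(mu2, sd2, n - n1)]
    )


def fake_fit(log_density, grid=None) -> KDEFit:
    y = np.asarray(log_density, dtype=float)
    x = np.arange(y.size, dtype=float) if grid is None else np.asarray(grid, dtype=float)
    return KDEFit(
        bandwidth=1.0,
        bandwidth_grid=np.array([1.0]),
        cv_scores=np.array([0.0]),
        eval_grid=x,
        log_density=y,
        n=y.size,
    )


class TestSelectBandwidth:
    def test_standard_normal_bandwidth_in_plausible_range(self):
        """CV on N(0,1), n=1000: the plug-in optimum ≈ 1.06·n^(−1/5) ≈ 0.27."""
        rng = np.random.default_rng(1)
        fit = select_bandwidth(rng.normal(0, 1, 1000), grid=np.arange(0.05, 1.01, 0.05), seed=1)
        assert 0.1 <= fit.bandwidth <= 0.5

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            select_bandwidth([0.0, 0.0], grid=[0.1, 0.2])

    def test_fewer_values_than_folds(self):
        with pytest.raises(ValueError, match="n_folds"):
            select_bandwidth([1.0, 2.0, 3.0], n_folds=5)

    def test_deterministic_under_seed(self):
        values = np.random.default_rng(3).normal(400, 30, 200)
        a = select_bandwidth(values, seed=7)
        b = select_bandwidth(values, seed=7)
        assert a.bandwidth == b.bandwidth
        np.testing.assert_array_equal(a.cv_scores, b.cv_scores)
        np.testing.assert_array_equal(a.log_density, b.log_density)

    def test_cv_score_ties_resolve_to_smaller_bandwidth(self):
        fit = select_bandwidth(
            np.random.default_rng(0).normal(0, 1, 50), grid=[0.3, 0.3, 0.3], seed=0
        )
        assert fit.bandwidth == 0.3
        assert fit.bandwidth == fit.bandwidth_grid[0]

    def test_cv_score_matches_sklearn_kernel_density(self):
        """The fold scoring equals sklearn KernelDensity.score for each bandwidth."""
        from sklearn.model_selection import KFold
        from sklearn.neighbors import KernelDensity

        values = np.random.default_rng(17).normal(400, 30, 80)
        grid = np.array([5.0, 10.0, 20.0])
        fit = select_bandwidth(values, grid=grid, n_folds=4, seed=17)
        X = values[:, None]
        splits = list(KFold(n_splits=4, shuffle=True, random_state=17).split(X))
        for i, bw in enumerate(grid):
            expected = np.mean(
                [
                    KernelDensity(kernel="gaussian", bandwidth=bw).fit(X[tr]).score(X[te])
                    for tr, te in splits
                ]
            )
            assert fit.cv_scores[i] == pytest.approx(expected, rel=1e-9)

    def test_density_normalized_on_eval_grid(self):
        """exp(log_density) integrates to 1 over the padded grid (trapezoid)."""
        fit = select_bandwidth(mixture(2000, 11), seed=11)
        total = np.trapezoid(np.exp(fit.log_density), fit.eval_grid)
        assert total == pytest.approx(1.0, abs=0.01)


class TestFirstValley:
    def test_mixture_valley_between_modes(self):
        """Debris at 90 and eggs at 410: the valley lies well between them."""
        fit = select_bandwidth(mixture(5000, 7), seed=7)
        valley = first_valley(fit)
        assert 150 < valley.threshold_um < 350
        assert valley.modes_detected >= 2

    def test_unimodal_raises_no_valley(self):
        fit = select_bandwidth(np.random.default_rng(5).normal(400, 30, 2000), seed=5)
        with pytest.raises(NoValleyError) as exc:
            first_valley(fit)
        assert exc.value.modes_detected == 1

    def test_strictly_increasing_curve_has_no_valley(self):
        with pytest.raises(NoValleyError):
            first_valley(fake_fit(np.linspace(-5, -1, 50)))

    def test_flat_valley_plateau_resolves_to_left_edge(self):
        y = np.array([-3.0, -1.0, -2.0, -2.0, -2.0, -1.0, -3.0])
        valley = first_valley(fake_fit(y))
        assert valley.valley_index == 2
        assert valley.modes_detected == 2

    def test_threshold_strictly_between_first_two_maxima(self):
        fit = select_bandwidth(mixture(3000, 13), seed=13)
        valley = first_valley(fit)
        dens = fit.log_density
        maxima = [
            i
            for i in range(1, len(dens) - 1)
            if dens[i] > dens[i - 1] and dens[i] > dens[i + 1]
        ]
        assert maxima[0] < valley.valley_index < maxima[1]


class TestModeFilter:
    @staticmethod
    def _sample(seed, n=3000):
        sizes = mixture(n, seed, sd1=15.0, sd2=30.0)
        ids = [f"o{i}" for i in range(n)]
        return make_sample(ids, np.ones(n), sizes=sizes), sizes

    def test_mode_means_recovered(self):
        sample, sizes = self._sample(seed=21)
        res = mode_filter(sample, STATUS_DEBRIS, seed=21)
        assert res.mode_mean_dropped_um == pytest.approx(90, abs=10)
        assert res.mode_mean_kept_um == pytest.approx(410, abs=10)
        assert res.n_dropped == (sizes < res.threshold_um).sum()
        assert (sample.events["status"] == STATUS_DEBRIS).sum() == res.n_dropped

    def test_unimodal_sample_propagates_no_valley(self):
        n = 2000
        sizes = np.random.default_rng(9).normal(410, 30, n)
        sample = make_sample([f"o{i}" for i in range(n)], np.ones(n), sizes=sizes)
        with pytest.raises(NoValleyError):
            mode_filter(sample, STATUS_DEBRIS, seed=9)
        assert (sample.events["status"] == "raw").all()  # nothing marked

    def test_all_debris_unimodal_propagates(self):
        n = 1500
        sizes = np.random.default_rng(2).normal(90, 20, n)
        sample = make_sample([f"o{i}" for i in range(n)], np.ones(n), sizes=sizes)
        with pytest.raises(NoValleyError):
            mode_filter(sample, STATUS_DEBRIS, seed=2)

    def test_uncalibrated_sample_rejected(self):
        sample = make_sample(["a", "b"], [1.0, 2.0])
        with pytest.raises(ValueError, match="calibrated"):
            mode_filter(sample, STATUS_DEBRIS)

    def test_deterministic_threshold(self):
        a, _ = self._sample(seed=4)
        b, _ = self._sample(seed=4)
        ra = mode_filter(a, STATUS_DEBRIS, seed=4)
        rb = mode_filter(b, STATUS_DEBRIS, seed=4)
        assert ra.threshold_um == rb.threshold_um
        assert ra.drop_ids == rb.drop_ids


def test_threshold_separation_on_well_separated_mixtures():
    """With |μ₂−μ₁| > 4(σ₁+σ₂) the valley sits in [μ₁+2σ₁, μ₂−2σ₂] (5 seeds)."""
    mu1, sd1, mu2, sd2 = 90.0, 15.0, 410.0, 40.0
    assert mu2 - mu1 > 4 * (sd1 + sd2)
    hits = 0
    for seed in range(5):
        fit = select_bandwidth(mixture(2000, 100 + seed), seed=seed)
        thr = first_valley(fit).threshold_um
        hits += mu1 + 2 * sd1 <= thr <= mu2 - 2 * sd2
    assert hits == 5
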