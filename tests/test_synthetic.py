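"""Ground-truth event simulator: class structure, determinism, shape contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eggflow import (
    SimConfig,
    apply_calibration,
    compute_features,
    select_bandwidth,
    simulate_sample,
    truth_metrics,
)
from eggflow.io_lpfc import STATUS_DEBRIS, STATUS_RETAINED
from eggflow.synthetic import KLASS_ALIGNED, KLASS_DEBRIS, KLASS_MISALIGNED


class TestSimulateSample:
    def test_class_counts_within_binomial_bounds(self):
        """n=3000, proportions (0.3, 0.55, 0.15): counts within 99% binomial bands."""
        _, truth = simulate_sample(SimConfig(seed=42))
        counts = truth["klass"].value_counts()
        for klass, p in [(KLASS_DEBRIS, 0.30), (KLASS_ALIGNED, 0.55), (KLASS_MISALIGNED, 0.15)]:
            mean, sd = 3000 * p, np.sqrt(3000 * p * (1 - p))
            assert abs(counts[klass] - mean) < 2.58 * sd

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_objects=200, seed=7)
        s1, t1 = simulate_sample(cfg)
        s2, t2 = simulate_sample(cfg)
        pd.testing.assert_frame_equal(s1.events, s2.events)
        pd.testing.assert_frame_equal(t1, t2)
        for oid in s1.profiles:
            np.testing.assert_array_equal(s1.profiles[oid], s2.profiles[oid])

    def test_all_aligned_mean_size(self, true_model):
        """Calibrating the TOFs back recovers the 440 µm egg-length mean."""
        cfg = SimConfig(n_objects=5000, class_proportions=(0.0, 1.0, 0.0), seed=11)
        sample, _ = simulate_sample(cfg)
        sized = apply_calibration(true_model, sample)
        assert sized.events["size_um"].mean() == pytest.approx(440.0, abs=3.0)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="proportions"):
            SimConfig(class_proportions=(0.5, 0.5, 0.5))

    def test_eggs_are_prolate_in_truth(self, standard_sample):
        _, truth = standard_sample
        eggs = truth[truth["klass"] != KLASS_DEBRIS]
        assert (eggs["true_width_um"] < eggs["true_length_um"]).all()

    def test_ext_equals_profile_sum(self, standard_sample):
        sample, _ = standard_sample
        head = sample.events.head(20)
        for oid, ext in zip(head["object_id"], head["ext"]):
            assert ext == pytest.approx(sample.profiles[oid].sum())


@pytest.fixture(scope="module")
def egg_features():
    cfg = SimConfig(n_objects=2000, class_proportions=(0.0, 0.5, 0.5), seed=13)
    sample, truth = simulate_sample(cfg)
    feats = {oid: compute_features(oid, prof) for oid, prof in sample.profiles.items()}
    klass = truth.set_index("object_id")["klass"]
    return feats, klass


class TestShapeContrasts:
    def test_aligned_ei_near_unity(self, egg_features):
        """Aligned half-ellipse profiles keep EI in [0.9, 1.1] at default noise."""
        feats, klass = egg_features
        eis = [f.ei for oid, f in feats.items() if klass[oid] == KLASS_ALIGNED]
        assert np.all((np.array(eis) > 0.9) & (np.array(eis) < 1.1))

    def test_misaligned_w_over_l_dominates(self, egg_features):
        """Short-axis transit concentrates extinction: W/L is stochastically larger."""
        feats, klass = egg_features
        wl_aligned = [f.w_over_l for oid, f in feats.items() if klass[oid] == KLASS_ALIGNED]
        wl_mis = [f.w_over_l for oid, f in feats.items() if klass[oid] == KLASS_MISALIGNED]
        res = stats.mannwhitneyu(wl_mis[:1000], wl_aligned[:1000], alternative="greater")
        assert res.pvalue < 0.01
        assert np.median(wl_mis) > np.median(wl_aligned)

    def test_angle_mode_interpolates_extent(self):
        cfg = SimConfig(
            n_objects=500,
            class_proportions=(0.0, 0.0, 1.0),
            orientation_mode="angle",
            seed=3,
        )
        sample, truth = simulate_sample(cfg)
        extents = 5.94 * sample.events["tof"].to_numpy() - 491.78
        merged = truth.set_index("object_id")
        w = merged.loc[sample.events["object_id"], "true_width_um"].to_numpy()
        ell = merged.loc[sample.events["object_id"], "true_length_um"].to_numpy()
        # ℓcosθ + w·sinθ over θ ∈ [0, π/2] ranges from w up to √(ℓ² + w²)
        assert np.all(extents >= w - 1e-6)
        assert np.all(extents <= np.hypot(ell, w) + 1e-6)


def test_raw_size_distribution_bimodal_near_90_and_440(standard_sample, true_model):
    """The unfiltered sample reproduces modes near 90 µm (debris) and 440 µm (eggs)."""
    sample, _ = standard_sample
    sizes = apply_calibration(true_model, sample).events["size_um"].to_numpy()
    fit = select_bandwidth(sizes, seed=0)
    y, x = fit.log_density, fit.eval_grid
    peaks = x[
        [i for i in range(1, len(y) - 1) if y[i] > y[i - 1] and y[i] > y[i + 1]]
    ]
    assert np.any(np.abs(peaks - 90) < 15)
    assert np.any(np.abs(peaks - 440) < 15)


class TestTruthMetrics:
    @staticmethod
    def _tiny(statuses):
        sample, truth = simulate_sample(SimConfig(n_objects=60, seed=2))
        events = sample.events
        if statuses == "perfect":
            klass = truth.set_index("object_id")["klass"]
            is_egg = klass[events["object_id"]].to_numpy() == KLASS_ALIGNED
            events["status"] = np.where(is_egg, STATUS_RETAINED, STATUS_DEBRIS)
        else:
            events["status"] = STATUS_RETAINED
        return sample, truth

    def test_perfect_filter_full_sensitivity(self):
        sample, truth = self._tiny("perfect")
        tm = truth_metrics(truth, sample)
        assert tm.aligned_retention == 1.0
        assert tm.debris_removal == 1.0
        assert tm.misaligned_removal == 1.0

    def test_filter_that_drops_nothing(self):
        sample, truth = self._tiny("none")
        tm = truth_metrics(truth, sample)
        assert tm.debris_removal == 0.0
        assert tm.aligned_retention == 1.0

    def test_id_mismatch_rejected(self):
        sample, truth = self._tiny("none")
        with pytest.raises(ValueError, match="mismatch"):
            truth_metrics(truth.iloc[:-1], sample)
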