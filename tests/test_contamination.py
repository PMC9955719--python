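"""Outlier injection, scaled-MAD detection, and cleaning remedies."""

import numpy as np
import pytest

from entrosim import (
    ArfimaSpec,
    ContaminationSpec,
    adjusted_r,
    clean_with_classification,
    contaminate,
    detect_outliers,
    percent_bias,
    remove_outliers,
    sampen,
    simulate_fgn,
    spec_for_alpha,
)
from entrosim.contamination import _increment_flags_to_positions


class TestContaminate:
    @pytest.mark.parametrize("n,k", [(250, 3), (500, 5), (1000, 10)])
    def test_ceil_count(self, n, k):
        x = np.random.default_rng(0).standard_normal(n)
        xc, idx = contaminate(x, ContaminationSpec(seed=1))
        assert len(idx) == k
        assert len(np.unique(idx)) == k
        changed = np.flatnonzero(xc != x)
        assert set(changed.tolist()) <= set(idx.tolist())

    def test_zero_amplitude_identity(self):
        x = np.random.default_rng(1).standard_normal(100)
        xc, _ = contaminate(x, ContaminationSpec(amplitude_factor=0.0, seed=2))
        assert np.array_equal(xc, x)

    def test_determinism(self):
        x = np.random.default_rng(2).standard_normal(400)
        spec = ContaminationSpec(seed=9)
        a, ia = contaminate(x, spec)
        b, ib = contaminate(x, spec)
        assert np.array_equal(a, b) and np.array_equal(ia, ib)

    def test_additive_on_original_range(self):
        x = np.random.default_rng(3).standard_normal(200)
        xc, idx = contaminate(x, ContaminationSpec(seed=4))
        # perturbation = z * 3 * ptp(x), so spikes scale with the clean range
        assert np.all(xc[idx] != x[idx])
        assert np.max(np.abs(xc[idx] - x[idx])) < 10 * np.ptp(x)


class TestDetect:
    def test_single_gross_outlier(self):
        x = np.clip(np.random.default_rng(11).standard_normal(100), -3, 3)
        x[77] = 100.0
        rep = detect_outliers(x)
        assert list(rep.flagged_indices) == [77]
        assert 0 < rep.sd_ratio < 1

    def test_clean_series_empty_report(self):
        x = np.random.default_rng(5).standard_normal(500)
        x = np.clip(x, -4, 4)
        rep = detect_outliers(x)
        assert len(rep.flagged_indices) == 0
        assert rep.sd_ratio == 1.0

    def test_false_positive_rate_on_clean_fgn(self):
        """At 5 scaled MADs, flags on clean Gaussian fGn are rare."""
        n_flagged = 0
        for s in range(60):
            sim = simulate_fgn(ArfimaSpec(d=0.2, n=500, seed=s))
            n_flagged += len(detect_outliers(sim.values).flagged_indices)
        assert n_flagged <= 1

    def test_zero_mad_warns(self):
        x = np.zeros(20)
        x[0] = 5.0
        with pytest.warns(UserWarning):
            rep = detect_outliers(x)
        assert len(rep.flagged_indices) == 0


class TestRemedies:
    def test_adjusted_r_example(self):
        x = np.zeros(100)
        x[:50] = np.linspace(-0.5, 0.5, 50)
        x[7] = 100.0
        rep = detect_outliers(x)
        assert adjusted_r(0.2, rep) == pytest.approx(0.2 * rep.sd_ratio)
        clean = np.random.default_rng(0).standard_normal(100)
        clean = np.clip(clean, -4, 4)
        assert adjusted_r(0.2, detect_outliers(clean)) == 0.2

    def test_adjusted_r_monotone_in_outlier_magnitude(self):
        base = np.random.default_rng(1).standard_normal(200)
        r_prev = 0.25
        for mag in (10.0, 30.0, 100.0):
            x = base.copy()
            x[50] = mag
            r_adj = adjusted_r(0.25, detect_outliers(x))
            assert r_adj <= r_prev + 1e-12
            r_prev = r_adj

    def test_remove(self):
        x = np.arange(10.0)
        x[4] = 1000.0
        rep = detect_outliers(x)
        out = remove_outliers(x, rep)
        assert len(out) == 9 and 1000.0 not in out
        clean = np.random.default_rng(2).standard_normal(50)
        clean = np.clip(clean, -3, 3)
        assert np.array_equal(remove_outliers(clean, detect_outliers(clean)), clean)

    def test_removal_restores_entropy_of_contaminated_noise(self):
        biases = []
        for s in range(25):
            sim = simulate_fgn(ArfimaSpec(d=0.0, n=500, seed=300 + s))
            base = sampen(sim.values).value
            xc, _ = contaminate(sim.values, ContaminationSpec(seed=s))
            cleaned = remove_outliers(xc, detect_outliers(xc))
            biases.append(percent_bias(sampen(cleaned).value, base))
        assert abs(np.mean(biases)) < 1.0


class TestClassifyRemove:
    def test_single_spike_in_fbm_recovered(self):
        sim = simulate_fgn(ArfimaSpec(d=0.0, n=1000, seed=21, integrate=True))  # alpha 1.5
        x = sim.values.copy()
        p = 400
        x[p] += 8.0
        outcome, report = clean_with_classification(x)
        assert outcome.class_label == "nonstationary"
        assert outcome.removed_count == 1
        assert np.array_equal(outcome.cleaned_values, np.delete(x, p))

    def test_increment_flag_mapping(self):
        # one spike flags increments {p, p+1}; pairs merge to position p
        assert list(_increment_flags_to_positions(np.array([4, 5]))) == [5]
        # isolated flags map to their own position j = i + 1
        assert list(_increment_flags_to_positions(np.array([4, 9]))) == [5, 10]
        assert list(_increment_flags_to_positions(np.array([2, 3, 7, 8]))) == [3, 8]

    def test_stationary_branch_equals_plain_removal(self):
        sim = simulate_fgn(ArfimaSpec(d=0.1, n=500, seed=33))
        xc, _ = contaminate(sim.values, ContaminationSpec(seed=3))
        outcome, _ = clean_with_classification(xc)
        assert outcome.class_label == "stationary"
        plain = remove_outliers(xc, detect_outliers(xc))
        assert np.array_equal(outcome.cleaned_values, plain)

    def test_clean_input_untouched(self):
        removed = []
        for s in range(20):
            sim = simulate_fgn(ArfimaSpec(d=0.2, n=500, seed=700 + s))
            outcome, _ = clean_with_classification(sim.values)
            removed.append(outcome.removed_count)
        assert np.mean(removed) < 0.1

    def test_classification_robust_to_contamination(self):
        """Contaminated fBm keeps its nonstationary label."""
        labels = []
        for s in range(15):
            sim = simulate_fgn(spec_for_alpha(1.8, 500, 800 + s))
            xc, _ = contaminate(sim.values, ContaminationSpec(seed=s))
            outcome, _ = clean_with_classification(xc)
            labels.append(outcome.class_label)
        assert labels.count("nonstationary") >= 14

    def test_detection_recall_on_increments_for_fbm(self):
        """Spikes missed on raw fBm are recovered on its increments."""
        hit_raw = hit_inc = total = 0
        for s in range(15):
            sim = simulate_fgn(spec_for_alpha(1.7, 500, 900 + s))
            xc, idx = contaminate(sim.values, ContaminationSpec(seed=s))
            big = idx[np.abs(xc[idx] - sim.values[idx]) >= np.ptp(sim.values)]
            raw_flags = set(detect_outliers(xc).flagged_indices.tolist())
            inc_flags = set(
                _increment_flags_to_positions(
                    detect_outliers(np.diff(xc)).flagged_indices
                ).tolist()
            )
            hit_raw += len(raw_flags & set(big.tolist()))
            hit_inc += len(inc_flags & set(big.tolist()))
            total += len(big)
        assert hit_inc == total  # full recall on increments
        assert hit_raw <= hit_inc


class TestPercentBias:
    @pytest.mark.parametrize("est,base,out", [(1.0, 2.0, -50.0), (2.0, 2.0, 0.0),
                                              (1.476, 1.968, -25.0)])
    def test_examples(self, est, base, out):
        assert percent_bias(est, base) == pytest.approx(out)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_bias(1.0, 0.0)
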