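import numpy as np
import pytest

import symptomnet as sn
from symptomnet.datamodel import WAVES
from symptomnet.synthetic import (
    default_thresholds,
    true_model_from_json,
    true_model_to_json,
)


class TestTrueNetwork:
    def test_exact_edge_count_at_density(self):
        m = sn.generate_true_network(p=16, density=0.2, seed=0)
        iu = np.triu_indices(16, 1)
        assert np.count_nonzero(m.true_partial[iu]) == 24  # round(0.2 * 120)

    def test_zero_density_gives_diagonal_precision(self):
        m = sn.generate_true_network(p=8, density=0.0, seed=0)
        assert np.count_nonzero(m.true_partial) == 0
        assert np.allclose(m.precision, np.eye(8))

    def test_stored_partials_match_inverse_covariance_oracle(self):
        """Brute force: invert the implied correlation and recompute the
        partial correlations; they must equal the stored entries."""
        m = sn.generate_true_network(p=5, density=0.4, seed=7)
        S = m.correlation
        assert np.linalg.eigvalsh(S).min() > 0
        K = np.linalg.inv(S)
        d = np.sqrt(np.diag(K))
        partial = -K / np.outer(d, d)
        np.fill_diagonal(partial, 0.0)
        assert np.allclose(partial, m.true_partial, atol=1e-10)

    def test_infeasible_weight_range_rejected(self):
        with pytest.raises(ValueError):
            sn.generate_true_network(p=5, density=0.4, weight_range=(0, 0))


class TestSampleWave:
    def test_determinism_same_seed(self):
        m = sn.generate_true_network(p=16, density=0.2, seed=1)
        X1 = sn.sample_wave(m, 50, "T1", seed=9)
        X2 = sn.sample_wave(m, 50, "T1", seed=9)
        assert np.array_equal(X1, X2)

    def test_unreachable_thresholds_make_item_constant(self):
        m = sn.generate_true_network(p=4, density=0.3, seed=2)
        thr = default_thresholds(4)
        thr[0] = [10.0, 11.0, 12.0]  # no latent draw exceeds these
        m.thresholds = thr
        X = sn.sample_wave(m, 500, "T1", seed=0)
        assert X[:, 0].var() == 0

    def test_latent_independence_carries_to_ordinal_scores(self):
        m = sn.generate_true_network(p=6, density=0.0, seed=3)
        X = sn.sample_wave(m, 5000, "T1", seed=4)
        r = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(5000)

    def test_nonpositive_n_rejected(self):
        m = sn.generate_true_network(p=4, density=0.2, seed=0)
        with pytest.raises(ValueError):
            sn.sample_wave(m, 0, "T1", seed=0)


class TestCohort:
    def test_wave_counts_hit_targets_exactly(self, default_cohort):
        panel, spec = default_cohort
        assert sn.complete_case_counts(panel) == {
            "T1": 343, "T2": 269, "T3": 261, "T4": 212,
        }

    def test_completer_count_exact(self, default_cohort):
        panel, _ = default_cohort
        present = {w: set(panel.participants_at(w)) for w in WAVES}
        completers = set.intersection(*present.values())
        assert len(completers) == 210

    def test_intermittent_patterns_minimal(self, default_cohort):
        """Only the 2 participants needed to reconcile T4=212 with 210
        completers skip an interior wave; everyone else drops out for good."""
        panel, _ = default_cohort
        present = {w: set(panel.participants_at(w)) for w in WAVES}
        returners = present["T4"] - present["T2"]
        assert len(returners) == 2
        assert returners <= present["T3"] & present["T1"]
        assert (present["T3"] - returners) <= present["T2"]
        assert (present["T4"] - returners) <= present["T3"]

    def test_null_age_effect_centered(self):
        diffs = []
        for seed in range(20):
            spec = sn.CohortSpec(seed=seed, dropout_age_effect=0.0)
            panel = sn.generate_cohort(spec)
            at_t4 = set(panel.participants_at("T4"))
            ages = panel.rows_at("T1").set_index("participant_id")["age"]
            dropped = ages.index.difference(at_t4)
            diffs.append(ages[dropped].mean() - ages[list(at_t4)].mean())
        # sign should flip freely across seeds under the null
        positive = np.mean(np.array(diffs) > 0)
        assert 0.2 <= positive <= 0.8

    def test_unreachable_targets_rejected(self):
        with pytest.raises(ValueError):
            sn.CohortSpec(n_baseline=343, retention=(343, 269, 261, 212),
                          completers=260)  # completers > T4 count


def test_true_model_json_round_trip(tmp_path):
    m = sn.generate_true_network(p=16, density=0.2, seed=11)
    true_model_to_json(m, tmp_path / "m.json")
    back = true_model_from_json(tmp_path / "m.json")
    assert np.allclose(back.true_partial, m.true_partial)
    assert np.allclose(back.thresholds, m.thresholds)
    assert back.density == m.density


def test_cohort_spec_yaml_round_trip(tmp_path):
    from symptomnet.synthetic import cohort_spec_from_yaml, cohort_spec_to_yaml

    spec = sn.CohortSpec(seed=5, dropout_age_effect=0.2)
    cohort_spec_to_yaml(spec, tmp_path / "spec.yaml")
    back = cohort_spec_from_yaml(tmp_path / "spec.yaml")
    assert back.retention == spec.retention
    assert back.seed == spec.seed
    assert back.dropout_age_effect == spec.dropout_age_effect
    assert np.allclose(back.model.true_partial, spec.model.true_partial)
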