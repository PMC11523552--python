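"""Data generator, midpoint-Cox comparator and the Monte-Carlo harness."""

import numpy as np
import pandas as pd
import pytest

from cshmpl import midpoint_cox_fit, midpoint_transform, run_study, simulate_dataset, study_preset
from cshmpl.data import CompetingRisksData
from cshmpl.simulation import ScenarioSpec, replicate_seeds


class TestGenerator:
    def test_censoring_shares_study1_balanced(self):
        """Study-1 balanced preset: ~47.5% right and ~47.5% interval+left."""
        data = simulate_dataset(study_preset(1, "balanced", n=100_000), seed=1)
        c = data.status_counts()
        n = data.n
        assert c["right"] / n == pytest.approx(0.475, abs=0.02)
        assert (c["interval"] + c["left"]) / n == pytest.approx(0.475, abs=0.02)
        assert c["event"] / n == pytest.approx(0.05, abs=0.005)

    def test_censoring_shares_heavy_mixes(self):
        """The 75/20 presets of studies 1 and 2 hit ~20% right censoring."""
        for study in (1, 2):
            data = simulate_dataset(study_preset(study, "heavy_interval", n=50_000), seed=2)
            c = data.status_counts()
            assert c["right"] / data.n == pytest.approx(0.20, abs=0.02)

    def test_constant_risk_share_for_equal_shapes(self):
        """lambda1=1, lambda2=0.5, equal shapes, no covariate effects:
        risk-1 share is 2/3 at any time."""
        spec = ScenarioSpec(scale=(1.0, 0.5), shape=(3.0, 3.0),
                            beta=((0.0, 0.0), (0.0, 0.0)), n=60_000)
        data = simulate_dataset(spec, seed=3)
        non_right = data.risk[data.status != "right"]
        share = np.mean(non_right == 1)
        se = np.sqrt((2 / 3) * (1 / 3) / non_right.size)
        assert share == pytest.approx(2 / 3, abs=3 * se)

    def test_all_events_when_pi_is_one(self):
        spec = ScenarioSpec(scale=(1.0, 0.5), shape=(3.0, 3.0),
                            beta=((0.0, 0.0), (0.0, 0.0)), pi_event=1.0, n=500)
        data = simulate_dataset(spec, seed=0)
        assert np.all(data.status == "event")

    def test_unequal_shapes_inversion_matches_survival(self):
        """Root-finding branch: the all-cause survival at generated event
        times is uniform (probability-integral transform)."""
        spec = ScenarioSpec(scale=(1.0, 0.5), shape=(3.0, 1.5),
                            beta=((0.3, 0.0), (-0.2, 0.0)), pi_event=1.0, n=4000)
        data = simulate_dataset(spec, seed=9)
        T = data.t_left
        rates = np.stack([
            spec.scale[r] * np.exp(data.X @ np.array(spec.beta[r])) for r in range(2)
        ])
        S = np.exp(-(rates[0] * T ** 3.0 + rates[1] * T ** 1.5))
        # Kolmogorov-Smirnov style bound on the empirical cdf deviation
        u = np.sort(S)
        dev = np.max(np.abs(u - np.arange(1, u.size + 1) / u.size))
        assert dev < 1.63 / np.sqrt(u.size)  # 1% critical value

    def test_valid_dataset_and_interval_geometry(self):
        data = simulate_dataset(study_preset(1, "heavy_interval", n=2000), seed=4)
        assert data.validate() == []
        iv = data.status == "interval"
        assert np.all(data.t_left[iv] < data.t_right[iv])
        le = data.status == "left"
        assert np.all(data.t_left[le] == 0.0)

    def test_determinism(self):
        a = simulate_dataset(study_preset(1, "balanced", n=100), seed=5)
        b = simulate_dataset(study_preset(1, "balanced", n=100), seed=5)
        assert a == b


class TestMidpointTransform:
    def make_data(self):
        return CompetingRisksData(
            t_left=[1.0, 0.0, 1.0, 2.0],
            t_right=[2.0, 2.0, 1.0, np.inf],
            status=["interval", "left", "event", "right"],
            risk=[1, 2, 1, 0],
            X=np.arange(4, dtype=float)[:, None],
            n_risks=2,
        )

    def test_interval_becomes_midpoint_event_or_censoring(self):
        frames = midpoint_transform(self.make_data())
        # risk-1 dataset: interval subject is an event at 1.5
        assert frames[0].loc[0, "time"] == 1.5 and frames[0].loc[0, "event"] == 1
        # risk-2 dataset: same subject right-censored at 1.5
        assert frames[1].loc[0, "time"] == 1.5 and frames[1].loc[0, "event"] == 0

    def test_left_censoring_time_halved(self):
        frames = midpoint_transform(self.make_data())
        assert frames[1].loc[1, "time"] == 1.0 and frames[1].loc[1, "event"] == 1

    def test_exact_event_unchanged(self):
        frames = midpoint_transform(self.make_data())
        assert frames[0].loc[2, "time"] == 1.0 and frames[0].loc[2, "event"] == 1

    def test_right_censored_everywhere(self):
        frames = midpoint_transform(self.make_data())
        for f in frames:
            assert f.loc[3, "event"] == 0 and f.loc[3, "time"] == 2.0


class TestMidpointCox:
    def test_recovers_truth_without_censoring(self):
        """Exponential single-covariate data, no censoring: the partial-
        likelihood estimate is near the truth at large n."""
        rng = np.random.default_rng(11)
        n = 5000
        x = rng.normal(size=n)
        beta = 0.6
        t = rng.exponential(1.0 / np.exp(beta * x))
        data = CompetingRisksData(t, t, ["event"] * n, [1] * n, x[:, None], n_risks=1)
        b, se = midpoint_cox_fit(midpoint_transform(data))
        assert abs(b[0, 0] - beta) < 3 * se[0, 0]

    def test_duplication_equals_case_weighting(self):
        """Duplicating every subject is equivalent to weighting each case by
        two in the partial likelihood; the tie-handling correction applied to
        the duplicated exact ties perturbs the identity only at O(1/n)."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(13)
        n = 300
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.5 * x))
        data2 = CompetingRisksData(
            np.concatenate([t, t]), np.concatenate([t, t]),
            ["event"] * (2 * n), [1] * (2 * n),
            np.concatenate([x, x])[:, None], n_risks=1, validate=False,
        )
        b_dup, _ = midpoint_cox_fit(midpoint_transform(data2))
        weighted = pd.DataFrame({"time": t, "event": 1, "x1": x, "w": 2.0})
        cph = CoxPHFitter()
        cph.fit(weighted, duration_col="time", event_col="event", weights_col="w")
        assert b_dup[0, 0] == pytest.approx(cph.params_.iloc[0], abs=2.0 / n)

    def test_no_events_rejected(self):
        rng = np.random.default_rng(1)
        n = 20
        t = rng.uniform(0.5, 2.0, n)
        # every event belongs to risk 1; risk 2's dataset has no events
        data = CompetingRisksData(
            t, t, ["event"] * n, [1] * n, rng.normal(size=(n, 1)),
            n_risks=2, validate=False,
        )
        with pytest.raises(ValueError, match="no events"):
            midpoint_cox_fit(midpoint_transform(data))


class TestHarness:
    def test_truth_estimator_has_zero_bias_full_coverage(self):
        spec = study_preset(1, "balanced", n=50)
        truth = spec.true_beta
        stub = lambda data: (truth, np.full_like(truth, 0.1))
        tab = run_study(spec, estimator=stub, replicates=20, seed=0)
        np.testing.assert_allclose(tab.bias, 0.0)
        np.testing.assert_allclose(tab.cov_prob, 1.0)

    def test_std_mc_of_gaussian_stub(self):
        spec = study_preset(1, "balanced", n=50)
        rng = np.random.default_rng(7)

        def stub(data):
            return spec.true_beta + rng.normal(0, 0.1, (2, 2)), np.full((2, 2), 0.1)

        tab = run_study(spec, estimator=stub, replicates=300, seed=0)
        np.testing.assert_allclose(tab.std_mc, 0.1, rtol=0.15)

    def test_failed_replicates_counted_and_excluded(self):
        spec = study_preset(1, "balanced", n=50)
        calls = {"k": 0}

        def flaky(data):
            calls["k"] += 1
            if calls["k"] % 3 == 0:
                raise RuntimeError("boom")
            return spec.true_beta, np.full((2, 2), 0.1)

        tab = run_study(spec, estimator=flaky, replicates=9, seed=0)
        assert tab.n_failed == 3
        assert tab.estimates.shape[0] == 6

    def test_replicate_seeds_are_deterministic_and_distinct(self):
        a = replicate_seeds(42, 5)
        b = replicate_seeds(42, 5)
        da = [simulate_dataset(study_preset(1, "balanced", n=20), s) for s in a]
        db = [simulate_dataset(study_preset(1, "balanced", n=20), s) for s in b]
        assert all(x == y for x, y in zip(da, db))
        assert not np.allclose(da[0].t_left, da[1].t_left)

    def test_metrics_frame_layout(self):
        spec = study_preset(1, "balanced", n=50)
        stub = lambda data: (spec.true_beta, np.full((2, 2), 0.1))
        frame = run_study(spec, estimator=stub, replicates=5, seed=0).to_frame()
        assert list(frame["metric"]) == ["bias", "std_asymp", "std_mc", "cov_prob"]
        assert "beta11" in frame.columns and "beta22" in frame.columns


class TestPresets:
    def test_gamma_pairs(self):
        assert study_preset(1, "balanced").gamma_right == 0.91
        assert study_preset(1, "heavy-interval").gamma_right == 1.34
        assert study_preset(2, "heavy_interval").gamma_right == 1.64
        assert study_preset(3, "balanced").gamma_right == 0.74

    def test_study3_has_bernoulli_covariate(self):
        spec = study_preset(3, "balanced", n=1000)
        data = simulate_dataset(spec, seed=0)
        assert set(np.unique(data.X[:, 1])) <= {0.0, 1.0}

    def test_invalid_preset_rejected(self):
        with pytest.raises(ValueError):
            study_preset(4, "balanced")
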