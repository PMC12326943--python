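"""Calibration, slope scoring, classification, filtering and restoration."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from p53eff import (
    CLASS_ABOVE,
    CLASS_IMPAIRED,
    CLASS_NORMAL,
    ExpressionMatrix,
    GenePanel,
    P53EffectivenessClassifier,
    SimulationConfig,
    classify_samples,
    classify_slope,
    filter_impaired,
    fit_target_responses,
    predict_expected,
    restoration_analysis,
    sample_response_slope,
    simulate_dataset,
    with_seed,
)
from p53eff.effectiveness import TargetResponseModel, SampleSlope


def _calibration_frame(rng, n=10):
    p53 = rng.normal(8, 1, n)
    return p53, pd.DataFrame({"TP53": p53}, index=[f"n{i}" for i in range(n)])


class TestFitTargetResponses:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        p53, X = _calibration_frame(rng)
        X["G1"] = 2.0 + 0.8 * p53
        est = P53EffectivenessClassifier(targets=["G1"]).fit(X)
        m = est.models_[0]
        assert m.intercept == pytest.approx(2.0, abs=1e-9)
        assert m.slope == pytest.approx(0.8, abs=1e-9)
        assert m.residual_sd == pytest.approx(0.0, abs=1e-9)
        assert m.r_squared == pytest.approx(1.0, abs=1e-9)
        assert m.n_fit == 10

    def test_unresponsive_target_flat_fit(self):
        rng = np.random.default_rng(1)
        p53, X = _calibration_frame(rng, n=200)
        X["G1"] = 3.0 + 0.01 * rng.normal(size=200)
        est = P53EffectivenessClassifier(targets=["G1"]).fit(X)
        assert abs(est.models_[0].slope) < 0.01
        assert est.models_[0].r_squared < 0.1

    def test_matches_independent_lstsq_oracle(self):
        rng = np.random.default_rng(2)
        p53, X = _calibration_frame(rng, n=40)
        for i in range(59):
            a, b = rng.uniform(1, 4), rng.uniform(0.4, 1.2)
            X[f"G{i}"] = a + b * p53 + 0.3 * rng.normal(size=40)
        est = P53EffectivenessClassifier(targets=[f"G{i}" for i in range(59)]).fit(X)
        A = np.column_stack([np.ones(40), p53])
        for m in est.models_:
            coef, *_ = np.linalg.lstsq(A, X[m.target].to_numpy(), rcond=None)
            assert m.intercept == pytest.approx(coef[0], abs=1e-8)
            assert m.slope == pytest.approx(coef[1], abs=1e-8)
            resid = X[m.target].to_numpy() - A @ coef
            assert m.residual_sd == pytest.approx(np.sqrt(resid @ resid / 38), abs=1e-8)

    def test_slope_recovery_error_within_theory_bound(self):
        rng = np.random.default_rng(3)
        p53 = rng.normal(8, 1, 40)
        X = pd.DataFrame({"TP53": p53})
        true_b = rng.uniform(0.4, 1.2, 59)
        for i, b in enumerate(true_b):
            X[f"G{i}"] = rng.uniform(1, 4) + b * p53 + 0.3 * rng.normal(size=40)
        models = P53EffectivenessClassifier(targets=[f"G{i}" for i in range(59)]).fit(X).models_
        mae = np.mean([abs(m.slope - true_b[i]) for i, m in enumerate(models)])
        assert mae < 3 * (0.3 / np.sqrt(40)) / np.std(p53)

    def test_too_few_calibration_samples(self):
        X = pd.DataFrame({"TP53": [1.0, 2.0], "G1": [1.0, 2.0]})
        with pytest.raises(ValueError, match=">= 3"):
            P53EffectivenessClassifier(targets=["G1"]).fit(X)

    def test_missing_regulator_errors(self):
        X = pd.DataFrame({"G1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="TP53"):
            P53EffectivenessClassifier(targets=["G1"]).fit(X)

    def test_quadratic_form_recovers_curvature(self):
        rng = np.random.default_rng(4)
        p53 = rng.normal(8, 1, 50)
        X = pd.DataFrame({"TP53": p53, "G1": 1.0 + 0.5 * p53 + 0.2 * p53**2})
        m = P53EffectivenessClassifier(targets=["G1"], form="quadratic").fit(X).models_[0]
        assert m.quad == pytest.approx(0.2, abs=1e-6)
        assert m.slope == pytest.approx(0.5, abs=1e-5)


class TestPredictExpected:
    def test_linear_arithmetic(self):
        models = [TargetResponseModel("G1", 1.0, 1.0, 0.0, 1.0, 5)]
        assert predict_expected(models, 4.0) == pytest.approx([5.0])

    def test_flat_response(self):
        models = [TargetResponseModel("G1", 3.0, 0.0, 0.0, 0.0, 5)]
        for lvl in (0.0, 7.3, -2.0):
            assert predict_expected(models, lvl) == pytest.approx([3.0])

    def test_matches_fitted_values_at_calibration_points(self):
        rng = np.random.default_rng(5)
        p53 = rng.normal(8, 1, 40)
        X = pd.DataFrame({"TP53": p53})
        for i in range(10):
            X[f"G{i}"] = rng.uniform(1, 4) + rng.uniform(0.4, 1.2) * p53 + 0.3 * rng.normal(size=40)
        models = P53EffectivenessClassifier(targets=[f"G{i}" for i in range(10)]).fit(X).models_
        A = np.column_stack([np.ones(40), p53])
        lvl = float(p53.mean())
        expected = predict_expected(models, lvl)
        for j, m in enumerate(models):
            coef, *_ = np.linalg.lstsq(A, X[m.target].to_numpy(), rcond=None)
            assert expected[j] == pytest.approx(coef[0] + coef[1] * lvl, abs=1e-8)


class TestSampleResponseSlope:
    def test_identity_gives_unit_slope(self):
        e = np.array([1.0, 2.0, 5.0, 7.0])
        s = sample_response_slope(e, e)
        assert s.slope == pytest.approx(1.0, abs=1e-12)
        assert s.label == CLASS_NORMAL

    def test_exact_attenuation(self):
        e = np.array([1.0, 2.0, 5.0, 7.0])
        s = sample_response_slope(0.5 * e, e)
        assert s.slope == pytest.approx(0.5, abs=1e-12)
        assert s.label == CLASS_IMPAIRED

    def test_noisy_attenuation_matches_closed_form_ols(self):
        rng = np.random.default_rng(6)
        e = rng.uniform(2, 12, 59)
        o = 1.0 + 0.6 * e + 0.05 * rng.normal(size=59)
        s = sample_response_slope(o, e, sample_id="t1")
        # independent closed-form check
        slope = np.cov(e, o, ddof=1)[0, 1] / np.var(e, ddof=1)
        assert s.slope == pytest.approx(slope, abs=1e-10)
        assert abs(s.slope - 0.6) < 0.05
        assert s.label == CLASS_IMPAIRED
        assert s.n_targets == 59

    def test_scaling_property(self):
        rng = np.random.default_rng(7)
        e = rng.uniform(2, 12, 30)
        o = 0.5 + 0.8 * e + 0.1 * rng.normal(size=30)
        base = sample_response_slope(o, e).slope
        for k in (0.5, 2.0, 3.7):
            assert sample_response_slope(k * o, e).slope == pytest.approx(k * base, rel=1e-12)

    def test_through_origin_flag(self):
        e = np.array([1.0, 2.0, 4.0])
        s = sample_response_slope(2.0 * e, e, through_origin=True)
        assert s.slope == pytest.approx(2.0) and s.intercept == 0.0

    def test_degenerate_expected_names_sample(self):
        with pytest.raises(ValueError, match="t42"):
            sample_response_slope([1.0, 2.0, 3.0], [5.0, 5.0, 5.0], sample_id="t42")

    @pytest.mark.parametrize(
        "slope,label",
        [(0.89999, CLASS_IMPAIRED), (0.9, CLASS_NORMAL), (1.0, CLASS_NORMAL),
         (1.1, CLASS_NORMAL), (1.10001, CLASS_ABOVE)],
    )
    def test_boundaries_inclusive_into_normal_like(self, slope, label):
        assert classify_slope(slope) == label


class TestClassifySamples:
    def test_known_impaired_count_recovered(self, sim_panel):
        hits = []
        for seed in range(5):
            cfg = SimulationConfig(noise_sd=0.2, attenuation_range=(0.5, 0.5), seed=seed)
            m, truth = simulate_dataset(cfg)
            models = fit_target_responses(m, sim_panel)
            slopes = classify_samples(m, sim_panel, models)
            hits.append(sum(s.label == CLASS_IMPAIRED for s in slopes))
        assert all(abs(h - 20) <= 2 for h in hits)

    def test_fully_functional_cohort_rarely_flags(self, sim_panel):
        zero_flag_seeds = 0
        for seed in range(20):
            cfg = SimulationConfig(impaired_fraction=0.0, noise_sd=0.1, seed=seed)
            m, _ = simulate_dataset(cfg)
            models = fit_target_responses(m, sim_panel)
            slopes = classify_samples(m, sim_panel, models)
            zero_flag_seeds += all(s.label != CLASS_IMPAIRED for s in slopes)
        assert zero_flag_seeds >= 19

    def test_partition_property(self, sim_panel):
        m, _ = simulate_dataset(SimulationConfig(seed=9))
        models = fit_target_responses(m, sim_panel)
        slopes = classify_samples(m, sim_panel, models)
        counts = {c: sum(s.label == c for s in slopes)
                  for c in (CLASS_NORMAL, CLASS_IMPAIRED, CLASS_ABOVE)}
        assert all(s.label in counts for s in slopes)
        assert sum(counts.values()) == len(slopes) == 100

    def test_no_samples_in_groups_errors(self, sim_panel):
        m, _ = simulate_dataset(SimulationConfig(n_tumor=5, seed=0))
        models = fit_target_responses(m, sim_panel)
        with pytest.raises(ValueError, match="no samples"):
            classify_samples(m, sim_panel, models, groups=("unknown",))


class TestEstimatorConventions:
    def test_get_set_params_and_clone(self):
        est = P53EffectivenessClassifier(regulator="TP53", lower=0.85)
        assert est.get_params()["lower"] == 0.85
        est.set_params(upper=1.2)
        cl = clone(est)
        assert cl.get_params() == est.get_params()

    def test_predict_before_fit_raises(self):
        est = P53EffectivenessClassifier()
        with pytest.raises(NotFittedError):
            est.predict(pd.DataFrame({"TP53": [1.0, 2.0, 3.0]}))

    def test_fit_predict_labels(self, sim_panel):
        m, truth = simulate_dataset(SimulationConfig(seed=4, noise_sd=0.1))
        Xn = m.subset(groups=["nontumor"]).to_samples_by_genes()
        Xt = m.subset(groups=["tumor"]).to_samples_by_genes()
        est = P53EffectivenessClassifier(targets=sim_panel.targets).fit(Xn)
        labels = est.predict(Xt)
        truth_t = truth.is_impaired[Xt.index].to_numpy()
        assert np.array_equal(labels == CLASS_IMPAIRED, truth_t)
        slopes = est.decision_function(Xt)
        assert slopes.shape == (100,)


class TestFilterAndRestoration:
    def _slopes(self, ids, labels):
        return [SampleSlope(i, 0.5, 0.0, 10, l) for i, l in zip(ids, labels)]

    def test_filter_removes_only_impaired(self, small_matrix):
        slopes = self._slopes(["s3", "s4"], [CLASS_IMPAIRED, CLASS_ABOVE])
        out = filter_impaired(small_matrix, slopes)
        assert out.sample_ids == ["s1", "s2", "s4"]

    def test_filter_identity_when_none_impaired(self, small_matrix):
        slopes = self._slopes(["s3", "s4"], [CLASS_NORMAL, CLASS_NORMAL])
        out = filter_impaired(small_matrix, slopes)
        assert out.sample_ids == small_matrix.sample_ids

    def test_filter_unknown_sample_errors(self, small_matrix):
        with pytest.raises(ValueError, match="absent"):
            filter_impaired(small_matrix, self._slopes(["zz"], [CLASS_NORMAL]))

    def test_restoration_improves_when_coupling_lost_in_impaired(self, sim_panel):
        gains = []
        for seed in range(20):
            cfg = SimulationConfig(impaired_fraction=0.3, attenuation_range=(0.0, 0.0), seed=seed)
            m, _ = simulate_dataset(cfg)
            models = fit_target_responses(m, sim_panel)
            slopes = classify_samples(m, sim_panel, models)
            rep = restoration_analysis(m, slopes, [("ZNF224", "CDKN1A")])[0]
            gains.append(rep.bicor_filtered - rep.bicor_all)
            assert rep.n_filtered + rep.n_removed == rep.n_all
        assert np.median(gains) > 0
        assert sum(g > 0 for g in gains) >= 18

    def test_no_impaired_means_identical_correlation(self, sim_panel):
        cfg = SimulationConfig(impaired_fraction=0.0, noise_sd=0.1, seed=1)
        m, _ = simulate_dataset(cfg)
        models = fit_target_responses(m, sim_panel)
        slopes = classify_samples(m, sim_panel, models)
        rep = restoration_analysis(m, slopes, [("ZNF224", "CDKN1A")])[0]
        assert rep.bicor_filtered == rep.bicor_all
        assert rep.n_removed == 0

    def test_missing_pair_gene_errors(self, small_matrix):
        slopes = self._slopes(["s3", "s4"], [CLASS_NORMAL, CLASS_NORMAL])
        with pytest.raises(ValueError, match="NOPE"):
            restoration_analysis(small_matrix, slopes, [("TP53", "NOPE")])
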