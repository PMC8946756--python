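"""LASSO logistic models: feature tables, penalty limits, CV, McNemar, bands."""

import numpy as np
import pandas as pd
import pytest

from lowernet.classify import (
    FeatureTable,
    auc_band,
    bootstrap_sens_spec,
    build_feature_models,
    classify_by_etiology,
    evaluate_cv,
    hemisphere_counts,
    lasso_logistic_cv,
    mcnemar_compare,
    _confusion_metrics,
)
from lowernet.networks import default_synthetic_model
from lowernet.scoring import build_profile
from lowernet.synthcohort import CohortSpec, generate_cohort


def separable_table(n=40, p=4, seed=0, margin=2.0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    x = rng.standard_normal((n, p))
    x[:, 0] += margin * (2 * y - 1)
    return FeatureTable(
        model_id="toy",
        scope="all4",
        x=pd.DataFrame(x, columns=[f"f{i}" for i in range(p)]),
        y=y,
        subject_ids=[f"s{i}" for i in range(n)],
        column_hemisphere={"f0": "L", "f1": "R", "f2": "L", "f3": "R"},
    )


@pytest.fixture(scope="module")
def cohort_tables():
    """Feature tables from generated records (ratings/intensities synthesized
    directly from ground truth so no imaging pipeline is needed here)."""
    model = default_synthetic_model()
    spec = CohortSpec(n_vs=25, n_mcs=25, n_sd=0, n_controls=0, rng_seed=31)
    recs, _, _ = generate_cohort(spec, model, with_bold=False)
    rng = np.random.default_rng(5)
    profiles = []
    shape = spec.grid_shape
    for r in recs:
        sba_maps = {}
        ica_maps = {}
        for net in ("SM", "AUD", "LVIS", "MVIS"):
            ica_maps[net] = None
        for nd in model.nodes():
            c = r.node_effective_coupling[nd.name]
            z = np.zeros(shape)
            roi = model.node_roi(nd, shape)
            # map intensity rises with residual coupling plus noise
            z[roi] = max(0.0, c * 2 + rng.normal(0, 0.2))
            sba_maps[nd.name] = z
        prof = build_profile(
            r.subject_id, model, sba_maps, ica_maps,
            {net: model.network_mask(net, shape) for net in ("SM", "AUD", "LVIS", "MVIS")},
            r.mri_node_ratings, shape,
        )
        profiles.append(prof)
    return build_feature_models(profiles, recs, model, scope="all4"), recs


class TestBuildFeatureModels:
    def test_single_network_rating_model_has_two_scores_per_node(self):
        model = default_synthetic_model()
        spec = CohortSpec(n_vs=3, n_mcs=3, n_sd=0, n_controls=0, rng_seed=1)
        recs, _, _ = generate_cohort(spec, model, with_bold=False)
        profiles = []
        shape = spec.grid_shape
        for r in recs:
            prof = build_profile(
                r.subject_id, model, {}, {n: None for n in ("SM", "AUD", "LVIS", "MVIS")},
                {net: model.network_mask(net, shape) for net in ("SM", "AUD", "LVIS", "MVIS")},
                r.mri_node_ratings, shape,
            )
            profiles.append(prof)
        tables = build_feature_models(profiles, recs, model, scope="AUD")
        assert tables["rating"].x.shape[1] == 4  # 2 nodes x (ICA + SBA)
        assert tables["intensity+mri"].x.shape[1] == 6  # 2 nodes x 3 scores
        assert list(tables["clinical"].x.columns) == [
            "etiology_vascular", "etiology_anoxic", "disease_duration_months", "age_years",
        ]

    def test_four_network_combined_model_has_thirty_columns(self, cohort_tables):
        tables, _ = cohort_tables
        assert tables["intensity+mri"].x.shape[1] == 30  # 10 nodes x 3 scores
        assert tables["rating"].x.shape[1] == 20
        hemis = set(tables["intensity+mri"].column_hemisphere.values())
        assert hemis == {"L", "R"}

    def test_sd_patients_rejected_from_classification_rows(self):
        model = default_synthetic_model()
        spec = CohortSpec(n_vs=1, n_mcs=1, n_sd=1, n_controls=0, rng_seed=2)
        recs, _, _ = generate_cohort(spec, model, with_bold=False)
        with pytest.raises(ValueError, match="SD"):
            build_feature_models([None] * 3, recs, model)


class TestLassoLogistic:
    def test_vanishing_penalty_matches_unpenalized_mle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        n = 200
        x = rng.standard_normal((n, 3))
        logits = 0.8 * x[:, 0] - 0.5 * x[:, 1] + 0.3
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        fit = lasso_logistic_cv(x, y, penalty_override=1e8)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert np.allclose(fit.coef, ref.params[1:], atol=1e-4)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-4)

    def test_infinite_penalty_predicts_training_majority(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 4))
        y = np.array([0] * 20 + [1] * 10)
        fit = lasso_logistic_cv(x, y, penalty_override=1e-8)
        assert fit.selected == []
        assert "no_variables_retained" in fit.flags
        probs = fit.predict_proba(x)
        assert np.all(probs < 0.5)  # majority class is 0
        assert probs[0] == pytest.approx(10 / 30, abs=1e-6)

    def test_informative_feature_selected_consistently(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 120
            x = rng.standard_normal((n, 10))
            logits = 2.0 * x[:, 0]
            y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
            fit = lasso_logistic_cv(
                pd.DataFrame(x, columns=[f"v{i}" for i in range(10)]), y, rng_seed=seed
            )
            hits += "v0" in fit.selected
        assert hits >= 9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="per class"):
            lasso_logistic_cv(np.zeros((10, 2)), np.zeros(10, dtype=int))

    def test_hemisphere_counts(self):
        counts = hemisphere_counts(["a", "b", "c"], {"a": "L", "b": "R", "c": "L"})
        assert counts == (2, 1)


class TestEvaluateCV:
    def test_separable_features_classify_perfectly(self):
        res = evaluate_cv(separable_table(margin=4.0), rng_seed=0, n_boot=200)
        assert res.auc == 1.0
        assert res.balanced_accuracy >= 0.95
        assert res.false_positive_ids == [] and res.false_negative_ids == []

    def test_balanced_accuracy_is_mean_of_sens_spec(self):
        res = evaluate_cv(separable_table(margin=0.5, seed=3), rng_seed=0, n_boot=200)
        assert res.balanced_accuracy == pytest.approx(
            (res.sensitivity + res.specificity) / 2, abs=1e-12
        )

    def test_confusion_arithmetic_on_fixed_counts(self):
        # TP=30 FN=4 TN=40 FP=25 -> balanced accuracy (30/34 + 40/65)/2
        y = np.array([1] * 34 + [0] * 65)
        pred = np.array([1] * 30 + [0] * 4 + [0] * 40 + [1] * 25)
        acc, bal, sens, spec = _confusion_metrics(y, pred)
        assert bal == pytest.approx((30 / 34 + 40 / 65) / 2)
        assert acc == pytest.approx(70 / 99)

    def test_null_labels_give_chance_level_auc(self):
        rng = np.random.default_rng(0)
        aucs = []
        for rep in range(10):
            t = separable_table(n=30, margin=0.0, seed=100 + rep)
            aucs.append(
                evaluate_cv(t, rng_seed=rep, n_boot=50, cs=np.logspace(-1, 1, 3)).auc
            )
        aucs = [a for a in aucs if np.isfinite(a)]
        assert 0.3 <= np.median(aucs) <= 0.7

    def test_auc_invariant_under_monotone_probability_transform(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        p = rng.random(50)
        assert roc_auc_score(y, p) == pytest.approx(roc_auc_score(y, p**3))

    def test_fold_models_are_reproducible(self):
        t = separable_table(seed=5)
        x, y = t.x.to_numpy(), t.y
        train = np.arange(1, len(y))
        f1 = lasso_logistic_cv(t.x.iloc[train], y[train], rng_seed=0)
        f2 = lasso_logistic_cv(t.x.iloc[train], y[train], rng_seed=0)
        assert np.array_equal(f1.coef, f2.coef)
        assert f1.chosen_c == f2.chosen_c


class TestBootstrapSensSpec:
    def test_perfect_classifier_has_degenerate_cis(self):
        y = np.array([0] * 10 + [1] * 10)
        s_ci, p_ci = bootstrap_sens_spec(y, y, n_boot=200, rng_seed=0)
        assert s_ci == (1.0, 1.0)
        assert p_ci == (1.0, 1.0)

    def test_constant_positive_predictor(self):
        y = np.array([0] * 10 + [1] * 10)
        pred = np.ones(20, dtype=int)
        s_ci, p_ci = bootstrap_sens_spec(pred, y, n_boot=200, rng_seed=0)
        assert s_ci == (1.0, 1.0)
        assert p_ci == (0.0, 0.0)

    def test_coin_flip_interval_covers_half(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 100 + [1] * 100)
        pred = rng.integers(0, 2, 200)
        s_ci, _ = bootstrap_sens_spec(pred, y, n_boot=500, rng_seed=1)
        assert s_ci[0] <= 0.5 <= s_ci[1]

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            bootstrap_sens_spec(np.array([1, 0, 1]), np.array([1, 0, 0]))


class TestMcnemar:
    def test_identical_predictions_give_p_one(self):
        y = np.array([0, 1, 0, 1])
        pred = np.array([0, 1, 1, 1])
        assert mcnemar_compare(pred, pred, y) == 1.0

    def test_ten_zero_discordance_exact_binomial(self):
        y = np.zeros(10, dtype=int)
        a = np.zeros(10, dtype=int)  # all correct
        b = np.ones(10, dtype=int)  # all wrong
        assert mcnemar_compare(a, b, y) == pytest.approx(2 * 0.5**10)

    def test_symmetric_discordance_gives_p_one(self):
        y = np.zeros(10, dtype=int)
        a = np.array([0] * 5 + [1] * 5)
        b = np.array([1] * 5 + [0] * 5)
        assert mcnemar_compare(a, b, y) == 1.0


class TestAucBand:
    @pytest.mark.parametrize(
        "auc,label",
        [(0.80, "very good"), (0.85, "very good"), (0.75, "good"), (0.65, "sufficient"),
         (0.55, "bad"), (0.45, "bad")],
    )
    def test_band_boundaries(self, auc, label):
        assert auc_band(auc) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            auc_band(1.2)


class TestClassifyByEtiology:
    def test_strata_flagged_or_evaluated(self, cohort_tables):
        tables, recs = cohort_tables
        et = [r.etiology for r in recs]
        out = classify_by_etiology(tables["intensity"], et, rng_seed=0, n_boot=50)
        assert set(out) <= {"traumatic", "vascular", "anoxic"}
        for stratum, res in out.items():
            if isinstance(res, dict):
                assert res["flag"] in ("single_class", "underpowered")
            else:
                assert 0.0 <= res.balanced_accuracy <= 1.0

    def test_three_patient_stratum_is_underpowered(self):
        t = separable_table(n=40)
        et = np.array(["vascular"] * 37 + ["anoxic"] * 3)
        out = classify_by_etiology(t, et, rng_seed=0, n_boot=50)
        assert out["anoxic"]["flag"] in ("underpowered", "single_class")

    def test_strong_effect_stratum_reaches_high_auc(self):
        t = separable_table(n=40, margin=3.0, seed=9)
        et = np.array(["anoxic"] * 40)
        out = classify_by_etiology(t, et, rng_seed=0, n_boot=50)
        assert out["anoxic"].auc > 0.9
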