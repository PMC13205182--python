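import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import stagepath as sp


class TestMakeReferencePanel:
    def test_zero_noise_response_exactly_linear(self):
        panel = sp.make_reference_panel(n_lines=30, n_genes=40, n_drugs=1,
                                        noise_sd=0.0, seed=0)
        drug = panel.drugs[0]
        w = np.array(panel.truth["weights"][drug])
        expected = panel.truth["intercepts"][drug] + w @ panel.expression.to_numpy()
        assert np.allclose(panel.response.loc[drug].to_numpy(), expected)

    def test_seeded_determinism(self):
        a = sp.make_reference_panel(seed=5)
        b = sp.make_reference_panel(seed=5)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.response, b.response)

    def test_too_few_lines_errors(self):
        with pytest.raises(ValueError, match="20"):
            sp.make_reference_panel(n_lines=10)

    def test_planted_signature_is_honoured(self):
        sig = {"D": {"G0001": 1.5, "G0003": -0.5}}
        panel = sp.make_reference_panel(
            n_lines=40, n_genes=5, planted_signatures=sig, noise_sd=0.0, seed=1
        )
        w = np.array(panel.truth["weights"]["D"])
        assert w[1] == 1.5 and w[3] == -0.5 and w[[0, 2, 4]].sum() == 0


class TestFitRidge:
    def test_infinite_penalty_limit_predicts_mean(self):
        panel = sp.make_reference_panel(n_lines=50, n_genes=30, n_drugs=1, seed=2)
        drug = panel.drugs[0]
        predictor = sp.fit_ridge(panel, drug, folds=5, seed=2,
                                 penalties=np.array([1e9]))
        pred = sp.predict_lnic50(predictor, panel.expression)
        mean_resp = panel.response.loc[drug].mean()
        assert np.allclose(pred, mean_resp, atol=0.02 * abs(mean_resp) + 0.02)

    def test_noiseless_panel_near_perfect_heldout_correlation(self):
        panel = sp.make_reference_panel(n_lines=200, n_genes=50, n_drugs=1,
                                        noise_sd=0.0, seed=3)
        drug = panel.drugs[0]
        predictor = sp.fit_ridge(panel, drug, folds=10, seed=3)
        # fresh cohort from the same generative law
        rng = np.random.default_rng(33)
        Xc = rng.standard_normal((50, 100))
        cohort = pd.DataFrame(Xc, index=panel.expression.index,
                              columns=[f"c{i}" for i in range(100)])
        w = np.array(panel.truth["weights"][drug])
        true = panel.truth["intercepts"][drug] + w @ Xc
        pred = sp.predict_lnic50(predictor, cohort)
        assert np.corrcoef(pred, true)[0, 1] >= 0.99

    def test_single_signal_gene_dominates_coefficients(self):
        sig = {"D": {"G0000": 2.0}}
        panel = sp.make_reference_panel(n_lines=150, n_genes=30, noise_sd=0.2,
                                        planted_signatures=sig, seed=4)
        predictor = sp.fit_ridge(panel, "D", folds=10, seed=4)
        coef = np.abs(predictor.coef)
        assert coef[0] >= 10 * np.delete(coef, 0).max()

    def test_constant_response_errors(self):
        panel = sp.make_reference_panel(n_lines=30, n_genes=10, n_drugs=1, seed=5)
        panel.response.iloc[0] = 3.0
        with pytest.raises(ValueError, match="constant"):
            sp.fit_ridge(panel, panel.drugs[0])


class TestPredict:
    def test_constant_cohort_predicts_intercept(self):
        panel = sp.make_reference_panel(n_lines=40, n_genes=20, n_drugs=1, seed=6)
        predictor = sp.fit_ridge(panel, panel.drugs[0], folds=5, seed=6)
        cohort = pd.DataFrame(
            2.5, index=panel.expression.index, columns=["s1", "s2", "s3"]
        )
        pred = sp.predict_lnic50(predictor, cohort)
        assert np.allclose(pred, predictor.intercept)

    def test_affine_rescaling_invariance(self):
        panel = sp.make_reference_panel(n_lines=40, n_genes=20, n_drugs=1, seed=7)
        predictor = sp.fit_ridge(panel, panel.drugs[0], folds=5, seed=7)
        rng = np.random.default_rng(7)
        cohort = pd.DataFrame(
            rng.normal(size=(20, 15)), index=panel.expression.index,
            columns=[f"s{i}" for i in range(15)],
        )
        scale = rng.uniform(0.5, 3.0, size=(20, 1))
        shift = rng.normal(size=(20, 1))
        rescaled = cohort * scale + shift
        assert np.allclose(
            sp.predict_lnic50(predictor, cohort),
            sp.predict_lnic50(predictor, rescaled),
        )

    def test_low_gene_coverage_errors(self):
        panel = sp.make_reference_panel(n_lines=40, n_genes=20, n_drugs=1, seed=8)
        predictor = sp.fit_ridge(panel, panel.drugs[0], folds=5, seed=8)
        cohort = pd.DataFrame(
            np.zeros((4, 2)), index=list(panel.expression.index[:4]),
            columns=["s1", "s2"],
        )
        with pytest.raises(ValueError, match="predictor genes present"):
            sp.predict_lnic50(predictor, cohort)

    def test_no_shared_genes_errors(self):
        panel = sp.make_reference_panel(n_lines=40, n_genes=10, n_drugs=1, seed=9)
        predictor = sp.fit_ridge(panel, panel.drugs[0], folds=5, seed=9)
        cohort = pd.DataFrame(np.zeros((3, 2)), index=["x", "y", "z"],
                              columns=["s1", "s2"])
        with pytest.raises(ValueError, match="no shared genes"):
            sp.predict_lnic50(predictor, cohort)


class TestFisherZ:
    def test_closed_form_worked_example(self):
        z, p = sp.fisher_z_diff(0.5, 103, 0.0, 53)
        assert z == pytest.approx(3.17, abs=0.01)
        assert p == pytest.approx(0.0015, abs=0.0002)

    def test_antisymmetry_exact(self):
        z1, p1 = sp.fisher_z_diff(0.42, 80, -0.11, 60)
        z2, p2 = sp.fisher_z_diff(-0.11, 60, 0.42, 80)
        assert z1 == -z2
        assert p1 == p2

    def test_equal_correlations_null(self):
        z, p = sp.fisher_z_diff(0.3, 50, 0.3, 50)
        assert z == 0.0 and p == 1.0


class TestStageSensitivityCorrelation:
    def make_assignments(self, subtypes, stages):
        n = len(subtypes)
        resp = np.zeros((n, 2))
        resp[np.arange(n), subtypes] = 1.0
        post = np.zeros((n, 18))
        post[np.arange(n), stages] = 1.0
        return sp.AssignmentTable(
            sample_ids=[f"s{i}" for i in range(n)],
            responsibilities=resp,
            stage_posteriors=post,
            map_subtype=np.asarray(subtypes),
            map_stage=np.asarray(stages),
        )

    def test_identical_groups_give_zero_z(self):
        stages = [1, 2, 3, 4, 5, 6, 7, 8]
        a = self.make_assignments([0] * 8 + [1] * 8, stages + stages)
        pred = pd.Series(
            [s * 0.5 for s in stages] * 2, index=[f"s{i}" for i in range(16)]
        )
        out = sp.stage_sensitivity_correlation(pred, a)
        assert out["fisher_z"] == pytest.approx(0.0)
        assert out["fisher_p"] == pytest.approx(1.0)

    def test_small_subtype_excluded_with_warning(self):
        a = self.make_assignments([0] * 10 + [1] * 3, list(range(10)) + [1, 2, 3])
        pred = pd.Series(np.arange(13, dtype=float),
                         index=[f"s{i}" for i in range(13)])
        with pytest.warns(UserWarning, match="excluded"):
            out = sp.stage_sensitivity_correlation(pred, a)
        assert list(out["per_subtype"]) == [0]

    def test_planted_trend_detected_in_one_subtype_only(self):
        truth = sp.GroundTruth()
        hits = 0
        for seed in range(5):
            cohort = sp.generate_mutations(truth, 260, seed=900 + seed)
            sp.generate_expression(cohort, truth, n_null_genes=100)
            a = sp.true_assignments(cohort, truth)
            sig = {
                "D": {g: -0.3 * slope for (g, slope, _) in truth.planted_genes[0]}
            }
            panel = sp.make_reference_panel(
                n_lines=100, gene_names=list(cohort.expression.index),
                planted_signatures=sig, seed=900 + seed,
            )
            predictor = sp.fit_ridge(panel, "D", folds=10, seed=900 + seed)
            pred = sp.predict_lnic50(predictor, cohort.expression)
            out = sp.stage_sensitivity_correlation(pred, a)
            ap = out["per_subtype"][0]
            gp = out["per_subtype"][1]
            significant_negative_only_in_ap = (
                ap["rho"] < 0 and ap["p"] < 0.01
                and not (gp["rho"] < 0 and gp["p"] < 0.01)
            )
            hits += significant_negative_only_in_ap
        assert hits >= 4

    def test_no_overlap_errors(self):
        a = self.make_assignments([0] * 8, list(range(8)))
        pred = pd.Series([1.0], index=["zz"])
        with pytest.raises(ValueError, match="overlap"):
            sp.stage_sensitivity_correlation(pred, a)


def test_predictor_round_trip(tmp_path):
    panel = sp.make_reference_panel(n_lines=30, n_genes=10, n_drugs=1, seed=10)
    predictor = sp.fit_ridge(panel, panel.drugs[0], folds=5, seed=10)
    predictor.to_json(tmp_path / "pred.json")
    import json

    d = json.loads((tmp_path / "pred.json").read_text())
    assert d["drug"] == panel.drugs[0]
    assert len(d["coef"]) == 10
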