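import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau

import stagepath as sp


def model_of(orderings, fractions, alpha=0.1, beta=0.1):
    return sp.SubtypeModel(
        [sp.EventOrdering(o) for o in orderings],
        np.asarray(fractions, float),
        sp.NoiseModel(alpha, beta),
    )


class TestDataLogLikelihood:
    def test_two_event_profile_hand_enumeration(self, tiny_matrix):
        # stages 0..2 contribute 0.09, 0.81, 0.09; mean = 0.33
        _, total = sp.data_log_likelihood(tiny_matrix, model_of([["A", "B"]], [1.0]))
        assert np.exp(total) == pytest.approx(0.33, abs=1e-12)

    def test_noiseless_prefix_leaves_single_stage(self, tiny_matrix):
        _, total = sp.data_log_likelihood(
            tiny_matrix, model_of([["A", "B"]], [1.0], alpha=0.0, beta=0.0)
        )
        assert np.exp(total) == pytest.approx(1 / 3, abs=1e-12)

    def test_two_subtype_mixture_hand_enumeration(self, tiny_matrix):
        _, total = sp.data_log_likelihood(
            tiny_matrix, model_of([["A", "B"], ["B", "A"]], [0.5, 0.5])
        )
        assert np.exp(total) == pytest.approx(0.5 * 0.33 + 0.5 * 0.19 / 3, abs=1e-12)

    def test_matches_exhaustive_enumeration_small_n(self, brute_likelihood):
        rng = np.random.default_rng(0)
        events = ["A", "B", "C"]
        for trial in range(20):
            X = rng.integers(0, 2, (6, 3))
            m = sp.BinaryMutationMatrix(
                pd.DataFrame(X, columns=events,
                             index=[f"s{i}" for i in range(6)])
            )
            perm = list(rng.permutation(events))
            perm2 = list(rng.permutation(events))
            model = model_of([perm, perm2], [0.3, 0.7], alpha=0.08, beta=0.12)
            per_sample, _ = sp.data_log_likelihood(m, model)
            for i in range(6):
                expected = brute_likelihood(
                    X[i], model.orderings, model.fractions, 0.08, 0.12, events
                )
                assert np.exp(per_sample[i]) == pytest.approx(expected, abs=1e-12)

    def test_subtype_label_permutation_invariance(self, small_cohort):
        m = small_cohort.mutations
        events = m.event_names
        rng = np.random.default_rng(1)
        o1, o2 = list(rng.permutation(events)), list(rng.permutation(events))
        _, t1 = sp.data_log_likelihood(m, model_of([o1, o2], [0.4, 0.6]))
        _, t2 = sp.data_log_likelihood(m, model_of([o2, o1], [0.6, 0.4]))
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_event_mismatch_lists_symmetric_difference(self, tiny_matrix):
        model = model_of([["A", "C"]], [1.0])
        with pytest.raises(ValueError, match="B.*C|C.*B"):
            sp.data_log_likelihood(tiny_matrix, model)


class TestAssignSubjects:
    def test_noiseless_single_mutation_pins_stage_one(self, tiny_matrix):
        a = sp.assign_subjects(
            tiny_matrix, model_of([["A", "B"]], [1.0], alpha=0.0, beta=0.0)
        )
        assert np.allclose(a.stage_posteriors[0], [0, 1, 0])
        assert a.map_stage[0] == 1
        assert a.p_stage[0] == pytest.approx(1.0)

    def test_all_zero_profile_maps_to_stage_zero(self):
        m = sp.BinaryMutationMatrix(
            pd.DataFrame([[0, 0]], index=["s1"], columns=["A", "B"])
        )
        a = sp.assign_subjects(m, model_of([["A", "B"]], [1.0], alpha=0.0, beta=0.0))
        assert a.map_stage[0] == 0

    def test_mixture_responsibility_ratio(self, tiny_matrix):
        a = sp.assign_subjects(
            tiny_matrix, model_of([["A", "B"], ["B", "A"]], [0.5, 0.5])
        )
        assert a.responsibilities[0, 0] == pytest.approx(0.33 / (0.33 + 0.19 / 3), abs=1e-9)
        assert a.map_subtype[0] == 0

    def test_posterior_certainty_grows_as_noise_shrinks(self, default_truth):
        cohort = sp.generate_mutations(default_truth, 200, seed=21)
        model_low = model_of(
            [list(o.events) for o in default_truth.orderings], [0.65, 0.35],
            alpha=0.02, beta=0.02,
        )
        model_high = model_of(
            [list(o.events) for o in default_truth.orderings], [0.65, 0.35],
            alpha=0.15, beta=0.15,
        )
        low = sp.assign_subjects(cohort.mutations, model_low)
        high = sp.assign_subjects(cohort.mutations, model_high)
        assert low.p_stage.mean() > high.p_stage.mean()


class TestFitModel:
    def test_noiseless_single_subtype_exact_recovery(self):
        events = ("E1", "E2", "E3", "E4", "E5", "E6")
        ordering = sp.EventOrdering(events)
        truth = sp.GroundTruth(
            event_names=events, orderings=[ordering], fractions=(1.0,),
            alpha=0.0, beta=0.0, planted_genes=[[]],
            pn_probs=((0.25, 0.25, 0.25, 0.25),),
        )
        cohort = sp.generate_mutations(truth, 400, seed=22)
        model = sp.fit_model(
            cohort.mutations, 1, sp.NoiseModel(1e-6, 1e-6),
            iters=3000, burn_in=300, n_starts=1, seed=22,
        )
        assert model.orderings[0].events == events

    def test_seeded_determinism(self, small_cohort):
        kw = dict(iters=1500, burn_in=150, n_starts=1, seed=7)
        a = sp.fit_model(small_cohort.mutations, 2, sp.NoiseModel(), **kw)
        b = sp.fit_model(small_cohort.mutations, 2, sp.NoiseModel(), **kw)
        assert [o.events for o in a.orderings] == [o.events for o in b.orderings]
        assert np.allclose(a.fractions, b.fractions)
        assert a.log_likelihood == b.log_likelihood

    def test_best_state_likelihood_beats_frequency_initialisation(self, small_cohort):
        m = small_cohort.mutations
        model = sp.fit_model(m, 2, sp.NoiseModel(), iters=2000, burn_in=200,
                             n_starts=1, seed=3)
        freq_order = list(m.column_counts().sort_values(ascending=False).index)
        init = model_of([freq_order, freq_order], [0.5, 0.5], 0.05, 0.05)
        _, init_ll = sp.data_log_likelihood(m, init)
        assert model.log_likelihood >= init_ll

    def test_two_subtype_recovery_small(self):
        events = tuple(f"E{i}" for i in range(8))
        o1 = sp.EventOrdering(events)
        o2 = sp.EventOrdering(events[::-1])
        truth = sp.GroundTruth(
            event_names=events, orderings=[o1, o2], fractions=(0.6, 0.4),
            alpha=0.05, beta=0.05, planted_genes=[[], []],
        )
        cohort = sp.generate_mutations(truth, 400, seed=23)
        model = sp.fit_model(cohort.mutations, 2, sp.NoiseModel(),
                             iters=8000, burn_in=800, n_starts=2, seed=23)
        taus = []
        for fitted, planted in zip(model.orderings, truth.orderings):
            pos = {e: i for i, e in enumerate(planted.events)}
            taus.append(
                kendalltau(range(8), [pos[e] for e in fitted.events]).statistic
            )
        assert min(taus) >= 0.8

    def test_all_zero_matrix_errors(self):
        m = sp.BinaryMutationMatrix(
            pd.DataFrame(0, index=["s1", "s2"], columns=["A", "B"])
        )
        with pytest.raises(ValueError, match="zero"):
            sp.fit_model(m, 1, sp.NoiseModel(), iters=100, burn_in=10)

    def test_invalid_iteration_budget(self, tiny_matrix):
        with pytest.raises(ValueError, match="burn_in"):
            sp.fit_model(tiny_matrix, 1, sp.NoiseModel(), iters=10, burn_in=10)


class TestSelectSubtypeCount:
    def test_cmax_one_reports_single_candidate(self, small_cohort):
        report = sp.select_subtype_count(
            small_cohort.mutations, C_max=1, folds=3, iters=300, burn_in=30, seed=1
        )
        assert report.candidates == [1]
        assert report.chosen == 1

    def test_more_folds_than_samples_errors(self, tiny_matrix):
        with pytest.raises(ValueError, match="folds"):
            sp.select_subtype_count(tiny_matrix, C_max=1, folds=5)


def test_noise_model_bounds():
    with pytest.raises(ValueError):
        sp.NoiseModel(alpha=0.6)
    with pytest.raises(ValueError):
        sp.NoiseModel(beta=-0.1)


def test_model_round_trip(tmp_path, small_cohort):
    model = sp.fit_model(small_cohort.mutations, 2, sp.NoiseModel(),
                         iters=500, burn_in=50, n_starts=1, seed=9)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = sp.SubtypeModel.from_json(path)
    assert [o.events for o in back.orderings] == [o.events for o in model.orderings]
    assert np.allclose(back.fractions, model.fractions)
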