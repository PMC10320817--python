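"""Analysis pipeline: baseline coding, condition effects, contingency and
agreement statistics, latent profiles and type recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import cohen_kappa_score
from sklearn.mixture import GaussianMixture
from statsmodels.api import GLM, families

import refgame as rg
from refgame.analysis import (
    PROFILES,
    accuracy_by_condition,
    assign_mixture_classes,
    chisq_independence,
    classify_nearest_profile,
    code_ambiguous,
    cohens_kappa,
    estimate_condition_effects,
    fit_latent_profiles,
    homogeneity_completeness,
    randomization_variance_study,
    recovery_experiment,
)
from refgame.design import RefgameError
from refgame.simulate import PopulationSpec, simulate_dataset


def toy_responses(n_ambig=10, n_other=6, ambig_distractors=0):
    """Minimal response table with uncoded ambiguous rows."""
    rows = []
    for i in range(n_ambig):
        rows.append(dict(participant_id="p0", trial_index=i + 1,
                         condition="ambiguous",
                         chosen_role="distractor" if i < ambig_distractors else "target",
                         chosen_position="left", message_dimension="creature",
                         correct=np.nan))
    for i in range(n_other):
        rows.append(dict(participant_id="p0", trial_index=100 + i,
                         condition="simple", chosen_role="target",
                         chosen_position="left", message_dimension="creature",
                         correct=1.0))
    return pd.DataFrame(rows)


class TestCodeAmbiguous:
    def test_forced_even_codes_exactly_half(self, rng):
        df = code_ambiguous(toy_responses(n_ambig=10), "forced_even", rng)
        assert df.loc[df.condition == "ambiguous", "correct"].sum() == 5

    def test_forced_even_floors_odd_counts(self, rng):
        df = code_ambiguous(toy_responses(n_ambig=11), "forced_even", rng)
        assert df.loc[df.condition == "ambiguous", "correct"].sum() == 5

    def test_coinflip_is_binomial(self, rng):
        df = code_ambiguous(toy_responses(n_ambig=10_000), "coinflip", rng)
        k = df.loc[df.condition == "ambiguous", "correct"].sum()
        assert abs(k - 5000) <= 3 * np.sqrt(10_000 * 0.25)

    def test_distractor_responses_coded_incorrect(self, rng):
        df = code_ambiguous(toy_responses(n_ambig=6, ambig_distractors=2),
                            "forced_even", rng)
        amb = df[df.condition == "ambiguous"]
        assert (amb.loc[amb.chosen_role == "distractor", "correct"] == 0).all()
        assert amb.loc[amb.chosen_role != "distractor", "correct"].sum() == 2

    def test_empty_case_and_non_ambiguous_untouched(self, rng):
        base = toy_responses(n_ambig=0)
        df = code_ambiguous(base, "coinflip", rng)
        pd.testing.assert_frame_equal(df, base)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(RefgameError):
            code_ambiguous(toy_responses(), "oracle", rng)


class TestAccuracyByCondition:
    def test_perfect_responder(self, rng):
        pop = PopulationSpec(n_participants=3, mixture={"rsa_L2": 1.0},
                             lam=50.0, lapse_rate=0.0, position_bias=(0.0, 0.0),
                             seed=1)
        coded = code_ambiguous(simulate_dataset(pop), "forced_even", rng)
        acc = accuracy_by_condition(coded)
        assert (acc.acc_simple == 1.0).all()
        assert (acc.acc_complex == 1.0).all()
        assert (acc.acc_unambiguous == 1.0).all()
        # forced-even coding pins the pooled ambiguous accuracy near 1/2
        assert acc.acc_ambiguous.mean() == pytest.approx(0.5, abs=0.1)

    def test_all_distractor_responder_flagged_undefined(self):
        df = toy_responses(n_other=4)
        df["chosen_role"] = "distractor"
        df["correct"] = 0.0
        acc = accuracy_by_condition(df, exclude_distractors=True)
        assert acc.acc_simple.isna().all()
        assert acc.exclude.all()

    def test_guesser_accuracy_near_half(self):
        pop = PopulationSpec(n_participants=100, mixture={"guess": 1.0},
                             lapse_rate=0.0, position_bias=(0.0, 0.0), seed=8)
        acc = accuracy_by_condition(simulate_dataset(pop))
        se = np.sqrt(0.25 / (100 * 12))
        assert acc.acc_simple.mean() == pytest.approx(0.5, abs=3 * se)


class TestConditionEffects:
    def test_closed_form_equals_logit_difference(self):
        # p_simple = 0.8 vs p_complex = 0.5 gives logit(0.8) - logit(0.5)
        rows = []
        for cond, n, k in (("simple", 100, 80), ("complex", 100, 50),
                           ("ambiguous", 100, 50)):
            for i in range(n):
                rows.append(dict(participant_id="p0", trial_index=i,
                                 condition=cond, chosen_role="target",
                                 chosen_position="left",
                                 message_dimension="creature",
                                 correct=float(i < k)))
        eff = estimate_condition_effects(pd.DataFrame(rows))
        assert eff.beta["simple_vs_complex"] == pytest.approx(1.3862943611, abs=1e-9)
        assert eff.beta["ambiguous_vs_complex"] == pytest.approx(0.0, abs=1e-12)
        assert not eff.significant("ambiguous_vs_complex")
        assert eff.significant("simple_vs_complex")

    def test_matches_iterative_mle(self, rng):
        pop = PopulationSpec(n_participants=25, seed=6)
        coded = code_ambiguous(simulate_dataset(pop), "forced_even", rng)
        eff = estimate_condition_effects(coded)
        df = coded[(coded.chosen_role != "distractor")
                   & coded.condition.isin(["simple", "complex", "ambiguous"])]
        X = pd.get_dummies(df.condition).astype(float)[["simple", "ambiguous"]]
        X.insert(0, "intercept", 1.0)
        fit = GLM(df.correct.to_numpy(), X, family=families.Binomial()).fit()
        assert eff.beta["simple_vs_complex"] == pytest.approx(fit.params["simple"], abs=1e-8)
        assert eff.beta["ambiguous_vs_complex"] == pytest.approx(fit.params["ambiguous"], abs=1e-8)
        assert eff.se["simple_vs_complex"] == pytest.approx(fit.bse["simple"], abs=1e-6)

    def test_separation_reported_as_infinite_with_warning(self):
        df = toy_responses(n_ambig=0, n_other=10)
        extra = df.copy()
        extra["condition"] = "complex"
        extra["correct"] = 0.0
        both = pd.concat([df, extra], ignore_index=True)
        with pytest.warns(RuntimeWarning, match="separation"):
            eff = estimate_condition_effects(both, conditions=("simple", "complex"))
        assert np.isinf(eff.beta["simple_vs_complex"])

    def test_pure_l2_population_has_no_condition_effect(self, rng):
        # at moderate rationality both conditions sit high but off ceiling,
        # so the estimate is finite and small relative to a real effect
        pop = PopulationSpec(n_participants=60, mixture={"rsa_L2": 1.0},
                             lam=8.0, position_bias=(0.0, 0.0), seed=3)
        coded = code_ambiguous(simulate_dataset(pop), "forced_even", rng)
        eff = estimate_condition_effects(coded)
        acc = accuracy_by_condition(coded)
        assert acc.acc_simple.mean() > 0.9 and acc.acc_complex.mean() > 0.9
        assert abs(acc.acc_simple.mean() - acc.acc_complex.mean()) < 0.05
        assert np.isfinite(eff.beta["simple_vs_complex"])


class TestVarianceStudy:
    def test_dispersion_ordering_and_forced_even_stability(self):
        pop = PopulationSpec(n_participants=20, seed=4)
        responses = simulate_dataset(pop)
        out = randomization_variance_study(
            responses, n_runs=40, rng=np.random.default_rng(2)
        ).set_index("method")
        assert out.loc["coinflip", "sd_beta"] >= out.loc["forced_even", "sd_beta"]
        # forced even pins the pooled ambiguous accuracy, so the
        # condition-only estimate cannot vary across recodings
        assert out.loc["forced_even", "sd_beta"] == pytest.approx(0.0, abs=1e-10)

    def test_requires_ambiguous_trials_and_multiple_runs(self):
        df = toy_responses(n_ambig=0)
        with pytest.raises(RefgameError):
            randomization_variance_study(df, n_runs=10)
        with pytest.raises(RefgameError):
            randomization_variance_study(toy_responses(), n_runs=1)


class TestContingency:
    def test_matches_reference_implementation_on_random_tables(self, rng):
        for _ in range(100):
            table = rng.integers(1, 40, size=(2, 3))
            stat, dof = chisq_independence(table)
            ref = stats.chi2_contingency(table, correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-9)
            assert dof == ref.dof

    def test_identical_rows_give_zero(self):
        stat, dof = chisq_independence([[5, 10, 5], [5, 10, 5]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert dof == 2

    def test_zero_marginal_rejected(self):
        with pytest.raises(RefgameError):
            chisq_independence([[0, 5], [0, 10]])


class TestKappa:
    def test_perfect_agreement(self):
        k, (lo, hi) = cohens_kappa(list("abcabc"), list("abcabc"))
        assert k == 1.0

    def test_known_two_by_two(self):
        # confusion [[45, 5], [5, 45]]: p_o = 0.9, p_e = 0.5, kappa = 0.8
        a = [0] * 50 + [1] * 50
        b = [0] * 45 + [1] * 5 + [0] * 5 + [1] * 45
        k, (lo, hi) = cohens_kappa(a, b)
        assert k == pytest.approx(0.8, abs=1e-12)
        assert lo < 0.8 < hi

    def test_independent_labels_near_zero(self, rng):
        n = 10_000
        a = rng.integers(0, 3, n)
        b = rng.integers(0, 3, n)
        k, _ = cohens_kappa(a, b)
        se = 1 / np.sqrt(n)  # rough scale of kappa under independence
        assert abs(k) <= 3 * se

    def test_matches_sklearn_point_estimate(self, rng):
        a = rng.integers(0, 4, 300)
        b = np.where(rng.random(300) < 0.7, a, rng.integers(0, 4, 300))
        k, _ = cohens_kappa(a, b)
        assert k == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(RefgameError):
            cohens_kappa([1, 2], [1])


def four_cluster_accuracies(rng, n=60):
    """Well-separated synthetic accuracy profiles for four planted classes."""
    means = np.array([[0.5, 0.5], [0.92, 0.5], [0.92, 0.92], [0.2, 0.35]])
    labels = np.repeat(np.arange(4), n // 4)
    X = means[labels] + rng.normal(0, 0.04, size=(len(labels), 2))
    X = np.clip(X, 0, 1)
    return pd.DataFrame(X, columns=["acc_simple", "acc_complex"]), labels


class TestLatentProfiles:
    def test_recovers_planted_cluster_count(self, rng):
        acc, _ = four_cluster_accuracies(rng)
        fits, K_bic, K_aic = fit_latent_profiles(acc, K_range=range(1, 7), seed=0)
        assert K_bic == 4
        assert {fits[K].K for K in fits} == set(range(1, 7))

    def test_single_tight_cluster_selects_one(self, rng):
        acc = pd.DataFrame(
            rng.normal(0.7, 0.03, size=(50, 2)),
            columns=["acc_simple", "acc_complex"],
        )
        _, K_bic, _ = fit_latent_profiles(acc, K_range=range(1, 5), seed=0)
        assert K_bic == 1

    def test_responsibilities_are_distributions(self, rng):
        acc, _ = four_cluster_accuracies(rng)
        fits, K_bic, _ = fit_latent_profiles(acc, K_range=[2, 4], seed=0)
        for fit in fits.values():
            np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0,
                                       atol=1e-9)
            assert fit.aic == pytest.approx(
                2 * fit.n_parameters - 2 * fit.log_likelihood, abs=1e-6)
            assert fit.bic == pytest.approx(
                fit.n_parameters * np.log(len(acc)) - 2 * fit.log_likelihood,
                abs=1e-6)

    def test_em_log_likelihood_non_decreasing(self, rng):
        # step the EM one iteration at a time and watch the lower bound
        acc, _ = four_cluster_accuracies(rng)
        X = acc.to_numpy()
        gm = GaussianMixture(n_components=4, covariance_type="diag",
                             max_iter=1, warm_start=True, reg_covar=1e-4,
                             random_state=0, tol=0.0)
        bounds = []
        import warnings as w
        for _ in range(25):
            with w.catch_warnings():
                w.simplefilter("ignore")
                gm.fit(X)
            bounds.append(gm.lower_bound_)
        assert all(b2 >= b1 - 1e-6 for b1, b2 in zip(bounds, bounds[1:]))

    def test_too_few_participants_rejected(self):
        acc = pd.DataFrame({"acc_simple": [0.5] * 5, "acc_complex": [0.5] * 5})
        with pytest.raises(RefgameError):
            fit_latent_profiles(acc, K_range=range(1, 7))


class TestNearestProfile:
    @pytest.mark.parametrize(
        "point,expected",
        [
            ((0.5, 0.5), "L0"),
            ((1.0, 0.5), "L1"),
            ((1.0, 1.0), "L2"),
            ((0.95, 0.45), "L1"),
            ((0.2, 0.4), "other"),
            ((0.55, 0.6), "L0"),
        ],
    )
    def test_canonical_assignments(self, point, expected):
        assert classify_nearest_profile(*point) == expected

    def test_tie_breaks_toward_lower_level(self):
        # equidistant between L0 (.5,.5) and L1 (1,.5)
        assert classify_nearest_profile(0.75, 0.5) == "L0"
        # equidistant between L1 (1,.5) and L2 (1,1)
        assert classify_nearest_profile(1.0, 0.75) == "L1"

    def test_undefined_accuracy_falls_to_other(self):
        assert classify_nearest_profile(float("nan"), 0.5) == "other"


class TestHomogeneityCompleteness:
    def test_identical_partitions(self):
        h, c = homogeneity_completeness(list("aabb"), list("xxyy"))
        assert (h, c) == (1.0, 1.0)

    def test_single_cluster_prediction(self):
        h, c = homogeneity_completeness(["a"] * 6, ["x", "x", "y", "y", "z", "z"])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(1.0, abs=1e-12)

    def test_label_permutation_invariance(self, rng):
        ref = rng.integers(0, 3, 60)
        pred = rng.integers(0, 4, 60)
        h1, c1 = homogeneity_completeness(pred, ref)
        h2, c2 = homogeneity_completeness((pred + 7) % 11, ref)
        assert (h1, c1) == pytest.approx((h2, c2), abs=1e-12)

    def test_noisy_four_class_recovery(self, rng):
        ref = np.repeat(np.arange(4), 15)
        pred = ref.copy()
        flip = rng.random(60) < 0.1
        pred[flip] = rng.integers(0, 4, flip.sum())
        h, c = homogeneity_completeness(pred, ref)
        assert h > 0.6 and c > 0.6


class TestRecovery:
    def test_pure_l0_population_recovered(self):
        pop = PopulationSpec(n_participants=30, mixture={"rsa_L0": 1.0},
                             lam=20.0, lapse_rate=0.02,
                             position_bias=(0.0, 0.0), seed=21,
                             design_id="exp4_abstract")
        res = recovery_experiment(pop, K_range=range(1, 4))
        assert res["recovery_by_class"]["L0"] >= 0.9

    def test_visual_resemblance_misread_as_reasoner_on_original_stimuli(self):
        pop = PopulationSpec(n_participants=30,
                             mixture={"visual_resemblance": 1.0},
                             position_bias=(0.0, 0.0), seed=22)
        res = recovery_experiment(pop, K_range=range(1, 4))
        assigned = res["assignments"]["nearest_class"]
        assert (assigned.isin(["L1", "L2"])).mean() > 0.5

    def test_visual_resemblance_exposed_on_remapped_stimuli(self):
        pop = PopulationSpec(n_participants=30,
                             mixture={"visual_resemblance": 1.0},
                             design_id="exp2_remapped",
                             position_bias=(0.0, 0.0), seed=23)
        res = recovery_experiment(pop, K_range=range(1, 4))
        assigned = res["assignments"]["nearest_class"]
        assert (assigned.isin(["other", "L0"])).mean() > 0.5
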