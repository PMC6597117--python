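"""Likelihood, multi-start fitting, LR test, information criteria."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from objspace.fitting import (
    FitResult,
    MemoryTraceModel,
    chance_log_likelihood,
    compare_models,
    fit_session,
    information_criteria,
    likelihood_ratio_vs_chance,
    proportions_from_behavior,
    session_log_likelihood,
)
from objspace.io import Dataset
from objspace.memory_model import ModelParams, predict_proportions
from objspace.schedule import generate_session
from objspace.simulator import simulate_session


@pytest.mark.parametrize("n,expected", [(1, math.log(0.5)), (6, 6 * math.log(0.5)),
                                        (21, -14.556090791758852)])
def test_chance_log_likelihood(n, expected):
    assert chance_log_likelihood(n) == pytest.approx(expected)


def test_session_ll_chance_equivalence(rat_overlapping):
    # beta = 0 predicts 0.5 everywhere: LL = N ln 0.5 for any data
    trials = rat_overlapping.to_frame()
    rng = np.random.default_rng(0)
    q = rng.uniform(0, 1, len(trials))
    behav = trials.assign(time_obj1_s=40 * q, time_obj2_s=40 * (1 - q))
    params = ModelParams("M1", alpha=0.3, beta=0.0)
    assert session_log_likelihood(behav, trials, params) == pytest.approx(
        6 * math.log(0.5))


def test_session_ll_single_trial_cross_entropy(rat_overlapping):
    # q = p = 0.7 on one trial: 0.7 ln 0.7 + 0.3 ln 0.3 = -0.610864
    q = np.array([0.7])
    from objspace.fitting import _cross_entropy_ll

    assert _cross_entropy_ll(q, np.array([0.7])) == pytest.approx(-0.610864, abs=1e-5)


def test_zero_exploration_trials_are_skipped(rat_overlapping):
    trials = rat_overlapping.to_frame()
    behav = trials.assign(time_obj1_s=20.0, time_obj2_s=20.0)
    behav.loc[2, ["time_obj1_s", "time_obj2_s"]] = 0.0
    params = ModelParams("M1", alpha=0.3, beta=0.0)
    ll = session_log_likelihood(behav, trials, params)
    assert ll == pytest.approx(5 * math.log(0.5))  # 5 explored trials only


def test_ll_invariant_to_joint_slot_relabel(rat_overlapping):
    trials = rat_overlapping.to_frame()
    params = ModelParams("M1", alpha=0.6, beta=3.0)
    p = predict_proportions(trials, params)
    rng = np.random.default_rng(1)
    q = np.clip(p + rng.normal(0, 0.05, p.size), 0, 1)
    behav = trials.assign(time_obj1_s=40 * q, time_obj2_s=40 * (1 - q))
    ll = session_log_likelihood(behav, trials, params)
    # swap slots jointly in schedule and behavior
    swapped = trials.rename(columns={"loc_slot1": "loc_slot2",
                                     "loc_slot2": "loc_slot1"})
    behav_sw = swapped.assign(time_obj1_s=40 * (1 - q), time_obj2_s=40 * q)
    # slot roles swapped => entropies swap => p -> 1-p, q -> 1-q: same LL
    ll_sw = session_log_likelihood(behav_sw, swapped, params)
    assert ll == pytest.approx(ll_sw, abs=1e-10)


def _simulated_behavior(schedule, params, noise_sd, seed):
    sim = simulate_session(schedule, params, noise_sd, seed=seed)
    return sim.to_behavior_frame()


def test_fit_beats_brute_force_grid():
    # 200x200 grid over (alpha, beta in [-20, 20]) on a 6-trial session
    sched = generate_session("overlapping", "rat_2day", 1, seed=5)
    truth = ModelParams("M1", alpha=0.6, beta=5.0)
    behav = _simulated_behavior(sched, truth, noise_sd=0.05, seed=3)
    trials = sched.to_frame()
    q = proportions_from_behavior(behav)

    from objspace.fitting import _cross_entropy_ll

    best = -np.inf
    for alpha in np.linspace(0, 1, 200):
        for beta in np.linspace(-20, 20, 200):
            p = predict_proportions(trials, ModelParams("M1", alpha, beta))
            best = max(best, _cross_entropy_ll(q, p))
    fr = fit_session(behav, trials, "M1", n_starts=100, seed=0)
    assert fr.ll_opt >= best - 1e-3


def test_fit_uninformative_data_matches_chance(rat_overlapping):
    trials = rat_overlapping.to_frame()
    behav = trials.assign(time_obj1_s=20.0, time_obj2_s=20.0)  # q = 0.5
    fr = fit_session(behav, trials, "M1", n_starts=30, seed=1)
    assert fr.ll_opt == pytest.approx(fr.ll_chance, abs=1e-6)
    assert fr.pseudo_r2 == pytest.approx(0.0, abs=1e-6)


def test_fit_determinism(small_rat_dataset):
    sess = next(Dataset(small_rat_dataset.schedules,
                        small_rat_dataset.behavior).sessions())
    a = fit_session(sess.behavior, sess.trials, "M1", n_starts=20, seed=7)
    b = fit_session(sess.behavior, sess.trials, "M1", n_starts=20, seed=7)
    assert (a.params_opt, a.ll_opt) == (b.params_opt, b.ll_opt)


def test_fit_recovers_sign_and_scale():
    sched = generate_session("overlapping", "mouse_5day", 2, seed=11)
    truth = ModelParams("M1", alpha=0.6, beta=5.0)
    behav = _simulated_behavior(sched, truth, noise_sd=0.05, seed=4)
    fr = fit_session(behav, sched.to_frame(), "M1", n_starts=100, seed=2)
    assert fr.params_opt.beta > 0
    assert fr.pseudo_r2 > 0.3
    # fitted predictions must track the generating model's proportions
    p_hat = predict_proportions(sched.to_frame(), fr.params_opt)
    p_true = predict_proportions(sched.to_frame(), truth)
    assert np.corrcoef(p_hat, p_true)[0, 1] > 0.8


def test_estimator_sklearn_protocol(rat_overlapping):
    est = MemoryTraceModel(model_id="M1", n_starts=10, seed=0)
    assert est.get_params() == {"model_id": "M1", "n_starts": 10, "seed": 0}
    est2 = clone(est).set_params(n_starts=5)
    assert est2.n_starts == 5
    trials = rat_overlapping.to_frame()
    p_true = predict_proportions(trials, ModelParams("M1", 0.6, 2.0))
    est.fit(trials, p_true)
    assert hasattr(est, "alpha_") and hasattr(est, "ll_")
    preds = est.predict(trials)
    assert preds.shape == (6,)
    assert np.all((preds >= 0) & (preds <= 1))
    assert est.score(trials, p_true) <= 0  # mean log-likelihood


def test_likelihood_ratio_vs_chance_values():
    fr = FitResult(ModelParams("M1", 0.5, 0.0), -4.0, -4.0, 0.0, 6, 10, 1.0, False)
    stat, p = likelihood_ratio_vs_chance(fr)
    assert stat == 0.0 and p == pytest.approx(1.0)
    fr2 = FitResult(ModelParams("M1", 0.5, 1.0), -1.0, -4.0, 0.75, 6, 10, 1.0, False)
    stat2, p2 = likelihood_ratio_vs_chance(fr2)
    assert stat2 == pytest.approx(6.0)
    assert p2 == pytest.approx(0.049787, abs=1e-5)


def test_information_criteria_formula():
    fr = FitResult(ModelParams("M1", 0.5, 1.0), -10.0, -14.56, 0.3, 21, 10, 1.0, False)
    aic, bic = information_criteria([fr])
    assert aic == pytest.approx(24.0)
    assert bic == pytest.approx(2 * math.log(21) + 20, abs=1e-9)
    with pytest.raises(ValueError):
        information_criteria([])
    fr2 = FitResult(ModelParams("M2", 0.5, 1.0, gamma=0.5), -10.0, -14.56,
                    0.3, 21, 10, 1.0, False)
    with pytest.raises(ValueError, match="same model"):
        information_criteria([fr, fr2])


def test_nested_model_penalty_arithmetic():
    # On identical data, AIC(M2) >= AIC(M1) - 2*(ll gain) + 2 by construction
    ll1, ll2, n = -8.0, -7.2, 6
    f1 = FitResult(ModelParams("M1", 0.5, 1.0), ll1, -4.2, 0.1, n, 5, 1.0, False)
    f2 = FitResult(ModelParams("M2", 0.5, 1.0, gamma=0.9), ll2, -4.2, 0.1, n, 5,
                   1.0, False)
    assert f2.aic == pytest.approx(f1.aic - 2 * (ll2 - ll1) + 2)


def test_compare_models_single_session_sem_missing(small_rat_dataset):
    data = Dataset(small_rat_dataset.schedules, small_rat_dataset.behavior)
    one = next(data.sessions())
    single = Dataset(
        small_rat_dataset.schedules[
            (small_rat_dataset.schedules["animal_id"] == one.animal_id)
            & (small_rat_dataset.schedules["condition"] == one.condition)],
        one.behavior,
    )
    table = compare_models(single, model_ids=("M1", "M4"), n_starts=10, seed=0)
    assert len(table) == 2
    assert table["sem_alpha"].isna().all()
    assert table["aic_winner"].sum() >= 1
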