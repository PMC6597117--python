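"""Trace updates, forgetting, entropy, softmax, and session trajectories."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from objspace.memory_model import (
    LOG4,
    MemoryTraceState,
    ModelParams,
    TrialObservation,
    allocation_probabilities,
    apply_day_forgetting,
    predict_proportions,
    run_model_over_session,
    trace_entropy,
    update_trace,
)
from objspace.schedule import generate_session


def test_update_from_zero_trace():
    params = ModelParams("M1", alpha=0.6, beta=0.2)
    state = MemoryTraceState.initial(0.0)
    new = update_trace(state, TrialObservation(1, 3), params)
    assert new.m[0, 0] == pytest.approx(0.6)
    assert np.all(new.m[0, 1:] == 0.0)
    assert new.m[1, 2] == pytest.approx(0.6)
    assert new.trial_index == 1


def test_update_alpha_one_overwrites():
    params = ModelParams("M1", alpha=1.0, beta=0.2)
    state = MemoryTraceState(m=np.random.default_rng(0).uniform(size=(2, 4)))
    new = update_trace(state, TrialObservation(2, 4), params)
    assert np.allclose(new.m[0], [0, 1, 0, 0])
    assert np.allclose(new.m[1], [0, 0, 0, 1])


@pytest.mark.parametrize("n", [1, 3, 7])
def test_repeated_observation_geometric_buildup(n):
    # n repeats of the same location from m0=0 give 1 - (1-alpha)^n
    alpha = 0.6
    params = ModelParams("M1", alpha=alpha, beta=0.0)
    state = MemoryTraceState.initial(0.0)
    for _ in range(n):
        state = update_trace(state, TrialObservation(1, 2), params)
    assert state.m[0, 0] == pytest.approx(1 - (1 - alpha) ** n)


def test_day_forgetting_limits_and_value():
    m = MemoryTraceState(m=np.full((2, 4), 1.0))
    keep = apply_day_forgetting(m, ModelParams("M2", 0.5, 0.2, gamma=1.0))
    assert np.allclose(keep.m, 1.0)  # gamma = 1: identity
    reset = apply_day_forgetting(m, ModelParams("M2", 0.5, 0.2, gamma=0.0))
    assert np.allclose(reset.m, 0.0)  # gamma = 0: overnight reset to m0
    part = apply_day_forgetting(m, ModelParams("M2", 0.5, 0.2, gamma=0.36))
    assert np.allclose(part.m, 0.36)
    # n nights compose multiplicatively
    two = apply_day_forgetting(m, ModelParams("M2", 0.5, 0.2, gamma=0.6), n_nights=2)
    assert np.allclose(two.m, 0.36)


def test_day_forgetting_requires_forgetting_model():
    m = MemoryTraceState.initial(0.0)
    with pytest.raises(ValueError, match="M2/M3"):
        apply_day_forgetting(m, ModelParams("M1", 0.5, 0.2))


def test_params_validation():
    with pytest.raises(ValueError):
        ModelParams("M1", alpha=1.5, beta=0.0)
    with pytest.raises(ValueError):
        ModelParams("M2", alpha=0.5, beta=0.0)  # gamma missing
    with pytest.raises(ValueError):
        ModelParams("M1", alpha=0.5, beta=0.0, m0=0.3)  # m0 fixed at 0
    ModelParams("M4", alpha=0.5, beta=0.0, m0=0.3)  # m0 free for M4


@pytest.mark.parametrize(
    "row,expected",
    [
        ((0.25, 0.25, 0.25, 0.25), LOG4),
        ((0.7, 0.0, 0.0, 0.0), 0.0),
        ((0.5, 0.5, 0.0, 0.0), math.log(2)),
        ((0.0, 0.0, 0.0, 0.0), LOG4),  # no information: uniform
    ],
)
def test_trace_entropy_values(row, expected):
    state = MemoryTraceState(m=np.array([row, row], dtype=float))
    assert trace_entropy(state, 0) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.0, 10.0), min_size=4, max_size=4),
       st.permutations(range(4)))
def test_entropy_permutation_invariant(row, perm):
    m = np.array([row, row])
    s1 = trace_entropy(MemoryTraceState(m=m), 0)
    m2 = m[:, list(perm)]
    s2 = trace_entropy(MemoryTraceState(m=m2), 0)
    assert s1 == pytest.approx(s2, abs=1e-12)
    assert 0.0 <= s1 <= LOG4 + 1e-12


def test_allocation_probability_examples():
    assert allocation_probabilities(1.0, 0.3, 0.0) == (0.5, 0.5)
    p1, p2 = allocation_probabilities(LOG4, 0.0, 0.2)
    assert p1 == pytest.approx(0.568874, abs=1e-5)
    assert p1 + p2 == pytest.approx(1.0, abs=1e-12)
    # neophobia limit: beta -> -inf prefers the more certain object
    p1, _ = allocation_probabilities(0.0, LOG4, -1e4)
    assert p1 == pytest.approx(1.0)


@settings(max_examples=50, deadline=None)
@given(st.floats(0.0, LOG4), st.floats(0.0, LOG4),
       st.floats(-30, 30))
def test_allocation_symmetry_and_sign(s1, s2, beta):
    a = allocation_probabilities(s1, s2, beta)
    b = allocation_probabilities(s2, s1, beta)
    assert a == pytest.approx(b[::-1], abs=1e-12)
    if s1 != s2 and beta != 0:
        flipped = allocation_probabilities(s1, s2, -beta)
        assert (a[0] - 0.5) * (flipped[0] - 0.5) <= 0


@settings(max_examples=30, deadline=None)
@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0),
       st.integers(0, 2**31 - 1))
def test_trace_stays_in_unit_interval(alpha, gamma, m0, seed):
    params = ModelParams("M3", alpha=alpha, beta=0.0, gamma=gamma, m0=m0)
    rng = np.random.default_rng(seed)
    state = MemoryTraceState.initial(m0)
    for _ in range(15):
        if rng.integers(2):
            state = apply_day_forgetting(state, params)
        locs = rng.choice(4, size=2, replace=False) + 1
        state = update_trace(state, TrialObservation(int(locs[0]), int(locs[1])), params)
        assert np.all(state.m >= -1e-12) and np.all(state.m <= 1.0 + 1e-12)


def test_first_trial_allocation_is_even(rat_overlapping):
    for m0 in (0.0, 0.5):
        mid = "M4" if m0 else "M1"
        params = ModelParams(mid, alpha=0.7, beta=3.0, m0=m0)
        (pred, _), *_ = run_model_over_session(rat_overlapping.trials, params)
        assert pred.p_obj1 == pytest.approx(0.5, abs=1e-12)


def test_stable_entropy_jumps_only_at_test(rat_stable):
    params = ModelParams("M1", alpha=0.95, beta=0.2)
    out = run_model_over_session(rat_stable.trials, params)
    for pred, _ in out[:5]:
        assert pred.entropy_obj1 == pytest.approx(0.0, abs=1e-9)
        assert pred.entropy_obj2 == pytest.approx(0.0, abs=1e-9)
    test_pred = out[5][0]
    assert test_pred.entropy_obj2 > 0.1  # the moved object's trace spreads
    assert test_pred.entropy_obj1 == pytest.approx(0.0, abs=1e-9)


def test_overlapping_preference_builds_up(rat_overlapping, m1_params):
    out = run_model_over_session(rat_overlapping.trials, m1_params)
    p2 = [pred.p_obj2 for pred, _ in out[:5]]
    assert p2[0] == pytest.approx(0.5)
    assert p2[-1] > p2[0]
    assert all(p >= 0.5 - 1e-12 for p in p2)


def test_alpha_one_prediction_depends_only_on_current_trial():
    # "episodic memory of the last trial": any histories ending in the same
    # configuration yield the same prediction there
    params = ModelParams("M1", alpha=1.0, beta=5.0)
    a = generate_session("overlapping", "rat_2day", 0, seed=1)
    b = generate_session("random", "rat_2day", 0, seed=9)
    trials_a = a.to_frame()
    trials_b = b.to_frame()
    trials_b.loc[trials_b.index[-1], ["loc_slot1", "loc_slot2"]] = (
        trials_a.iloc[-1][["loc_slot1", "loc_slot2"]].to_numpy())
    pa = predict_proportions(trials_a, params)
    pb = predict_proportions(trials_b, params)
    assert pa[-1] == pytest.approx(pb[-1], abs=1e-12)


def test_perfect_counter_oracle_matches_small_alpha_ranking():
    # An exact-count trace (increment the observed cell, no decay) must give
    # the same entropy ranking as the leaky trace in the alpha -> 0 limit.
    sched = generate_session("random", "mouse_5day", 2, seed=6)
    trials = sched.trials[:10]
    params = ModelParams("M1", alpha=1e-4, beta=1.0)
    out = run_model_over_session(trials, params)

    counts = np.zeros((2, 4))
    for t, (pred, _) in zip(trials, out):
        counts[0, t.loc_slot1 - 1] += 1
        counts[1, t.loc_slot2 - 1] += 1
        ent = []
        for row in counts:
            q = row / row.sum()
            ent.append(-np.sum(q[q > 0] * np.log(q[q > 0])))
        d_oracle = ent[0] - ent[1]
        d_model = pred.entropy_obj1 - pred.entropy_obj2
        if abs(d_oracle) > 1e-9:
            assert np.sign(d_model) == np.sign(d_oracle)
        else:
            assert abs(d_model) < 1e-3


def test_unordered_trials_rejected(rat_overlapping, m1_params):
    trials = list(rat_overlapping.trials)
    trials[0], trials[3] = trials[3], trials[0]
    with pytest.raises(ValueError, match="ordered"):
        run_model_over_session(trials, m1_params)


def test_forgetting_applied_per_elapsed_night():
    # Identical observation sequences (obj1 fixed at loc 1, obj2 at 3, 2, 3)
    # but a 1-night vs 3-night gap before the last trial: with gamma < 1 the
    # longer gap downweights the pre-gap history more, changing the final
    # allocation; with gamma = 1 the gap length is immaterial.
    def final_p(last_day, gamma):
        trials = np.array([[1, 1, 3], [1, 1, 2], [last_day, 1, 3]])
        params = ModelParams("M2", alpha=0.5, beta=1.0, gamma=gamma)
        return predict_proportions(trials, params)[-1]

    assert final_p(2, 0.5) != pytest.approx(final_p(4, 0.5))
    assert final_p(2, 1.0) == pytest.approx(final_p(4, 1.0))
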