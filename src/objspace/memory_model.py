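"""Memory-trace model family M1-M4 for the Object Space Task.

Each model maintains a leaky count ``m(o, l)`` of how often object-slot
``o`` (2 slots) has been observed at location ``l`` (4 locations). On every
trial the observed configuration is integrated with a low-pass filter

    m'(o, l) = (1 - alpha) * m(o, l) + alpha * delta(o, l)

where ``delta`` is 1 exactly at the observed location and ``alpha`` in
[0, 1] sets the balance between recent (alpha -> 1, episodic-like) and
remote (alpha -> 0, cumulative) information. The model's uncertainty about
an object's usual location is the Shannon entropy (in nats) of the
row-normalized trace, and exploration is allocated between the two objects
by a Boltzmann softmax over the entropies with weight ``beta`` (beta > 0:
neophilia, preference for the more uncertain object; beta < 0: neophobia).

A trial's allocation is computed *after* the trial's configuration has been
observed and integrated into the trace: the animal sees where the objects
are, and the resulting change in uncertainty drives how it splits its
exploration time within that trial. This is what produces the signature
test-trial effect in the stable condition -- the displaced object's trace
suddenly spreads over two locations, its entropy jumps, and exploration
shifts toward it.

Model variants:

* M1 -- alpha, beta; trace starts at 0.
* M2 -- adds overnight forgetting with rate gamma (Eq. m' = m + (1-gamma)(m0-m),
  applied once per elapsed night), attractor m0 fixed at 0.
* M3 -- M2 with m0 a free parameter (also the initial trace value).
* M4 -- M1 with m0 free but no forgetting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MODEL_IDS = ("M1", "M2", "M3", "M4")

#: Free parameters per model: (alpha, beta) + gamma for M2/M3 + m0 for M3/M4.
N_FREE_PARAMS = {"M1": 2, "M2": 3, "M3": 4, "M4": 3}

LOG4 = math.log(4.0)

#: Allocation probabilities are clamped to this range before any logarithm
#: is taken during fitting (part of the likelihood contract).
P_CLAMP = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Parameter set of one model variant."""

    model_id: str = "M1"
    alpha: float = 0.6
    beta: float = 0.2
    gamma: float | None = None
    m0: float = 0.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.uses_forgetting:
            if self.gamma is None or not 0.0 <= self.gamma <= 1.0:
                raise ValueError(f"{self.model_id} requires gamma in [0, 1]")
        elif self.gamma is not None:
            raise ValueError(f"{self.model_id} has no forgetting parameter gamma")
        if self.m0 < 0.0:
            raise ValueError("m0 must be >= 0")
        if self.model_id in ("M1", "M2") and self.m0 != 0.0:
            raise ValueError(f"m0 is fixed at 0 for {self.model_id}")

    @property
    def uses_forgetting(self) -> bool:
        return self.model_id in ("M2", "M3")

    @property
    def n_free(self) -> int:
        return N_FREE_PARAMS[self.model_id]


@dataclass
class MemoryTraceState:
    """2 objects x 4 locations trace matrix plus the trial counter."""

    m: np.ndarray
    trial_index: int = 0

    @classmethod
    def initial(cls, m0: float = 0.0) -> "MemoryTraceState":
        return cls(m=np.full((2, 4), float(m0)), trial_index=0)

    def copy(self) -> "MemoryTraceState":
        return MemoryTraceState(m=self.m.copy(), trial_index=self.trial_index)


@dataclass(frozen=True)
class TrialObservation:
    """Observed locations (1-4) of the two object slots; the Kronecker
    indicator is 1 exactly at each object's observed location."""

    loc_obj1: int
    loc_obj2: int

    def __post_init__(self) -> None:
        for loc in (self.loc_obj1, self.loc_obj2):
            if not 1 <= loc <= 4:
                raise ValueError("locations must be in 1..4")
        if self.loc_obj1 == self.loc_obj2:
            raise ValueError("the two objects must occupy distinct locations")


@dataclass(frozen=True)
class TrialPrediction:
    """Per-trial entropies (nats) and exploration-allocation probabilities."""

    entropy_obj1: float
    entropy_obj2: float
    p_obj1: float
    p_obj2: float


def update_trace(
    state: MemoryTraceState, observation: TrialObservation, params: ModelParams
) -> MemoryTraceState:
    """Low-pass integrate one trial's observation into both object rows."""
    a = params.alpha
    m = (1.0 - a) * state.m
    m[0, observation.loc_obj1 - 1] += a
    m[1, observation.loc_obj2 - 1] += a
    return MemoryTraceState(m=m, trial_index=state.trial_index + 1)


def apply_day_forgetting(
    state: MemoryTraceState, params: ModelParams, n_nights: int = 1
) -> MemoryTraceState:
    """Pull every trace entry toward the attractor m0, once per night.

    One night maps m to m + (1 - gamma) * (m0 - m) = gamma*m + (1-gamma)*m0;
    n nights compose to gamma**n * m + (1 - gamma**n) * m0.
    """
    if not params.uses_forgetting:
        raise ValueError(
            f"day forgetting is only defined for M2/M3, not {params.model_id}"
        )
    if n_nights < 1:
        raise ValueError("n_nights must be >= 1")
    g = params.gamma ** n_nights
    return MemoryTraceState(m=g * state.m + (1.0 - g) * params.m0,
                            trial_index=state.trial_index)


def _row_entropy(row: Sequence[float]) -> float:
    total = row[0] + row[1] + row[2] + row[3]
    if total <= 0.0:
        return LOG4  # no information yet: uniform over the 4 locations
    s = 0.0
    for x in row:
        if x > 0.0:
            p = x / total  # may underflow to 0 for subnormal x; 0 ln 0 = 0
            if p > 0.0:
                s -= p * math.log(p)
    return s


def trace_entropy(state: MemoryTraceState, object_index: int) -> float:
    """Entropy (nats) of the normalized trace row of one object (0 or 1).

    An all-zero row normalizes to the uniform distribution (maximal
    uncertainty before any observation), giving ln 4.
    """
    return _row_entropy(state.m[object_index])


def allocation_probabilities(
    entropy_obj1: float, entropy_obj2: float, params: ModelParams | float
) -> tuple[float, float]:
    """Boltzmann softmax over the two entropies: p1 = sigma(beta*(S1-S2))."""
    beta = params.beta if isinstance(params, ModelParams) else float(params)
    x = beta * (entropy_obj1 - entropy_obj2)
    if x >= 0:
        p1 = 1.0 / (1.0 + math.exp(-x))
    else:
        e = math.exp(x)
        p1 = e / (1.0 + e)
    return p1, 1.0 - p1


def trials_to_arrays(trials) -> tuple[list[int], list[int], list[int]]:
    """Extract (days, loc_slot1, loc_slot2) from trials.

    Accepts a sequence of :class:`~objspace.schedule.TrialConfig`-like
    objects, a DataFrame with columns ``day``/``loc_slot1``/``loc_slot2``,
    or an (n, 3) array of the same. Trials must already be in session order.
    """
    if isinstance(trials, pd.DataFrame):
        days = [int(x) for x in trials["day"]]
        l1 = [int(x) for x in trials["loc_slot1"]]
        l2 = [int(x) for x in trials["loc_slot2"]]
    elif isinstance(trials, np.ndarray):
        arr = np.asarray(trials, dtype=int)
        days, l1, l2 = (list(arr[:, i]) for i in range(3))
    else:
        days = [int(t.day) for t in trials]
        l1 = [int(t.loc_slot1) for t in trials]
        l2 = [int(t.loc_slot2) for t in trials]
    return days, l1, l2


def _check_ordered(trials) -> None:
    if isinstance(trials, pd.DataFrame):
        keys = list(zip(trials["day"], trials["trial_in_day"]))
    elif isinstance(trials, np.ndarray):
        return
    else:
        keys = [(t.day, t.trial_in_day) for t in trials]
    if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
        raise ValueError("trials must be strictly ordered by (day, trial_in_day)")


def session_trajectory(
    days: Sequence[int],
    loc1: Sequence[int],
    loc2: Sequence[int],
    model_id: str,
    alpha: float,
    beta: float,
    gamma: float | None = None,
    m0: float = 0.0,
) -> tuple[list[float], list[float], list[float]]:
    """Fast core loop: per-trial (S_obj1, S_obj2, p_obj1).

    Plain-Python inner loop over the 2x4 trace; this is the hot path of
    likelihood evaluation during multi-start fitting.
    """
    forget = model_id in ("M2", "M3")
    row1 = [m0, m0, m0, m0]
    row2 = [m0, m0, m0, m0]
    one_minus_a = 1.0 - alpha
    s1_out: list[float] = []
    s2_out: list[float] = []
    p_out: list[float] = []
    prev_day = days[0] if days else 0
    for t in range(len(days)):
        d = days[t]
        if forget and d != prev_day:
            g = gamma ** (d - prev_day)
            add = (1.0 - g) * m0
            for i in range(4):
                row1[i] = g * row1[i] + add
                row2[i] = g * row2[i] + add
        prev_day = d
        for i in range(4):
            row1[i] *= one_minus_a
            row2[i] *= one_minus_a
        row1[loc1[t] - 1] += alpha
        row2[loc2[t] - 1] += alpha
        s1 = _row_entropy(row1)
        s2 = _row_entropy(row2)
        x = beta * (s1 - s2)
        if x >= 0:
            p1 = 1.0 / (1.0 + math.exp(-x))
        else:
            e = math.exp(x)
            p1 = e / (1.0 + e)
        s1_out.append(s1)
        s2_out.append(s2)
        p_out.append(p1)
    return s1_out, s2_out, p_out


def run_model_over_session(
    trials, params: ModelParams
) -> list[tuple[TrialPrediction, MemoryTraceState]]:
    """Run one model over an ordered session of trials.

    For every trial, the observation is integrated into the trace (with
    M2/M3 overnight forgetting applied first at day boundaries, once per
    elapsed night) and the post-observation entropies drive that trial's
    allocation probabilities. Returns one (prediction, state) pair per
    trial; the state is the trace *after* the trial.
    """
    _check_ordered(trials)
    days, l1, l2 = trials_to_arrays(trials)
    state = MemoryTraceState.initial(params.m0)
    out: list[tuple[TrialPrediction, MemoryTraceState]] = []
    prev_day: int | None = None
    for t in range(len(days)):
        if params.uses_forgetting and prev_day is not None and days[t] != prev_day:
            state = apply_day_forgetting(state, params, n_nights=days[t] - prev_day)
        prev_day = days[t]
        state = update_trace(state, TrialObservation(l1[t], l2[t]), params)
        s1 = trace_entropy(state, 0)
        s2 = trace_entropy(state, 1)
        p1, p2 = allocation_probabilities(s1, s2, params)
        out.append((TrialPrediction(s1, s2, p1, p2), state.copy()))
    return out


def predict_proportions(trials, params: ModelParams) -> np.ndarray:
    """Model-predicted per-trial exploration proportion for slot 1's object."""
    _check_ordered(trials)
    days, l1, l2 = trials_to_arrays(trials)
    _, _, p = session_trajectory(
        days, l1, l2, params.model_id, params.alpha, params.beta, params.gamma, params.m0
    )
    return np.asarray(p)


def trajectory_frame(trials, params: ModelParams, session_id: str = "") -> pd.DataFrame:
    """Tidy per-trial trajectory (entropies and allocation probabilities)."""
    _check_ordered(trials)
    days, l1, l2 = trials_to_arrays(trials)
    s1, s2, p = session_trajectory(
        days, l1, l2, params.model_id, params.alpha, params.beta, params.gamma, params.m0
    )
    return pd.DataFrame(
        {
            "session_id": session_id,
            "day": days,
            "trial": np.arange(1, len(days) + 1),
            "S_obj1": s1,
            "S_obj2": s2,
            "p_obj1": p,
            "p_obj2": 1.0 - np.asarray(p),
        }
    )
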