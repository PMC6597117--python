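"""Simulate model agents over Object Space Task schedules.

The agent's per-trial exploration proportion for slot 1's object equals the
model's allocation probability, optionally perturbed by additive Gaussian
noise truncated to [0, 1]. With zero noise a simulated session is a pure
function of (schedule, parameters), which keeps reproductions of the model's
behavioral signatures deterministic. Total exploration time defaults to a
constant nominal 40 s per trial (times do not affect the discrimination
index of proportions); a per-trial array can be supplied for realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import discrimination_index
from .memory_model import ModelParams, TrialPrediction, run_model_over_session
from .schedule import (
    N_COUNTERBALANCE_SLOTS,
    Schedule,
    generate_session,
)


@dataclass
class SimulatedSession:
    """One agent run: model predictions plus simulated behavior."""

    schedule: Schedule
    params: ModelParams
    predictions: list[TrialPrediction]
    proportions: np.ndarray
    total_time_s: np.ndarray

    def to_behavior_frame(self) -> pd.DataFrame:
        """Behavior rows in the shared behavior-CSV schema."""
        t = self.schedule.trials
        total = self.total_time_s
        t1 = self.proportions * total
        return pd.DataFrame(
            {
                "animal_id": self.schedule.animal_id,
                "condition": self.schedule.condition,
                "day": [x.day for x in t],
                "trial_in_day": [x.trial_in_day for x in t],
                "phase": [x.phase for x in t],
                "loc_slot1": [x.loc_slot1 for x in t],
                "loc_slot2": [x.loc_slot2 for x in t],
                "time_obj1_s": t1,
                "time_obj2_s": total - t1,
            }
        )

    def di_series(self) -> np.ndarray:
        """Per-trial DI; slot 2 is the novel/less-often-shown reference."""
        total = self.total_time_s
        t1 = self.proportions * total
        return np.array(
            [discrimination_index(total[i] - t1[i], t1[i]) for i in range(len(total))]
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_session(
    schedule: Schedule,
    params: ModelParams,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    total_time_s: float | np.ndarray = 40.0,
) -> SimulatedSession:
    """Run one agent over one schedule.

    proportion_t = clip(p_obj1,t + eps_t, 0, 1) with eps_t ~ N(0, noise_sd^2);
    noise_sd = 0 returns the model probabilities exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    traj = run_model_over_session(schedule.trials, params)
    preds = [pred for pred, _ in traj]
    p = np.array([pred.p_obj1 for pred in preds])
    if noise_sd > 0:
        rng = _as_rng(seed)
        p = np.clip(p + rng.normal(0.0, noise_sd, size=p.size), 0.0, 1.0)
    total = np.broadcast_to(np.asarray(total_time_s, dtype=float), p.shape).copy()
    if np.any(total <= 0):
        raise ValueError("total_time_s must be > 0")
    return SimulatedSession(schedule, params, preds, p, total)


def simulate_cohort(
    schedules: Sequence[Schedule],
    params_per_animal: Sequence[ModelParams],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[SimulatedSession]:
    """Independent per-session substreams derived from one seed."""
    if len(schedules) != len(params_per_animal):
        raise ValueError(
            f"{len(schedules)} schedules but {len(params_per_animal)} parameter sets"
        )
    streams = np.random.SeedSequence(seed).spawn(len(schedules))
    return [
        simulate_session(s, p, noise_sd, seed=np.random.default_rng(ss))
        for s, p, ss in zip(schedules, params_per_animal, streams)
    ]


def _counterbalanced_schedules(
    condition: str, protocol: str, n_sessions: int, seed: int
) -> list[Schedule]:
    rng = np.random.default_rng(seed)
    return [
        generate_session(
            condition,
            protocol,
            counterbalance_slot=i % N_COUNTERBALANCE_SLOTS,
            seed=int(rng.integers(2**31)),
            animal_id=f"sim{i:03d}",
        )
        for i in range(n_sessions)
    ]


def session_di_summary(sim: SimulatedSession) -> tuple[float, float]:
    """(last-sample DI, test DI) of one simulated session; for protocols
    without a 24-h test the final trial is used."""
    di = sim.di_series()
    phases = [t.phase for t in sim.schedule.trials]
    sample_idx = [i for i, ph in enumerate(phases) if ph == "sample"]
    test_idx = [i for i, ph in enumerate(phases) if ph in ("test", "delayed_test")]
    last_sample = di[sample_idx[-1]] if sample_idx else np.nan
    test = di[test_idx[-1]] if test_idx else di[-1]
    return float(last_sample), float(test)


def sweep_parameters(
    alpha_grid: Sequence[float],
    beta_grid: Sequence[float],
    condition: str,
    protocol: str = "rat_2day",
    n_sessions: int = 24,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Mean (last-sample DI, test DI) over counterbalanced sessions for each
    (alpha, beta) grid cell; the same schedules are reused across cells."""
    if len(alpha_grid) == 0 or len(beta_grid) == 0:
        raise ValueError("parameter grids must be non-empty")
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    schedules = _counterbalanced_schedules(condition, protocol, n_sessions, seed)
    streams = np.random.SeedSequence(seed).spawn(len(schedules))
    rows = []
    for alpha in alpha_grid:
        for beta in beta_grid:
            params = ModelParams("M1", float(alpha), float(beta))
            last, test = [], []
            for sched, ss in zip(schedules, streams):
                sim = simulate_session(
                    sched, params, noise_sd, seed=np.random.default_rng(ss)
                )
                a, b = session_di_summary(sim)
                last.append(a)
                test.append(b)
            rows.append(
                {
                    "alpha": float(alpha),
                    "beta": float(beta),
                    "di_last_sample": float(np.mean(last)),
                    "di_test": float(np.mean(test)),
                }
            )
    return pd.DataFrame(rows)
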