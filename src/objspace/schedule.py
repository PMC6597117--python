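"""Counterbalanced trial-schedule generation for the Object Space Task.

The task presents two objects per trial at 2 of 4 magnet-marked corner
locations of a 75x75 cm arena, under three conditions:

* ``stable`` -- both locations constant over all sample trials; one object
  is displaced at the test trial.
* ``overlapping`` -- one location (the stable role, slot 1) is shared by
  every trial including the test; the other moves between the remaining
  three locations; the last sample trial and the test trial share the same
  configuration, so only cumulative memory predicts a test preference.
* ``random`` -- pseudo-random pairs with per-day balanced location usage;
  a negative control with no extractable pattern.

Locations are integers 1-4. Object identity changes every trial, so the
persistent identity a model can track is the schedule *slot*: slot 1 is
the stable-role location in stable/overlapping, and an arbitrary but fixed
pseudo-stable reference in random (needed so a discrimination index can be
defined there; counterbalancing makes its expectation zero).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("stable", "overlapping", "random")

#: Number of distinct counterbalance assignments: 4 stable-role locations x
#: 3 partner choices x 2 test-destination choices.
N_COUNTERBALANCE_SLOTS = 24

_MAX_ATTEMPTS = 10_000


class ScheduleError(ValueError):
    """Invalid schedule request."""


class InfeasibleScheduleError(ScheduleError):
    """The constraint set cannot be satisfied; the message names the rule."""


@dataclass(frozen=True)
class Protocol:
    """Trial layout of one training protocol.

    ``sample_days`` are calendar day indices (1-based); gaps between
    consecutive indices encode elapsed nights, which drive the day-level
    forgetting of models M2/M3 (e.g. the 4-week protocol trains Mon-Fri,
    so Friday->Monday is a 3-night gap).
    """

    name: str
    sample_days: tuple[int, ...]
    trials_per_day: int
    test_day: int | None = None
    final_trial_day: int | None = None
    delayed_test_trials: tuple[int, ...] = ()

    @property
    def n_sample_trials(self) -> int:
        return len(self.sample_days) * self.trials_per_day

    @property
    def n_trials(self) -> int:
        n = self.n_sample_trials
        if self.test_day is not None:
            n += 1
        if self.final_trial_day is not None:
            n += 1
        return n

    def layout(self) -> list[tuple[int, int, str]]:
        """Ordered (day, trial_in_day, phase) for every trial."""
        rows: list[tuple[int, int, str]] = []
        t = 0
        for day in self.sample_days:
            for k in range(1, self.trials_per_day + 1):
                t += 1
                phase = "delayed_test" if t in self.delayed_test_trials else "sample"
                rows.append((day, k, phase))
        if self.test_day is not None:
            rows.append((self.test_day, 1, "test"))
        if self.final_trial_day is not None:
            rows.append((self.final_trial_day, 1, "delayed_test"))
        return rows


PROTOCOLS: dict[str, Protocol] = {
    # Rats: 5 sample trials in one day, 10-min test 24 h later.
    "rat_2day": Protocol("rat_2day", sample_days=(1,), trials_per_day=5, test_day=2),
    # Mice: 5 sample trials/day for 4 days, test 24 h after the last.
    "mouse_5day": Protocol("mouse_5day", sample_days=(1, 2, 3, 4), trials_per_day=5, test_day=5),
    # Piloted mouse variant with 3 sample trials/day.
    "mouse_3trial": Protocol("mouse_3trial", sample_days=(1, 2, 3, 4), trials_per_day=3, test_day=5),
    # 3 weeks x 25 trials (Mon-Fri) + final trial on Wednesday of week 4.
    # Trial 26 (Monday of week 2) and trial 76 repeat the previous
    # configuration and act as 3-day and 5-day delayed tests.
    "mouse_4week": Protocol(
        "mouse_4week",
        sample_days=tuple(7 * w + d for w in range(3) for d in range(1, 6)),
        trials_per_day=5,
        final_trial_day=24,
        delayed_test_trials=(26,),
    ),
}


@dataclass(frozen=True)
class TrialConfig:
    """Object-location layout of a single trial (locations 1-4)."""

    session_id: str
    condition: str
    day: int
    trial_in_day: int
    phase: str
    loc_slot1: int
    loc_slot2: int
    object_pair_id: str

    @property
    def pair(self) -> frozenset[int]:
        return frozenset((self.loc_slot1, self.loc_slot2))


@dataclass
class Schedule:
    """All trials of one session (one animal x one condition)."""

    animal_id: str
    protocol: str
    condition: str
    trials: list[TrialConfig]
    counterbalance_slot: int
    condition_order: tuple[str, ...] = CONDITIONS

    @property
    def session_id(self) -> str:
        return self.trials[0].session_id

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "animal_id": self.animal_id,
                "protocol": self.protocol,
                "condition": t.condition,
                "day": t.day,
                "trial_in_day": t.trial_in_day,
                "phase": t.phase,
                "loc_slot1": t.loc_slot1,
                "loc_slot2": t.loc_slot2,
                "object_pair_id": t.object_pair_id,
                "counterbalance_slot": self.counterbalance_slot,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)


def get_protocol(protocol: str | Protocol) -> Protocol:
    if isinstance(protocol, Protocol):
        return protocol
    try:
        return PROTOCOLS[protocol]
    except KeyError:
        raise ScheduleError(
            f"unknown protocol {protocol!r}; choose from {sorted(PROTOCOLS)}"
        ) from None


def _counterbalance(cb: int) -> tuple[int, int, int, int]:
    """Decode a counterbalance slot into 0-based location roles.

    Returns (stable-role location for *stable*, its partner, the test
    destination pick, stable-role location for *overlapping*). The
    overlapping stable role always differs from the stable one, so a given
    animal never reuses its stable-role location across the two conditions.
    """
    s_stable = cb % 4
    offset = (cb // 4) % 3
    dest_pick = (cb // 12) % 2
    others = [l for l in range(4) if l != s_stable]
    partner = others[offset]
    s_over = (s_stable + 1 + offset) % 4
    return s_stable, partner, dest_pick, s_over


def _balanced_counts(n: int, items: Sequence[int], rng: np.random.Generator) -> dict[int, int]:
    base, extra = divmod(n, len(items))
    counts = {it: base for it in items}
    for it in rng.permutation(np.asarray(items))[:extra]:
        counts[int(it)] += 1
    return counts


def _moving_sequence(
    n_slots: int,
    movers: Sequence[int],
    forced_copy: Sequence[int],
    rng: np.random.Generator,
) -> list[int]:
    """Sequence of moving locations, balanced over ``movers``.

    ``forced_copy`` lists 0-based positions that must repeat the previous
    position (the delayed-test trials of the 4-week protocol). Elsewhere,
    immediate repeats are forbidden so that the moving location genuinely
    varies from trial to trial. Greedy randomized construction with restart.
    """
    forced = set(forced_copy)
    n_free = n_slots - len(forced)
    for _ in range(_MAX_ATTEMPTS):
        counts = _balanced_counts(n_free, movers, rng)
        seq: list[int] = []
        ok = True
        for pos in range(n_slots):
            if pos in forced:
                seq.append(seq[-1])
                continue
            valid = [m for m in movers if counts[m] > 0 and (not seq or m != seq[-1])]
            if not valid:
                ok = False
                break
            choice = int(rng.choice(np.asarray(valid)))
            counts[choice] -= 1
            seq.append(choice)
        if ok:
            return seq
    raise InfeasibleScheduleError(
        "moving-location rule: could not build a balanced, non-repeating "
        f"sequence of {n_slots} moving locations over {list(movers)}"
    )


def _random_day(
    n_trials: int,
    prev_pair: frozenset[int] | None,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """One pseudo-random day: ``n_trials`` ordered location pairs (0-based).

    Constraints: per-day slot counts of the 4 locations differ by at most 1
    (exactly equal when 2*n_trials divides by 4); every location appears in
    the first min(3, n_trials) trials; for 5-trial days each location is
    used exactly once over the last 2 trials; no trial repeats the previous
    trial's pair (including across the day boundary).
    """
    if 2 * n_trials < 4:
        raise InfeasibleScheduleError(
            "location-coverage rule: a day needs at least 2 trials so that "
            "all 4 locations can be used"
        )
    for _ in range(_MAX_ATTEMPTS):
        counts = _balanced_counts(2 * n_trials, range(4), rng)
        trials: list[tuple[int, int]] = []
        if n_trials == 5:
            # Last 2 trials: each location exactly once (disjoint pairs).
            perm = [int(x) for x in rng.permutation(4)]
            tail = [(perm[0], perm[1]), (perm[2], perm[3])]
            head_counts = {l: counts[l] - 1 for l in range(4)}
            if any(c < 0 for c in head_counts.values()):
                continue
            pool = [l for l in range(4) for _ in range(head_counts[l])]
            pool = [int(x) for x in rng.permutation(np.asarray(pool))]
            head = [(pool[2 * i], pool[2 * i + 1]) for i in range(3)]
            trials = head + tail
        else:
            pool = [l for l in range(4) for _ in range(counts[l])]
            pool = [int(x) for x in rng.permutation(np.asarray(pool))]
            trials = [(pool[2 * i], pool[2 * i + 1]) for i in range(n_trials)]
        if any(a == b for a, b in trials):
            continue
        pairs = [frozenset(t) for t in trials]
        seq = ([prev_pair] if prev_pair is not None else []) + pairs
        if any(seq[i] == seq[i + 1] for i in range(len(seq) - 1)):
            continue
        cover = min(3, n_trials)
        if {l for t in trials[:cover] for l in t} != set(range(4)):
            continue
        return trials
    raise InfeasibleScheduleError(
        f"pseudo-random rule: no valid {n_trials}-trial day found in "
        f"{_MAX_ATTEMPTS} attempts"
    )


def generate_session(
    condition: str,
    protocol: str | Protocol,
    counterbalance_slot: int,
    seed: int,
    animal_id: str = "animal000",
    condition_order: tuple[str, ...] = CONDITIONS,
    session_id: str | None = None,
) -> Schedule:
    """Generate one counterbalanced session; deterministic given the seed."""
    if condition not in CONDITIONS:
        raise ScheduleError(f"unknown condition {condition!r}; choose from {CONDITIONS}")
    proto = get_protocol(protocol)
    if proto.name == "mouse_4week" and condition != "overlapping":
        raise ScheduleError(
            "the mouse_4week protocol is defined for the overlapping condition only"
        )
    rng = np.random.default_rng(seed)
    layout = proto.layout()
    s_stable, partner, dest_pick, s_over = _counterbalance(counterbalance_slot)

    slot_pairs: list[tuple[int, int]] = []  # 0-based (slot1, slot2)
    if condition == "stable":
        free = [l for l in range(4) if l not in (s_stable, partner)]
        dest = free[dest_pick]
        for day, k, phase in layout:
            slot_pairs.append((s_stable, dest if phase == "test" else partner))
    elif condition == "overlapping":
        movers = [l for l in range(4) if l != s_over]
        n_samples = proto.n_sample_trials
        forced = [i for i in range(n_samples) if (i + 1) in proto.delayed_test_trials]
        seq = _moving_sequence(n_samples, movers, forced, rng)
        if proto.test_day is not None or proto.final_trial_day is not None:
            seq = seq + [seq[-1]]  # test repeats the last sample configuration
        slot_pairs = [(s_over, m) for m in seq]
    else:  # random
        prev: frozenset[int] | None = None
        for day in proto.sample_days:
            day_trials = _random_day(proto.trials_per_day, prev, rng)
            for a, b in day_trials:
                if rng.integers(2):
                    a, b = b, a
                slot_pairs.append((a, b))
                prev = frozenset((a, b))
        if proto.test_day is not None:
            for _ in range(_MAX_ATTEMPTS):
                a, b = (int(x) for x in rng.choice(4, size=2, replace=False))
                if frozenset((a, b)) != prev:
                    break
            slot_pairs.append((a, b))

    sid = session_id or f"{animal_id}:{condition}"
    trials = [
        TrialConfig(
            session_id=sid,
            condition=condition,
            day=day,
            trial_in_day=k,
            phase=phase,
            loc_slot1=a + 1,
            loc_slot2=b + 1,
            object_pair_id=f"{sid}:pair{t + 1:03d}",
        )
        for t, ((day, k, phase), (a, b)) in enumerate(zip(layout, slot_pairs))
    ]
    return Schedule(
        animal_id=animal_id,
        protocol=proto.name,
        condition=condition,
        trials=trials,
        counterbalance_slot=counterbalance_slot,
        condition_order=tuple(condition_order),
    )


def generate_cohort(
    n_animals: int,
    protocol: str | Protocol,
    seed: int,
    conditions: tuple[str, ...] | None = None,
) -> list[Schedule]:
    """Counterbalanced cohort: one schedule per animal per condition.

    Counterbalance slots cycle over the 24 distinct assignments and
    condition orders cycle over all permutations, so both are balanced as
    evenly as ``n_animals`` permits.
    """
    if n_animals < 1:
        raise ScheduleError("n_animals must be >= 1")
    proto = get_protocol(protocol)
    if conditions is None:
        conditions = ("overlapping",) if proto.name == "mouse_4week" else CONDITIONS
    rng = np.random.default_rng(seed)
    orders = list(itertools.permutations(conditions))
    schedules: list[Schedule] = []
    for i in range(n_animals):
        order = orders[i % len(orders)]
        for cond in order:
            schedules.append(
                generate_session(
                    cond,
                    proto,
                    counterbalance_slot=i % N_COUNTERBALANCE_SLOTS,
                    seed=int(rng.integers(2**31)),
                    animal_id=f"animal{i:03d}",
                    condition_order=order,
                )
            )
    return schedules


def validate_schedule(schedule: Schedule) -> list[str]:
    """Return a list of violated rules (empty iff the schedule is valid)."""
    v: list[str] = []
    trials = schedule.trials
    try:
        proto = get_protocol(schedule.protocol)
    except ScheduleError:
        return [f"unknown protocol {schedule.protocol!r}"]

    for i, t in enumerate(trials, start=1):
        if not (1 <= t.loc_slot1 <= 4 and 1 <= t.loc_slot2 <= 4):
            v.append(f"trial {i}: locations must be in 1..4")
        if t.loc_slot1 == t.loc_slot2:
            v.append(f"trial {i}: loc_slot1 == loc_slot2")
    ids = [t.object_pair_id for t in trials]
    if len(set(ids)) != len(ids):
        v.append("object_pair_id repeats within the session")

    layout = proto.layout()
    if len(trials) != len(layout):
        v.append(f"trial count {len(trials)} != protocol {proto.name} ({len(layout)})")
        return v
    for i, (t, (day, k, phase)) in enumerate(zip(trials, layout), start=1):
        if (t.day, t.trial_in_day, t.phase) != (day, k, phase):
            v.append(f"trial {i}: layout ({t.day},{t.trial_in_day},{t.phase}) "
                     f"!= protocol ({day},{k},{phase})")

    samples = [t for t in trials if t.phase == "sample"]
    tests = [t for t in trials if t.phase in ("test", "delayed_test")]
    cond = schedule.condition
    if cond == "stable":
        pairs = {(t.loc_slot1, t.loc_slot2) for t in samples}
        if len(pairs) != 1:
            v.append("stable: sample-trial locations are not constant")
        for t in tests:
            ref = samples[-1]
            diff = (t.loc_slot1 != ref.loc_slot1) + (t.loc_slot2 != ref.loc_slot2)
            if diff != 1:
                v.append(f"stable: test trial must move exactly one slot (moved {diff})")
    elif cond == "overlapping":
        if len({t.loc_slot1 for t in trials}) != 1:
            v.append("overlapping: slot1 (stable role) is not constant")
        for i, t in enumerate(trials):
            if t.phase != "sample" and i > 0 and t.pair != trials[i - 1].pair:
                v.append(f"trial {i + 1}: (delayed) test configuration differs "
                         "from the preceding trial")
    elif cond == "random":
        by_day: dict[int, list[TrialConfig]] = {}
        for t in samples:
            by_day.setdefault(t.day, []).append(t)
        for day, ts in by_day.items():
            slots = [l for t in ts for l in (t.loc_slot1, t.loc_slot2)]
            counts = [slots.count(l) for l in (1, 2, 3, 4)]
            if max(counts) - min(counts) > 1 or (
                len(slots) % 4 == 0 and max(counts) != min(counts)
            ):
                v.append(f"random: unbalanced location usage on day {day}: {counts}")
            cover = min(3, len(ts))
            seen = {l for t in ts[:cover] for l in (t.loc_slot1, t.loc_slot2)}
            if seen != {1, 2, 3, 4}:
                v.append(f"random: first {cover} trials of day {day} do not cover "
                         "all 4 locations")
            if len(ts) == 5:
                tail = [l for t in ts[3:] for l in (t.loc_slot1, t.loc_slot2)]
                if sorted(tail) != [1, 2, 3, 4]:
                    v.append(f"random: last 2 trials of day {day} do not use each "
                             "location exactly once")
        for i in range(1, len(trials)):
            if trials[i].pair == trials[i - 1].pair:
                v.append(f"random: trials {i} and {i + 1} repeat the same "
                         "location pair")
    else:
        v.append(f"unknown condition {cond!r}")
    return v


def schedules_to_frame(schedules: Iterable[Schedule]) -> pd.DataFrame:
    frames = [s.to_frame() for s in schedules]
    return pd.concat(frames, ignore_index=True)
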