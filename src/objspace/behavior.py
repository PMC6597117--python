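"""Behavioral outcome measures and statistics for the Object Space Task.

The central measure is the discrimination index

    DI = (t_novel - t_stable) / (t_novel + t_stable)  in [-1, 1],

where "novel" is the moved / less-often-shown object location: the moved
slot in the stable condition (for sample trials, the to-be-moved slot,
where no preference is expected), the moving slot in overlapping, and the
counterbalanced pseudo-stable reference's partner in random. Under the slot
conventions of :mod:`objspace.schedule`, slot 2 is the novel reference in
every condition, so DI = (time_obj2 - time_obj1) / total.

Statistics mirror the study's analysis: repeated-measures ANOVAs over
within-subject factors (condition, trial, day, week) and two-sided
one-sample t-tests of DI against the chance level 0. ANOVAs use uncorrected
degrees of freedom by default; a Greenhouse-Geisser-corrected single-factor
variant is available for the 4-week week analysis. No multiple-testing
correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Animals whose smallest per-trial total exploration falls below this many
#: seconds are excluded from analysis.
DEFAULT_EXCLUSION_THRESHOLD_S = 5.0


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


class DesignError(ValueError):
    """Within-subject design incomplete or unbalanced; lists missing cells."""


def discrimination_index(time_novel_s: float, time_stable_s: float) -> float:
    """(novel - stable) / (novel + stable); NaN when nothing was explored."""
    if time_novel_s < 0 or time_stable_s < 0:
        raise ValueError("exploration times must be >= 0")
    total = time_novel_s + time_stable_s
    if total <= 0:
        return float("nan")
    return (time_novel_s - time_stable_s) / total


def attach_di(behavior: pd.DataFrame) -> pd.DataFrame:
    """Add ``total_time_s``, ``novel_slot`` and ``di`` columns.

    A ``novel_slot`` column is honored if present; otherwise slot 2 is the
    novel reference (the schedule module's convention in all conditions).
    """
    df = behavior.copy()
    df["total_time_s"] = df["time_obj1_s"] + df["time_obj2_s"]
    if "novel_slot" not in df.columns:
        df["novel_slot"] = 2
    novel = np.where(df["novel_slot"] == 2, df["time_obj2_s"], df["time_obj1_s"])
    stable = df["total_time_s"] - novel
    with np.errstate(invalid="ignore", divide="ignore"):
        di = np.where(df["total_time_s"] > 0,
                      (novel - stable) / df["total_time_s"].where(df["total_time_s"] > 0, 1.0),
                      np.nan)
    df["di"] = di
    return df


@dataclass
class Exclusion:
    animal_id: str
    reason: str


def apply_exclusions(
    behavior: pd.DataFrame,
    min_total_exploration_s: float = DEFAULT_EXCLUSION_THRESHOLD_S,
) -> tuple[pd.DataFrame, list[Exclusion]]:
    """Drop animals whose minimum per-trial total exploration is below the
    threshold (default 5 s); returns the reduced table and the exclusions."""
    if min_total_exploration_s < 0:
        raise ValueError("threshold must be >= 0")
    totals = behavior["time_obj1_s"] + behavior["time_obj2_s"]
    worst = totals.groupby(behavior["animal_id"]).min()
    excluded = worst[worst < min_total_exploration_s]
    exclusions = [
        Exclusion(str(a), f"exploration time {v:.2f} s below "
                          f"{min_total_exploration_s:g} s threshold")
        for a, v in excluded.items()
    ]
    kept = behavior[~behavior["animal_id"].isin(excluded.index)].reset_index(drop=True)
    return kept, exclusions


def one_sample_t_vs_chance(di_values: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided one-sample t-test of the DI values against 0."""
    vals = np.asarray(di_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise InsufficientDataError(
            f"one-sample t-test needs >= 2 values, got {vals.size}"
        )
    res = stats.ttest_1samp(vals, 0.0)
    if np.all(vals == vals[0]) and vals[0] == 0.0:
        return 0.0, vals.size - 1, 1.0  # degenerate all-zero sample
    return float(res.statistic), vals.size - 1, float(res.pvalue)


def _check_complete(data: pd.DataFrame, subject: str, within: Sequence[str]) -> None:
    counts = data.groupby([subject, *within], observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index.tolist()[:10]
        raise DesignError(f"cells with != 1 observation per subject: {bad}")
    levels = [data[f].nunique() for f in within]
    expected = data[subject].nunique() * int(np.prod(levels))
    if len(counts) != expected:
        full = pd.MultiIndex.from_product(
            [data[subject].unique()] + [data[f].unique() for f in within],
            names=[subject, *within],
        )
        missing = full.difference(counts.index).tolist()[:10]
        raise DesignError(f"missing design cells (first 10): {missing}")


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: Sequence[str],
    correction: str | None = None,
) -> pd.DataFrame:
    """Repeated-measures ANOVA over fully-crossed within-subject factors.

    Returns one row per main effect / interaction with columns
    ``F, df_num, df_den, p``. ``correction="gg"`` applies the
    Greenhouse-Geisser sphericity correction (single-factor designs only,
    as used for the 4-week week analysis); degrees of freedom are then
    epsilon-scaled and fractional.
    """
    within = list(within)
    clean = data[[subject, dv, *within]].dropna(subset=[dv])
    _check_complete(clean, subject, within)
    if correction is None:
        from statsmodels.stats.anova import AnovaRM

        table = AnovaRM(clean, depvar=dv, subject=subject, within=within).fit().anova_table
        out = table.rename(
            columns={"F Value": "F", "Num DF": "df_num", "Den DF": "df_den", "Pr > F": "p"}
        )
        out.index = [i.replace(":", "X") for i in out.index]
        return out[["F", "df_num", "df_den", "p"]]
    if correction != "gg":
        raise ValueError("correction must be None or 'gg'")
    if len(within) != 1:
        raise NotImplementedError(
            "Greenhouse-Geisser correction is implemented for single-factor designs"
        )
    import pingouin as pg

    aov = pg.rm_anova(data=clean, dv=dv, within=within[0], subject=subject,
                      correction=True)
    row = aov.iloc[0]
    eps = float(row["eps"])
    gg_col = next((c for c in ("p_GG_corr", "p-GG-corr") if c in aov.columns), None)
    unc_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    p = float(row[gg_col]) if gg_col and not pd.isna(row[gg_col]) else float(row[unc_col])
    return pd.DataFrame(
        {
            "F": [float(row["F"])],
            "df_num": [eps * float(row["ddof1"])],
            "df_den": [eps * float(row["ddof2"])],
            "p": [p],
        },
        index=[within[0]],
    )


def di_timecourse(
    behavior: pd.DataFrame,
    by: Sequence[str] = ("condition", "day", "trial_in_day"),
) -> pd.DataFrame:
    """Mean +/- SEM DI per group (over animals)."""
    df = attach_di(behavior)
    g = df.groupby(list(by), observed=True)["di"]
    out = g.agg(mean_di="mean", sem_di="sem", n="count").reset_index()
    return out


@dataclass
class StatReport:
    """ANOVA tables, t-tests vs chance, and the applied exclusions."""

    anovas: dict = field(default_factory=dict)
    t_tests: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "anovas": {
                name: [
                    {"effect": str(idx), "F": float(r["F"]),
                     "df_num": float(r["df_num"]), "df_den": float(r["df_den"]),
                     "p": float(r["p"])}
                    for idx, r in table.iterrows()
                ]
                for name, table in self.anovas.items()
            },
            "t_tests": {
                name: {"t": t, "df": df, "p": p}
                for name, (t, df, p) in self.t_tests.items()
            },
            "exclusions": [
                {"animal_id": e.animal_id, "reason": e.reason} for e in self.exclusions
            ],
        }


def _ttests_by_condition(df: pd.DataFrame, label: str, report: StatReport) -> None:
    for cond, grp in df.groupby("condition", observed=True):
        try:
            report.t_tests[f"{label}:{cond}"] = one_sample_t_vs_chance(grp["di"])
        except InsufficientDataError:
            pass


def standard_analysis(
    behavior: pd.DataFrame,
    protocol: str,
    min_total_exploration_s: float = DEFAULT_EXCLUSION_THRESHOLD_S,
) -> StatReport:
    """The study's standard statistical battery for one protocol's data."""
    report = StatReport()
    behavior, report.exclusions = apply_exclusions(behavior, min_total_exploration_s)
    df = attach_di(behavior)
    df["trial"] = df["trial_in_day"]
    samples = df[df["phase"] == "sample"]
    tests = df[df["phase"].isin(["test", "delayed_test"])]

    if protocol == "rat_2day":
        # All 6 trials: overall trial index (test = trial 6).
        all6 = df.copy()
        all6["trial6"] = np.where(all6["phase"] == "sample", all6["trial"], 6)
        report.anovas["time_condition_x_trial"] = rm_anova(
            all6, "total_time_s", "animal_id", ["condition", "trial6"])
        report.anovas["di_condition_x_trial"] = rm_anova(
            all6, "di", "animal_id", ["condition", "trial6"])
        report.anovas["di_training_condition_x_trial"] = rm_anova(
            samples, "di", "animal_id", ["condition", "trial"])
        report.anovas["time_training_condition_x_trial"] = rm_anova(
            samples, "total_time_s", "animal_id", ["condition", "trial"])
        report.anovas["di_test_condition"] = rm_anova(
            tests, "di", "animal_id", ["condition"])
        _ttests_by_condition(tests, "test", report)
    elif protocol in ("mouse_5day", "mouse_3trial"):
        report.anovas["di_samples_condition_x_trial_x_day"] = rm_anova(
            samples, "di", "animal_id", ["condition", "trial", "day"])
        report.anovas["time_samples_condition_x_trial_x_day"] = rm_anova(
            samples, "total_time_s", "animal_id", ["condition", "trial", "day"])
        last_day = samples["day"].max()
        last_trial = samples.loc[samples["day"] == last_day, "trial"].max()
        final = samples[(samples["day"] == last_day) & (samples["trial"] == last_trial)]
        final = pd.concat([final, tests])
        final = final.assign(probe=np.where(final["phase"] == "sample",
                                            "last_sample", "test"))
        report.anovas["di_final_condition_x_trial"] = rm_anova(
            final, "di", "animal_id", ["condition", "probe"])
        _ttests_by_condition(final[final["probe"] == "last_sample"],
                             "last_sample", report)
        _ttests_by_condition(final[final["probe"] == "test"], "test", report)
    elif protocol == "mouse_4week":
        train = df[df["phase"] == "sample"].copy()
        train["week"] = (train["day"] - 1) // 7 + 1
        weekly = (train.groupby(["animal_id", "week"], observed=True)
                  [["di", "total_time_s"]].mean().reset_index())
        report.anovas["di_week"] = rm_anova(
            weekly, "di", "animal_id", ["week"], correction="gg")
        report.anovas["time_week"] = rm_anova(
            weekly, "total_time_s", "animal_id", ["week"], correction="gg")
        probes = df[df["phase"] == "delayed_test"].sort_values(["day", "trial_in_day"])
        labels = {}
        for day, grp in probes.groupby("day"):
            labels[day] = grp
        days = sorted(labels)
        if len(days) >= 1:
            report.t_tests["test_3day"] = one_sample_t_vs_chance(labels[days[0]]["di"])
        if len(days) >= 2:
            report.t_tests["test_5day"] = one_sample_t_vs_chance(labels[days[-1]]["di"])
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    return report
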