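"""Tabular readers/writers, dataset joining, and the pipeline runner.

CSV is the interchange format. All writers are deterministic (fixed column
order, stable row sort, floats at 6 significant digits, UTF-8, LF line
endings) so that identical inputs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

SCHEDULE_COLUMNS = [
    "animal_id", "protocol", "condition", "day", "trial_in_day", "phase",
    "loc_slot1", "loc_slot2", "object_pair_id", "counterbalance_slot",
]
BEHAVIOR_COLUMNS = [
    "animal_id", "condition", "day", "trial_in_day", "phase",
    "loc_slot1", "loc_slot2", "time_obj1_s", "time_obj2_s",
]
FITS_COLUMNS = [
    "animal_id", "condition", "model", "alpha", "beta", "gamma", "m0",
    "ll", "ll_chance", "pseudo_r2", "aic", "bic", "lr_stat", "lr_p",
    "beta_outlier",
]
TRUTH_COLUMNS = ["animal_id", "condition", "alpha", "beta", "gamma", "m0",
                 "seed_substream"]

_SORT_KEYS = {
    "schedule": ["animal_id", "condition", "day", "trial_in_day"],
    "behavior": ["animal_id", "condition", "day", "trial_in_day"],
    "fits": ["animal_id", "condition", "model"],
    "truth": ["animal_id", "condition"],
}
_REQUIRED = {
    "schedule": SCHEDULE_COLUMNS,
    "behavior": BEHAVIOR_COLUMNS,
    "fits": FITS_COLUMNS,
    "truth": TRUTH_COLUMNS,
}


class SchemaError(ValueError):
    """A table does not match its schema; the message names the problem row."""


def write_table(df: pd.DataFrame, path, kind: str | None = None) -> None:
    """Deterministic CSV write (canonical column order and row sort)."""
    df = df.copy()
    if kind is not None:
        required = _REQUIRED[kind]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{kind} table is missing columns {missing}")
        extras = sorted(c for c in df.columns if c not in required)
        df = df[required + extras]
        if len(df):
            df = df.sort_values(_SORT_KEYS[kind], kind="mergesort")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n",
              encoding="utf-8")


def _read(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def read_schedules(path) -> pd.DataFrame:
    return _read(path, "schedule")


def read_behavior(path) -> pd.DataFrame:
    return _read(path, "behavior")


@dataclass
class SessionData:
    """One session's schedule trials and aligned behavior rows."""

    animal_id: str
    condition: str
    trials: pd.DataFrame
    behavior: pd.DataFrame


@dataclass
class Dataset:
    """Joined, validated schedules + behavior (+ provenance)."""

    schedules: pd.DataFrame
    behavior: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        key = ["animal_id", "condition", "day", "trial_in_day"]
        sched = self.schedules.reset_index(drop=True)
        behav = self.behavior.reset_index(drop=True)
        merged = behav.merge(
            sched[key + ["loc_slot1", "loc_slot2"]].rename(
                columns={"loc_slot1": "_l1", "loc_slot2": "_l2"}),
            on=key, how="left", indicator=True,
        )
        orphans = merged.index[merged["_merge"] != "both"].tolist()
        if orphans:
            row = behav.iloc[orphans[0]]
            raise SchemaError(
                f"behavior row {orphans[0]} has no matching schedule trial: "
                f"{row[key].to_dict()}"
            )
        bad = merged.index[
            (merged["loc_slot1"] != merged["_l1"])
            | (merged["loc_slot2"] != merged["_l2"])
        ].tolist()
        if bad:
            raise SchemaError(
                f"behavior row {bad[0]} disagrees with the schedule on object "
                "locations"
            )

    def sessions(self) -> Iterator[SessionData]:
        key = ["animal_id", "condition"]
        order = ["day", "trial_in_day"]
        for (animal, cond), trials in self.schedules.groupby(key, sort=True):
            behav = self.behavior[
                (self.behavior["animal_id"] == animal)
                & (self.behavior["condition"] == cond)
            ]
            yield SessionData(
                str(animal), str(cond),
                trials.sort_values(order).reset_index(drop=True),
                behav.sort_values(order).reset_index(drop=True),
            )

    def n_sessions(self) -> int:
        return self.schedules.groupby(["animal_id", "condition"]).ngroups


def read_dataset(schedule_path, behavior_path) -> Dataset:
    """Read and join the two tables; row-order independent."""
    return Dataset(
        read_schedules(schedule_path),
        read_behavior(behavior_path),
        provenance={"schedule_path": str(schedule_path),
                    "behavior_path": str(behavior_path)},
    )


def read_supplementary(path, column_map: dict[str, str],
                       sheet_name=0) -> pd.DataFrame:
    """Best-effort adapter for supplementary spreadsheet layouts.

    The source layout is not standardized, so the caller supplies a
    ``column_map`` from source column names to the behavior schema. Reads
    .xlsx via pandas/openpyxl or CSV.
    """
    p = Path(path)
    if p.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(p, sheet_name=sheet_name)
    else:
        df = pd.read_csv(p)
    df = df.rename(columns=column_map)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: column_map leaves behavior columns missing: {missing}"
        )
    return df[[c for c in df.columns if c in BEHAVIOR_COLUMNS]
              + [c for c in df.columns if c not in BEHAVIOR_COLUMNS]]


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir) -> dict:
    """Run named stages (synth -> fit/compare_models -> analyze) from one
    master seed; writes outputs plus a manifest of inputs, seeds and hashes.
    """
    from . import __version__, behavior as behavior_mod, fitting
    from .synthetic_data import CohortSpec, TimeProfile, generate_dataset

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", [])
    if not stages:
        raise ValueError("pipeline config defines no stages")
    for st in stages:  # pre-flight before any stage runs
        if "name" not in st:
            raise ValueError(f"stage without a name: {st}")
        for key in ("schedule", "behavior"):
            if key in st and not Path(st[key]).exists():
                raise FileNotFoundError(
                    f"stage {st['name']!r} references missing file {st[key]}"
                )
    master = int(config.get("seed", 0))
    streams = np.random.SeedSequence(master).spawn(len(stages))
    manifest = {"seed": master, "version": __version__, "stages": []}
    dataset: Dataset | None = None
    for st, ss in zip(stages, streams):
        name = st["name"]
        stage_seed = int(ss.generate_state(1)[0] % 2**31)
        record = {"name": name, "seed": stage_seed, "outputs": {}}
        try:
            if name == "synth":
                spec_kwargs = dict(st.get("spec", {}))
                if "time_profile" in spec_kwargs:
                    spec_kwargs["time_profile"] = TimeProfile(
                        **spec_kwargs["time_profile"])
                if "conditions" in spec_kwargs:
                    spec_kwargs["conditions"] = tuple(spec_kwargs["conditions"])
                spec_kwargs.setdefault("seed", stage_seed)
                data = generate_dataset(CohortSpec(**spec_kwargs))
                record["outputs"] = data.write(out)
                dataset = Dataset(data.schedules, data.behavior)
            elif name in ("fit", "compare_models"):
                if dataset is None:
                    dataset = read_dataset(st["schedule"], st["behavior"])
                if name == "fit":
                    table = fitting.fit_dataset(
                        dataset, model_id=st.get("model", "M1"),
                        n_starts=int(st.get("n_starts", 100)), seed=stage_seed)
                    path = out / "fits.csv"
                    write_table(table, path, kind="fits")
                else:
                    table = fitting.compare_models(
                        dataset, n_starts=int(st.get("n_starts", 100)),
                        seed=stage_seed)
                    path = out / "model_comparison.csv"
                    write_table(table, path)
                record["outputs"][name] = str(path)
            elif name == "analyze":
                if dataset is None:
                    dataset = read_dataset(st["schedule"], st["behavior"])
                protocol = st.get("protocol") or str(
                    dataset.schedules["protocol"].iloc[0])
                report = behavior_mod.standard_analysis(dataset.behavior, protocol)
                path = out / "report.json"
                path.write_text(json.dumps(report.to_dict(), indent=2))
                record["outputs"]["report"] = str(path)
            else:
                raise ValueError(f"unknown stage {name!r}")
        except Exception as exc:
            manifest["stages"].append({**record, "error": str(exc)})
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        record["hashes"] = {k: _sha256(v) for k, v in record["outputs"].items()}
        manifest["stages"].append(record)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
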