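"""Table I/O, validation, configuration and the end-to-end pipeline.

All tables travel as long-format CSV (comma separator, UTF-8, "." decimal,
header row). Three schemas are recognized:

* ``trial`` — one row per trial presentation (the task engine's output or
  a deposited trial-level export);
* ``scored`` — one row per participant x session x stimulation x trial
  type, after presentation averaging;
* ``hr`` — one row per 3-minute heart-rate measurement (pre/post
  stimulation within each block).

Deposited data with different column names is ingested through an explicit
column-mapping file (old -> canonical names) rather than guessed.
``run_pipeline`` chains simulate -> score -> filter -> fit -> contrasts and
emits a manifest whose stage counts must reconcile exactly; every output is
a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import lmm, scoring, simulate

logger = logging.getLogger("mgtlab")

__all__ = [
    "SCHEMAS",
    "PipelineConfig",
    "DatasetManifest",
    "read_behavioral_table",
    "write_table",
    "run_pipeline",
]

SCHEMAS: dict[str, list[str]] = {
    "trial": ["participant", "session", "stimulation", "trial_code",
              "n_pink", "reward_pink", "reward_blue", "chosen_color",
              "hit", "points", "rt_seconds"],
    "scored": ["participant", "group", "session", "stimulation",
               "trial_code", "risk", "co", "rt"],
    "hr": ["participant", "group", "session", "stimulation", "time", "hr"],
}

_KEY_COLS = ["participant", "session", "stimulation", "trial_code"]


def read_behavioral_table(path: str | Path, schema: str = "trial",
                          column_map: dict[str, str] | str | Path | None = None,
                          expected_participants: int | None = None,
                          partial_run_policy: str = "drop"
                          ) -> pd.DataFrame:
    """Read and validate a behavioral CSV.

    ``column_map`` renames source columns to the canonical schema (a dict
    or the path of a two-column CSV ``source,canonical``). A trial-level
    run with fewer than 250 rows triggers ``partial_run_policy``: ``drop``
    removes the whole run (logged), ``keep`` retains the partial run.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from "
                         f"{sorted(SCHEMAS)}")
    df = pd.read_csv(path)
    if column_map is not None:
        if not isinstance(column_map, dict):
            mapping_df = pd.read_csv(column_map)
            column_map = dict(zip(mapping_df.iloc[:, 0],
                                  mapping_df.iloc[:, 1]))
        df = df.rename(columns=column_map)
    required = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} "
                         f"for schema {schema!r}")
    if schema == "trial":
        bad = set(df["chosen_color"]) - {"pink", "blue"}
        if bad:
            raise ValueError(f"unknown chosen_color value(s): {sorted(bad)}")
        if (df["rt_seconds"] < 0).any():
            raise ValueError("negative response times in trial table")
        sizes = df.groupby(["participant", "session", "stimulation"],
                           observed=True).size()
        short = sizes[sizes < 2 * df["trial_code"].nunique()]
        if len(short):
            if partial_run_policy not in ("drop", "keep"):
                raise ValueError("partial_run_policy must be 'drop' or "
                                 "'keep'")
            logger.warning("%d run(s) are incomplete; policy=%s",
                           len(short), partial_run_policy)
            if partial_run_policy == "drop":
                idx = df.set_index(
                    ["participant", "session", "stimulation"]).index
                df = df[~idx.isin(short.index)].reset_index(drop=True)
    if schema == "scored":
        dup = df.duplicated(subset=_KEY_COLS)
        if dup.any():
            raise ValueError(f"{int(dup.sum())} duplicate "
                             "participant x session x stimulation x "
                             "trial_code row(s)")
        if (df["rt"].dropna() <= 0).any():
            raise ValueError("non-positive averaged response times")
    if expected_participants is not None:
        n = df["participant"].nunique()
        if n != expected_participants:
            raise ValueError(f"table has {n} participants, manifest "
                             f"expects {expected_participants}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> str:
    """Write a CSV and return its sha256 checksum."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run: design, options, seed."""

    seed: int = 0
    mode: str = "agents"  # "agents" (task-level) or "lmm" (scored-level)
    n_placebo: int = 31
    n_probiotics: int = 29
    n_dropped_runs: int = 5
    n_trial_types: int = 125
    iqr_scope: str = "global"
    tie_rule: str = "optimal"  # EV ties score 1; flagged in the tables
    models: tuple[str, ...] = ("risk",)
    contrasts: bool = True
    out_dir: str = "mgt_output"

    def design(self) -> simulate.CohortDesign:
        return simulate.CohortDesign(
            n_placebo=self.n_placebo, n_probiotics=self.n_probiotics,
            n_dropped_runs=self.n_dropped_runs,
            n_trial_types=self.n_trial_types)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["models"] = list(d["models"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class DatasetManifest:
    """Audit record of a pipeline run; stage counts must reconcile."""

    source: str
    seed: int
    n_participants: int
    n_trial_rows: int
    n_scored_rows: int
    n_rt_removed: int
    n_rt_retained: int
    dropped_runs: list = field(default_factory=list)
    checksums: dict[str, str] = field(default_factory=dict)
    models: dict[str, dict] = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_pipeline(config: PipelineConfig) -> DatasetManifest:
    """simulate (or ingest) -> score -> filter -> fit -> contrasts.

    Writes every stage table under ``config.out_dir`` and returns the
    manifest. Identical configs produce identical outputs (checksums
    included), which the manifest makes checkable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design()
    checksums: dict[str, str] = {}
    logger.info("pipeline start: mode=%s seed=%d iqr_scope=%s tie_rule=%s",
                config.mode, config.seed, config.iqr_scope, config.tie_rule)

    if config.mode == "agents":
        trials = simulate.simulate_cohort(design, seed=config.seed)
        dropped = trials.attrs.get("dropped_runs", [])
        checksums["trials.csv"] = write_table(trials, out / "trials.csv")
        scored = scoring.aggregate_trials(scoring.score_trials(trials))
        n_trial_rows = len(trials)
    elif config.mode == "lmm":
        scored, truth = simulate.simulate_lmm_dataset(
            simulate.EffectSpec(), design, seed=config.seed)
        (out / "ground_truth.json").write_text(
            json.dumps(truth, indent=2))
        dropped, n_trial_rows = [], 0
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    if design.n_scored_rows != len(scored):
        raise RuntimeError(
            f"stage count drift: expected {design.n_scored_rows} scored "
            f"rows, got {len(scored)}")

    if "rt" in scored.columns:
        scored, audit = scoring.filter_response_times(
            scored, scope=config.iqr_scope)
    else:
        audit = {"n_removed": 0, "n_retained": len(scored)}
    checksums["scored.csv"] = write_table(scored, out / "scored.csv")
    (out / "filter_audit.json").write_text(json.dumps(audit, indent=2))

    model_reports: dict[str, dict] = {}
    for name in config.models:
        retain = "rt_retained" if (name == "rt"
                                   and "rt_retained" in scored.columns) \
            else None
        fit = lmm.fit_lmm(scored, name, retain_col=retain)
        (out / f"fit_{name}.json").write_text(json.dumps(fit.to_dict(),
                                                         indent=2))
        report = {"converged": fit.converged, "n_obs": fit.n_obs,
                  "icc": fit.icc, "aic": fit.aic}
        if config.contrasts:
            cr = lmm.contrast_analysis(fit, lmm.table2_family())
            checksums[f"contrasts_{name}.csv"] = write_table(
                cr.table, out / f"contrasts_{name}.csv")
            report["contrast_family_size"] = cr.family_size
        model_reports[name] = report
        logger.info("model %s: n_obs=%d icc=%.3f converged=%s",
                    name, fit.n_obs, fit.icc, fit.converged)

    manifest = DatasetManifest(
        source="synthetic-" + config.mode, seed=config.seed,
        n_participants=design.n_participants,
        n_trial_rows=n_trial_rows, n_scored_rows=len(scored),
        n_rt_removed=int(audit["n_removed"]),
        n_rt_retained=int(audit["n_retained"]),
        dropped_runs=[list(d) for d in dropped], checksums=checksums,
        models=model_reports,
        options={"iqr_scope": config.iqr_scope,
                 "tie_rule": config.tie_rule, "seed": config.seed})
    manifest.to_json(out / "manifest.json")
    return manifest
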