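"""End-to-end orchestration: simulate/load → metrics → indices → stats.

``run_pipeline`` executes the whole analysis on either a simulated cohort or
loaded study CSVs and writes a reproducible report bundle::

    rats.csv, sessions.csv, irritability.csv   (simulate mode)
    truth.csv                                  (simulate mode)
    behavior_summary.csv
    index_table.csv
    stats_report.csv
    pca_result.csv
    manifest.json

Re-running with the same config and seed reproduces the bundle
byte-for-byte; the manifest records the seed, a config hash and per-stage
row counts (rats dropped by exclusion or missing indices included).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import StudyTables, read_study_tables, write_study_tables
from .indices import build_indices
from .metrics import summarize_behavior
from .stats import cohens_d, pca_indices, pearson_r, two_group_t
from .synthetic import GeneratorConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "compute_stats_report"]

logger = logging.getLogger(__name__)

_Z_COLS = ["escalation_z", "motivation_z", "compulsivity_z", "irritability_z"]


@dataclasses.dataclass
class PipelineConfig:
    """One reproducible run.

    Exactly one input mode: ``simulate`` (with a generator config) or
    ``load`` (with the three study CSV paths). Seeds are mandatory — there
    is no wall-clock fallback — so runs are reproducible by construction.
    """

    mode: str = "simulate"
    out_dir: str | Path = "ratpheno_out"
    seed: int = 0
    generator: GeneratorConfig | None = None
    rats_csv: str | Path | None = None
    sessions_csv: str | Path | None = None
    irritability_csv: str | Path | None = None
    motivation_session: int = 2
    pca_include_irritability: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"mode must be 'simulate' or 'load', got {self.mode!r}")
        if self.mode == "simulate":
            if self.generator is None:
                self.generator = GeneratorConfig()
            if any(p is not None for p in (self.rats_csv, self.sessions_csv,
                                           self.irritability_csv)):
                raise ValueError("CSV paths are only valid in load mode")
        else:
            paths = (self.rats_csv, self.sessions_csv, self.irritability_csv)
            if any(p is None for p in paths):
                raise ValueError("load mode requires rats, sessions and "
                                 "irritability CSV paths")
            if self.generator is not None:
                raise ValueError("generator config is only valid in simulate mode")
        if self.motivation_session not in (2, 3):
            raise ValueError("motivation_session must be 2 or 3")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        mapping = dict(mapping)
        gen = mapping.pop("generator", None)
        if gen is not None:
            gen = GeneratorConfig.from_mapping(gen)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown pipeline parameters: {sorted(unknown)}")
        return cls(generator=gen, **mapping)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["out_dir"] = str(out["out_dir"])
        for key in ("rats_csv", "sessions_csv", "irritability_csv"):
            if out[key] is not None:
                out[key] = str(out[key])
        return out


def compute_stats_report(tables: StudyTables, summaries: pd.DataFrame,
                         index_table: pd.DataFrame) -> pd.DataFrame:
    """The standard battery of effect sizes and correlations, one row per test.

    Sex effect sizes (F vs M) on each behavioral metric, the
    preshock→shock correlation and paired suppression test, and the
    cocaine-vs-naive withdrawal irritability contrast.
    """
    rats = tables.rats
    merged = summaries.merge(rats[["rat_id", "sex", "group"]], on="rat_id")
    results = []

    for metric in ("esc_mean_last3", "pr_rewards_post_lga", "shock_infusions",
                   "irritability_delta_total"):
        sub = merged.dropna(subset=[metric])
        f = sub.loc[sub["sex"] == "F", metric]
        m = sub.loc[sub["sex"] == "M", metric]
        if len(f) >= 2 and len(m) >= 2:
            results.append(cohens_d(f, m, name=f"sex_d_{metric}"))

    pair = summaries.dropna(subset=["preshock_infusions", "shock_infusions"])
    if len(pair) >= 3 and pair["preshock_infusions"].std() > 0:
        results.append(pearson_r(pair["preshock_infusions"],
                                 pair["shock_infusions"],
                                 name="preshock_shock_r"))
        results.append(two_group_t(pair["preshock_infusions"],
                                   pair["shock_infusions"], paired=True,
                                   name="preshock_vs_shock_t"))

    # withdrawal irritability: cocaine deltas vs naive deltas
    irr = tables.irritability.pivot_table(index="rat_id", columns="timepoint",
                                          values="total", aggfunc="first")
    if {"baseline", "withdrawal"} <= set(irr.columns):
        delta = (irr["withdrawal"] - irr["baseline"]).rename("delta").reset_index()
        delta = delta.merge(rats[["rat_id", "group"]], on="rat_id").dropna()
        coc = delta.loc[delta["group"] == "cocaine", "delta"]
        nai = delta.loc[delta["group"] == "naive", "delta"]
        if len(coc) >= 2 and len(nai) >= 2:
            results.append(cohens_d(coc, nai, name="irritability_d_vs_naive"))

    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def _pca_frame(index_table: pd.DataFrame, include_irritability: bool):
    cols = _Z_COLS if include_irritability else _Z_COLS[:3]
    frame = index_table[cols].dropna()
    return frame


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the in-memory bundle and writes CSVs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "ratpheno",
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        # out_dir is where the bundle lands, not what it contains; leaving it
        # out keeps identical (config, seed) runs byte-identical anywhere
        "config": {k: v for k, v in config.to_dict().items() if k != "out_dir"},
        "stages": [],
    }
    canon = json.dumps(manifest["config"], sort_keys=True).encode()
    manifest["config_sha256"] = hashlib.sha256(canon).hexdigest()

    def stage(name, **counts):
        logger.info("stage %s: %s", name, counts)
        manifest["stages"].append({"name": name, **counts})

    truth = None
    if config.mode == "simulate":
        tables, truth = simulate_cohort(config.generator, seed=config.seed)
        write_study_tables(tables, out_dir)
        truth.to_csv(out_dir / "truth.csv", index=False)
    else:
        tables = read_study_tables(config.rats_csv, config.sessions_csv,
                                   config.irritability_csv)
    n_excluded = int(tables.rats["excluded"].sum())
    stage("input", rats=len(tables.rats), sessions=len(tables.sessions),
          irritability=len(tables.irritability), excluded=n_excluded)

    summaries = summarize_behavior(tables,
                                   motivation_session=config.motivation_session)
    stage("metrics", rats=len(summaries))

    index_table = build_indices(summaries, tables.rats)
    n_ai = int(index_table["addiction_index"].notna().sum())
    stage("indices", rats=len(index_table), with_addiction_index=n_ai,
          dropped_missing_ai=len(index_table) - n_ai)

    stats_report = compute_stats_report(tables, summaries, index_table)
    pca_input = _pca_frame(index_table, config.pca_include_irritability)
    pca = pca_indices(pca_input)
    stage("stats", tests=len(stats_report), pca_rows=len(pca_input))

    summaries.to_csv(out_dir / "behavior_summary.csv", index=False)
    index_table.to_csv(out_dir / "index_table.csv", index=False)
    stats_report.to_csv(out_dir / "stats_report.csv", index=False)
    pca_out = pca.loadings.copy()
    pca_out.index.name = "variable"
    pca_out.loc["explained_fraction"] = pca.explained_fraction
    pca_out.to_csv(out_dir / "pca_result.csv")

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "tables": tables,
        "truth": truth,
        "behavior_summary": summaries,
        "index_table": index_table,
        "stats_report": stats_report,
        "pca": pca,
        "manifest": manifest,
    }
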