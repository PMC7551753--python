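"""End-to-end orchestration: simulate -> etl -> featurize -> experiments -> rank.

A run is driven by one ``RunConfig`` (typically loaded from YAML), writes
all outputs as delimited text plus a JSON manifest, and is bit-identical
under rerun with the same config: no wall-clock, hostnames, or unordered
dicts reach the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import DISEASE_CATALOG, PV_CATALOG, default_range_table
from .etl import build_episodes, clean_events, read_events, read_labels, read_stays, select_cohort
from .features import featurize_cohort
from .rank import (
    AUCMatrix,
    ImportanceRanking,
    compare_diseases,
    design_pv_sets,
    rank_importance,
    run_experiment_family,
)
from .synth import SyntheticConfig, generate_cohort, write_cohort

log = logging.getLogger("pvrank")

__all__ = ["RunConfig", "PipelineError", "load_config", "run_pipeline",
           "write_ranking", "read_ranking"]


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and a machine-readable reason."""

    def __init__(self, stage: str, reason: str):
        self.stage = stage
        self.reason = reason
        super().__init__(f"[{stage}] {reason}")


_SYNTH_KEYS = {
    "n_stays", "pv_catalog", "disease_catalog", "effects", "intercepts",
    "sampling_rate", "stay_duration_hours", "missing_pv_prob", "noise_sd",
}
_TOP_KEYS = {
    "synthetic", "events", "stays", "labels", "range_table", "min_age",
    "train_fraction", "split_seed", "l2_lambda", "tol", "top_k",
    "diseases", "out_dir", "seed",
}


@dataclass
class RunConfig:
    out_dir: str
    synthetic: dict | None = None
    events: str | None = None
    stays: str | None = None
    labels: str | None = None
    range_table: dict[str, tuple[float, float]] | None = None
    min_age: float = 16.0
    train_fraction: float = 0.7
    split_seed: int = 0
    l2_lambda: float = 1.0
    tol: float = 1e-5
    top_k: int = 3
    diseases: list[str] | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ValueError("config requires out_dir")
        if raw.get("synthetic") is not None:
            bad = set(raw["synthetic"]) - _SYNTH_KEYS
            if bad:
                raise ValueError(f"unknown synthetic config keys: {sorted(bad)}")
        elif not all(raw.get(k) for k in ("events", "stays", "labels")):
            raise ValueError("config needs either a synthetic section or events/stays/labels paths")
        return cls(**raw)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} is not a mapping")
    return RunConfig.from_dict(raw)


def build_synthetic_config(section: dict, seed: int) -> SyntheticConfig:
    """Turn the YAML ``synthetic`` section into a SyntheticConfig.

    ``effects`` is a nested mapping disease -> pv -> log-odds shift;
    ``intercepts`` a mapping disease -> alpha (default -1.0).
    """
    pvs = tuple(section.get("pv_catalog", PV_CATALOG))
    diseases = tuple(section.get("disease_catalog", DISEASE_CATALOG))
    B = np.zeros((len(diseases), len(pvs)))
    for d, row in (section.get("effects") or {}).items():
        for pv, val in row.items():
            B[diseases.index(d), pvs.index(pv)] = float(val)
    alpha = np.full(len(diseases), -1.0)
    for d, val in (section.get("intercepts") or {}).items():
        alpha[diseases.index(d)] = float(val)
    kwargs = {
        k: section[k]
        for k in ("n_stays", "sampling_rate", "stay_duration_hours", "missing_pv_prob", "noise_sd")
        if k in section
    }
    return SyntheticConfig(
        pv_catalog=pvs, disease_catalog=diseases, effect_matrix=B,
        intercepts=alpha, seed=seed, **kwargs,
    )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def write_ranking(ranking: ImportanceRanking, path: str | Path) -> None:
    pd.DataFrame(
        {
            "rank": np.arange(1, len(ranking.ranking) + 1),
            "disease": ranking.disease,
            "pv": [pv for pv, _ in ranking.ranking],
            "delta": [d for _, d in ranking.ranking],
        }
    ).to_csv(path, index=False)


def read_ranking(path: str | Path) -> ImportanceRanking:
    df = pd.read_csv(path).sort_values("rank")
    disease = str(df["disease"].iloc[0])
    return ImportanceRanking(
        disease=disease, ranking=[(str(r.pv), float(r.delta)) for r in df.itertuples()]
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write outputs and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"pvrank_version": __version__, "seed": config.seed,
                      "split_seed": config.split_seed, "stages": {}}

    # --- simulate or load -------------------------------------------------
    if config.synthetic is not None:
        synth_cfg = _stage("simulate")(build_synthetic_config)(config.synthetic, config.seed)
        cohort = _stage("simulate")(generate_cohort)(synth_cfg)
        raw_dir = out / "raw"
        _stage("simulate")(write_cohort)(cohort, raw_dir)
        events, stays, labels = cohort.events, cohort.stays, cohort.labels
        pv_catalog = tuple(synth_cfg.pv_catalog)
        manifest["stages"]["simulate"] = {
            "n_stays": len(stays), "n_events": len(events),
            "pv_catalog": list(pv_catalog),
        }
        log.info("simulate: %d stays, %d events", len(stays), len(events))
    else:
        events = _stage("etl")(read_events)(config.events)
        stays = _stage("etl")(read_stays)(config.stays)
        labels = _stage("etl")(read_labels)(config.labels)
        pv_catalog = tuple(pv for pv in PV_CATALOG if pv in set(events["variable"]))

    # --- etl --------------------------------------------------------------
    @_stage("etl")
    def do_etl():
        retained, sel_report = select_cohort(stays, min_age=config.min_age)
        range_table = config.range_table or default_range_table()
        cleaned, clean_report = clean_events(events, range_table)
        episodes, ep_tally = build_episodes(cleaned, stays, retained)
        return retained, sel_report, cleaned, clean_report, episodes, ep_tally

    retained, sel_report, cleaned, clean_report, episodes, ep_tally = do_etl()
    labels_kept = labels[labels["stay_id"].astype(str).isin(retained)]
    cleaned.to_csv(out / "events_clean.csv", index=False)
    manifest["stages"]["etl"] = {
        "stays_in": sel_report.n_input,
        "stays_retained": sel_report.n_retained,
        "stay_exclusions": sel_report.rejections,
        "events_in": clean_report.n_input,
        "events_retained": clean_report.n_retained,
        "event_rejections": clean_report.rejections,
        "events_unit_converted": clean_report.n_converted,
        "episode_tally": ep_tally,
        "n_episodes": len(episodes),
    }
    with open(out / "etl_report.json", "w") as fh:
        json.dump(manifest["stages"]["etl"], fh, indent=2, sort_keys=True)
    log.info("etl: %d/%d stays retained, %d/%d events retained",
             sel_report.n_retained, sel_report.n_input,
             clean_report.n_retained, clean_report.n_input)

    # --- featurize --------------------------------------------------------
    matrix = _stage("featurize")(featurize_cohort)(episodes, pv_catalog)
    manifest["stages"]["featurize"] = {
        "n_rows": matrix.values.shape[0],
        "n_columns": matrix.values.shape[1],
        "n_features_per_pv": matrix.values.shape[1] // len(pv_catalog),
    }

    # --- experiments ------------------------------------------------------
    @_stage("experiments")
    def do_experiments():
        family = design_pv_sets(pv_catalog)
        diseases = config.diseases or [c for c in labels_kept.columns if c != "stay_id"]
        auc = run_experiment_family(
            matrix, labels_kept, family, split_seed=config.split_seed,
            train_fraction=config.train_fraction, diseases=diseases,
            l2_lambda=config.l2_lambda, tol=config.tol,
        )
        return family, diseases, auc

    family, diseases, auc = do_experiments()
    auc.to_csv(out / "auc_matrix.csv")
    manifest["stages"]["experiments"] = {
        "n_experiments": len(family.ids),
        "n_diseases": len(diseases),
        "train_fraction": config.train_fraction,
        "l2_lambda": config.l2_lambda,
        "missing_cells": sorted(f"{s}:{d}" for (s, d) in auc.missing),
    }

    # --- rank + compare ---------------------------------------------------
    @_stage("rank")
    def do_rank():
        rankings: dict[str, ImportanceRanking] = {}
        skipped: dict[str, str] = {}
        for d in diseases:
            try:
                rankings[d] = rank_importance(auc, d)
            except ValueError as exc:
                skipped[d] = str(exc)
        return rankings, skipped

    rankings, skipped = do_rank()
    ranked = sorted(rankings)
    table = pd.DataFrame(
        {d: rankings[d].order for d in ranked},
        index=pd.Index(np.arange(1, family.n + 1), name="rank"),
    )
    table.to_csv(out / "rankings.csv")
    deltas = pd.DataFrame(
        {d: dict(rankings[d].ranking) for d in ranked}
    ).reindex(list(family.full_set))
    deltas.index.name = "pv"
    deltas.to_csv(out / "ranking_deltas.csv")

    jac = pd.DataFrame(1.0, index=ranked, columns=ranked)
    tau = pd.DataFrame(1.0, index=ranked, columns=ranked)
    for a, b in combinations(ranked, 2):
        rep = compare_diseases(rankings[a], rankings[b], k=config.top_k)
        jac.loc[a, b] = jac.loc[b, a] = rep.jaccard_top_k
        tau.loc[a, b] = tau.loc[b, a] = rep.kendall_tau
    jac.to_csv(out / "similarity_jaccard.csv", index_label="disease")
    tau.to_csv(out / "similarity_tau.csv", index_label="disease")
    manifest["stages"]["rank"] = {
        "n_ranked": len(ranked),
        "skipped": skipped,
        "top_k": config.top_k,
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
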