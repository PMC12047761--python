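"""Experiment runner: simulate participants, analyze, serialize, manifest.

(config, base seed) fully determines every output byte; participant p uses
seed base_seed + p.  The manifest snapshots the resolved config, the seeds
consumed and a checksum per output file, so a run can be reproduced and
verified from its artifacts alone.
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
from .analysis import (
    anova_load,
    bin_foraging,
    bin_speeded,
    bin_wm,
    compose_dacc_signal,
    fit_polynomial_aic,
    linear_trend_ttest,
    participant_slopes,
)
from .config import ExperimentConfig, config_to_dict
from .records import write_records
from .sessions import run_foraging_session, run_speeded_session, run_wm_session

__all__ = [
    "simulate_task",
    "speeded_statistics",
    "wm_statistics",
    "foraging_statistics",
    "run_experiment",
]

log = logging.getLogger(__name__)

_RUNNERS = {
    "speeded": (run_speeded_session, "speeded", "n_participants"),
    "wm": (run_wm_session, "wm_task", "n_participants"),
    "foraging": (run_foraging_session, "foraging", "n_participants"),
}


def simulate_task(
    task_id: str,
    cfg: ExperimentConfig,
    n_participants: int | None = None,
) -> pd.DataFrame:
    """Simulate all participants of one task; returns pooled trial records."""
    if task_id not in _RUNNERS:
        raise ValueError(f"unknown task id: {task_id!r}")
    runner, section, count_attr = _RUNNERS[task_id]
    if n_participants is None:
        n_participants = getattr(getattr(cfg, section), count_attr)
    frames = []
    for p in range(n_participants):
        seed = cfg.base_seed + p
        frames.append(runner(cfg, participant=p, seed=seed))
    return pd.concat(frames, ignore_index=True)


def speeded_statistics(records: pd.DataFrame, cfg: ExperimentConfig) -> dict:
    """Shape statistics of the simulated dACC signal in the speeded task."""
    table = bin_speeded(records)
    x = table.index.to_numpy(dtype=float)
    composed = compose_dacc_signal(table, "speeded").to_numpy()
    pair = fit_polynomial_aic(x, composed, degrees=(2, 4),
                              corrected=cfg.analysis.use_aicc)
    full = fit_polynomial_aic(x, composed, degrees=cfg.analysis.poly_degrees,
                              corrected=cfg.analysis.use_aicc)
    value_fit = fit_polynomial_aic(x, table["value"].to_numpy(), degrees=(2,))
    boost_fit = fit_polynomial_aic(x, table["boost"].to_numpy(), degrees=(2,))
    surprise_fit = fit_polynomial_aic(
        x, table["surprise"].to_numpy(), degrees=(2,))
    return {
        "quartic_akaike_weight": float(pair.loc[4, "akaike_weight"]),
        "quartic_leading_coeff": float(pair.loc[4, "leading_coeff"]),
        "quartic_quadratic_coeff": float(pair.loc[4, "quadratic_coeff"]),
        "full_akaike_weights": {int(d): float(w)
                                for d, w in full["akaike_weight"].items()},
        "value_quadratic_coeff": float(value_fit.loc[2, "leading_coeff"]),
        "boost_quadratic_coeff": float(boost_fit.loc[2, "leading_coeff"]),
        "surprise_quadratic_coeff": float(surprise_fit.loc[2, "leading_coeff"]),
        "accuracy": float(records.loc[~records.timed_out, "correct"].mean()),
        "timeout_rate": float(records["timed_out"].mean()),
        "n_participants": int(records["participant"].nunique()),
        "n_trials": int(len(records)),
    }


def wm_statistics(records: pd.DataFrame) -> dict:
    """Boost/accuracy/surprise/value statistics for the WM task."""
    per = bin_wm(records, per_participant=True)
    boost_t = linear_trend_ttest(participant_slopes(per, "load", "boost"))
    surprise_t = linear_trend_ttest(participant_slopes(per, "load", "surprise"))
    value_t = linear_trend_ttest(participant_slopes(per, "load", "value"))
    acc_table = per.pivot(index="participant", columns="load", values="accuracy")
    anova = anova_load(acc_table)
    return {
        "accuracy_pct": float(records["correct"].mean() * 100.0),
        "accuracy_by_load": {int(l): float(a)
                             for l, a in acc_table.mean().items()},
        "boost_trend": boost_t,
        "surprise_trend": surprise_t,
        "value_trend": value_t,
        "load_anova": anova,
        "n_participants": int(records["participant"].nunique()),
        "n_trials": int(len(records)),
    }


def foraging_statistics(records: pd.DataFrame, cfg: ExperimentConfig) -> dict:
    """Foraging-value and choice-difficulty coding of the boost signal."""
    out: dict = {
        "n_participants": int(records["participant"].nunique()),
        "n_trials": int(len(records)),
        "timeout_rate": float(records["timed_out"].mean()),
        "engage_rate": float((records["choice"] == 1).mean()),
    }
    fv = bin_foraging(records, by="forage_value",
                      n_bins=cfg.analysis.foraging_value_bins)
    for signal in ("boost", "composite"):
        pair = fit_polynomial_aic(
            fv["bin_center"].to_numpy(), fv[signal].to_numpy(), degrees=(1, 2),
            corrected=cfg.analysis.use_aicc)
        out[f"{signal}_quadratic_akaike_weight"] = float(
            pair.loc[2, "akaike_weight"])
        out[f"{signal}_quadratic_coeff"] = float(pair.loc[2, "leading_coeff"])
    diff = bin_foraging(records, by="choice_difficulty",
                        n_bins=cfg.analysis.foraging_difficulty_bins,
                        per_participant=True)
    for signal in ("boost", "composite"):
        trend = linear_trend_ttest(
            participant_slopes(diff, "bin_center", signal))
        out[f"{signal}_difficulty_trend"] = trend
    return out


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(
    task_id: str,
    cfg: ExperimentConfig,
    out_dir: str | Path,
    n_participants: int | None = None,
) -> dict:
    """Run one task end to end and write records, tables, stats, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = simulate_task(task_id, cfg, n_participants=n_participants)
    n_used = int(records["participant"].nunique())

    files: dict[str, Path] = {}
    rec_path = out / f"{task_id}_records.csv"
    write_records(records, rec_path)
    files["records"] = rec_path

    if task_id == "speeded":
        stats = speeded_statistics(records, cfg)
        table = bin_speeded(records).reset_index()
    elif task_id == "wm":
        stats = wm_statistics(records)
        table = bin_wm(records).reset_index()
    else:
        stats = foraging_statistics(records, cfg)
        table = bin_foraging(records, by="forage_value",
                             n_bins=cfg.analysis.foraging_value_bins)
        table = table.drop(columns="bin", errors="ignore")

    table_path = out / f"{task_id}_regressors.csv"
    table.to_csv(table_path, index=False)
    files["regressors"] = table_path

    stats_path = out / f"{task_id}_statistics.json"
    stats_path.write_text(json.dumps(stats, indent=2, sort_keys=True))
    files["statistics"] = stats_path

    manifest = {
        "task": task_id,
        "version": __version__,
        "base_seed": cfg.base_seed,
        "n_participants": n_used,
        "seeds": [cfg.base_seed + p for p in range(n_used)],
        "config": config_to_dict(cfg),
        "files": {k: {"path": p.name, "sha256": _checksum(p)}
                  for k, p in files.items()},
    }
    (out / f"{task_id}_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    log.info("wrote %s outputs to %s", task_id, out)
    return stats
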