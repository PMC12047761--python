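"""Trial-record serialization: CSV with a documented, stable column order.

One file per (task, participant) or one pooled file per task; numeric
columns round-trip at full precision (Python float repr).  Lines starting
with '#' document column semantics and units and are ignored on read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["write_records", "read_records", "COLUMN_DOC"]

COLUMN_DOC = {
    "task": "task identifier: speeded | wm | foraging",
    "participant": "simulated participant index (0-based)",
    "seed": "RNG seed for this participant (base_seed + participant)",
    "trial": "trial index within the session (0-based)",
    "left_reward": "reward of the left option (reward units)",
    "right_reward": "reward of the right option (reward units)",
    "value_difference": "left - right reward (reward units)",
    "trial_total_reward": "left + right reward (reward units)",
    "load": "working-memory load (words)",
    "is_match": "probe matched a memorized word",
    "decision": "model's match response",
    "context": "foraging context (patch) index",
    "bandit": "proposed bandit index within the context",
    "engage_value": "design value of engaging the proposed bandit (reward units)",
    "forage_value": "design value of foraging: context mean excluding the "
                    "proposed bandit, minus forage cost (reward units)",
    "choice_difficulty": "-|engage_value - forage_value| (reward units)",
    "boost": "selected boost level (control intensity, dimensionless)",
    "lc": "locus-coeruleus output (dimensionless gain)",
    "dv": "learned option-value difference driving the drift (reward units)",
    "evidence": "probe-unit activation at end of delay (activation units)",
    "value_regressor": "expected-value signal at cue onset (reward units)",
    "surprise_regressor": "unsigned surprise regressor (reward units)",
    "outcome_surprise": "|outcome - expectation| for the chosen option",
    "choice": "+1 upper boundary (left/engage), -1 lower, 0 none",
    "rt_cycles": "reaction time in integration cycles",
    "timed_out": "deadline reached without a decision",
    "n_forages": "consecutive forage choices in the trial",
    "correct": "response was correct / option with higher reward chosen",
    "reward": "delivered reward after any devaluation (reward units)",
    "net_value": "reward - forage costs - boost cost (reward units)",
}


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write a trial-record table with a commented column-glossary header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for col in records.columns:
            doc = COLUMN_DOC.get(col, "")
            fh.write(f"# {col}: {doc}\n")
        records.to_csv(fh, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a trial-record table written by :func:`write_records`."""
    try:
        return pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed record file {path}: {exc}") from exc
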