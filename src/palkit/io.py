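"""File formats binding campaigns to disk: design CSV, labels CSV, history
CSV and campaign-state JSON.  The CSV dialect is pinned (comma, UTF-8, "."
decimals, LF endings) so outputs are diffable and campaigns resumable
bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .polymers import DesignSpace, PolymerSequence
from .surrogate import LabelTable

STATE_SCHEMA_VERSION = 1

__all__ = [
    "write_design_csv",
    "read_design_csv",
    "write_labels_csv",
    "read_labels_csv",
    "write_history_csv",
    "save_state",
    "load_state",
]


def _write_df(df: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False, lineterminator="\n")


def write_design_csv(design: DesignSpace, path) -> None:
    """Columns: id, sequence (bracket notation), then one column per feature."""
    df = pd.DataFrame(design.features, columns=design.feature_names)
    df.insert(0, "sequence", design.ids)
    df.insert(0, "id", design.ids)
    _write_df(df, path)


def read_design_csv(path) -> DesignSpace:
    df = pd.read_csv(path)
    if "sequence" not in df.columns:
        raise ValueError(f"{path}: design CSV needs a 'sequence' column")
    sequences = [PolymerSequence.from_string(s) for s in df["sequence"]]
    feature_names = [c for c in df.columns if c not in ("id", "sequence")]
    features = df[feature_names].to_numpy(dtype=float)
    return DesignSpace(sequences, features, feature_names)


def write_labels_csv(labels: LabelTable, path, ids=None) -> None:
    """Columns: candidate_id, objective, value, noise_sd (empty = absent)."""
    rows = []
    for r in labels.rows:
        rows.append(
            {
                "candidate_id": ids[r.candidate] if ids is not None else r.candidate,
                "candidate_index": r.candidate,
                "objective": r.objective,
                "value": r.value,
                "noise_sd": "" if r.noise_sd is None else r.noise_sd,
            }
        )
    _write_df(pd.DataFrame(rows), path)


def read_labels_csv(path, n_objectives: int) -> LabelTable:
    df = pd.read_csv(path)
    table = LabelTable(n_objectives)
    for _, row in df.iterrows():
        noise = row.get("noise_sd")
        noise = None if noise is None or (isinstance(noise, float) and np.isnan(noise)) else float(noise)
        table.add(int(row["candidate_index"]), int(row["objective"]), float(row["value"]), noise)
    return table


def write_history_csv(history: pd.DataFrame, path) -> None:
    _write_df(history, path)


def save_state(result, config_dict: dict, seed: int, path) -> None:
    """Persist a campaign's classification, rectangles and config as JSON.

    Together with the labels CSV this replays/resumes bit-exactly, because
    every random draw in a campaign is keyed off (seed, purpose, iteration)
    rather than a consumed global stream.
    """
    lower, upper = result.rectangles
    state = {
        "schema_version": STATE_SCHEMA_VERSION,
        "seed": int(seed),
        "config": config_dict,
        "iteration": int(result.history["iteration"].max()) if len(result.history) else 0,
        "pareto": result.state.pareto.tolist(),
        "discarded": result.state.discarded.tolist(),
        "unclassified": result.state.unclassified.tolist(),
        "sampled": result.state.sampled_indices.tolist(),
        "rectangles": {
            "lower": np.asarray(lower).tolist(),
            "upper": np.asarray(upper).tolist(),
        },
    }
    Path(path).write_text(json.dumps(state, indent=1), encoding="utf-8")


def load_state(path) -> dict:
    try:
        state = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted state file {path}: {exc}") from exc
    missing = {"schema_version", "seed", "config", "pareto", "discarded"} - set(state)
    if missing:
        raise ValueError(f"state file {path} missing keys: {sorted(missing)}")
    if state["schema_version"] != STATE_SCHEMA_VERSION:
        raise ValueError(
            f"state schema {state['schema_version']} unsupported "
            f"(expected {STATE_SCHEMA_VERSION})"
        )
    return state
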