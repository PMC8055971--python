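"""Sequence featurization, standardization and feature-vector backtracing.

A polymer sequence is described by simple, chemistry-motivated descriptors
computed from the monomer string alone: degree of polymerization, relative
sequence entropy, one-hot encoded end groups (head and tail bead), per-type
bead counts, a summed bead-solvent interaction parameter, and run-length
("cluster") statistics of the maximal same-type blocks.

A reduced *invertible* subset of these descriptors (counts, end groups,
per-type run counts — relative entropy excluded) can be decoded back into a
concrete monomer sequence by randomized backtracing; that decoder is what
makes GA-proposed feature vectors actionable.
"""

from __future__ import annotations

import math
from itertools import groupby

import numpy as np

from .polymers import MONOMER_TYPES, PolymerSequence

__all__ = [
    "DEFAULT_INTERACTION_TABLE",
    "FEATURE_NAMES",
    "INVERTIBLE_FEATURE_NAMES",
    "relative_sequence_entropy",
    "cluster_statistics",
    "featurize",
    "featurize_all",
    "standardize_features",
    "apply_standardization",
    "invert_standardization",
    "invertible_components",
    "backtrace_sequence",
]

# Placeholder bead–solvent interaction parameters (arbitrary units).  The
# real coarse-grained force-field values are simulation-engine specific; all
# code paths accept a custom table, these defaults merely order the beads by
# solvent quality (W good solvent < theta < R bad solvent).
DEFAULT_INTERACTION_TABLE: dict[str, float] = {"W": 0.5, "R": 2.0, "Ta": 1.0, "Tr": 1.2}

_PER_TYPE_CLUSTER = ("n_runs", "mean_run", "max_run")

FEATURE_NAMES: list[str] = (
    ["degree_of_polymerization", "rel_entropy"]
    + [f"head_{t}" for t in MONOMER_TYPES]
    + [f"tail_{t}" for t in MONOMER_TYPES]
    + [f"count_{t}" for t in MONOMER_TYPES]
    + ["sum_interaction"]
    + [f"{stat}_{t}" for t in MONOMER_TYPES for stat in _PER_TYPE_CLUSTER]
    + ["n_runs_total", "mean_run_total", "max_run_total"]
)

# The reduced schema the GA optimizes over and the backtracer can decode.
INVERTIBLE_FEATURE_NAMES: list[str] = (
    [f"count_{t}" for t in MONOMER_TYPES]
    + [f"head_{t}" for t in MONOMER_TYPES]
    + [f"tail_{t}" for t in MONOMER_TYPES]
    + [f"n_runs_{t}" for t in MONOMER_TYPES]
)


def relative_sequence_entropy(sequence: PolymerSequence) -> float:
    """Shannon entropy of the bead-type frequencies, normalized by log 4.

    The normalization always uses the full four-letter alphabet so values are
    comparable across polymers: 0 for a homopolymer, 1 iff all four types are
    equifrequent.
    """
    n = len(sequence)
    h = 0.0
    for t in MONOMER_TYPES:
        p = sequence.beads.count(t) / n
        if p > 0:
            h -= p * math.log(p)
    return h / math.log(len(MONOMER_TYPES))


def _runs(sequence: PolymerSequence) -> list[tuple[str, int]]:
    return [(t, len(list(g))) for t, g in groupby(sequence.beads)]


def cluster_statistics(sequence: PolymerSequence) -> dict[str, float]:
    """Run-length descriptors of the maximal same-type blocks.

    Returns per-type and total ``n_runs`` / ``mean_run`` / ``max_run``; types
    absent from the sequence get zeros.  A homopolymer is one run of length N.
    """
    runs = _runs(sequence)
    stats: dict[str, float] = {}
    for t in MONOMER_TYPES:
        lengths = [ln for sym, ln in runs if sym == t]
        stats[f"n_runs_{t}"] = float(len(lengths))
        stats[f"mean_run_{t}"] = float(np.mean(lengths)) if lengths else 0.0
        stats[f"max_run_{t}"] = float(max(lengths)) if lengths else 0.0
    all_lengths = [ln for _, ln in runs]
    stats["n_runs_total"] = float(len(all_lengths))
    stats["mean_run_total"] = float(np.mean(all_lengths))
    stats["max_run_total"] = float(max(all_lengths))
    return stats


def featurize(
    sequence: PolymerSequence,
    interaction_table: dict[str, float] | None = None,
) -> np.ndarray:
    """Fixed-order descriptor vector for one sequence (see FEATURE_NAMES)."""
    table = DEFAULT_INTERACTION_TABLE if interaction_table is None else interaction_table
    missing = [t for t in MONOMER_TYPES if t not in table]
    if missing:
        raise ValueError(f"interaction table missing monomer types: {missing}")
    beads = sequence.beads
    counts = {t: beads.count(t) for t in MONOMER_TYPES}
    clusters = cluster_statistics(sequence)
    values = [float(len(beads)), relative_sequence_entropy(sequence)]
    values += [1.0 if beads[0] == t else 0.0 for t in MONOMER_TYPES]
    values += [1.0 if beads[-1] == t else 0.0 for t in MONOMER_TYPES]
    values += [float(counts[t]) for t in MONOMER_TYPES]
    values.append(float(sum(table[b] for b in beads)))
    values += [clusters[f"{stat}_{t}"] for t in MONOMER_TYPES for stat in _PER_TYPE_CLUSTER]
    values += [clusters["n_runs_total"], clusters["mean_run_total"], clusters["max_run_total"]]
    return np.asarray(values, dtype=float)


def featurize_all(sequences, interaction_table=None):
    """Feature matrix (n, n_features) and the shared name list."""
    mat = np.vstack([featurize(s, interaction_table) for s in sequences])
    return mat, list(FEATURE_NAMES)


def standardize_features(features: np.ndarray, train_rows):
    """Z-score all rows using training-set (population) mean and SD.

    Zero-variance training columns standardize to 0 rather than NaN so that
    constant descriptors cannot poison a kernel.  Returns the transformed
    matrix plus the (mean, sd) statistics for later reuse; the stored sd of a
    constant column is 1 by the same convention.
    """
    x = np.asarray(features, dtype=float)
    train_rows = np.asarray(list(train_rows), dtype=int)
    if train_rows.size == 0:
        raise ValueError("training row set must be non-empty")
    mean = x[train_rows].mean(axis=0)
    sd = x[train_rows].std(axis=0)  # population SD
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mean) / sd, mean, sd


def apply_standardization(features, mean, sd):
    return (np.asarray(features, dtype=float) - mean) / sd


def invert_standardization(standardized, mean, sd):
    return np.asarray(standardized, dtype=float) * sd + mean


def invertible_components(sequence: PolymerSequence) -> np.ndarray:
    """The reduced feature vector (INVERTIBLE_FEATURE_NAMES order)."""
    beads = sequence.beads
    clusters = cluster_statistics(sequence)
    values = [float(beads.count(t)) for t in MONOMER_TYPES]
    values += [1.0 if beads[0] == t else 0.0 for t in MONOMER_TYPES]
    values += [1.0 if beads[-1] == t else 0.0 for t in MONOMER_TYPES]
    values += [clusters[f"n_runs_{t}"] for t in MONOMER_TYPES]
    return np.asarray(values, dtype=float)


def _decode_onehot(vec: np.ndarray) -> str | None:
    """Monomer symbol from a one-hot block, or None if not a valid one-hot."""
    if not np.all(np.isin(vec, (0.0, 1.0))) or vec.sum() != 1.0:
        return None
    return MONOMER_TYPES[int(np.argmax(vec))]


def backtrace_sequence(
    feature_vector,
    max_tries: int = 200,
    seed: int = 0,
) -> PolymerSequence | None:
    """Decode a reduced feature vector into a concrete monomer sequence.

    ``feature_vector`` follows INVERTIBLE_FEATURE_NAMES: per-type counts,
    head/tail one-hots, per-type run counts.  Randomized backtracing splits
    each type's count into its requested number of runs and searches for a
    block arrangement with the requested end groups and no two adjacent
    same-type blocks (which would merge and change the run counts).

    Returns ``None`` (INVALID) when the vector is structurally impossible
    (non-integer/negative counts, end groups contradicting counts, infeasible
    run counts) or when no valid arrangement is found within ``max_tries``.
    INVALID is a value, not an error: the GA consumes it as a penalty.
    """
    vec = np.asarray(feature_vector, dtype=float)
    if vec.shape != (len(INVERTIBLE_FEATURE_NAMES),):
        raise ValueError(
            f"expected reduced feature vector of length {len(INVERTIBLE_FEATURE_NAMES)}"
        )
    counts_v, head_v, tail_v, runs_v = vec[:4], vec[4:8], vec[8:12], vec[12:16]
    if np.any(counts_v < 0) or np.any(counts_v != np.round(counts_v)):
        return None
    if np.any(runs_v < 0) or np.any(runs_v != np.round(runs_v)):
        return None
    counts = {t: int(c) for t, c in zip(MONOMER_TYPES, counts_v)}
    runs = {t: int(r) for t, r in zip(MONOMER_TYPES, runs_v)}
    total = sum(counts.values())
    if total < 1:
        return None
    head = _decode_onehot(head_v)
    tail = _decode_onehot(tail_v)
    if head is None or tail is None:
        return None
    if counts[head] == 0 or counts[tail] == 0:
        return None
    for t in MONOMER_TYPES:
        if counts[t] == 0 and runs[t] != 0:
            return None
        if counts[t] > 0 and not 1 <= runs[t] <= counts[t]:
            return None
    total_runs = sum(runs.values())
    # no two same-type blocks may touch: the most numerous type's runs must
    # fit into the alternation, i.e. max_t runs_t <= total_runs - max_t + 1
    if max(runs.values()) > total_runs - max(runs.values()) + 1:
        return None
    if total_runs == 1 and head != tail:
        return None

    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        pattern = _sample_block_pattern(runs, head, tail, rng)
        if pattern is None:
            continue
        parts: dict[str, list[int]] = {}
        for t in MONOMER_TYPES:
            if counts[t] == 0:
                continue
            # random composition of counts[t] into runs[t] positive parts
            if runs[t] == 1:
                lengths = [counts[t]]
            else:
                cuts = np.sort(
                    rng.choice(np.arange(1, counts[t]), size=runs[t] - 1, replace=False)
                )
                bounds = np.concatenate(([0], cuts, [counts[t]]))
                lengths = list(np.diff(bounds).astype(int))
                rng.shuffle(lengths)
            parts[t] = lengths
        part_iters = {t: iter(v) for t, v in parts.items()}
        beads = [t for t in pattern for _ in range(int(next(part_iters[t])))]
        return PolymerSequence(tuple(beads))
    return None


def _sample_block_pattern(runs: dict, head: str, tail: str, rng) -> list[str] | None:
    """Random block-type pattern with the exact per-type run counts, no two
    adjacent blocks of one type, fixed first and last type.  Guided greedy
    sampling with feasibility pruning (the most numerous remaining type must
    always fit into the remaining alternation slots); returns None when this
    attempt dead-ends."""
    remaining = dict(runs)
    if remaining.get(head, 0) < 1:
        return None
    total = sum(remaining.values())
    pattern = [head]
    remaining[head] -= 1
    for pos in range(1, total):
        slots_left = total - pos
        if slots_left == 1:
            if remaining.get(tail, 0) == 1 and tail != pattern[-1]:
                pattern.append(tail)
                remaining[tail] -= 1
                return pattern
            return None
        choices = []
        for t, r in remaining.items():
            if r == 0 or t == pattern[-1]:
                continue
            rem = dict(remaining)
            rem[t] -= 1
            mx = max(rem.values())
            # pruning: the dominant type must fit the remaining slots; the
            # tail type must survive until the end
            if mx > (slots_left - 1 + 1) // 2 + (1 if rem.get(tail, 0) == mx else 0):
                continue
            if rem.get(tail, 0) == 0:
                continue
            choices.append(t)
        if not choices:
            return None
        pattern.append(choices[int(rng.integers(len(choices)))])
        remaining[pattern[-1]] -= 1
    return pattern if pattern[-1] == tail else None
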