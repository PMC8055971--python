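"""Dominance relations, Pareto-set extraction and hypervolume indicators.

All functions assume a *maximization* orientation: larger is better in every
objective.  Minimization objectives must be negated before calling in here
(the campaign loop in :mod:`palkit.pal` does this at ingestion).

The hypervolume indicator is the Lebesgue measure of the region of objective
space that is dominated by a front and dominates a reference point.  An exact
dimension-sweep algorithm is provided for up to three objectives (the
dispersant problem has three); higher dimensions fall back to the Monte-Carlo
estimator with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "dominates",
    "epsilon_dominates",
    "pareto_mask",
    "nadir_point",
    "hypervolume",
    "hypervolume_mc",
    "hypervolume_error",
    "HVErrorTracker",
]


def dominates(a, b) -> bool:
    """True iff ``a`` Pareto-dominates ``b``: a >= b everywhere, > somewhere."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"objective vectors differ in length: {a.shape} vs {b.shape}")
    return bool(np.all(a >= b) and np.any(a > b))


def epsilon_dominates(a, b, epsilon, scale) -> bool:
    """Mean-scaled epsilon-dominance: a_i + eps_i * scale_i >= b_i for all i.

    ``scale`` carries the |mu| values used for the relative tolerance; with
    ``epsilon = 0`` this reduces to weak dominance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"objective vectors differ in length: {a.shape} vs {b.shape}")
    eps = np.broadcast_to(np.asarray(epsilon, dtype=float), a.shape)
    sc = np.broadcast_to(np.asarray(scale, dtype=float), a.shape)
    return bool(np.all(a + eps * np.abs(sc) >= b))


def pareto_mask(points) -> np.ndarray:
    """Boolean mask of the non-dominated points of an (n, d) objective matrix.

    Points with identical objective vectors are all kept (discarding either
    duplicate would be arbitrary).  Vectorized O(n^2); the tests check it
    against a plain double-loop oracle.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("objective matrix must be finite")
    n = pts.shape[0]
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        if not mask[i]:
            continue
        # strictly dominated by any other point?
        ge = np.all(pts >= pts[i], axis=1)
        gt = np.any(pts > pts[i], axis=1)
        dominated_by = ge & gt
        dominated_by[i] = False
        if dominated_by.any():
            mask[i] = False
    return mask


def nadir_point(points) -> np.ndarray:
    """Per-objective minimum over the Pareto-optimal subset (maximization)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    front = pts[pareto_mask(pts)]
    return front.min(axis=0)


def _hv2(front: np.ndarray, ref: np.ndarray) -> float:
    """Exact 2-D hypervolume of a (possibly redundant) point set."""
    keep = np.all(front >= ref, axis=1)
    pts = front[keep]
    if pts.shape[0] == 0:
        return 0.0
    pts = pts[pareto_mask(pts)]
    order = np.argsort(-pts[:, 0])
    pts = pts[order]
    hv = 0.0
    y_prev = ref[1]
    for x, y in pts:
        if y > y_prev:
            hv += (x - ref[0]) * (y - y_prev)
            y_prev = y
    return hv


def _hv3(front: np.ndarray, ref: np.ndarray) -> float:
    """Exact 3-D hypervolume by sweeping slabs along the last objective."""
    keep = np.all(front >= ref, axis=1)
    pts = front[keep]
    if pts.shape[0] == 0:
        return 0.0
    pts = pts[pareto_mask(pts)]
    order = np.argsort(-pts[:, 2])
    pts = pts[order]
    zs = pts[:, 2]
    hv = 0.0
    for k in range(len(pts)):
        z_hi = zs[k]
        z_lo = zs[k + 1] if k + 1 < len(pts) else ref[2]
        if z_hi <= z_lo:  # duplicate z level: slab handled at first occurrence
            continue
        hv += (z_hi - z_lo) * _hv2(pts[: k + 1, :2], ref[:2])
    return hv


def hypervolume(front, ref) -> float:
    """Exact hypervolume of ``front`` w.r.t. reference point ``ref`` (d <= 3).

    Every front point must weakly dominate the reference point; a point that
    does not is reported by index.  Dominated front members contribute
    nothing, so passing a full objective matrix is safe.
    """
    pts = np.atleast_2d(np.asarray(front, dtype=float))
    ref = np.asarray(ref, dtype=float)
    if pts.shape[0] == 0:
        return 0.0
    if pts.shape[1] != ref.shape[0]:
        raise ValueError("front and reference point dimensions differ")
    bad = np.where(np.any(pts < ref, axis=1))[0]
    if bad.size:
        raise ValueError(
            f"front point {bad[0]} ({pts[bad[0]]}) does not dominate the "
            f"reference point {ref}"
        )
    d = pts.shape[1]
    if d == 1:
        return float(pts[:, 0].max() - ref[0])
    if d == 2:
        return float(_hv2(pts, ref))
    if d == 3:
        return float(_hv3(pts, ref))
    warnings.warn(
        "exact hypervolume implemented for d <= 3; using Monte-Carlo estimate",
        RuntimeWarning,
        stacklevel=2,
    )
    est, _ = hypervolume_mc(pts, ref, n_samples=200_000, seed=0)
    return est


def hypervolume_mc(front, ref, n_samples: int = 100_000, seed: int = 0):
    """Monte-Carlo hypervolume estimate and its standard error.

    Samples uniformly in the bounding box [ref, coordinate-wise max] and
    counts the fraction dominated by at least one front point.  Serves as the
    independent oracle for the exact algorithm.
    """
    pts = np.atleast_2d(np.asarray(front, dtype=float))
    ref = np.asarray(ref, dtype=float)
    if pts.shape[0] == 0:
        return 0.0, 0.0
    hi = pts.max(axis=0)
    vol = float(np.prod(hi - ref))
    if vol <= 0:
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    samples = rng.uniform(ref, hi, size=(int(n_samples), len(ref)))
    # sample s is dominated iff some p >= s in every coordinate
    dominated = np.zeros(len(samples), dtype=bool)
    for p in pts:
        dominated |= np.all(samples <= p, axis=1)
    frac = dominated.mean()
    se = vol * float(np.sqrt(frac * (1.0 - frac) / len(samples)))
    return vol * float(frac), se


def hypervolume_error(current_front, full_space, ref=None) -> float:
    """Relative hypervolume shortfall of a front vs. the true front.

    ``(HV_max - HV_current) / HV_max`` where ``HV_max`` uses the Pareto
    subset of ``full_space`` and ``ref`` defaults to the nadir point of that
    subset.  Current-front points that do not dominate the reference point
    contribute nothing (they are clipped out, not an error: early campaign
    fronts are often partly below the nadir).
    """
    full = np.atleast_2d(np.asarray(full_space, dtype=float))
    cur = np.atleast_2d(np.asarray(current_front, dtype=float))
    if ref is None:
        ref = nadir_point(full)
    ref = np.asarray(ref, dtype=float)
    true_front = full[pareto_mask(full)]
    hv_max = hypervolume(true_front, ref)
    if hv_max <= 0:
        raise ValueError("maximum hypervolume is zero; reference point degenerate")
    if cur.size == 0:
        return 1.0
    keep = np.all(cur >= ref, axis=1)
    hv_cur = hypervolume(cur[keep], ref) if keep.any() else 0.0
    return float((hv_max - hv_cur) / hv_max)


class HVErrorTracker:
    """Hypervolume error against a fixed design space, with the reference
    point and maximum hypervolume computed once.  Use for per-iteration
    error curves where calling :func:`hypervolume_error` repeatedly would
    redo the full-space Pareto extraction every time."""

    def __init__(self, full_space, ref=None):
        full = np.atleast_2d(np.asarray(full_space, dtype=float))
        self.ref = np.asarray(ref, dtype=float) if ref is not None else nadir_point(full)
        true_front = full[pareto_mask(full)]
        self.hv_max = hypervolume(true_front, self.ref)
        if self.hv_max <= 0:
            raise ValueError("maximum hypervolume is zero; reference point degenerate")

    def error(self, points) -> float:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.size == 0:
            return 1.0
        keep = np.all(pts >= self.ref, axis=1)
        hv = hypervolume(pts[keep], self.ref) if keep.any() else 0.0
        return float((self.hv_max - hv) / self.hv_max)
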