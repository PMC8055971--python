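"""The modified ε-PAL loop: confidence hyperrectangles, ε-accurate
classification, coefficient-of-variation acquisition, and the campaign driver.

The algorithm maintains, for every candidate of a finite design space, an
axis-aligned uncertainty box ``[μ - √β_t σ, μ + √β_t σ]`` per objective
(measurement noise replaces the posterior SD for sampled values).  Boxes are
intersected with their predecessors so they only shrink.  Candidates are
discarded once some other candidate's pessimistic corner ε-dominates their
optimistic corner, and promoted to the ε-accurate Pareto set once no
remaining candidate could ε-dominate them even optimistically.  The next
sample is the candidate near the predicted front with the largest
dimensionless box size (coefficient of variation), which makes the tolerance
relative: ε_i is interpreted against |μ_i|, not against a known objective
range.

All dominance logic runs in a maximization orientation; minimization
objectives are negated at ingestion and re-negated on output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .pareto import HVErrorTracker
from .surrogate import ICMSurrogate, LabelTable

logger = logging.getLogger(__name__)

__all__ = [
    "EpalConfig",
    "ClassificationState",
    "CampaignResult",
    "select_initial_design",
    "beta",
    "build_rectangles",
    "epsilon_discard",
    "epsilon_pareto_promote",
    "acquisition",
    "run_campaign",
]

_CV_TOL = 1e-8  # |μ| clamp for coefficient-of-variation denominators

UNCLASSIFIED, PARETO, DISCARDED = 0, 1, 2


@dataclass
class EpalConfig:
    """Campaign hyperparameters.

    epsilon
        Per-objective relative tolerances ε_i (scalar broadcasts).  The
        effective slack on objective i of candidate x is ε_i·|μ_i(x)|.
    delta
        Confidence parameter of the β schedule, in (0, 1).
    beta_scale
        Multiplier on the theoretical β_t; 1/9 is the customary practical
        deflation of the (conservative) union-bound schedule.
    objective_directions
        Per-objective "maximize"/"minimize"; internally everything is
        maximized.
    exclude_high_variance
        When set, candidates whose dimensionless box size exceeds the
        ``high_variance_quantile`` of the unsampled population are skipped
        by the classification stage that iteration (they remain eligible as
        dominators and for acquisition).
    """

    epsilon: float | list | np.ndarray = 0.05
    delta: float = 0.05
    beta_scale: float = 1.0 / 9.0
    init_size: int = 10
    max_iterations: int = 500
    objective_directions: list[str] | None = None
    batch_size: int = 1
    exclude_high_variance: bool = False
    high_variance_quantile: float = 0.95
    refit_interval: int = 10
    n_restarts: int = 5
    rank: int = 1
    max_opt_iter: int = 100

    def __post_init__(self):
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")
        if np.any(np.asarray(self.epsilon, dtype=float) < 0):
            raise ValueError("epsilon must be non-negative")
        if self.beta_scale <= 0:
            raise ValueError("beta_scale must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def epsilon_vector(self, n_objectives: int) -> np.ndarray:
        eps = np.asarray(self.epsilon, dtype=float)
        if eps.ndim == 0:
            return np.full(n_objectives, float(eps))
        if eps.shape != (n_objectives,):
            raise ValueError("epsilon length does not match the number of objectives")
        return eps

    def direction_signs(self, n_objectives: int) -> np.ndarray:
        if self.objective_directions is None:
            return np.ones(n_objectives)
        if len(self.objective_directions) != n_objectives:
            raise ValueError("objective_directions length mismatch")
        signs = []
        for d in self.objective_directions:
            if d not in ("maximize", "minimize"):
                raise ValueError(f"unknown direction {d!r}")
            signs.append(1.0 if d == "maximize" else -1.0)
        return np.asarray(signs)


@dataclass
class ClassificationState:
    """Disjoint partition of candidate indices plus the sampled set."""

    status: np.ndarray  # int array: UNCLASSIFIED / PARETO / DISCARDED
    sampled: np.ndarray  # boolean

    @classmethod
    def empty(cls, n: int) -> "ClassificationState":
        return cls(np.full(n, UNCLASSIFIED), np.zeros(n, dtype=bool))

    @property
    def pareto(self) -> np.ndarray:
        return np.flatnonzero(self.status == PARETO)

    @property
    def discarded(self) -> np.ndarray:
        return np.flatnonzero(self.status == DISCARDED)

    @property
    def unclassified(self) -> np.ndarray:
        return np.flatnonzero(self.status == UNCLASSIFIED)

    @property
    def sampled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.sampled)


@dataclass
class CampaignResult:
    state: ClassificationState
    history: pd.DataFrame
    model: ICMSurrogate | None
    labels: LabelTable
    rectangles: tuple[np.ndarray, np.ndarray]  # (lower, upper), maximization scale
    means: np.ndarray  # the μ used for scaling in the final iteration
    config: EpalConfig = field(repr=False, default=None)


def select_initial_design(features: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Greedy farthest-point (maximin) subset of the candidate features.

    The first point is drawn with ``seed``; each subsequent point maximizes
    its minimum Euclidean distance to the chosen set, ties broken by lowest
    index.  Deterministic given the seed.
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} candidates")
    rng = np.random.default_rng(seed)
    first = int(rng.integers(n))
    chosen = [first]
    mindist = cdist(X, X[[first]]).ravel()
    while len(chosen) < k:
        nxt = int(np.argmax(mindist))  # argmax takes the lowest index on ties
        chosen.append(nxt)
        mindist = np.minimum(mindist, cdist(X, X[[nxt]]).ravel())
    return np.asarray(chosen, dtype=int)


def beta(iteration: int, n_candidates: int, n_objectives: int, config: EpalConfig) -> float:
    """Confidence scaling β_t = scale · 2 log(n_obj · |E| · π² t² / (6 δ))."""
    if iteration < 1:
        raise ValueError("iteration must be >= 1")
    arg = n_objectives * n_candidates * np.pi**2 * iteration**2 / (6.0 * config.delta)
    return float(config.beta_scale * 2.0 * np.log(arg))


def build_rectangles(
    mean: np.ndarray,
    sd: np.ndarray,
    beta_t: float,
    previous: tuple[np.ndarray, np.ndarray] | None = None,
    measured_value: np.ndarray | None = None,
    measured_noise: np.ndarray | None = None,
):
    """Per-candidate confidence boxes, intersected with their predecessors.

    ``measured_value`` / ``measured_noise`` are dense (n, d) arrays with NaN
    where a (candidate, objective) pair has not been measured.  For measured
    pairs the box is centered on the measurement with the measurement noise
    in place of the posterior SD, so a noiseless measurement collapses the
    box to a point.  Intersection with the previous box guarantees monotone
    shrinkage; an empty intersection (model inconsistency) falls back to the
    new box with a warning.

    Returns ``(lower, upper, center)`` where ``center`` is the measurement
    where available, else the posterior mean — the μ used for ε scaling.
    """
    mu = np.array(mean, dtype=float)
    sigma = np.array(sd, dtype=float)
    if measured_value is not None:
        got = ~np.isnan(measured_value)
        mu[got] = measured_value[got]
        sigma[got] = measured_noise[got]
    half = np.sqrt(beta_t) * sigma
    lower, upper = mu - half, mu + half
    if previous is not None:
        prev_lo, prev_hi = previous
        new_lo = np.maximum(lower, prev_lo)
        new_hi = np.minimum(upper, prev_hi)
        bad = np.any(new_lo > new_hi, axis=1)
        if bad.any():
            logger.warning(
                "empty rectangle intersection for %d candidate(s); model "
                "inconsistency — falling back to the new box",
                int(bad.sum()),
            )
            new_lo[bad], new_hi[bad] = lower[bad], upper[bad]
        lower, upper = new_lo, new_hi
    return lower, upper, mu


def _active_mask(state: ClassificationState) -> np.ndarray:
    return state.status != DISCARDED


def epsilon_discard(
    state: ClassificationState,
    lower: np.ndarray,
    upper: np.ndarray,
    mu: np.ndarray,
    epsilon: np.ndarray,
    eligible: np.ndarray | None = None,
) -> ClassificationState:
    """Move U → D where some active candidate certainly ε-dominates.

    Candidate x is discarded iff there is x' ∈ P ∪ U, x' ≠ x, with
    ``lower(x')_i + ε_i·|μ_i(x')| >= upper(x)_i`` for every objective i.
    Discarded candidates never return.  ``eligible`` optionally restricts
    which unclassified candidates may be *moved* this call.
    """
    boosted = lower + epsilon * np.abs(mu)
    active = _active_mask(state)
    for x in state.unclassified:
        if eligible is not None and not eligible[x]:
            continue
        dominators = active.copy()
        dominators[x] = False
        dominators[state.status == DISCARDED] = False
        if np.any(np.all(boosted[dominators] >= upper[x], axis=1)):
            state.status[x] = DISCARDED
    return state


def epsilon_pareto_promote(
    state: ClassificationState,
    lower: np.ndarray,
    upper: np.ndarray,
    mu: np.ndarray,
    epsilon: np.ndarray,
    eligible: np.ndarray | None = None,
) -> ClassificationState:
    """Move U → P where no remaining candidate could ε-dominate even
    optimistically: x is promoted iff there is no x' ∈ U ∪ P, x' ≠ x, with
    ``upper(x')_i >= lower(x)_i + ε_i·|μ_i(x)|`` for every i.  Runs after
    the discard step of the same iteration; promotions are permanent.
    """
    active = _active_mask(state)
    for x in state.unclassified:
        if eligible is not None and not eligible[x]:
            continue
        threat = active.copy()
        threat[x] = False
        threshold = lower[x] + epsilon * np.abs(mu[x])
        if not np.any(np.all(upper[threat] >= threshold, axis=1)):
            state.status[x] = PARETO
    return state


def _dimensionless_width(lower, upper, mu) -> np.ndarray:
    denom = np.maximum(np.abs(mu), _CV_TOL)
    return np.max((upper - lower) / denom, axis=1)


def acquisition(
    state: ClassificationState,
    lower: np.ndarray,
    upper: np.ndarray,
    mu: np.ndarray,
    batch_size: int = 1,
) -> np.ndarray:
    """Top-``batch_size`` unsampled candidates of P ∪ U by dimensionless
    rectangle size w(x) = max_i (upper_i − lower_i)/|μ_i|; ties by lowest
    index.  Never selects a discarded candidate.  Empty candidate pool
    signals natural termination (returns an empty array).
    """
    pool = np.flatnonzero((state.status != DISCARDED) & ~state.sampled)
    if pool.size == 0:
        return pool
    w = _dimensionless_width(lower[pool], upper[pool], mu[pool])
    # stable sort on -w keeps lowest index first among ties
    order = np.argsort(-w, kind="stable")
    return pool[order[: int(batch_size)]]


def _query_oracle(oracle, idx: int, n_objectives: int):
    """Normalize an oracle reply to {objective: (value, noise_sd)}."""
    reply = oracle(idx)
    if reply is None:
        return {}
    out = {}
    if isinstance(reply, dict):
        items = reply.items()
    else:
        items = enumerate(np.asarray(reply, dtype=float))
    for o, v in items:
        if isinstance(v, tuple):
            value, noise = v
        else:
            value, noise = float(v), None
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        if not 0 <= int(o) < n_objectives:
            raise ValueError(f"oracle returned objective index {o} out of range")
        out[int(o)] = (float(value), noise)
    return out


def run_campaign(
    features: np.ndarray,
    oracle,
    config: EpalConfig,
    n_objectives: int,
    seed: int = 0,
    truth: np.ndarray | None = None,
    stop_hv_error: float | None = None,
    surrogate_factory=None,
    on_iteration=None,
) -> CampaignResult:
    """Run a full ε-PAL campaign on a finite design space.

    features
        (n, d) candidate descriptors, already standardized.
    oracle
        ``oracle(index) -> {objective: value | (value, noise_sd)}`` (missing
        objectives simply absent) or a sequence of per-objective values.
        Values are on the *user* scale; minimization objectives are negated
        internally per ``config.objective_directions``.
    truth
        Optional (n, n_objectives) noiseless objective matrix (user scale)
        used only to record the per-iteration hypervolume error of the
        classified Pareto set.
    stop_hv_error
        Optional early stop once the recorded hypervolume error falls to or
        below this value (requires ``truth``).
    surrogate_factory
        Optional ``f(seed) -> ICMSurrogate`` overriding the default model
        construction, e.g. to pin known prior hyperparameters.
    on_iteration
        Optional observer ``f(t, state, lower, upper, sampled_ids)`` called
        after each iteration's classification (diagnostics only; mutating
        the state from the callback is unsupported).

    Returns the final classification, the per-iteration history, the fitted
    surrogate (retrained on all sampled points, including discarded ones),
    and the final rectangles.  Identical config + seed gives an identical
    history.
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    signs = config.direction_signs(n_objectives)
    eps = config.epsilon_vector(n_objectives)

    # all RNG draws are keyed off (seed, purpose) so that replays and
    # resumed campaigns are bit-exact
    init_seed = np.random.SeedSequence([seed, 0xA11CE]).generate_state(1)[0] % (2**31)
    model_seed = int(np.random.SeedSequence([seed, 0xB0B]).generate_state(1)[0] % (2**31))

    state = ClassificationState.empty(n)
    labels = LabelTable(n_objectives)
    measured_value = np.full((n, n_objectives), np.nan)
    measured_noise = np.full((n, n_objectives), np.nan)
    unmeasurable: set[int] = set()

    truth_max = None
    hv_tracker = None
    if truth is not None:
        truth_max = np.asarray(truth, dtype=float) * signs
        try:
            hv_tracker = HVErrorTracker(truth_max)
        except ValueError:  # degenerate single-point front: no HV curve
            hv_tracker = None

    def sample(idx: int, iteration: int):
        try:
            reply = _query_oracle(oracle, idx, n_objectives)
        except (ValueError, TypeError):
            raise
        except Exception as exc:  # oracle failure: skip candidate, keep going
            logger.warning("oracle failed on candidate %d: %s", idx, exc)
            unmeasurable.add(idx)
            return
        if not reply:
            logger.warning("oracle returned no objectives for candidate %d", idx)
            unmeasurable.add(idx)
            return
        state.sampled[idx] = True
        for o, (value, noise) in reply.items():
            v = value * signs[o]
            labels.add(idx, o, v, noise)
            measured_value[idx, o] = v
            measured_noise[idx, o] = 0.0 if noise is None else noise
        logger.info("iteration %d: sampled candidate %d -> %s", iteration, idx, reply)

    k = min(config.init_size, n)
    for idx in select_initial_design(X, k, seed=init_seed):
        sample(int(idx), 0)

    if surrogate_factory is not None:
        model = surrogate_factory(model_seed)
    else:
        model = ICMSurrogate(
            rank=config.rank,
            n_restarts=config.n_restarts,
            seed=model_seed,
            max_opt_iter=config.max_opt_iter,
        )
    model.fit(X, labels)
    added_since_refit = 0

    prev_rect = None
    history_rows = []
    t = 0
    mu = np.zeros((n, n_objectives))
    lower = upper = None

    def classify_and_record(t: int, sampled_ids, refit_flag: bool):
        nonlocal prev_rect, lower, upper, mu
        pred = model.predict(X)
        beta_t = beta(max(t, 1), n, n_objectives, config)
        lower, upper, mu = build_rectangles(
            pred.mean, pred.sd, beta_t, prev_rect, measured_value, measured_noise
        )
        prev_rect = (lower, upper)
        eligible = None
        if config.exclude_high_variance:
            w = _dimensionless_width(lower, upper, mu)
            cut = np.quantile(w[~state.sampled] if (~state.sampled).any() else w,
                              config.high_variance_quantile)
            eligible = w <= cut
        epsilon_discard(state, lower, upper, mu, eps, eligible)
        epsilon_pareto_promote(state, lower, upper, mu, eps, eligible)
        hv_err = np.nan
        if hv_tracker is not None:
            hv_err = hv_tracker.error(truth_max[state.pareto])
        history_rows.append(
            {
                "iteration": t,
                "sampled_ids": ";".join(str(i) for i in sampled_ids),
                "n_pareto": int(len(state.pareto)),
                "n_discarded": int(len(state.discarded)),
                "n_unclassified": int(len(state.unclassified)),
                "hypervolume_error": hv_err,
                "refit": bool(refit_flag),
            }
        )
        if on_iteration is not None:
            on_iteration(t, state, lower, upper, list(sampled_ids))
        return hv_err

    hv_err = classify_and_record(0, state.sampled_indices.tolist(), True)

    while t < config.max_iterations:
        if stop_hv_error is not None and np.isfinite(hv_err) and hv_err <= stop_hv_error:
            break
        pool_ok = np.flatnonzero(
            (state.status != DISCARDED)
            & ~state.sampled
            & ~np.isin(np.arange(n), list(unmeasurable))
        )
        if pool_ok.size == 0:
            break
        batch = acquisition(state, lower, upper, mu, config.batch_size)
        batch = [int(b) for b in batch if b not in unmeasurable]
        if not batch:
            break
        t += 1
        n_before = len(labels)
        for idx in batch:
            sample(idx, t)
        added_since_refit += len(labels) - n_before
        refit = added_since_refit >= config.refit_interval
        new_rows = labels.rows[n_before:]
        if new_rows:
            model.update(new_rows, reoptimize=refit)
            if refit:
                added_since_refit = 0
        hv_err = classify_and_record(t, batch, refit)

    # final retrain on all sampled points, including discarded ones
    model.update([], reoptimize=True)

    history = pd.DataFrame(history_rows)
    return CampaignResult(
        state=state,
        history=history,
        model=model,
        labels=labels,
        rectangles=(lower, upper),
        means=mu,
        config=config,
    )
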