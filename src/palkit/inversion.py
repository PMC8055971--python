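"""Elitist-GA inversion of trained surrogates: propose polymers beyond the DoE.

The trained GP surrogate is first distilled into a fast gradient-boosted
tree regressor over a *reduced, invertible* feature set (per-type counts,
end groups, per-type run counts — relative sequence entropy is dropped
because no decoder can target it directly).  An elitist genetic algorithm
then searches integer feature vectors that maximize the distilled model
output, penalized for vectors that cannot be backtraced into a valid
monomer sequence and (optionally) for vectors too similar to the design
space already enumerated.  Every reported candidate is decoded into
concrete sequences so its true performance can be checked against the DoE
Pareto front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.metrics import r2_score

from .features import (
    INVERTIBLE_FEATURE_NAMES,
    backtrace_sequence,
    invertible_components,
)
from .pareto import dominates, pareto_mask
from .polymers import MONOMER_TYPES, DesignSpace, PolymerSequence

__all__ = [
    "GAConfig",
    "GACandidate",
    "reduced_feature_matrix",
    "distill_surrogate",
    "fitness",
    "evolve",
    "evaluate_discoveries",
    "invert_model",
]


@dataclass
class GAConfig:
    population_size: int = 80
    generations: int = 40
    elitist_ratio: float = 0.1
    novelty_weight: float = 0.0
    invalid_penalty: float = 10.0
    mutation_rate: float = 0.15
    crossover_rate: float = 0.7
    tournament_size: int = 3
    novelty_lengthscale: float = 2.0
    n_decodes_per_vector: int = 3
    backtrace_tries: int = 100
    count_step: int = 1  # bead-count granularity; 2 keeps the DoE lattice
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.elitist_ratio < 1.0:
            raise ValueError("elitist_ratio must lie in (0, 1)")
        if int(self.elitist_ratio * self.population_size) < 1:
            raise ValueError("elitist_ratio * population_size must be >= 1")
        if self.novelty_weight < 0:
            raise ValueError("novelty_weight must be >= 0")


@dataclass
class GACandidate:
    genome: np.ndarray  # integer vector (see genome_bounds)
    fitness: float
    decoded: list = field(default_factory=list)  # PolymerSequence or None


# genome layout: counts (4) | head type index | tail type index | runs per type (4)
GENOME_NAMES = (
    [f"count_{t}" for t in MONOMER_TYPES]
    + ["head_type", "tail_type"]
    + [f"n_runs_{t}" for t in MONOMER_TYPES]
)


def genome_bounds(max_count: int = 12, min_count: int = 0) -> list[tuple[int, int]]:
    """Per-gene inclusive integer bounds for the default polymer space.

    ``min_count`` > 0 enforces a design rule such as "at least four beads
    of every type"."""
    return (
        [(min_count, max_count)] * 4
        + [(0, len(MONOMER_TYPES) - 1)] * 2
        + [(0, max_count)] * 4
    )


def genome_to_reduced_vector(genome: np.ndarray) -> np.ndarray:
    """Expand a genome into the INVERTIBLE_FEATURE_NAMES vector (one-hots)."""
    g = np.asarray(genome, dtype=int)
    counts = g[:4].astype(float)
    head = np.zeros(4)
    tail = np.zeros(4)
    head[g[4] % 4] = 1.0
    tail[g[5] % 4] = 1.0
    runs = g[6:10].astype(float)
    return np.concatenate([counts, head, tail, runs])


def reduced_feature_matrix(design: DesignSpace) -> np.ndarray:
    """Reduced invertible feature rows for every design-space sequence."""
    return np.vstack([invertible_components(s) for s in design.sequences])


def distill_surrogate(
    model, design: DesignSpace, objective_index: int, seed: int = 0, features=None
):
    """Distill one GP output into a gradient-boosted tree on reduced features.

    The tree is trained to reproduce the GP posterior mean over the design
    space; its training R² against those means is returned alongside.  A
    constant target (degenerate model) is an error.  ``features`` overrides
    the matrix fed to the GP (e.g. the standardized matrix a campaign used).
    """
    pred = model.predict(features if features is not None else design_features_for(model, design))
    target = pred.mean[:, objective_index]
    if np.ptp(target) == 0:
        raise ValueError("GP predictions are constant; nothing to distill")
    Xred = reduced_feature_matrix(design)
    reg = GradientBoostingRegressor(random_state=seed, n_estimators=300, max_depth=3)
    reg.fit(Xred, target)
    r2 = float(r2_score(target, reg.predict(Xred)))
    return reg, r2


def design_features_for(model, design: DesignSpace) -> np.ndarray:
    """The feature matrix the GP was trained on (full schema, standardized
    upstream); kept as a hook so campaigns can stash their transform."""
    X = getattr(design, "standardized_features", None)
    return X if X is not None else design.features


def fitness(
    genome: np.ndarray,
    regressor,
    dataset_reduced: np.ndarray,
    config: GAConfig,
    dataset_scale: np.ndarray | None = None,
) -> tuple[float, list]:
    """Objective − novelty penalty − validity penalty for one genome.

    The novelty term is ``novelty_weight · exp(−d²/ℓ²)`` with ``d`` the
    minimum Euclidean distance from the genome's reduced feature vector to
    the dataset (optionally column-scaled); the validity term subtracts
    ``invalid_penalty`` when the vector cannot be backtraced into any
    sequence.  Returns (fitness, decoded sequences).
    """
    vec = genome_to_reduced_vector(genome)
    decode_seed = int(np.random.SeedSequence(
        [config.seed, 0xDEC0DE] + [int(v) for v in genome]
    ).generate_state(1)[0] % (2**31))
    decoded = [
        backtrace_sequence(vec, max_tries=config.backtrace_tries, seed=decode_seed + j)
        for j in range(config.n_decodes_per_vector)
    ]
    value = float(regressor.predict(vec[None, :])[0])
    fit = value
    if all(d is None for d in decoded):
        fit -= config.invalid_penalty
    if config.novelty_weight > 0:
        scale = dataset_scale if dataset_scale is not None else np.ones(vec.shape)
        diffs = (dataset_reduced - vec) / scale
        d2 = float(np.min(np.einsum("ij,ij->i", diffs, diffs)))
        fit -= config.novelty_weight * np.exp(-d2 / config.novelty_lengthscale**2)
    return fit, decoded


def _repair(genome: np.ndarray, bounds, count_step: int = 1) -> np.ndarray:
    g = np.rint(genome).astype(int)
    for i, (lo, hi) in enumerate(bounds):
        g[i] = min(max(g[i], lo), hi)
    if count_step > 1:  # snap bead counts onto the design-rule lattice
        for t in range(4):
            lo, hi = bounds[t]
            g[t] = min(lo + count_step * round((g[t] - lo) / count_step), hi)
    # run counts must be consistent with counts: 1..count when present, 0 when absent
    for t in range(4):
        if g[t] == 0:
            g[6 + t] = 0
        else:
            g[6 + t] = min(max(g[6 + t], 1), g[t])
    return g


def evolve(config: GAConfig, fitness_fn, bounds) -> list[GACandidate]:
    """Elitist GA over bounded integer genomes.

    Top ``elitist_ratio`` of each generation is copied unchanged (so the
    best fitness is monotone non-decreasing); the rest comes from
    tournament selection, uniform crossover and bounded integer mutation
    with repair-by-rounding.  Returns the final population sorted by
    fitness, best first.  Deterministic given ``config.seed``.
    """
    bounds = list(bounds)
    if any(lo > hi for lo, hi in bounds):
        raise ValueError("infeasible bounds")
    rng = np.random.default_rng(config.seed)
    n_genes = len(bounds)
    pop_size = config.population_size
    n_elite = max(1, int(config.elitist_ratio * pop_size))

    def random_genome():
        return _repair(
            np.array([rng.integers(lo, hi + 1) for lo, hi in bounds]),
            bounds,
            config.count_step,
        )

    def evaluate(genome):
        fit, decoded = fitness_fn(genome)
        return GACandidate(genome=genome, fitness=float(fit), decoded=decoded)

    population = [evaluate(random_genome()) for _ in range(pop_size)]
    population.sort(key=lambda c: -c.fitness)

    for _ in range(config.generations):
        next_pop = [population[i] for i in range(n_elite)]  # elitism
        while len(next_pop) < pop_size:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                idx = rng.integers(0, pop_size, size=config.tournament_size)
                parents.append(min(idx, key=lambda i: -population[i].fitness))
            g1 = population[parents[0]].genome.copy()
            g2 = population[parents[1]].genome.copy()
            child = g1
            if rng.random() < config.crossover_rate:
                swap = rng.random(n_genes) < 0.5
                child = np.where(swap, g2, g1)
            # bounded integer mutation
            for i, (lo, hi) in enumerate(bounds):
                if rng.random() < config.mutation_rate:
                    child[i] += rng.integers(-2, 3)
            next_pop.append(evaluate(_repair(child, bounds, config.count_step)))
        next_pop.sort(key=lambda c: -c.fitness)
        population = next_pop
    return population


def evaluate_discoveries(
    candidates: list[GACandidate],
    oracle,
    doe_objectives: np.ndarray,
) -> dict:
    """Score decoded GA proposals against the DoE Pareto front.

    ``oracle(sequence) -> objective vector`` evaluates each decoded
    sequence; a proposal is flagged *dominating* when it Pareto-dominates a
    member of the DoE front.  Returns a report with the evaluated
    objectives, flags, and per-objective distribution summaries.
    """
    doe_front = np.atleast_2d(doe_objectives)[pareto_mask(doe_objectives)]
    rows = []
    for cand in candidates:
        for seq in cand.decoded:
            if seq is None:
                continue
            values = np.asarray(oracle(seq), dtype=float)
            dominates_front = any(dominates(values, p) for p in doe_front)
            rows.append(
                {
                    "sequence": seq.id,
                    "fitness": cand.fitness,
                    "objectives": values,
                    "dominates_doe_front": bool(dominates_front),
                }
            )
    if not rows:
        return {
            "n_evaluated": 0,
            "n_dominating": 0,
            "rows": [],
            "objective_summary": None,
        }
    obj = np.vstack([r["objectives"] for r in rows])
    summary = {
        "min": obj.min(axis=0).tolist(),
        "median": np.median(obj, axis=0).tolist(),
        "max": obj.max(axis=0).tolist(),
    }
    return {
        "n_evaluated": len(rows),
        "n_dominating": int(sum(r["dominates_doe_front"] for r in rows)),
        "rows": rows,
        "objective_summary": summary,
    }


def invert_model(
    model,
    design: DesignSpace,
    config: GAConfig,
    objective_indices=None,
    n_weighted_sums: int = 1,
    max_count: int = 12,
    min_count: int = 0,
    features=None,
) -> dict:
    """Full inversion protocol: distill, evolve, collect proposals.

    One GA run per single objective plus ``n_weighted_sums`` runs on random
    convex combinations of the distilled outputs (the surrogate is
    multi-output but a GA needs a scalar target; both views are reported).
    Returns distilled regressors with their R², and the GA populations.
    """
    pred_dim = model.n_objectives
    objective_indices = list(objective_indices or range(pred_dim))
    regressors = {}
    for o in objective_indices:
        regressors[o] = distill_surrogate(
            model, design, o, seed=config.seed + o, features=features
        )
    dataset_reduced = reduced_feature_matrix(design)
    bounds = genome_bounds(max_count, min_count)
    runs = {}
    for o in objective_indices:
        reg, _ = regressors[o]
        runs[f"objective_{o}"] = evolve(
            GAConfig(**{**config.__dict__, "seed": config.seed + 100 + o}),
            lambda g, reg=reg: fitness(g, reg, dataset_reduced, config),
            bounds,
        )
    rng = np.random.default_rng(config.seed + 500)
    for k in range(n_weighted_sums):
        w = rng.dirichlet(np.ones(len(objective_indices)))

        class _Blend:
            def __init__(self, regs, weights):
                self.regs, self.weights = regs, weights

            def predict(self, X):
                return sum(
                    wi * r.predict(X) for wi, (r, _) in zip(self.weights, self.regs)
                )

        blend = _Blend([regressors[o] for o in objective_indices], w)
        runs[f"weighted_{k}"] = evolve(
            GAConfig(**{**config.__dict__, "seed": config.seed + 900 + k}),
            lambda g, blend=blend: fitness(g, blend, dataset_reduced, config),
            bounds,
        )
    return {
        "regressors": {o: {"r2": r2} for o, (_, r2) in regressors.items()},
        "runs": runs,
    }
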