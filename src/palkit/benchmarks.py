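"""Synthetic stand-in oracles with known Pareto sets.

The molecular-simulation labels of the dispersant study are expensive; these
benchmarks replace them with cheap, fully controlled problems:

* ``pseudo_simulate`` — an invented analytic polymer oracle that reproduces
  the qualitative structure–property trends of the dispersant system
  (Flory-type R_g ~ N^ν scaling with a composition-weighted effective
  exponent; surface adsorption growing with bead–surface affinity and
  falling with good-solvent content; dimer repulsion growing with
  good-solvent content and sequence disorder).  Its coefficients are
  documented emulations, not calibrated physics.
* ``make_benchmark`` — reproducible problems with precomputed truth:
  a 2-objective convex front on 2-D features, the 3-objective polymer
  problem, a GP-prior draw (functions from the surrogate's own prior), and
  a missing-data variant that withholds a fraction of one objective.
* ``random_search_baseline`` — the bootstrapped random-sampling hypervolume
  error trajectories that ε-PAL campaigns are compared against.

All benchmark objectives are oriented as maximization.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .features import cluster_statistics, relative_sequence_entropy, standardize_features
from .pareto import HVErrorTracker, pareto_mask
from .polymers import MONOMER_TYPES, PolymerSequence, full_factorial_design

__all__ = [
    "PseudoSimConfig",
    "BenchmarkProblem",
    "pseudo_simulate",
    "make_benchmark",
    "random_search_baseline",
    "BENCHMARK_NAMES",
]

# textbook Flory exponents: good solvent (self-avoiding walk), theta, collapsed
_NU_GOOD, _NU_THETA, _NU_COLLAPSED = 0.588, 0.5, 1.0 / 3.0


@dataclass
class PseudoSimConfig:
    """Coefficients of the invented polymer pseudo-simulator.

    flory_prefactor
        ``a`` in R_g = a · N^ν_eff (length units are arbitrary).
    flory_exponents
        Per-bead-type ν used in the composition-weighted blend: W is a
        good-solvent bead (raises ν_eff), R a bad-solvent bead (lowers it),
        Ta/Tr theta beads.
    surface_affinities
        Per-type bead–surface attraction; R adsorbs most, W least.
    rep_w_coupling / rep_entropy_coupling
        Weights of good-solvent fraction and relative sequence entropy in
        the dimer-repulsion score.
    ads_scale / rep_scale
        Overall magnitudes of the adsorption and repulsion scores.  Both
        scores are *intensive* (composition fractions, not counts): the
        competing pulls are then chain growth (R_g), R-content (adsorption)
        and W-content/disorder (repulsion), which keeps the three objectives
        in genuine conflict the way the dispersant trade-offs are described.
    noise_sd
        Additive Gaussian noise SD per objective (R_g, ads, rep); the
        defaults are ~2% of the typical objective magnitude.
    """

    flory_prefactor: float = 1.0
    flory_exponents: dict = field(
        default_factory=lambda: {
            "W": _NU_GOOD,
            "R": _NU_COLLAPSED,
            "Ta": _NU_THETA,
            "Tr": _NU_THETA,
        }
    )
    surface_affinities: dict = field(
        default_factory=lambda: {"W": 0.2, "R": 1.0, "Ta": 0.7, "Tr": 0.4}
    )
    rep_w_coupling: float = 1.2
    rep_entropy_coupling: float = 0.8
    ads_scale: float = 3.0
    rep_scale: float = 2.0
    # sequence (arrangement) effects: without them two arrangements of one
    # composition would be exact objective ties, which no real simulation
    # produces.  Blockiness b = (n_runs − 1)/(N − 1) ∈ [0 blocky, 1
    # alternating]: disordered chains are slightly more expanded and more
    # mutually repulsive; long contiguous R runs adsorb more strongly.
    rg_blockiness_coupling: float = 0.05
    ads_run_coupling: float = 0.3
    rep_blockiness_coupling: float = 0.3
    # idiosyncratic sequence effects: a deterministic, sequence-keyed
    # relative deviation per objective, emulating the part of a real
    # simulation observable that no smooth feature map explains.  It is part
    # of the *true* objective (reproducible, not noise); the repulsion
    # barrier — the costliest, roughest observable — gets the largest share.
    roughness: tuple = (0.01, 0.01, 0.03)
    noise_sd: tuple = (0.1, 0.04, 0.03)

    def __post_init__(self):
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise SDs must be non-negative")
        for nu in self.flory_exponents.values():
            if not 0.0 < nu < 1.0:
                raise ValueError("Flory exponents must lie in (0, 1)")


def pseudo_simulate(
    sequence: PolymerSequence,
    config: PseudoSimConfig | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Noisy (R_g, ΔG_ads score, ΔG_rep score) for one polymer.

    Noiseless when ``seed`` is None and all noise SDs are zero, or simply
    when ``seed`` is None (no noise drawn).  Deterministic given the seed.
    """
    cfg = config or PseudoSimConfig()
    n = len(sequence)
    frac = {t: sequence.beads.count(t) / n for t in MONOMER_TYPES}
    clusters = cluster_statistics(sequence)
    blockiness = (clusters["n_runs_total"] - 1.0) / max(n - 1.0, 1.0)
    nu_eff = sum(frac[t] * cfg.flory_exponents[t] for t in MONOMER_TYPES)
    rg = (
        cfg.flory_prefactor
        * n**nu_eff
        * (1.0 + cfg.rg_blockiness_coupling * (blockiness - 0.5))
    )
    ads = cfg.ads_scale * sum(
        frac[t] * cfg.surface_affinities[t] for t in MONOMER_TYPES
    ) + cfg.ads_run_coupling * clusters["max_run_R"] / n
    rep = cfg.rep_scale * (
        cfg.rep_w_coupling * frac["W"]
        + cfg.rep_entropy_coupling * relative_sequence_entropy(sequence)
        + cfg.rep_blockiness_coupling * blockiness
    )
    values = np.array([rg, ads, rep], dtype=float)
    if any(r > 0 for r in cfg.roughness):
        rough_rng = np.random.default_rng(zlib.crc32(sequence.id.encode()))
        z = np.clip(rough_rng.standard_normal(3), -3.0, 3.0)
        values = values * (1.0 + np.asarray(cfg.roughness) * z)
    if seed is not None:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, cfg.noise_sd)
    return values


@dataclass
class BenchmarkProblem:
    """A finite design space with known noiseless truth.

    ``features`` are standardized descriptors (what the surrogate sees);
    ``objectives_true`` the noiseless objective matrix (maximization);
    ``noise_sd`` per-objective oracle noise; ``missing`` an optional boolean
    (n, d) mask of labels the noisy oracle withholds.
    """

    name: str
    features: np.ndarray
    objectives_true: np.ndarray
    noise_sd: np.ndarray
    seed: int
    sequences: list | None = None
    missing: np.ndarray | None = None

    def __post_init__(self):
        self.pareto_mask_true = pareto_mask(self.objectives_true)

    @property
    def n_candidates(self) -> int:
        return self.features.shape[0]

    @property
    def n_objectives(self) -> int:
        return self.objectives_true.shape[1]

    def oracle(self, noiseless: bool = False, respect_missing: bool = True):
        """A campaign oracle ``f(index) -> {objective: (value, noise_sd)}``.

        Noise draws are keyed by (problem seed, candidate, objective) so the
        oracle is deterministic and independent of query order.
        """

        def query(idx: int):
            out = {}
            for o in range(self.n_objectives):
                if respect_missing and self.missing is not None and self.missing[idx, o]:
                    continue
                value = self.objectives_true[idx, o]
                if noiseless or self.noise_sd[o] == 0:
                    out[o] = (float(value), 0.0)
                else:
                    rng = np.random.default_rng(
                        np.random.SeedSequence([self.seed, 7919, idx, o])
                    )
                    out[o] = (
                        float(value + rng.normal(0.0, self.noise_sd[o])),
                        float(self.noise_sd[o]),
                    )
            return out

        return query


BENCHMARK_NAMES = (
    "two_obj_convex",
    "three_obj_polymer",
    "correlated_missing",
    "gp_prior_two_obj",
)


def _two_obj_convex(size: int, seed: int) -> BenchmarkProblem:
    rng = np.random.default_rng(seed)
    X = rng.uniform(-0.5, 1.5, size=(size, 2))
    f1 = 1.0 - (X[:, 0] ** 2 + X[:, 1] ** 2) / 2.0
    f2 = 1.0 - ((X[:, 0] - 1.0) ** 2 + X[:, 1] ** 2) / 2.0
    obj = np.column_stack([f1, f2])
    Xs, _, _ = standardize_features(X, np.arange(size))
    return BenchmarkProblem("two_obj_convex", Xs, obj, np.array([0.02, 0.02]), seed)


def _three_obj_polymer(
    size: int,
    seed: int,
    missing_fraction: float = 0.0,
    levels=(4, 8, 12),
    sequences_per_point: int | None = None,
    sim_config: PseudoSimConfig | None = None,
):
    # DoE-backed: by default 3 count levels x 4 bead types, enough
    # arrangements per composition to reach the requested size.  The default
    # levels {4, 8, 12} span the full 4..12 count range of the dispersant
    # design space at reduced resolution; the dense 5-level lattice is
    # available via ``levels``.
    n_comps = len(levels) ** 4
    per_point = sequences_per_point or max(1, int(round(size / n_comps)))
    design = full_factorial_design(
        levels=levels, n_factors=4, sequences_per_point=per_point, seed=seed
    )
    cfg = sim_config or PseudoSimConfig()
    truth = np.vstack([pseudo_simulate(s, cfg, seed=None) for s in design.sequences])
    Xs, _, _ = standardize_features(design.features, np.arange(len(design)))
    # drop constant columns (counts are all-positive here but e.g. one-hots vary)
    keep = Xs.std(axis=0) > 0
    Xs = Xs[:, keep]
    missing = None
    name = "three_obj_polymer"
    if missing_fraction > 0:
        rng = np.random.default_rng((seed, 13))
        n_missing = int(len(design) * missing_fraction)
        rows = rng.choice(len(design), size=n_missing, replace=False)
        missing = np.zeros((len(design), 3), dtype=bool)
        missing[rows, 2] = True  # the dimer-repulsion objective is withheld
        name = "correlated_missing"
    return BenchmarkProblem(
        name, Xs, truth, np.asarray(cfg.noise_sd), seed, sequences=design.sequences,
        missing=missing,
    )


def _gp_prior_two_obj(size: int, seed: int) -> BenchmarkProblem:
    """Two-output functions drawn from the surrogate's own ICM prior.

    The draw happens in the (standardized) feature space the model sees and
    the generating hyperparameters are stored on the problem
    (``problem.gp_params``), so the ε-accuracy guarantee can be checked
    under the correct kernel, which is what the theory assumes.  The two
    outputs are anti-correlated (w = [1, −0.7]) to produce non-trivial
    Pareto fronts.
    """
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(size, 2))
    Xs, _, _ = standardize_features(X, np.arange(size))
    dist = cdist(Xs, Xs)
    ls = 1.2  # in standardized-feature units
    s = np.sqrt(5.0) * dist / ls
    M = (1.0 + s + s * s / 3.0) * np.exp(-s)
    w = np.array([1.0, -0.7])
    kappa = np.array([0.15, 0.15])
    B = np.outer(w, w) + np.diag(kappa)
    K = np.kron(B, M) + 1e-8 * np.eye(2 * size)
    L = np.linalg.cholesky(K)
    y = (L @ rng.standard_normal(2 * size)).reshape(2, size).T
    y = y + 4.0  # shift away from zero so the CV tolerance is well behaved
    noise = np.array([0.02, 0.02])
    problem = BenchmarkProblem("gp_prior_two_obj", Xs, y, noise, seed)
    problem.gp_params = {
        "lengthscale": ls,
        "w": w.reshape(2, 1),
        "kappa": kappa,
        "noise_sd": noise,
    }
    return problem


def make_benchmark(name: str, size: int = 100, seed: int = 0, **kwargs) -> BenchmarkProblem:
    """Build a named benchmark problem with precomputed truth.

    ``correlated_missing`` accepts ``missing_fraction`` (default 1/3) and
    withholds that fraction of the third objective's labels.
    """
    if size < 10:
        raise ValueError("size must be >= 10")
    if name == "two_obj_convex":
        return _two_obj_convex(size, seed)
    if name == "three_obj_polymer":
        return _three_obj_polymer(size, seed, **kwargs)
    if name == "correlated_missing":
        fraction = kwargs.pop("missing_fraction", 1.0 / 3.0)
        return _three_obj_polymer(size, seed, missing_fraction=fraction, **kwargs)
    if name == "gp_prior_two_obj":
        return _gp_prior_two_obj(size, seed)
    raise ValueError(f"unknown benchmark {name!r}; options: {BENCHMARK_NAMES}")


def random_search_baseline(
    problem: BenchmarkProblem,
    n_iterations: int,
    n_bootstrap: int = 100,
    seed: int = 0,
    init_indices=None,
):
    """Bootstrapped random-search hypervolume-error trajectories.

    Each replicate samples unlabeled candidates uniformly without
    replacement (optionally starting from a shared initial set) and records,
    after every draw, the hypervolume error of the true-Pareto subset of the
    sampled points.  Returns ``(trajectories, mean, sd)`` with shape
    ``(n_bootstrap, n_recorded)``.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    n = problem.n_candidates
    init = list(init_indices) if init_indices is not None else []
    budget = len(init) + n_iterations
    if budget > n:
        warnings.warn(
            f"requested {budget} samples from {n} candidates; truncating",
            RuntimeWarning,
            stacklevel=2,
        )
        budget = n
    truth = problem.objectives_true
    tracker = HVErrorTracker(truth)
    trajectories = np.empty((n_bootstrap, budget - len(init) + 1 if init else budget))
    for b in range(n_bootstrap):
        rng = np.random.default_rng((seed, b))
        remaining = np.setdiff1d(np.arange(n), init)
        order = list(init) + list(rng.permutation(remaining))
        start = len(init) if init else 1
        # incremental: the sampled set's front (and hence its hypervolume)
        # only changes when a non-dominated point arrives
        front = truth[np.asarray(order[:start], dtype=int)]
        front = front[pareto_mask(front)]
        err = tracker.error(front)
        errs = [err]
        for m in range(start, budget):
            v = truth[order[m]]
            dominated = np.any(np.all(front >= v, axis=1) & np.any(front > v, axis=1))
            if not dominated:
                keep = ~(np.all(v >= front, axis=1) & np.any(v > front, axis=1))
                front = np.vstack([front[keep], v])
                err = tracker.error(front)
            errs.append(err)
        trajectories[b] = errs
    return trajectories, trajectories.mean(axis=0), trajectories.std(axis=0)
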