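# Methods

`palkit` classifies every candidate of a finite materials design space as
ε-accurate Pareto optimal or confidently discarded, using as few oracle
evaluations (simulations, experiments) as possible. This note records the
model, the algorithmic choices, the synthetic study conditions, and what
the tests do and do not demonstrate.

## The classification model

All objectives are handled in a maximization orientation (minimization
objectives are negated at ingestion). For every candidate `x` the algorithm
maintains an axis-aligned uncertainty box per objective `i`,

    Q_t(x)_i = [μ_i(x) − √β_t σ_i(x),  μ_i(x) + √β_t σ_i(x)],

intersected with the box of the previous iteration so boxes only shrink.
For an unsampled candidate, `μ` and `σ` are the GP posterior mean and SD;
once a (candidate, objective) pair has been measured, the measured value
replaces `μ` and the measurement noise SD replaces `σ` — a noiseless
measurement collapses the box to a point. The confidence multiplier follows
the union-bound schedule of the original Pareto-active-learning analysis,

    β_t = beta_scale · 2 log( q · n · π² t² / (6 δ) ),

with `q` objectives, `n` candidates, iteration `t`, and confidence
parameter `δ`. `beta_scale` defaults to 1/9, a customary practical
deflation of the (very conservative) theoretical constant; `beta_scale = 1`
restores the schedule the guarantee is proved for.

Classification uses mean-scaled ε-dominance: the slack on objective `i` of
candidate `x` is `ε_i · |μ_i(x)|`, so ε is a *relative* tolerance and no
prior knowledge of objective ranges is needed. A candidate is discarded
when some still-active candidate's pessimistic corner ε-dominates its
optimistic corner; it is promoted to the Pareto set when no remaining
candidate could ε-dominate it even optimistically. Both moves are
permanent. The next sample is the unsampled, not-discarded candidate with
the largest dimensionless box size `max_i (upper_i − lower_i)/|μ_i|` — the
coefficient-of-variation acquisition rule. Denominators below 1e-8 are
clamped; the mean-scaled scheme presupposes sign-stable objectives whose
magnitudes are not vanishingly small, and the polymer objectives satisfy
this.

Campaigns stop when every non-discarded candidate has been sampled, or at
`max_iterations`. With noisy measurements a handful of near-tied sampled
candidates can remain unclassified indefinitely — their measurement boxes
(`2√β·noise_sd` wide) exceed the ε slack — which is why ε should be chosen
larger than the relative measurement error. With deterministic labels
(precomputed simulation results) classification of sampled candidates
always resolves and campaigns end with an empty unclassified set.

## Surrogate

The multi-output surrogate is an intrinsic coregionalization model: output
`o` at features `x` and output `o'` at `x'` covary as
`B[o,o'] · k(x,x')` with a Matérn-5/2 base kernel (single lengthscale on
z-scored features) and `B = W Wᵀ + diag(κ)` of rank 1 by default (rank 2
selectable). Observations are stacked `(feature row, output index)` pairs,
which gives missing-label support directly: a candidate may contribute any
non-empty subset of its objectives, and cross-output covariance transfers
information to unlabeled outputs. Labels are z-scored per output
internally. Per-label noise SDs, when supplied, enter as fixed
heteroscedastic noise; otherwise a homoscedastic noise variance is learned
per output.

Hyperparameters maximize the log marginal likelihood with analytic
gradients (L-BFGS-B, 5 random restarts by default, re-initialized per
refit, bounds keeping lengthscale/κ/noise in sane log ranges, jitter 1e-6).
Full re-optimization runs every 10 added labels; between refits the model
is conditioned on new data with fixed hyperparameters and fixed label
standardization, so posterior variances are guaranteed non-increasing. For
problems whose generating kernel is known (the GP-prior benchmarks) the
hyperparameters can be pinned (`fixed_params`), which is the regime in
which the ε-accuracy guarantee is actually stated.

## Polymer design space and features

The dispersant design space crosses count levels over four bead types
(W good-solvent, R bad-solvent/strongly adsorbing, Ta/Tr theta-solvent
beads differing in surface affinity); each composition is expanded into a
fixed number of distinct random arrangements. The default study settings —
4 factors, levels {4, 6, 8, 10, 12}, 5 arrangements — give 3125 polymers.

Features per sequence: degree of polymerization, relative sequence entropy
(natural-log Shannon entropy of type frequencies normalized by log 4,
always over the full alphabet so values are comparable), one-hot head and
tail bead, per-type counts, a summed bead interaction parameter from a
configurable 4-entry table (shipped defaults are documented placeholders
that order the beads by solvent quality), and run-length cluster statistics
(per-type and total number of runs, mean run and max run). Features are
z-scored with training-set statistics; zero-variance columns map to 0.

A reduced invertible schema (counts, end groups, per-type run counts;
entropy excluded) can be decoded back to a concrete sequence by randomized
backtracing: split each count into the requested number of runs, then build
a block-type pattern left-to-right with feasibility pruning (no two
adjacent blocks of one type, fixed ends). Structurally impossible vectors
and exhausted search budgets return INVALID, which the GA consumes as a
penalty rather than an error.

## Synthetic study conditions

The pseudo-simulator replaces the dissipative-particle-dynamics oracle with
cheap analytic surrogates for the three dispersant performance indicators,
reproducing the reported qualitative structure–property trends without any
claim of physical accuracy:

* radius of gyration `R_g = a · N^ν_eff`, where `ν_eff` blends textbook
  Flory exponents (0.588 good solvent, 0.5 theta, 1/3 collapsed) by
  composition; disordered (less blocky) chains are slightly expanded;
* adsorption score increasing in per-type surface affinities (R most, W
  least) and in the longest contiguous R run;
* repulsion score increasing in good-solvent fraction, sequence entropy
  and alternation (disorder).

Two deliberate realism features matter for the campaign dynamics. First,
objectives carry a small deterministic sequence-keyed "roughness"
(1%/1%/3% relative, largest on the repulsion barrier): the idiosyncratic
part of a real observable that no smooth feature map explains. Without it,
two arrangements of one composition would tie exactly (blocking
ε-classification) and withheld labels would be perfectly imputable, hiding
the cost of missing data. Second, optional Gaussian measurement noise
defaults to ~2% CV per objective; campaigns emulating precomputed
deterministic simulation labels use the noiseless oracle with
`noise_sd = 0`.

Benchmarks (`make_benchmark`): `two_obj_convex` (2-D features, known convex
front), `three_obj_polymer` (a DoE at levels {4, 8, 12} spanning the full
4–12 count range, pseudo-simulated truth), `correlated_missing` (the same
with a third of the repulsion labels withheld), and `gp_prior_two_obj`
(anti-correlated two-output draws from the surrogate's own ICM prior, with
the generating kernel stored on the problem). The random-search baseline
samples uniformly without replacement, optionally from a shared initial
set, and reports bootstrapped hypervolume-error bands (100 replicates by
default); within a replicate the sampled front is maintained incrementally.

What passing tests show — and do not. The synthetic problems have smooth,
low-dimensional structure plus controlled roughness; real simulation or
experimental campaigns face higher noise, model misspecification and
feature inadequacy. The guarantee test conditions on the correct kernel,
as the theory does; with learned hyperparameters on few samples the GP can
be overconfident and the practical β deflation trades guarantee slack for
speed. Efficiency results at n≈300 demonstrate ordering (active learning
beats random search), not the magnitude of the full-scale study.

## Evaluation metrics

Dominance, Pareto masks (vectorized O(n²), checked against a double-loop
oracle), nadir point over the Pareto subset, and the hypervolume indicator:
exact by dimension sweep for up to three objectives, Monte-Carlo fallback
(with standard error) beyond, the MC estimator doubling as the independent
test oracle. Hypervolume error is `(HV_max − HV)/HV_max` with the nadir of
the true front as the reference; for ε-PAL curves only candidates
*classified* Pareto-optimal count, for random search the true-Pareto subset
of sampled points. Ties in objective vectors are all kept Pareto-optimal.

## GA inversion

To probe for designs the DoE missed, each GP output is distilled into a
gradient-boosted tree on the reduced invertible features (training R²
against the GP means is reported; ≥0.99 on the synthetic benchmarks), and
an elitist GA searches integer genomes (counts, end-group types, run
counts) maximizing the distilled output minus `novelty_weight ·
exp(−d²/ℓ²)` (minimum distance to the enumerated design space) minus an
invalidity penalty for undecodable vectors. The top elite fraction is
copied unchanged each generation, so best fitness is monotone; selection is
3-way tournament, variation is uniform crossover plus bounded integer
mutation with repair. Because a GA needs a scalar target, one run is
performed per objective plus runs on random convex combinations; each
proposed vector is decoded into three arrangements. On benchmarks whose
optimum lies inside the DoE hull the evaluated proposals do not
Pareto-dominate the DoE front, matching the qualitative finding the
workflow is designed to check. That check is meaningful only when the
enumerated design actually contains the reachable optima, so it is run
with the GA held to the design rule of the enumeration (minimum bead
counts and lattice granularity via `min_count` / `count_step`) and the
composition-determined simulator; on a coarse demonstration lattice with
sequence effects enabled, an unconstrained GA legitimately finds
front-extending designs between the lattice points — a feature of the
inversion step, not a defect (see `examples/05_inverse_design.py`).

## Numerical and reproducibility choices

Every random draw is keyed off `(master seed, purpose, iteration)` via
`SeedSequence`, never a consumed global stream: identical configuration and
seed replay bit-exactly, and a campaign rebuilt from its saved labels and
state file continues identically. Tie-breaks everywhere (acquisition,
initialization, classification order) resolve to the lowest candidate
index. Degenerate cases: empty box intersections fall back to the new box
with a logged warning (model inconsistency); single-point true fronts make
the nadir-referenced hypervolume zero and the error curve undefined, and
are reported as such rather than silently patched.

## Problem sizes used in the shipped checks

Desk-scaled: the guarantee check uses 50-candidate two-objective GP-prior
problems over 50 seeds; the efficiency comparison uses the 324-candidate
polymer benchmark (ε=0.01, threshold 0.05, shared 20-point
farthest-point initialization, deterministic labels) against the
random-search bootstrap mean; missing-data campaigns use 150 candidates
with one third of repulsion labels withheld. The full 3125-polymer space is
generated and featurized in the checks, but full-scale labeled campaigns
would require the original simulation label set.
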