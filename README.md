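# palkit

Pareto active learning for discrete materials design spaces.

## The problem

In most materials-design campaigns there is no single number to optimize:
a dispersant polymer must adsorb strongly onto particle surfaces, repel
other polymer-coated particles, and keep solution viscosity acceptable —
and these goals compete. The only bias-free answer a screening campaign
can give is the *Pareto front*: the set of candidates for which no
objective can be improved without degrading another. When each evaluation
is an expensive simulation or experiment, computing that front by brute
force is off the table.

`palkit` implements the ε-PAL (Pareto active learning) approach for
finite candidate sets. A multi-output Gaussian-process surrogate supplies
a predictive mean μ and SD σ per objective; each candidate gets a
confidence hyperrectangle

    [ μ_i − √β_t σ_i ,  μ_i + √β_t σ_i ],    β_t = c · 2 log(q n π² t² / 6δ),

intersected across iterations so it only shrinks. A candidate is
**discarded** once another candidate's pessimistic corner ε-dominates its
optimistic corner, and **classified ε-accurate Pareto optimal** once no
remaining candidate could ε-dominate it even optimistically, where the
tolerance on objective *i* is the *relative* slack ε_i·|μ_i| — no prior
knowledge of objective ranges required. The next sample is the candidate
near the predicted front with the largest dimensionless uncertainty
(coefficient of variation, `max_i (upper_i − lower_i)/|μ_i|`). With a
correctly specified GP prior and the theoretical β schedule, every true
Pareto-optimal candidate is ε-dominated by the returned set with
probability 1−δ.

Around this core the package provides the full campaign workflow for a
coarse-grained polymer dispersant study: full-factorial design-space
generation over four bead types (3125 sequences at the default settings),
sequence featurization (composition, entropy, end groups, run-length
clusters), an intrinsic-coregionalization GP that handles partially
missing objective labels, hypervolume diagnostics against a known truth,
a bootstrapped random-search baseline, and elitist-GA inversion of the
trained surrogate back into candidate polymer sequences.

## A worked example

```python
from palkit import EpalConfig, make_benchmark, run_campaign

problem = make_benchmark("three_obj_polymer", size=160, seed=0)
config = EpalConfig(epsilon=0.05, init_size=15, max_iterations=120)
result = run_campaign(
    problem.features, problem.oracle(noiseless=True), config,
    n_objectives=3, seed=0, truth=problem.objectives_true,
)
```

This explores a 162-polymer design space (three objectives: radius of
gyration, surface adsorption, dimer repulsion) and prints, via
`examples/02_run_campaign.py`:

```
candidates: 162, true front: 43
iterations: 42, sampled: 57
classified: 32 Pareto, 130 discarded, 0 unclassified
hypervolume error of the classified front: 0.077
```

Read: after sampling only 57 of 162 candidates the campaign has classified
*every* candidate — 32 ε-accurate Pareto polymers, the rest confidently
discarded — and the classified front covers all but 7.7% of the
objective-space hypervolume of the true front (ε=0.05 allows the front to
be locally up to ~5% of an objective's magnitude short, which is where
that residual comes from).

The other scripts in `examples/` each demonstrate one capability:
design-space generation and featurization, the random-search comparison,
campaigns with a third of one objective's labels missing, and GA-based
inverse design.

A thin CLI wraps the same calls for shell use:

```bash
palkit generate-design --levels 4,6,8,10,12 --factors 4 --seqs 5 --out design.csv
palkit run --benchmark three_obj_polymer --size 160 --epsilon 0.05 --out-dir campaign/
palkit baseline --benchmark three_obj_polymer --size 160 --out baseline.csv
palkit invert --size 160 --out ga_report.json
```

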