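"""Campaign with partially missing labels.

One third of the candidates never report their dimer-repulsion score (the
costliest observable). The coregionalized GP imputes the missing output
from the other two, so the campaign still classifies every candidate —
just with more iterations than the complete-data run.
"""

from palkit import EpalConfig, make_benchmark, run_campaign

for name in ("three_obj_polymer", "correlated_missing"):
    problem = make_benchmark(name, size=150, seed=0)
    config = EpalConfig(epsilon=0.05, init_size=15, max_iterations=300)
    result = run_campaign(
        problem.features, problem.oracle(noiseless=True), config, 3, seed=0
    )
    final = result.history.iloc[-1]
    missing = 0 if problem.missing is None else int(problem.missing.sum())
    print(
        f"{name:>20}: {missing:3d} labels withheld | "
        f"{int(final['iteration'])} iterations | "
        f"{int(final['n_pareto'])} Pareto / {int(final['n_unclassified'])} unclassified"
    )
# Missing labels leave model-based uncertainty on the withheld objective,
# so classification needs extra sampling elsewhere before it can finish.
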