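"""Shared configuration for the numbered analysis drivers.

One synthetic cohort, one seed, one output directory: each driver runs
its stage(s) of the pipeline against ``results/analysis`` and can be
re-run independently (later stages resume from the files earlier stages
wrote). Scales are modest so the full sequence finishes in a few minutes
on one core.
"""

from pathlib import Path

from dupdyn.io import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 20240901


def make_config(stages) -> RunConfig:
    return RunConfig(
        out_dir=str(RESULTS),
        seed=SEED,
        stages=tuple(stages),
        synthetic=dict(
            n_families=20,
            tips_per_family=6,
            n_conditions=24,
            n_sites=10,
            expression_rate=0.3,
            missing_rate=0.02,
            mean_edge=0.12,
        ),
        consensus_runs=30,
        consensus_min=15,
        permutations=500,
        bernoulli_reps=1000,
        ode_n_starts=8,
    )
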