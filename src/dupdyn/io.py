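"""Tabular I/O, run configuration, and the Diff expression subset.

All tables are TSV with a mandatory header row and "NA" as the missing
token; trees are newick (see :mod:`dupdyn.trees`). Run configuration is a
YAML/JSON mapping validated into :class:`RunConfig`; every pipeline run
writes a JSON manifest echoing the seed and all thresholds so results are
auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ancestral import MISSING

__all__ = [
    "RunConfig",
    "read_table",
    "write_table",
    "read_state_table",
    "write_state_table",
    "compute_diff_subset",
    "read_config",
    "write_manifest",
]

NA = "NA"

SUBSETS = ("Ctrl", "LightDev", "Stress", "Diff")
STAGES = ("simulate", "discretize", "ancestral", "classify", "asymmetry",
          "ode", "retention")


@dataclass
class RunConfig:
    """Paths, thresholds and the RNG seed for one pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    stages: tuple = STAGES
    # inputs (ignored by stages run on synthetic data)
    trees: str | None = None
    expression: str | None = None
    sites: str | None = None
    pairs: str | None = None
    groups: str | None = None
    features: str | None = None
    # synthetic generation
    synthetic: dict = field(default_factory=dict)
    # thresholds
    consensus_runs: int = 100
    consensus_min: int = 50
    posterior_min: float = 0.5
    min_partitioned: int = 5
    min_sites: int = 5
    permutations: int = 1000
    bernoulli_reps: int = 1000
    ode_variants: tuple = ("one", "two", "four")
    ode_n_starts: int = 20

    def __post_init__(self):
        for name in ("consensus_runs", "consensus_min", "min_partitioned",
                     "min_sites", "permutations", "bernoulli_reps",
                     "ode_n_starts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if not 0 < self.posterior_min < 1:
            raise ValueError("posterior_min must be in (0, 1)")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def read_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], index_col=index_col)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep=NA, index=index)


def read_state_table(path) -> pd.DataFrame:
    """Gene x item integer state table; NA becomes the MISSING token."""
    df = pd.read_csv(path, sep="\t", na_values=[NA], index_col=0)
    return df.fillna(MISSING).astype(int)


def write_state_table(df: pd.DataFrame, path) -> None:
    out = df.astype(object).mask(df == MISSING)
    write_table(out, path)


def compute_diff_subset(
    stress: pd.DataFrame,
    control: pd.DataFrame,
    pairing: dict[str, str] | pd.DataFrame,
) -> pd.DataFrame:
    """Element-wise stress - control on the log2 scale, per matched pair.

    ``pairing`` maps each stress condition to its control condition (or a
    two-column DataFrame stress/control). Output columns are the stress
    condition names; a value missing on either side is missing in the
    output. An unmatched condition on either side of the map is an error.
    """
    if isinstance(pairing, pd.DataFrame):
        pairing = dict(zip(pairing.iloc[:, 0], pairing.iloc[:, 1]))
    missing_s = [c for c in pairing if c not in stress.columns]
    missing_c = [c for c in pairing.values() if c not in control.columns]
    if missing_s or missing_c:
        raise KeyError(
            f"unmatched conditions: stress={missing_s}, control={missing_c}"
        )
    out = {}
    for s_col, c_col in pairing.items():
        out[s_col] = stress[s_col] - control[c_col]
    return pd.DataFrame(out, index=stress.index)


def write_manifest(config: RunConfig, out_dir, extra: dict | None = None
                   ) -> Path:
    import dupdyn

    manifest = {
        "package": "dupdyn",
        "version": getattr(dupdyn, "__version__", "0"),
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    if extra:
        manifest.update(extra)
    path = Path(out_dir) / "manifest.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
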