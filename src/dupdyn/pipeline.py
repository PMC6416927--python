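"""Pipeline orchestration: synthetic generation through retention modeling.

``run_pipeline`` executes the configured stages in order on one seeded RNG
stream: simulate -> discretize -> ancestral -> classify -> asymmetry ->
ode -> retention, writing each stage's TSV/JSON under the output directory
plus a manifest with the seed and thresholds. A stage failure aborts with
the stage name; outputs written so far are flagged in the manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestral, asymmetry, dynamics, pairs as pair_mod, retention
from .io import RunConfig, write_manifest, write_state_table, write_table
from .simulate import (
    empirical_retention_odds,
    simulate_family_dataset,
    simulate_group_feature_table,
)
from .trees import write_newick_tree

log = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; return a dict of in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    results: dict = {}
    done = []
    try:
        for stage in config.stages:
            log.info("stage %s", stage)
            _STAGE_FUNCS[stage](config, rng, out, results)
            done.append(stage)
    except Exception as e:
        write_manifest(config, out, {"stages_completed": done,
                                     "failed_stage": stage,
                                     "error": str(e)})
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    write_manifest(config, out, {"stages_completed": done})
    return results


def _stage_simulate(config, rng, out, results):
    params = dict(config.synthetic)
    ds = simulate_family_dataset(rng=rng, **params)
    results["dataset"] = ds
    tree_dir = out / "trees"
    tree_dir.mkdir(exist_ok=True)
    for fam, tree in ds.trees.items():
        write_newick_tree(tree, tree_dir / f"{fam}.nwk")
    write_table(ds.expression, out / "expression.tsv")
    write_state_table(ds.sites, out / "sites.tsv")
    write_table(ds.pairs, out / "pairs.tsv", index=False)
    write_table(ds.condition_meta, out / "condition_meta.tsv", index=False)


def _require(results, key, stage, out=None):
    """Fetch an upstream result, falling back to precomputed files in the
    output directory so stage subsets can resume a previous run."""
    if key in results:
        return results[key]
    if out is not None:
        from .io import read_table, read_state_table

        def _load_dataset():
            from .simulate import FamilyDataset
            from .trees import read_newick_tree

            trees = {p.stem: read_newick_tree(p)
                     for p in sorted((out / "trees").glob("*.nwk"))}
            return FamilyDataset(
                trees=trees,
                expression=read_table(out / "expression.tsv"),
                tip_states=None,
                true_ancestors={},
                sites=read_state_table(out / "sites.tsv"),
                true_site_ancestors={},
                pairs=read_table(out / "pairs.tsv", index_col=None),
                condition_meta=read_table(out / "condition_meta.tsv",
                                          index_col=None),
            )

        if key == "dataset" and (out / "pairs.tsv").exists():
            results[key] = _load_dataset()
            return results[key]

        loaders = {
            "states": lambda: read_state_table(out / "states.tsv"),
            "calls": lambda: read_table(out / "ancestral_calls.tsv",
                                        index_col=None),
            "site_calls": lambda: read_table(
                out / "ancestral_site_calls.tsv", index_col=None),
            "classified": lambda: read_table(out / "pair_classes.tsv",
                                             index_col=None),
        }
        if key in loaders:
            path_map = {
                "states": "states.tsv",
                "calls": "ancestral_calls.tsv",
                "site_calls": "ancestral_site_calls.tsv",
                "classified": "pair_classes.tsv",
            }
            if (out / path_map[key]).exists():
                results[key] = loaders[key]()
                return results[key]
    raise RuntimeError(f"stage {stage!r} needs {key!r} from an earlier stage "
                       "(run it first or place its output in the out dir)")


def _stage_discretize(config, rng, out, results):
    ds = _require(results, "dataset", "discretize", out)
    states = ancestral.discretize_expression(ds.expression)
    results["states"] = states
    write_state_table(states, out / "states.tsv")


def _stage_ancestral(config, rng, out, results):
    ds = _require(results, "dataset", "ancestral", out)
    states = _require(results, "states", "ancestral", out)
    call_frames = []
    site_frames = []
    for fam, tree in ds.trees.items():
        fam_genes = [g for g in states.index if g.startswith(fam + "_")]
        calls = ancestral.consensus_ancestral_calls(
            tree, states.loc[fam_genes],
            consensus_runs=config.consensus_runs,
            consensus_min=config.consensus_min,
            posterior_min=config.posterior_min,
            n_states=4, rng=rng,
        )
        calls.insert(0, "family", fam)
        call_frames.append(calls)
        scalls = ancestral.consensus_ancestral_calls(
            tree, ds.sites.loc[fam_genes],
            consensus_runs=config.consensus_runs,
            consensus_min=config.consensus_min,
            posterior_min=config.posterior_min,
            n_states=2, rng=rng,
        )
        scalls.insert(0, "family", fam)
        site_frames.append(scalls)
    results["calls"] = pd.concat(call_frames, ignore_index=True)
    results["site_calls"] = pd.concat(site_frames, ignore_index=True)
    write_table(results["calls"], out / "ancestral_calls.tsv", index=False)
    write_table(results["site_calls"], out / "ancestral_site_calls.tsv",
                index=False)


def _stage_classify(config, rng, out, results):
    ds = _require(results, "dataset", "classify", out)
    states = _require(results, "states", "classify", out)
    calls = _require(results, "calls", "classify", out)
    classified = pair_mod.classify_pairs(ds.pairs, calls, states)
    results["classified"] = classified
    write_table(classified, out / "pair_classes.tsv", index=False)
    if len(classified):
        grid = pair_mod.permutation_zscores(
            pd.concat([classified["state_a"], classified["state_b"]]),
            pd.concat([classified["ancestral_state"]] * 2),
            n_perm=config.permutations, rng=rng,
        )
        zdf = pd.DataFrame(grid.z, index=grid.row_values,
                           columns=grid.col_values)
        write_table(zdf, out / "zscore_grid.tsv")
        results["zgrid"] = grid


def _stage_asymmetry(config, rng, out, results):
    classified = _require(results, "classified", "asymmetry", out)
    part = classified[classified["class"] == "I"]
    records = asymmetry.asymmetry_records(
        part, min_partitioned=config.min_partitioned, rng=rng)
    results["asymmetry"] = records
    write_table(records, out / "asymmetry.tsv", index=False)
    if len(records) >= 2:
        null = asymmetry.grouped_bernoulli_null(
            records["n"], reps=config.bernoulli_reps, rng=rng,
            min_partitioned=config.min_partitioned)
        report = asymmetry.compare_to_null(records, null)
        report["exact_by_n"] = null.exact_by_n
        results["asymmetry_null"] = report
        with open(out / "asymmetry_null.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)


def _stage_ode(config, rng, out, results):
    classified = _require(results, "classified", "ode", out)
    # one observation per pair x item: (class, ds)
    obs = classified[["class", "ds"]]
    fits = {}
    for variant in config.ode_variants:
        fits[variant] = dynamics.fit_ode(
            obs, variant=variant, kind="pair",
            n_starts=config.ode_n_starts, rng=rng,
        )
    results["ode_fits"] = fits
    rows = []
    for variant, fit in fits.items():
        rows.append({"variant": variant, "log_likelihood": fit.log_likelihood,
                     "n_free": fit.n_free, **fit.rates})
    write_table(pd.DataFrame(rows), out / "ode_fits.tsv", index=False)
    lrt_rows = []
    order = [v for v in ("one", "two", "four") if v in fits]
    for null_v, alt_v in zip(order, order[1:]):
        res = dynamics.likelihood_ratio_test(fits[null_v], fits[alt_v])
        lrt_rows.append({"null": null_v, "alt": alt_v,
                         "statistic": res.statistic, "df": res.df,
                         "p": res.p_value})
    if lrt_rows:
        write_table(pd.DataFrame(lrt_rows), out / "ode_lrt.tsv", index=False)
        results["ode_lrt"] = lrt_rows


def _stage_retention(config, rng, out, results):
    sim = simulate_group_feature_table(rng=rng)
    odds = empirical_retention_odds(sim["counts"])
    model = retention.fit_retention_model(sim["features"], odds)
    robust = retention.leave_one_out_robustness(sim["features"], odds)
    results["retention"] = {"model": model, "odds": odds,
                            "robustness": robust, "truth": sim["truth"]}
    write_table(odds.to_frame(), out / "retention_odds.tsv")
    with open(out / "retention_model.json", "w") as fh:
        json.dump({
            "features": model.features,
            "coefficients": model.coefficients,
            "f_statistic": model.f_statistic,
            "r_squared": model.r_squared,
            "p_value": model.p_value,
            "importance": model.importance,
        }, fh, indent=2)
    write_table(robust, out / "retention_robustness.tsv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "discretize": _stage_discretize,
    "ancestral": _stage_ancestral,
    "classify": _stage_classify,
    "asymmetry": _stage_asymmetry,
    "ode": _stage_ode,
    "retention": _stage_retention,
}
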