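"""End-to-end orchestration (simulate → adjust → test → evaluate) and the CLI.

The library entry points are :func:`run_association` (per-trait, per-replicate,
per-gene testing over in-memory containers) and :func:`run_evaluation`
(metric assembly from per-replicate results).  The ``rarepool`` console
script wraps them behind ``simulate`` / ``test`` / ``evaluate`` / ``full``
subcommands; every run writes a JSON manifest (option echo, seed, version,
wall time) next to its outputs, and a failed run removes its partial outputs.

Per-gene permutation seeds are derived from (master seed, replicate, gene
name), so results are independent of gene processing order and reruns with
the same seed are byte-identical.
"""

from __future__ import annotations

import contextlib
import dataclasses
import json
import logging
import time
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Mapping, Sequence

import click
import numpy as np
import pandas as pd
import yaml

from . import adjust as adjust_mod
from . import core, evaluate, pooled, simulate

log = logging.getLogger(__name__)

#: desk-scale permutation default for CLI runs; full analyses raise this to
#: pooled.DEFAULT_N_PERM (100,000)
CLI_DEFAULT_N_PERM = 999


def _replicate_plan(plan: pooled.PermutationPlan, rep) -> pooled.PermutationPlan:
    if rep is None:
        return plan
    return dataclasses.replace(plan, seed=pooled.gene_seed(plan.seed, f"replicate:{rep}"))


def run_association(
    genotypes: core.GenotypeMatrix,
    variants: pd.DataFrame,
    gene_index: Mapping[str, np.ndarray],
    phenotypes: core.PhenotypeTable,
    trait: str,
    tests: Sequence[str] = evaluate.TEST_NAMES,
    plan: pooled.PermutationPlan = pooled.PermutationPlan(n_perm=CLI_DEFAULT_N_PERM),
    adjust_covariates: Sequence[str] = (),
    sided: str = "one-sided-greater",
) -> list[list[pooled.TestResult]]:
    """Test every gene for one trait across all replicates.

    Covariate residualization (when requested) happens once per replicate
    before the gene loop; all requested tests share each gene's permutation
    stream.  Returns one result list per replicate.
    """
    if np.isnan(variants["maf"].to_numpy(dtype=float)).any():
        variants = core.compute_maf(genotypes, variants)
    table = phenotypes
    if adjust_covariates:
        table = adjust_mod.adjust_table(table, list(adjust_covariates))
    slices = {
        g: (genotypes.counts[:, np.asarray(cols, dtype=int)],
            variants["maf"].to_numpy(dtype=float)[np.asarray(cols, dtype=int)])
        for g, cols in gene_index.items()
    }
    out: list[list[pooled.TestResult]] = []
    for rep in table.replicate_ids:
        y = table.vector(trait, rep, sample_ids=genotypes.sample_ids)
        plan_r = _replicate_plan(plan, rep)
        rep_results = []
        for gene, (counts, mafs) in slices.items():
            res = pooled.run_gene_tests(
                gene, counts, mafs, y, tests=tests, plan=plan_r, sided=sided
            )
            rep_results.extend(res[t] for t in tests)
        out.append(rep_results)
        log.info("trait %s replicate %s: tested %d genes", trait, rep, len(slices))
    return out


def results_to_frames(replicate_results: Sequence[Sequence[pooled.TestResult]]) -> list[pd.DataFrame]:
    """Per-replicate results as DataFrames (testable rows only)."""
    frames = []
    for rep in replicate_results:
        rows = [
            {
                "gene": r.gene_name,
                "test": r.test_name,
                "n_variants_used": r.n_variants_used,
                "statistic": r.statistic,
                "optimal_threshold": r.optimal_threshold,
                "n_permutations": r.n_permutations,
                "p_value": r.p_value,
            }
            for r in rep
            if r.testable
        ]
        frames.append(
            pd.DataFrame(rows, columns=core.RESULT_COLUMNS).sort_values(
                ["gene", "test"], kind="stable"
            )
        )
    return frames


def run_evaluation(
    replicate_frames: Sequence[pd.DataFrame],
    truth: Mapping[str, Sequence],
    variants: pd.DataFrame,
    gene_index: Mapping[str, np.ndarray],
    alphas: Sequence[float] = (1.56e-5, 0.001, 0.005, 0.01, 0.05, 0.1),
    tests: Sequence[str] = evaluate.TEST_NAMES,
) -> evaluate.EvaluationResult:
    """Assemble the p-value grid and compute type I error / TPP / FPP / AUC."""
    universes = {t: evaluate.build_universe(t, variants, gene_index) for t in tests}
    grid = evaluate.grid_from_results(replicate_frames, universes, tests)
    return evaluate.evaluate_grid(grid, set(truth), alphas=alphas, tests=tests)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@contextlib.contextmanager
def _output_guard(paths: list[Path]):
    """Remove any partially written outputs if the command fails."""
    try:
        yield
    except Exception:
        for p in paths:
            Path(p).unlink(missing_ok=True)
        raise


def _write_manifest(out_dir: Path, subcommand: str, options: dict, started: float) -> None:
    manifest = {
        "subcommand": subcommand,
        "options": {k: (str(v) if isinstance(v, Path) else v) for k, v in options.items()},
        "seed": options.get("seed"),
        "rarepool_version": _pkg_version("rarepool"),
        "wall_time_s": round(time.time() - started, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def _write_dataset(ds: simulate.SimulatedDataset, out_dir: Path) -> list[Path]:
    paths = {
        "genotypes": out_dir / "genotypes.tsv",
        "variants": out_dir / "variants.tsv",
        "regions": out_dir / "regions.tsv",
        "phenotypes": out_dir / "phenotypes.tsv",
        "truth": out_dir / "truth.tsv",
    }
    core.write_genotypes(ds.genotypes, ds.variants, paths["genotypes"], paths["variants"])
    core.write_regions(ds.regions, paths["regions"])
    core.write_phenotypes(ds.phenotype_frame(), paths["phenotypes"])
    core.write_truth(ds.truth, paths["truth"])
    return list(paths.values())


def _load_sim_config(preset: str | None, config_path: str | None, seed, n_replicates) -> simulate.SimulationConfig:
    if config_path:
        raw = yaml.safe_load(Path(config_path).read_text()) or {}
        nested = {
            "maf_distribution": simulate.MafDistribution,
            "binary_spec": simulate.BinaryTraitSpec,
            "confounding_spec": simulate.ConfoundingSpec,
        }
        kwargs = {}
        for k, v in raw.items():
            if k in nested and isinstance(v, dict):
                kwargs[k] = nested[k](**v)
            elif k == "causal_genes":
                kwargs[k] = [simulate.CausalGeneSpec(**c) for c in v]
            elif k == "trait_specs":
                kwargs[k] = [simulate.TraitSpec(**c) for c in v]
            elif k == "variants_per_gene":
                kwargs[k] = tuple(v)
            else:
                kwargs[k] = v
        cfg = simulate.SimulationConfig(**kwargs)
    elif preset:
        cfg = simulate.PRESETS[preset]()
    else:
        raise click.UsageError("supply --preset or --config")
    if seed is not None:
        cfg.seed = seed
    if n_replicates is not None:
        cfg.n_replicates = n_replicates
    return cfg


def _build_dataset(cfg: simulate.SimulationConfig) -> simulate.SimulatedDataset:
    if cfg.confounding_spec is not None:
        return simulate.make_confounded_null(cfg)
    return simulate.simulate_dataset(cfg)


@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def main(log_level: str) -> None:
    """Pooled rare-variant association testing (T1/T5, WS, VT)."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")


@main.command("simulate")
@click.option("--preset", type=click.Choice(sorted(simulate.PRESETS)), default=None)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="YAML SimulationConfig overriding the preset.")
@click.option("--out-dir", type=click.Path(), required=True)
@click.option("--seed", type=int, default=None)
@click.option("--n-replicates", type=int, default=None)
def simulate_cmd(preset, config_path, out_dir, seed, n_replicates):
    """Write a synthetic dataset (genotypes, variants, regions, phenotypes, truth)."""
    started = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = _load_sim_config(preset, config_path, seed, n_replicates)
    ds = _build_dataset(cfg)
    with _output_guard([]):
        written = _write_dataset(ds, out)
        with _output_guard(written):
            _write_manifest(out, "simulate", {
                "preset": preset, "config": config_path, "seed": cfg.seed,
                "n_replicates": cfg.n_replicates,
            }, started)
    click.echo(f"wrote dataset ({ds.genotypes.n_samples} samples, "
               f"{ds.genotypes.n_variants} variants, {len(ds.regions)} genes) to {out}")


def _load_inputs(genotypes, variants, regions, phenotypes, traits, binary_traits, covariates):
    gm, vtab = core.read_genotypes(genotypes, "matrix-tsv", variants_path=variants)
    vtab = core.compute_maf(gm, vtab)
    region_list = core.read_regions(regions)
    idx = core.map_variants_to_genes(vtab, region_list)
    pheno = core.read_phenotypes(
        phenotypes, traits=traits, binary_traits=binary_traits,
        covariates=covariates, replicate_col="replicate_id",
        genotype_sample_ids=gm.sample_ids,
    )
    return gm, vtab, idx, pheno


@main.command("test")
@click.option("--genotypes", type=click.Path(exists=True), required=True)
@click.option("--variants", type=click.Path(exists=True), required=True)
@click.option("--regions", type=click.Path(exists=True), required=True)
@click.option("--phenotypes", type=click.Path(exists=True), required=True)
@click.option("--trait", required=True)
@click.option("--binary-trait", "binary", is_flag=True, help="Trait column is {0,1}.")
@click.option("--covariates", default="Age,Smoking", show_default=True)
@click.option("--adjust", "adjust_names", default="",
              help="Comma-separated covariates to residualize on (empty = unadjusted).")
@click.option("--tests", default="T1,T5,WS,VT", show_default=True)
@click.option("--n-permutations", type=int, default=CLI_DEFAULT_N_PERM, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--sided", type=click.Choice(pooled.SIDEDNESS), default="one-sided-greater")
@click.option("--mode", type=click.Choice(["monte-carlo", "exhaustive"]), default="monte-carlo")
@click.option("--out-dir", type=click.Path(), required=True)
def test_cmd(genotypes, variants, regions, phenotypes, trait, binary, covariates,
             adjust_names, tests, n_permutations, seed, sided, mode, out_dir):
    """Run the selected tests per gene and replicate; one results file per replicate."""
    started = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    covs = [c for c in covariates.split(",") if c]
    adj = [c for c in adjust_names.split(",") if c]
    test_list = [t for t in tests.split(",") if t]
    gm, vtab, idx, pheno = _load_inputs(
        genotypes, variants, regions, phenotypes,
        traits=[] if binary else [trait],
        binary_traits=[trait] if binary else [],
        covariates=covs,
    )
    plan = pooled.PermutationPlan(n_perm=n_permutations, seed=seed, mode=mode)
    written: list[Path] = []
    with _output_guard(written):
        reps = run_association(gm, vtab, idx, pheno, trait, tests=test_list,
                               plan=plan, adjust_covariates=adj, sided=sided)
        for r, frame in enumerate(results_to_frames(reps)):
            path = out / f"results_{trait}_rep{r:03d}.tsv"
            frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
            written.append(path)
        _write_manifest(out, "test", {
            "trait": trait, "tests": test_list, "adjust": adj, "seed": seed,
            "n_permutations": n_permutations, "sided": sided, "mode": mode,
        }, started)
    click.echo(f"wrote {len(written)} replicate results files to {out}")


@main.command("evaluate")
@click.option("--results", "results_paths", type=click.Path(exists=True),
              multiple=True, required=True, help="Per-replicate results files, in order.")
@click.option("--truth", "truth_path", type=click.Path(exists=True), required=True)
@click.option("--genotypes", type=click.Path(exists=True), required=True)
@click.option("--variants", type=click.Path(exists=True), required=True)
@click.option("--regions", type=click.Path(exists=True), required=True)
@click.option("--tests", default="T1,T5,WS,VT", show_default=True)
@click.option("--out-prefix", type=click.Path(), required=True)
def evaluate_cmd(results_paths, truth_path, genotypes, variants, regions, tests, out_prefix):
    """Compute type I error / TPP / FPP / AUC from results + truth files."""
    started = time.time()
    test_list = [t for t in tests.split(",") if t]
    gm, vtab = core.read_genotypes(genotypes, "matrix-tsv", variants_path=variants)
    vtab = core.compute_maf(gm, vtab)
    idx = core.map_variants_to_genes(vtab, core.read_regions(regions))
    frames = [core.read_results(p) for p in results_paths]
    truth = core.read_truth(truth_path)
    result = run_evaluation(frames, truth, vtab, idx, tests=test_list)
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    metrics_path = prefix.with_suffix(".metrics.tsv")
    summary_path = prefix.with_suffix(".summary.tsv")
    with _output_guard([metrics_path, summary_path]):
        evaluate.write_evaluation(result, metrics_path, summary_path)
        _write_manifest(prefix.parent, "evaluate", {
            "results": [str(p) for p in results_paths], "truth": str(truth_path),
            "tests": test_list, "seed": None,
        }, started)
    click.echo(f"wrote {metrics_path} and {summary_path}")


@main.command("full")
@click.option("--preset", type=click.Choice(sorted(simulate.PRESETS)), required=True)
@click.option("--out-dir", type=click.Path(), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--n-replicates", type=int, default=None)
@click.option("--n-permutations", type=int, default=CLI_DEFAULT_N_PERM, show_default=True)
@click.option("--adjust", "adjust_names", default="", show_default=True)
def full_cmd(preset, out_dir, seed, n_replicates, n_permutations, adjust_names):
    """Simulate, test the first trait, and evaluate, all under one master seed."""
    started = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = _load_sim_config(preset, None, seed, n_replicates)
    ds = _build_dataset(cfg)
    trait = (cfg.trait_specs[0].name if cfg.trait_specs else "Q4")
    adj = [c for c in adjust_names.split(",") if c]
    plan = pooled.PermutationPlan(n_perm=n_permutations, seed=seed)
    written: list[Path] = []
    with _output_guard(written):
        written.extend(_write_dataset(ds, out))
        reps = run_association(ds.genotypes, ds.variants, ds.gene_index,
                               ds.phenotype_frame(), trait, plan=plan,
                               adjust_covariates=adj)
        frames = results_to_frames(reps)
        for r, frame in enumerate(frames):
            path = out / f"results_{trait}_rep{r:03d}.tsv"
            frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
            written.append(path)
        result = run_evaluation(frames, ds.truth, ds.variants, ds.gene_index)
        metrics_path = out / "evaluation.metrics.tsv"
        summary_path = out / "evaluation.summary.tsv"
        written.extend([metrics_path, summary_path])
        evaluate.write_evaluation(result, metrics_path, summary_path)
        _write_manifest(out, "full", {
            "preset": preset, "seed": seed, "n_replicates": cfg.n_replicates,
            "n_permutations": n_permutations, "adjust": adj, "trait": trait,
        }, started)
    click.echo(f"full run complete; outputs in {out}")


if __name__ == "__main__":  # pragma: no cover
    main()
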