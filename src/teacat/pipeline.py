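"""End-to-end orchestration and command-line interface.

Stages mirror the analysis chain: simulate -> screen (PLS/VIP) -> fit
(regression + error metrics) -> optimize (grouped LP) -> express (qPCR)
-> stats (correlation/PCA).  Every stochastic stage takes an explicit
seed and all outputs are CSVs in the schemas of the library modules, so
a fixed seed reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import optimize as opt
from . import pls, regression, stats, synth
from .core import CATECHINS, FACTORS, GROUPS, Dataset, ValidationError, read_dataset, write_dataset
from .expression import delta_delta_ct, hclust_leaf_order, log2_matrix
from .regression import CoefficientTable, load_table1

logger = logging.getLogger("teacat")

__all__ = ["run_pipeline", "make_demo_fixtures", "cli"]

_STAGES = ("simulate", "screen", "fit", "optimize", "express", "stats")


def _stage_log(stage: str, config: dict, **counts) -> None:
    digest = hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s config=%s %s", stage, digest, extras)


def _load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    return cfg


def run_pipeline(config: dict, out_dir: str | Path) -> dict[str, Path]:
    """Run the configured stages; returns {artifact name: path}.

    Config keys: ``seed`` (required), ``stages`` (subset of
    simulate/screen/fit/optimize/express/stats; default all), ``input``
    (CSV path; otherwise the simulate stage must run), ``generator``
    (overrides for the synthetic generator), ``precision`` (report
    decimals, default 2).
    """
    if "seed" in config and config["seed"] is not None:
        seed = int(config["seed"])
    else:
        raise ValidationError("config must set an explicit seed before any stage runs")
    stages = list(config.get("stages", _STAGES))
    unknown = sorted(set(stages) - set(_STAGES))
    if unknown:
        raise ValidationError(f"unknown stage(s): {unknown}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    precision = int(config.get("precision", 2))
    artifacts: dict[str, Path] = {}

    # -- data ---------------------------------------------------------------
    if "simulate" in stages:
        gen_cfg = dict(config.get("generator", {}))
        gen_cfg.setdefault("seed", seed)
        gcfg = synth.GeneratorConfig(**gen_cfg)
        dataset = synth.generate_dataset(gcfg)
        path = out_dir / "dataset.csv"
        write_dataset(dataset, path)
        artifacts["dataset"] = path
        _stage_log("simulate", gen_cfg, rows=dataset.n)
    elif "input" in config:
        dataset = read_dataset(config["input"])
        _stage_log("load", {"input": config["input"]}, rows=dataset.n)
    else:
        raise ValidationError("config needs either the simulate stage or an input path")

    responses = [c for c in CATECHINS if c in dataset.frame.columns]
    table: CoefficientTable | None = None

    if "screen" in stages:
        vt = pls.vip_table_for(dataset, responses)
        path = out_dir / "vip_table.csv"
        vt.to_csv(path)
        links = vt.links()
        links_path = out_dir / "vip_links.csv"
        links.to_csv(links_path, index=False)
        artifacts["vip_table"] = path
        artifacts["vip_links"] = links_path
        _stage_log("screen", {"responses": responses}, links=len(links))

    if "fit" in stages:
        models = {}
        train, test = regression.train_test_split(dataset, 0.3, seed=seed)
        for resp in responses:
            res = regression.CatechinLinearModel(dataset, resp).fit()
            cv = res.rmsecv("loo")
            rp = regression.rmsep(train, test, resp)
            models[resp] = res.to_model(rmsecv_value=cv, rmsep_value=rp)
        table = CoefficientTable(models, provenance="fitted")
        path = out_dir / "model_table.csv"
        table.to_csv(path)
        artifacts["model_table"] = path
        _stage_log("fit", {"responses": responses}, models=len(models))

    if "optimize" in stages:
        use_table = table if table is not None else load_table1()
        box = opt.box_from_dataset(dataset)
        frames = []
        for group in GROUPS:
            rep = opt.optimize_group_report(group, use_table, box, thresholds_source=dataset)
            rep.insert(0, "group", group)
            frames.append(rep)
        report = pd.concat(frames, ignore_index=True)
        num = report.select_dtypes(include=[np.number]).columns
        report[num] = report[num].round(precision)
        path = out_dir / "optimization_report.csv"
        report.to_csv(path, index=False)
        artifacts["optimization"] = path
        _stage_log("optimize", {"table": use_table.provenance}, targets=len(report))

    if "express" in stages:
        genes = dataset.expression_genes()
        if genes:
            sample_ids = [f"{r.site}_{r.season}" for r in dataset.frame.itertuples(index=False)]
            rel = pd.DataFrame(
                {s: dataset.frame.loc[i, ["expr_" + g for g in genes]].to_numpy(float)
                 for i, s in enumerate(sample_ids)},
                index=genes,
            )
            log2 = log2_matrix(rel)
            path = out_dir / "expression_matrix.csv"
            rel.to_csv(path, index_label="gene")
            order_path = out_dir / "leaf_order.txt"
            order = hclust_leaf_order(log2, axis="rows")
            order_path.write_text("\n".join(order) + "\n")
            artifacts["expression"] = path
            artifacts["leaf_order"] = order_path
            _stage_log("express", {"genes": genes}, genes=len(genes))
        else:
            logger.info("stage=express skipped: dataset has no expression columns")

    if "stats" in stages:
        corr = stats.pearson_with_stars(dataset, variables=list(FACTORS), columns=responses)
        path = out_dir / "correlation.csv"
        corr.to_long().to_csv(path, index=False)
        pca = stats.pca_catechins(dataset)
        pca_path = out_dir / "pca.csv"
        head = pca.to_frame()
        load = pca.loadings.reset_index().rename(columns={"index": "variable"})
        with open(pca_path, "w") as fh:
            head.to_csv(fh, index=False)
            fh.write("\n")
            load.to_csv(fh, index=False)
        artifacts["correlation"] = path
        artifacts["pca"] = pca_path
        _stage_log("stats", {}, pairs=len(corr.to_long()))

    return artifacts


def make_demo_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the published coefficient table, factor box and optimal
    condition vectors as ready-to-run CSV inputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table = load_table1()
    paths["table1"] = out_dir / "table1.csv"
    table.to_csv(paths["table1"])

    box = pd.DataFrame(
        [{"factor": f, "low": lo, "high": hi} for f, (lo, hi) in opt.DEMO_FACTOR_BOX.items()]
    )
    paths["factor_box"] = out_dir / "factor_box.csv"
    box.to_csv(paths["factor_box"], index=False)

    optima = pd.DataFrame(
        [{"target": t, **dict(zip(FACTORS, x))} for t, x in opt.OPTIMAL_CONDITIONS.items()]
    )
    paths["optima"] = out_dir / "optimal_conditions.csv"
    optima.to_csv(paths["optima"], index=False)
    return paths


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Enable INFO-level stage logging.")
def cli(verbose: bool) -> None:
    """Meteorological drivers of tea catechin accumulation."""
    logging.basicConfig(level=logging.INFO if verbose else logging.WARNING,
                        format="%(levelname)s %(message)s")


def _run_stages(config, seed, out, stages):
    cfg = _load_config(config) if config else {}
    if seed is not None:
        cfg["seed"] = seed
    if stages:
        cfg["stages"] = list(stages)
    try:
        artifacts = run_pipeline(cfg, out)
    except ValidationError as exc:
        raise click.exceptions.Exit(1) from exc
    for name, path in artifacts.items():
        click.echo(f"{name}: {path}")


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None, help="YAML config file.")
@click.option("--seed", type=int, default=None, help="Master seed (overrides config).")
@click.option("--out", type=click.Path(), required=True, help="Output directory.")
@click.option("--stage", "stages", multiple=True, type=click.Choice(_STAGES),
              help="Stage(s) to run; default all.")
def run(config, seed, out, stages):
    """Run the full pipeline (or selected stages)."""
    _run_stages(config, seed, out, stages)


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), required=True)
def simulate(config, seed, out):
    """Generate a synthetic site-season dataset."""
    _run_stages(config, seed, out, ("simulate",))


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), required=True)
def screen(config, seed, out):
    """PLS/VIP screening of meteorological factors."""
    _run_stages(config, seed, out, ("simulate", "screen"))


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), required=True)
def fit(config, seed, out):
    """Fit per-catechin regressions with RMSEC/RMSECV/RMSEP."""
    _run_stages(config, seed, out, ("simulate", "fit"))


@cli.command(name="optimize")
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), required=True)
def optimize_cmd(config, seed, out):
    """Grouped LP optimization of meteorological conditions."""
    _run_stages(config, seed, out, ("simulate", "fit", "optimize"))


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), required=True)
def express(config, seed, out):
    """qPCR relative-expression matrix and clustering order."""
    _run_stages(config, seed, out, ("simulate", "express"))


@cli.command(name="stats")
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), required=True)
def stats_cmd(config, seed, out):
    """Pearson correlation report and catechin PCA."""
    _run_stages(config, seed, out, ("simulate", "stats"))


@cli.command()
@click.option("--out", type=click.Path(), required=True)
@click.option("--precision", type=int, default=2, show_default=True)
def demo(out, precision):
    """Write the published-fixture inputs and the worked optimization examples."""
    paths = make_demo_fixtures(out)
    table = load_table1()
    problem = opt.OptimizationProblem("c", table, dict(opt.DEMO_FACTOR_BOX))
    result = opt.solve_lp(problem)
    egcg_at_opt = table["egcg"].predict(np.array(opt.OPTIMAL_CONDITIONS["egcg"]))
    tec_at_ecg_opt = sum(
        table[m].predict(np.array(opt.OPTIMAL_CONDITIONS["ecg"])) for m in GROUPS["TEC"]
    )
    rows = [
        {"quantity": "egcg_at_reported_optimum", "value": round(egcg_at_opt, precision)},
        {"quantity": "tec_at_ecg_optimum", "value": round(tec_at_ecg_opt, precision)},
        {"quantity": "c_box_lp_objective", "value": round(result.objective, precision)},
    ]
    report = Path(out) / "worked_examples.csv"
    pd.DataFrame(rows).to_csv(report, index=False)
    for name, path in {**paths, "worked_examples": report}.items():
        click.echo(f"{name}: {path}")


if __name__ == "__main__":
    cli()
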