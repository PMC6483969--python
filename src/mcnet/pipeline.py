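"""End-to-end pipeline orchestration with config, manifest, and provenance.

Stages run in a fixed order: model -> network -> salience -> mc -> qc ->
gwas -> conditional -> eqtl_decomposition.  A single master seed is fanned
out to deterministic per-stage seeds, and a run manifest (config snapshot,
input checksums, stage seeds, timestamps) is written next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import derive_seed, sha256_file
from .association import conditional_scan, gwas_scan, manhattan_qq_export
from .coherence import mc_profile, write_mc_tsv
from .eqtl_decomposition import (binary_distance, decompose_subclusters,
                                 min_p_per_gene, select_target_subcluster,
                                 trans_eqtl, ward_cluster, write_eqtl_tsv)
from .genetics import QCCriteria, read_panel_tsv, read_vcf, snp_qc, write_panel_tsv
from .network_builder import (project_gene_network, read_metabolic_model,
                              remove_currency_metabolites, restrict_to_measured,
                              write_edgelist, write_graphml)
from .salience import dichotomize, preprocess_counts, read_expression_tsv, write_salience_tsv
from .synthetic_data import SimulationConfig, make_fixture

__all__ = ["PipelineError", "run_pipeline", "DEFAULT_PARAMS"]

STAGES = ["model", "network", "salience", "mc", "qc", "gwas", "conditional",
          "eqtl_decomposition"]

DEFAULT_PARAMS = {
    "currency_fraction": 0.05,
    "quantile": 0.02,
    "null_draws": 2000,
    "min_call_rate": 0.99,
    "min_maf": 0.05,
    "min_minor_homs": 5,
    "min_hwe_p": 0.001,
    "alpha": 0.05,
    "k_max": 10,
    "adjust": ["population", "sex"],
    "gwas_enabled": True,
    "conditional_enabled": True,
    "eqtl_enabled": True,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _validate_config(cfg: dict) -> None:
    if "output_dir" not in cfg:
        raise ValueError("config must set output_dir")
    has_inputs = isinstance(cfg.get("inputs"), dict)
    has_sim = isinstance(cfg.get("simulate"), dict)
    if has_inputs == has_sim:
        raise ValueError("config must set exactly one of 'inputs' or 'simulate'")
    if has_inputs:
        required = {"model", "expression"}
        missing = required - set(cfg["inputs"])
        if missing:
            raise ValueError(f"inputs block missing {sorted(missing)}")
        for key, path in cfg["inputs"].items():
            if not Path(path).exists():
                raise ValueError(f"input {key!r} does not exist: {path}")
    params = cfg.get("params", {})
    unknown = set(params) - set(DEFAULT_PARAMS)
    if unknown:
        raise ValueError(f"unknown params: {sorted(unknown)}")


def run_pipeline(config_path: str | Path) -> Path:
    """Run all configured stages; returns the output directory.

    The YAML config names either an ``inputs`` block (model/expression/vcf/
    covariates paths) or a ``simulate`` block (SimulationConfig fields), plus
    ``params`` overriding the default thresholds and a master ``seed``.
    """
    config_path = Path(config_path)
    with open(config_path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    _validate_config(cfg)

    params = {**DEFAULT_PARAMS, **cfg.get("params", {})}
    master_seed = int(cfg.get("seed", 0))
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    stage_seeds = {s: derive_seed(master_seed, i) for i, s in enumerate(STAGES)}
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "master_seed": master_seed,
        "stage_seeds": stage_seeds,
        "stages": [],
        "inputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def record(stage: str, outputs: list[Path]) -> None:
        manifest["stages"].append({
            "name": stage,
            "seed": stage_seeds[stage],
            "outputs": [str(p.name) for p in outputs],
        })

    # stage: model ---------------------------------------------------------
    stage = "model"
    try:
        if "simulate" in cfg:
            sim_cfg = SimulationConfig(**{**cfg["simulate"], "seed": master_seed})
            fixture_dir = outdir / "fixture"
            paths = make_fixture(sim_cfg, fixture_dir)
            inputs = {k: str(v) for k, v in paths.items()}
        else:
            inputs = dict(cfg["inputs"])
        for key in ("model", "expression", "vcf", "covariates"):
            if key in inputs and Path(inputs[key]).exists():
                manifest["inputs"][key] = sha256_file(inputs[key])
        model = read_metabolic_model(inputs["model"])
        record(stage, [])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # stage: network -------------------------------------------------------
    stage = "network"
    try:
        expr = read_expression_tsv(inputs["expression"])
        if params.get("preprocess_counts"):
            expr = preprocess_counts(expr.values)
        pruned, currency_report = remove_currency_metabolites(
            model, params["currency_fraction"])
        network = restrict_to_measured(project_gene_network(pruned), expr.genes)
        edges_path = outdir / "network_edges.tsv"
        write_edgelist(network, edges_path)
        graphml_path = outdir / "network.graphml"
        write_graphml(network, graphml_path)
        record(stage, [edges_path, graphml_path])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # stage: salience ------------------------------------------------------
    stage = "salience"
    try:
        sal = dichotomize(expr, params["quantile"])
        sal_path = outdir / "salience.tsv"
        write_salience_tsv(sal, sal_path)
        record(stage, [sal_path])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # stage: mc ------------------------------------------------------------
    stage = "mc"
    try:
        profile = mc_profile(network, sal, n_draws=params["null_draws"],
                             seed=stage_seeds[stage],
                             currency_fraction=params["currency_fraction"])
        mc_path = outdir / "mc.tsv"
        write_mc_tsv(profile, mc_path)
        record(stage, [mc_path])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # stage: qc ------------------------------------------------------------
    stage = "qc"
    panel = None
    try:
        if "vcf" in inputs:
            panel = read_vcf(inputs["vcf"])
        elif "panel" in inputs:
            panel = read_panel_tsv(inputs["panel"])
        if panel is not None:
            criteria = QCCriteria(params["min_call_rate"], params["min_maf"],
                                  params["min_minor_homs"], params["min_hwe_p"])
            panel, qc_report = snp_qc(panel, criteria)
            panel_path = outdir / "panel_qc.tsv"
            report_path = outdir / "qc_report.tsv"
            write_panel_tsv(panel, panel_path)
            qc_report.to_csv(report_path, sep="\t")
            record(stage, [panel_path, report_path])
        else:
            record(stage, [])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    covars = None
    if "covariates" in inputs:
        covars = pd.read_csv(inputs["covariates"], sep="\t", index_col=0)
        covars.index = covars.index.astype(str)

    # stage: gwas ----------------------------------------------------------
    stage = "gwas"
    top_snp = None
    try:
        if panel is not None and params["gwas_enabled"]:
            results = gwas_scan(profile, panel, covars, adjust=params["adjust"])
            gwas_path = outdir / "gwas.tsv"
            results.to_csv(gwas_path, sep="\t", index=False, float_format="%.6g")
            usable = results.dropna(subset=["p"])
            if not usable.empty:
                top_snp = usable.loc[usable["p"].idxmin(), "snp"]
                manhattan, qq, lam = manhattan_qq_export(results)
                manhattan.to_csv(outdir / "manhattan.tsv", sep="\t", index=False)
                qq.to_csv(outdir / "qq.tsv", sep="\t", index=False)
                (outdir / "lambda_gc.txt").write_text(f"{lam:.6g}\n")
            record(stage, [gwas_path])
        else:
            record(stage, [])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # stage: conditional ---------------------------------------------------
    stage = "conditional"
    try:
        if panel is not None and params["gwas_enabled"] and \
                params["conditional_enabled"] and top_snp is not None:
            cond = conditional_scan(profile, panel, covars,
                                    adjust=params["adjust"], top_snp=top_snp)
            cond_path = outdir / "conditional.tsv"
            cond.to_csv(cond_path, sep="\t", index=False, float_format="%.6g")
            record(stage, [cond_path])
        else:
            record(stage, [])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # stage: eqtl_decomposition -------------------------------------------
    stage = "eqtl_decomposition"
    try:
        if panel is not None and params["eqtl_enabled"]:
            net_genes = [g for g in expr.genes if g in network.nodes]
            expr_net = read_expression_tsv(inputs["expression"])
            expr_net.values = expr_net.values.loc[net_genes]
            eqtl = trans_eqtl(expr_net, panel)
            eqtl_path = outdir / "eqtl_p.tsv"
            write_eqtl_tsv(eqtl, eqtl_path)
            gene_min_p = min_p_per_gene(eqtl)
            sal_net = sal.states.loc[net_genes]
            nonzero = sal_net.index[sal_net.sum(axis=1) > 0]
            dist = binary_distance(
                type(sal)(sal_net.loc[nonzero], q=sal.q, dataset=sal.dataset))
            outputs = [eqtl_path]
            if len(nonzero) >= 2:
                dendro = ward_cluster(dist)
                (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
                decomp = decompose_subclusters(dendro, gene_min_p,
                                               alpha=params["alpha"],
                                               k_max=params["k_max"])
                summary = pd.DataFrame(
                    {"k": list(decomp.kw_p_by_k), "kw_p": list(decomp.kw_p_by_k.values())})
                summary.to_csv(outdir / "decomposition_summary.tsv", sep="\t", index=False)
                outputs.append(outdir / "decomposition_summary.tsv")
                if decomp.n_subclusters is not None:
                    decomp.labels.to_csv(outdir / "subcluster_labels.tsv", sep="\t",
                                         index_label="gene")
                    target = select_target_subcluster(decomp)
                    (outdir / "target_subcluster.txt").write_text(
                        "\n".join(sorted(target)) + "\n")
                    outputs += [outdir / "subcluster_labels.tsv",
                                outdir / "target_subcluster.txt"]
            record(stage, outputs)
        else:
            record(stage, [])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return outdir
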