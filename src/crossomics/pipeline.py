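"""End-to-end orchestration of the four analysis stages.

Stage order (mirrors the study workflow): meta-integration of gene and
miRNA layers -> pathway impact -> prize-collecting Steiner module ->
miRNA attachment and regulation-pattern classification.  A single
global seed is fanned out to per-stage seeds through a numpy
SeedSequence spawn (stage index = spawn position), so any stage re-run
in isolation with its manifest seed reproduces bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .containers import ConfigurationError, OmicsMatrix
from . import io as cio
from .integration import integrate, two_group_t_vec
from .mirna import (ClassificationThresholds, build_bipartite, classify_module,
                    mirna_gene_correlations, screen_pairs, select_mirnas)
from .pathways import run_pathway_impact
from .steiner import calibrate_lambda, find_module, select_candidates
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "PipelineConfig", "ResultsBundle", "run_analysis",
           "run_pipeline"]

_STAGES = ("integration", "pathways", "module", "mirna", "calibration")


@dataclass(frozen=True)
class PipelineParams:
    """Analysis thresholds and options (paths live in PipelineConfig)."""

    alpha_seed: float = 0.05
    q_candidates: float = 0.05
    p_candidates: float = 0.05
    corr_cutoff: float = -0.55
    alpha_mirna: float = 0.05
    integration_method: str = "exact_convolution"
    permutation_scheme: str = "auto"
    n_perm: int = 10_000
    n_boot: int = 1000
    lam: float | str = "calibrate"   # fixed value in (0,1] or "calibrate"
    recovery_target: float = 0.70
    calibration_sims: int = 10
    allow_linkers: bool = True
    pattern_thresholds: ClassificationThresholds = ClassificationThresholds()

    def __post_init__(self) -> None:
        if isinstance(self.lam, str):
            if self.lam != "calibrate":
                raise ConfigurationError("lam must be a number in (0,1] or 'calibrate'")
        elif not 0 < float(self.lam) <= 1:
            raise ConfigurationError("fixed lambda must lie in (0, 1]")
        if self.corr_cutoff >= 0:
            raise ConfigurationError("corr_cutoff must be negative")


@dataclass(frozen=True)
class PipelineConfig:
    """File-based pipeline configuration (see io module for formats)."""

    expression: str
    methylation: str
    mirna_expression: str
    mirna_methylation: str
    samples: str
    interactome: str
    pathways_gmt: str
    pathway_topology: str
    target_map: str
    outdir: str
    seed: int = 0
    params: PipelineParams = PipelineParams()

    @classmethod
    def from_json(cls, path, **overrides) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text())
        doc.update({k: v for k, v in overrides.items() if v is not None})
        params = doc.pop("params", {})
        missing = [f for f in ("expression", "methylation", "mirna_expression",
                               "mirna_methylation", "samples", "interactome",
                               "pathways_gmt", "pathway_topology", "target_map",
                               "outdir") if f not in doc]
        if missing:
            raise ConfigurationError(f"config is missing required fields: {missing}")
        if "pattern_thresholds" in params:
            params["pattern_thresholds"] = ClassificationThresholds(
                **params["pattern_thresholds"])
        return cls(params=PipelineParams(**params), **doc)


@dataclass
class ResultsBundle:
    gene_integration: pd.DataFrame
    mirna_integration: pd.DataFrame
    mirna_expression_p: pd.Series
    pathway_table: pd.DataFrame
    candidates: set
    lam: float
    lambda_report: pd.DataFrame | None
    module: Any
    module_graph: Any
    validated_pairs: pd.DataFrame
    pattern_table: pd.DataFrame
    network: Any
    manifest: dict


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(_STAGES, children)}


def run_analysis(
    expression: OmicsMatrix,
    methylation: OmicsMatrix,
    mirna_expression: OmicsMatrix,
    mirna_methylation: OmicsMatrix,
    interactome_edges: pd.DataFrame,
    pathways: list,
    target_map: pd.DataFrame,
    seed: int = 0,
    params: PipelineParams = PipelineParams(),
) -> ResultsBundle:
    """Run the full analysis on in-memory inputs."""
    seeds = _stage_seeds(seed)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    gene_tbl = integrate(
        {"exp": expression, "methy": methylation},
        method=params.integration_method, scheme=params.permutation_scheme,
        n_perm=params.n_perm, seed=seeds["integration"])
    # miRNA integration: only miRNAs with both layers integrate at D=2;
    # the remainder are assessed on expression alone
    em_ids = [m for m in mirna_methylation.feature_ids
              if m in set(mirna_expression.feature_ids)]
    mirna_tbl = integrate(
        {"exp": OmicsMatrix(mirna_expression.values.loc[em_ids],
                            mirna_expression.groups),
         "methy": OmicsMatrix(mirna_methylation.values.loc[em_ids],
                              mirna_methylation.groups)},
        method=params.integration_method, scheme=params.permutation_scheme,
        n_perm=params.n_perm, seed=seeds["integration"] + 1) if em_ids else pd.DataFrame()
    t_mirna = two_group_t_vec(mirna_expression.values.to_numpy(dtype=float),
                              mirna_expression.high_mask())
    df = 2 * (expression.high_mask().sum()) - 2  # balanced designs
    mirna_expr_p = pd.Series(2 * stats.t.sf(np.abs(t_mirna), df),
                             index=mirna_expression.feature_ids)
    timings["integration"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pathway_tbl = run_pathway_impact(
        pathways, gene_tbl, expression, alpha=params.alpha_seed,
        n_boot=params.n_boot, seed=seeds["pathways"])
    timings["pathways"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    members = {p.pathway_id: p.members for p in pathways}
    candidates = select_candidates(
        gene_tbl, pathway_tbl, members,
        q_thresh=params.q_candidates, p_thresh=params.p_candidates)
    interactome = cio.edge_list_to_graph(interactome_edges)
    lam_report = None
    if params.lam == "calibrate":
        present = candidates & set(interactome.nodes)
        n_nodes = max(len(present), 10)
        sub = interactome.subgraph(present)
        possible = n_nodes * (n_nodes - 1) / 2
        density = min(0.5, max(0.02, sub.number_of_edges() / possible if possible else 0.05))
        lam, lam_report = calibrate_lambda(
            n_nodes=n_nodes, density=density,
            n_essential=max(3, int(0.4 * n_nodes)),
            recovery_target=params.recovery_target,
            n_sim=params.calibration_sims, seed=seeds["calibration"])
    else:
        lam = float(params.lam)
    module, module_graph = find_module(
        candidates, interactome, expression, gene_tbl, lam,
        allow_linkers=params.allow_linkers, methylation=methylation)
    timings["module"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cands = select_mirnas(mirna_tbl if len(mirna_tbl) else None, mirna_expr_p,
                          alpha=params.alpha_mirna)
    corr = mirna_gene_correlations(
        mirna_expression, expression, module.nodes,
        mirnas=[c.mirna_id for c in cands])
    pairs = screen_pairs(corr, target_map.itertuples(index=False, name=None),
                         cutoff=params.corr_cutoff)
    methyl_p = {}
    common = [g for g in module.nodes if g in set(methylation.feature_ids)]
    if common:
        t_m = two_group_t_vec(methylation.values.loc[common].to_numpy(dtype=float),
                              methylation.high_mask())
        methyl_p = dict(zip(common, 2 * stats.t.sf(np.abs(t_m), df)))
    pattern_tbl = classify_module(
        module_graph, module, expression, methylation, methyl_p, pairs,
        thresholds=params.pattern_thresholds)
    network = build_bipartite(module, pairs, pattern_tbl, module_graph) \
        if not module.is_empty else None
    timings["mirna"] = time.perf_counter() - t0

    manifest = {
        "version": __version__,
        "seed": int(seed),
        "stage_seeds": seeds,
        "lambda": lam,
        "params_hash": hashlib.sha256(
            json.dumps(asdict(params), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_genes": int(len(gene_tbl)),
        "n_mirnas_em": int(len(mirna_tbl)),
        "module_size": len(module),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    return ResultsBundle(
        gene_integration=gene_tbl, mirna_integration=mirna_tbl,
        mirna_expression_p=mirna_expr_p, pathway_table=pathway_tbl,
        candidates=candidates, lam=lam, lambda_report=lam_report,
        module=module, module_graph=module_graph, validated_pairs=pairs,
        pattern_table=pattern_tbl, network=network, manifest=manifest,
    )


def write_results(bundle: ResultsBundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    drop = [c for c in bundle.gene_integration.columns if c.startswith("_")]
    bundle.gene_integration.drop(columns=drop).to_csv(
        out / "gene_integration.tsv", sep="\t", float_format="%.17g")
    if len(bundle.mirna_integration):
        drop = [c for c in bundle.mirna_integration.columns if c.startswith("_")]
        bundle.mirna_integration.drop(columns=drop).to_csv(
            out / "mirna_integration.tsv", sep="\t", float_format="%.17g")
    bundle.pathway_table.to_csv(out / "pathway_impact.tsv", sep="\t",
                                float_format="%.17g")
    if bundle.lambda_report is not None:
        bundle.lambda_report.to_csv(out / "lambda_sweep.tsv", sep="\t", index=False,
                                    float_format="%.17g")
    node_rows = [{"gene": g, **{k: v for k, v in bundle.module_graph.nodes[g].items()}}
                 for g in bundle.module.nodes]
    pd.DataFrame(node_rows).to_csv(out / "module_nodes.tsv", sep="\t", index=False,
                                   float_format="%.17g")
    pd.DataFrame(list(bundle.module.edges), columns=["u", "v", "cost"]).to_csv(
        out / "module_edges.tsv", sep="\t", index=False, float_format="%.17g")
    bundle.validated_pairs.to_csv(out / "mirna_pairs.tsv", sep="\t", index=False,
                                  float_format="%.17g")
    bundle.pattern_table.to_csv(out / "regulation_patterns.tsv", sep="\t",
                                float_format="%.17g")
    if bundle.network is not None:
        cio.write_graphml(bundle.network, out / "network.graphml")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=1,
                                                  sort_keys=True))


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """File-based wrapper: read inputs, run the analysis, write outputs."""
    groups = cio.read_group_labels(config.samples)
    def matrix(path):
        return OmicsMatrix(cio.read_matrix_tsv(path), groups)
    bundle = run_analysis(
        expression=matrix(config.expression),
        methylation=matrix(config.methylation),
        mirna_expression=matrix(config.mirna_expression),
        mirna_methylation=matrix(config.mirna_methylation),
        interactome_edges=cio.read_edge_list(config.interactome),
        pathways=cio.read_pathways(config.pathways_gmt, config.pathway_topology),
        target_map=cio.read_target_map(config.target_map),
        seed=config.seed, params=config.params,
    )
    write_results(bundle, config.outdir)
    return bundle
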