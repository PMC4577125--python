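"""miRNA attachment and regulation-pattern classification.

miRNAs associated with the phenotype (integrated p <= alpha when both
expression and methylation are measured, class EM; expression-only p
otherwise, class E) are correlated with the expression of the module
genes.  Pairs with Pearson r at or below the negative cutoff (default
-0.55) enter the network; pairs additionally present in the supplied
miRNA->target map are "target-supported" and are the only ones that
count as miRNA regulation evidence.

Each module gene is then assigned one of four regulation patterns:

1. METHYLATION - differential promoter methylation anti-correlated
   with expression;
2. MIRNA - a target-supported anti-correlated differential miRNA;
3. NEIGHBOR_TF - neither of the above, but a module neighbour whose
   expression is strongly positively correlated (a transcription-factor
   style explanation);
4. CO_REGULATED - methylation and miRNA evidence simultaneously;

genes with none of the above stay UNCLASSIFIED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
import pandas as pd

from .containers import ConfigurationError, OmicsMatrix
from .steiner import SteinerModule

logger = logging.getLogger(__name__)

__all__ = [
    "MiRNACandidate",
    "RegulatoryAssignment",
    "ClassificationThresholds",
    "select_mirnas",
    "mirna_gene_correlations",
    "screen_pairs",
    "classify_regulation",
    "classify_module",
    "build_bipartite",
]

PATTERNS = ("METHYLATION", "MIRNA", "NEIGHBOR_TF", "CO_REGULATED", "UNCLASSIFIED")


@dataclass(frozen=True)
class MiRNACandidate:
    mirna_id: str
    klass: str  # "EM" or "E"
    p_select: float

    def __post_init__(self) -> None:
        if self.klass not in ("EM", "E"):
            raise ConfigurationError("miRNA class must be 'EM' or 'E'")
        if not 0 < self.p_select <= 1:
            raise ConfigurationError("p_select must lie in (0, 1]")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Evidence thresholds for the four regulation patterns."""

    alpha_methyl: float = 0.10    # nominal methylation p-value
    rho_neg: float = -0.55        # anti-correlation cutoff (methyl & miRNA)
    rho_pos: float = 0.55         # neighbour positive-correlation cutoff


@dataclass
class RegulatoryAssignment:
    gene_id: str
    pattern: str
    methylation_assoc: bool = False
    methyl_corr: float | None = None
    mirna_partner: str | None = None
    mirna_corr: float | None = None
    neighbor_partner: str | None = None
    neighbor_corr: float | None = None

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ConfigurationError(f"unknown pattern {self.pattern!r}")


def select_mirnas(
    mirna_integration: pd.DataFrame | None,
    mirna_expression_p: pd.Series,
    alpha: float = 0.05,
) -> list[MiRNACandidate]:
    """Phenotype-associated miRNAs, split into EM and E classes.

    ``mirna_integration`` is the integration table for miRNAs with both
    expression and methylation (may be None/empty); ``mirna_expression_p``
    maps every expression-measured miRNA to its expression-only
    two-group p-value.  A miRNA in both tables is classified EM only.
    """
    out: list[MiRNACandidate] = []
    em_ids: set[str] = set()
    if mirna_integration is not None and len(mirna_integration):
        em_ids = set(mirna_integration.index)
        hits = mirna_integration[mirna_integration["p_inte"] <= alpha]
        out.extend(MiRNACandidate(str(m), "EM", float(p))
                   for m, p in hits["p_inte"].items())
    e_hits = mirna_expression_p[(mirna_expression_p <= alpha)
                                & ~mirna_expression_p.index.isin(em_ids)]
    out.extend(MiRNACandidate(str(m), "E", float(p)) for m, p in e_hits.items())
    return sorted(out, key=lambda c: (c.klass, c.mirna_id))


def mirna_gene_correlations(
    mirna_expr: OmicsMatrix,
    gene_expr: OmicsMatrix,
    module_genes: Iterable[str],
    mirnas: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Pearson r for every (miRNA, module gene) pair over shared samples.

    Constant vectors make the correlation undefined; such miRNAs/genes
    are excluded with a log entry (their rows/columns are dropped).
    """
    if not mirna_expr.same_samples_as(gene_expr):
        raise ConfigurationError("miRNA and gene matrices must share the sample design")
    genes = [g for g in sorted(set(module_genes)) if g in gene_expr.values.index]
    rows = sorted(set(mirnas) & set(mirna_expr.values.index)) if mirnas is not None \
        else list(mirna_expr.values.index)
    M = mirna_expr.values.loc[rows].to_numpy(dtype=float)
    E = gene_expr.values.loc[genes].to_numpy(dtype=float)
    const_m = M.std(axis=1) == 0
    const_g = E.std(axis=1) == 0
    if const_m.any():
        logger.warning("excluding %d constant miRNA vectors", int(const_m.sum()))
    if const_g.any():
        logger.warning("excluding %d constant gene vectors", int(const_g.sum()))
    rows = [r for r, c in zip(rows, const_m) if not c]
    genes = [g for g, c in zip(genes, const_g) if not c]
    M, E = M[~const_m], E[~const_g]
    if not rows or not genes:
        return pd.DataFrame(index=rows, columns=genes, dtype=float)
    Mz = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, keepdims=True)
    Ez = (E - E.mean(axis=1, keepdims=True)) / E.std(axis=1, keepdims=True)
    R = (Mz @ Ez.T) / M.shape[1]
    return pd.DataFrame(np.clip(R, -1.0, 1.0), index=rows, columns=genes)


def screen_pairs(
    correlations: pd.DataFrame,
    target_map: Iterable[tuple[str, str]],
    cutoff: float = -0.55,
) -> pd.DataFrame:
    """Keep (miRNA, gene) pairs with r <= cutoff; flag target support.

    All kept pairs are reported (they appear in the displayed network),
    but only target-supported ones count as regulation evidence.
    """
    if cutoff >= 0:
        raise ConfigurationError("correlation cutoff must be negative")
    targets = {(str(m), str(g)) for m, g in target_map}
    rows = []
    for mirna in correlations.index:
        for gene in correlations.columns:
            r = correlations.loc[mirna, gene]
            if pd.isna(r) or r > cutoff:
                continue
            rows.append({"mirna": mirna, "gene": gene, "r": float(r),
                         "target_supported": (mirna, gene) in targets})
    return pd.DataFrame(rows, columns=["mirna", "gene", "r", "target_supported"])


def classify_regulation(
    gene: str,
    methyl_p: float | None,
    methyl_corr: float | None,
    validated_pairs: pd.DataFrame,
    neighbor_corrs: Mapping[str, float],
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> RegulatoryAssignment:
    """Assign one of the four regulation patterns to a module gene.

    ``neighbor_corrs`` maps the gene's module neighbours to the Pearson
    correlation of their expression with this gene's expression.
    Missing methylation data (None) simply means no methylation
    evidence.
    """
    th = thresholds
    methyl_evidence = (
        methyl_p is not None and methyl_corr is not None
        and methyl_p <= th.alpha_methyl and methyl_corr <= th.rho_neg
    )
    if methyl_p is None or methyl_corr is None:
        logger.info("gene %s: no methylation data; methylation evidence absent", gene)
    partner, partner_r = None, None
    if len(validated_pairs):
        mine = validated_pairs[(validated_pairs["gene"] == gene)
                               & validated_pairs["target_supported"]]
        if len(mine):
            hit = mine.sort_values(["r", "mirna"]).iloc[0]
            partner, partner_r = str(hit["mirna"]), float(hit["r"])
    mirna_evidence = partner is not None

    if methyl_evidence and mirna_evidence:
        pattern = "CO_REGULATED"
    elif methyl_evidence:
        pattern = "METHYLATION"
    elif mirna_evidence:
        pattern = "MIRNA"
    else:
        pattern = "UNCLASSIFIED"
    neighbor, neighbor_r = None, None
    if pattern == "UNCLASSIFIED" and neighbor_corrs:
        nb = max(sorted(neighbor_corrs), key=lambda n: neighbor_corrs[n])
        if neighbor_corrs[nb] >= th.rho_pos:
            pattern, neighbor, neighbor_r = "NEIGHBOR_TF", nb, float(neighbor_corrs[nb])
    return RegulatoryAssignment(
        gene_id=gene, pattern=pattern,
        methylation_assoc=methyl_evidence, methyl_corr=methyl_corr,
        mirna_partner=partner, mirna_corr=partner_r,
        neighbor_partner=neighbor, neighbor_corr=neighbor_r,
    )


def classify_module(
    module_graph: nx.Graph,
    module: SteinerModule,
    gene_expr: OmicsMatrix,
    methylation: OmicsMatrix | None,
    methyl_p: Mapping[str, float],
    validated_pairs: pd.DataFrame,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.DataFrame:
    """Classify every gene of a module; returns a tidy pattern table."""
    # neighbour evidence uses all interaction edges among module genes
    # (the module graph where available), not just the solution tree
    if module_graph is not None:
        tree = module_graph.subgraph(module.nodes)
    else:
        tree = nx.Graph()
        tree.add_nodes_from(module.nodes)
        tree.add_edges_from((u, v) for u, v, _ in module.edges)
    rows = []
    for gene in module.nodes:
        mp, mc = None, None
        if (methylation is not None and gene in methylation.values.index
                and gene in gene_expr.values.index):
            mp = methyl_p.get(gene)
            mc = float(np.corrcoef(gene_expr.values.loc[gene],
                                   methylation.values.loc[gene])[0, 1])
        ncorr = {}
        for nb in tree.neighbors(gene):
            if nb in gene_expr.values.index and gene in gene_expr.values.index:
                ncorr[nb] = float(np.corrcoef(gene_expr.values.loc[gene],
                                              gene_expr.values.loc[nb])[0, 1])
        a = classify_regulation(gene, mp, mc, validated_pairs, ncorr, thresholds)
        rows.append({
            "gene": a.gene_id, "pattern": a.pattern,
            "methylation_assoc": a.methylation_assoc, "methyl_p": mp,
            "methyl_corr": a.methyl_corr, "mirna_partner": a.mirna_partner,
            "mirna_corr": a.mirna_corr, "neighbor_partner": a.neighbor_partner,
            "neighbor_corr": a.neighbor_corr,
        })
    return pd.DataFrame(rows).set_index("gene")


def build_bipartite(
    module: SteinerModule,
    validated_pairs: pd.DataFrame,
    pattern_table: pd.DataFrame | None = None,
    module_graph: nx.Graph | None = None,
) -> nx.Graph:
    """Combined module + miRNA network.

    Union of the module tree edges (attribute ``cost``) and the
    screened miRNA-gene edges (attributes ``r`` and
    ``target_supported``).  Only miRNA edges touching module genes are
    included, so every miRNA node has degree >= 1.
    """
    if module.is_empty:
        raise ConfigurationError("module is empty; nothing to attach miRNAs to")
    G = nx.Graph()
    for g in module.nodes:
        attrs = {"kind": "gene"}
        if module_graph is not None and g in module_graph:
            attrs.update({k: v for k, v in module_graph.nodes[g].items()})
        if pattern_table is not None and g in pattern_table.index:
            attrs["pattern"] = pattern_table.loc[g, "pattern"]
        G.add_node(g, **attrs)
    for u, v, c in module.edges:
        G.add_edge(u, v, kind="interaction", cost=c)
    genes = set(module.nodes)
    for _, row in validated_pairs.iterrows():
        if row["gene"] not in genes:
            continue
        G.add_node(row["mirna"], kind="mirna")
        G.add_edge(row["mirna"], row["gene"], kind="mirna_target",
                   r=float(row["r"]), target_supported=bool(row["target_supported"]))
    return G
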