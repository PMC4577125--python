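"""Ground-truth-annotated synthetic multi-omics datasets.

Emulates the data structure of a small two-group (high vs low
phenotype) multi-omics study: a gene expression matrix, a gene-level
promoter methylation matrix, miRNA expression and miRNA methylation
matrices (all feature x sample, 5+5 samples by default), a weighted
gene-gene interactome, pathway definitions with signed directed
topology, and a miRNA->target map.

Planted structure (recorded in ``SyntheticDataset.truth``):

* a fraction of genes is differentially expressed between groups with a
  standardised mean difference ``effect_size`` (Cohen's d);
* a connected ``module_size``-gene module inside the interactome whose
  members are all differential and whose internal edges come from a
  higher-reliability stratum (Beta(5,2) vs Beta(2,5) background);
* each planted gene carries one of the four regulation patterns:
  METHYLATION and CO_REGULATED genes get promoter methylation coupled
  to expression with expected Pearson correlation ``methyl_anticorr``;
  MIRNA and CO_REGULATED genes are targeted by a planted differential
  miRNA whose expression is anti-correlated with the gene's;
  NEIGHBOR_TF genes carry expression evidence only;
* one pathway is seeded to overlap the planted differential set.

Gene-wise noise is independent Gaussian, which matches the pooled
t-test model of the integration stage and keeps closed-form power
calculations available for testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import ConfigurationError, OmicsMatrix, PathwaySpec

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dataset",
    "generate_interactome",
    "generate_pathway_topologies",
]

PATTERN_CYCLE = ("METHYLATION", "MIRNA", "NEIGHBOR_TF", "CO_REGULATED")

#: reliability strata for interactome edges
BACKGROUND_BETA = (2.0, 5.0)
MODULE_BETA = (5.0, 2.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic generator.

    Defaults mirror the emulated study: 5 samples per group, ~1% of
    2000 genes differential at d = 3, a planted 12-gene interactome
    module, and expression-methylation anti-correlation around -0.8 at
    coupled planted genes (the study reports gene-level correlations of
    -0.73 to -0.85).
    """

    n_genes: int = 2000
    n_mirnas: int = 200
    n_samples_per_group: int = 5
    frac_diff_genes: float = 0.01
    effect_size: float = 3.0
    methyl_anticorr: float = -0.8
    module_size: int = 12
    interactome_density: float = 0.005
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 40)
    targets_per_mirna: int = 5
    noise_sd: float = 1.0
    mirna_methyl_fraction: float = 0.6
    n_extra_diff_mirnas: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise ConfigurationError("seed must be an integer")
        for name in ("n_genes", "n_mirnas", "n_samples_per_group", "module_size",
                     "n_pathways", "targets_per_mirna"):
            if getattr(self, name) < (0 if name == "n_pathways" else 1):
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0.0 <= self.frac_diff_genes <= 1.0:
            raise ConfigurationError("frac_diff_genes must lie in [0, 1]")
        if not -1.0 <= self.methyl_anticorr <= 0.0:
            raise ConfigurationError("methyl_anticorr must lie in [-1, 0]")
        if self.module_size > self.n_genes:
            raise ConfigurationError("module_size cannot exceed n_genes")
        if not 0.0 < self.interactome_density < 1.0:
            raise ConfigurationError("interactome_density must lie in (0, 1)")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ConfigurationError("pathway_size_range must fit inside the gene universe")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not 0.0 <= self.mirna_methyl_fraction <= 1.0:
            raise ConfigurationError("mirna_methyl_fraction must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its planted ground truth."""

    expression: OmicsMatrix
    methylation: OmicsMatrix
    mirna_expression: OmicsMatrix
    mirna_methylation: OmicsMatrix
    interactome: pd.DataFrame          # columns node1, node2, reliability
    pathways: list[PathwaySpec]
    target_map: pd.DataFrame           # columns mirna, gene
    truth: dict
    config: SyntheticConfig


def _coupled_vector(z: np.ndarray, a: float, rng: np.random.Generator) -> np.ndarray:
    """-a * z + sqrt(1-a^2) * noise: expected correlation -a with z."""
    return -a * z + np.sqrt(max(0.0, 1.0 - a * a)) * rng.standard_normal(z.size)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate_interactome(
    gene_ids: Sequence[str] | int,
    density: float,
    module_nodes: Iterable[str] = (),
    seed: int | None = None,
) -> pd.DataFrame:
    """Erdos-Renyi interactome with a connectivity-guaranteed module.

    Background edges get reliabilities from Beta(2,5); edges added to
    make the module's induced subgraph connected (and any background
    edge inside the module) come from the higher Beta(5,2) stratum.
    Returns an edge list DataFrame (node1, node2, reliability).
    """
    if not 0.0 < density < 1.0:
        raise ConfigurationError("density must lie in (0, 1)")
    if isinstance(gene_ids, (int, np.integer)):
        gene_ids = [f"g{i:05d}" for i in range(int(gene_ids))]
    gene_ids = list(gene_ids)
    module = sorted(set(str(m) for m in module_nodes))
    unknown = set(module) - set(gene_ids)
    if unknown:
        raise ConfigurationError(f"module nodes outside gene universe: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    n = len(gene_ids)
    idx = np.triu_indices(n, k=1)
    hit = rng.uniform(size=idx[0].size) < density
    pairs = {(gene_ids[i], gene_ids[j]) for i, j in zip(idx[0][hit], idx[1][hit])}
    in_module = set(module)
    # ensure the module's induced subgraph is connected: union-find over
    # existing module-internal edges, then bridge the components randomly
    parent = {m: m for m in module}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for u, v in sorted(pairs):
        if u in in_module and v in in_module:
            parent[find(u)] = find(v)
    comps: dict[str, list[str]] = {}
    for m in module:
        comps.setdefault(find(m), []).append(m)
    comp_list = [sorted(c) for _, c in sorted(comps.items())]
    extra = []
    for a, b in zip(comp_list[:-1], comp_list[1:]):
        u = a[rng.integers(len(a))]
        v = b[rng.integers(len(b))]
        extra.append((u, v) if u < v else (v, u))
        parent[find(u)] = find(v)
    pairs |= set(extra)
    rows = []
    for u, v in sorted(pairs):
        stratum = MODULE_BETA if (u in in_module and v in in_module) else BACKGROUND_BETA
        rows.append((u, v, float(rng.beta(*stratum))))
    return pd.DataFrame(rows, columns=["node1", "node2", "reliability"])


def generate_pathway_topologies(
    n_pathways: int,
    size_range: tuple[int, int],
    gene_universe: Sequence[str],
    seed: int | None = None,
    planted_genes: Iterable[str] = (),
    min_overlap: int = 0,
) -> list[PathwaySpec]:
    """Random pathway memberships with signed directed DAG topologies.

    The first pathway is seeded to contain at least ``min_overlap``
    planted genes (capped by the pathway size and the planted set) so
    over-representation tests have a true positive; the overlap takes
    the planted genes in their given order, so passing the planted
    module first emulates a disease pathway that contains the module.
    Topology edges run from lower to higher member index (acyclic by
    construction) with beta = +1 (activation, 70%) or -1 (inhibition).
    """
    universe = list(gene_universe)
    if not universe:
        raise ConfigurationError("gene universe is empty")
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ConfigurationError("size_range must fit inside the universe")
    rng = np.random.default_rng(seed)
    seen = set(universe)
    planted = [g for g in planted_genes if g in seen]
    out = []
    for p in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members: list[str]
        if p == 0 and planted and min_overlap > 0:
            k = min(min_overlap, size, len(planted))
            chosen = list(planted[:k])
            rest_pool = [g for g in universe if g not in set(chosen)]
            rest = list(rng.choice(rest_pool, size=size - k, replace=False))
            members = chosen + rest
        else:
            members = list(rng.choice(universe, size=size, replace=False))
        members = sorted(members)
        edges = []
        p_edge = min(1.0, 2.0 / max(1, size - 1))
        for i, j in itertools.combinations(range(size), 2):
            if rng.uniform() < p_edge:
                beta = 1.0 if rng.uniform() < 0.7 else -1.0
                edges.append((members[i], members[j], beta))
        out.append(PathwaySpec.from_lists(f"pw{p:03d}", members, edges))
    return out


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic multi-omics dataset (deterministic per seed)."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (r_genes, r_expr, r_methyl, r_mirna, r_net, r_pw, r_tmap) = [
        np.random.default_rng(s) for s in ss.spawn(7)
    ]
    n = cfg.n_samples_per_group
    samples = [f"H{i+1}" for i in range(n)] + [f"L{i+1}" for i in range(n)]
    groups = pd.Series(["high"] * n + ["low"] * n, index=samples)
    group_sign = np.array([0.5] * n + [-0.5] * n)

    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    mirnas = [f"mir{i:04d}" for i in range(cfg.n_mirnas)]

    n_diff = int(round(cfg.frac_diff_genes * cfg.n_genes))
    diff_genes = sorted(r_genes.choice(genes, size=n_diff, replace=False)) if n_diff else []
    module_nodes = []
    if n_diff >= cfg.module_size and n_diff > 0:
        module_nodes = sorted(r_genes.choice(diff_genes, size=cfg.module_size,
                                             replace=False))
    ordered_planted = module_nodes + [g for g in diff_genes if g not in set(module_nodes)]
    patterns = {g: PATTERN_CYCLE[i % 4] for i, g in enumerate(ordered_planted)}
    # the module is a co-expressed unit: its genes shift in a common
    # direction (this is what makes neighbour/TF correlation evidence
    # possible); planted genes outside the module shift either way
    module_dir = 1.0 if r_genes.uniform() < 0.5 else -1.0
    directions = {g: (module_dir if g in set(module_nodes)
                      else (1.0 if r_genes.uniform() < 0.5 else -1.0))
                  for g in ordered_planted}

    # --- gene expression -------------------------------------------------
    base = r_expr.uniform(5.0, 10.0, size=cfg.n_genes)
    X = base[:, None] + cfg.noise_sd * r_expr.standard_normal((cfg.n_genes, 2 * n))
    gidx = {g: i for i, g in enumerate(genes)}
    for g in ordered_planted:
        X[gidx[g]] += directions[g] * cfg.effect_size * cfg.noise_sd * group_sign
    expression = OmicsMatrix(pd.DataFrame(X, index=genes, columns=samples), groups)

    # --- gene methylation ------------------------------------------------
    a = abs(cfg.methyl_anticorr)
    mbase = r_methyl.uniform(4.0, 9.0, size=cfg.n_genes)
    M = mbase[:, None] + r_methyl.standard_normal((cfg.n_genes, 2 * n))
    coupled = [g for g in ordered_planted if patterns[g] in ("METHYLATION", "CO_REGULATED")]
    for g in coupled:
        M[gidx[g]] = mbase[gidx[g]] + _coupled_vector(_zscore(X[gidx[g]]), a, r_methyl)
    methylation = OmicsMatrix(pd.DataFrame(M, index=genes, columns=samples), groups)

    # --- miRNA expression -------------------------------------------------
    regulated = [g for g in ordered_planted if patterns[g] in ("MIRNA", "CO_REGULATED")]
    if len(regulated) > cfg.n_mirnas:
        raise ConfigurationError("not enough miRNAs to regulate the planted genes")
    mirna_order = list(r_mirna.permutation(mirnas))
    regulators = {g: mirna_order[i] for i, g in enumerate(regulated)}
    extra_pool = mirna_order[len(regulated):]
    extra_diff = sorted(extra_pool[: cfg.n_extra_diff_mirnas])
    mirbase = r_mirna.uniform(3.0, 8.0, size=cfg.n_mirnas)
    Mi = mirbase[:, None] + r_mirna.standard_normal((cfg.n_mirnas, 2 * n))
    midx = {m: i for i, m in enumerate(mirnas)}
    for g, m in regulators.items():
        # anti-correlated with the target gene AND clearly differential:
        # the extra shift opposes the gene's direction, so it reinforces
        # rather than dilutes the anti-correlation
        Mi[midx[m]] = (mirbase[midx[m]]
                       + _coupled_vector(_zscore(X[gidx[g]]), a, r_mirna)
                       - directions[g] * (cfg.effect_size / 2.0) * group_sign)
    for m in extra_diff:
        sign = 1.0 if r_mirna.uniform() < 0.5 else -1.0
        Mi[midx[m]] += sign * cfg.effect_size * group_sign
    mirna_expression = OmicsMatrix(pd.DataFrame(Mi, index=mirnas, columns=samples), groups)

    # --- miRNA methylation (subset of the miRNA universe) -----------------
    n_with = max(1, int(round(cfg.mirna_methyl_fraction * cfg.n_mirnas)))
    with_methyl = sorted(r_mirna.choice(mirnas, size=n_with, replace=False))
    mm_base = r_mirna.uniform(4.0, 9.0, size=n_with)
    MM = mm_base[:, None] + r_mirna.standard_normal((n_with, 2 * n))
    diff_mirnas = sorted(set(regulators.values()) | set(extra_diff))
    for i, m in enumerate(with_methyl):
        if m in set(diff_mirnas):
            MM[i] = mm_base[i] + _coupled_vector(_zscore(Mi[midx[m]]), a, r_mirna)
    mirna_methylation = OmicsMatrix(
        pd.DataFrame(MM, index=with_methyl, columns=samples), groups)

    # --- interactome, pathways, target map --------------------------------
    interactome = generate_interactome(
        genes, cfg.interactome_density, module_nodes,
        seed=int(r_net.integers(2**31)))
    # the seeded pathway contains the planted module (disease-pathway
    # semantics) plus half of the remaining differential genes
    n_rest = max(0, len(diff_genes) - len(module_nodes))
    pathways = generate_pathway_topologies(
        cfg.n_pathways, cfg.pathway_size_range, genes,
        seed=int(r_pw.integers(2**31)),
        planted_genes=ordered_planted,
        min_overlap=max(3, len(module_nodes) + n_rest // 2),
    )
    tmap_rows = []
    taken: dict[str, set[str]] = {m: set() for m in mirnas}
    for g, m in regulators.items():
        tmap_rows.append((m, g))
        taken[m].add(g)
    for m in mirnas:
        pool = [g for g in genes if g not in taken[m]]
        extra = r_tmap.choice(pool, size=max(0, cfg.targets_per_mirna - len(taken[m])),
                              replace=False)
        tmap_rows.extend((m, str(g)) for g in extra)
    target_map = pd.DataFrame(sorted(tmap_rows), columns=["mirna", "gene"])

    truth = {
        "diff_genes": list(diff_genes),
        "diff_mirnas": list(diff_mirnas),
        "module_nodes": list(module_nodes),
        "patterns": dict(patterns),
        "directions": dict(directions),
        "regulators": dict(regulators),
        "methyl_coupled_genes": list(coupled),
        "mirnas_with_methylation": list(with_methyl),
        "seeded_pathway": pathways[0].pathway_id if pathways else None,
    }
    return SyntheticDataset(
        expression=expression, methylation=methylation,
        mirna_expression=mirna_expression, mirna_methylation=mirna_methylation,
        interactome=interactome, pathways=pathways, target_map=target_map,
        truth=truth, config=cfg,
    )
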