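"""Pathway impact analysis: over-representation plus topology perturbation.

Follows the signaling pathway impact analysis (SPIA) scheme: for each
pathway a hypergeometric over-representation p-value (P_NDE) for the
differentially expressed seed genes, and a perturbation p-value
(P_PERT) from propagating the seed genes' log fold-changes through the
signed directed pathway topology, combined into a single global
probability

    c = P_NDE * P_PERT,    P_G = c - c * ln(c).

Propagation solves PF = dE + B PF with B[i, j] = beta(j -> i) / N_ds(j)
(N_ds = number of downstream targets of j), i.e. PF = (I - B)^-1 dE.
The net accumulated perturbation of a pathway is
t_A = sum_g (PF(g) - dE(g)), and P_PERT is a median-centred two-sided
bootstrap p-value for t_A under random placement of resampled
fold-changes on the pathway.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError, OmicsMatrix, PathwaySpec
from .integration import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "SingularTopologyError",
    "select_seed_genes",
    "overrepresentation_p",
    "perturbation_factors",
    "perturbation_p",
    "combine_global",
    "run_pathway_impact",
]

#: pathways with fewer members measured on the array are skipped
MIN_MEASURED_MEMBERS = 3

_COND_LIMIT = 1e12


class SingularTopologyError(ConfigurationError):
    """(I - B) is singular: the propagation system has no unique solution."""


def select_seed_genes(
    integration_table: pd.DataFrame,
    expression: OmicsMatrix,
    alpha: float = 0.05,
) -> tuple[set[str], dict[str, float]]:
    """Seed genes (integrated p <= alpha) and their log2 fold-changes.

    dE(g) = mean expression in the high group minus mean in the low
    group (log2 scale assumed upstream); non-seed genes get dE = 0.
    """
    seeds = set(integration_table.index[integration_table["p_inte"] <= alpha])
    seeds &= set(expression.feature_ids)
    if not seeds:
        logger.warning("empty seed gene set at alpha=%g; all P_NDE will be 1", alpha)
    mask = expression.high_mask()
    X = expression.values.to_numpy(dtype=float)
    de = X[:, mask].mean(axis=1) - X[:, ~mask].mean(axis=1)
    de_map = dict(zip(expression.feature_ids, de))
    return seeds, {g: (de_map[g] if g in seeds else 0.0) for g in expression.feature_ids}


def overrepresentation_p(k: int, K: int, n: int, N: int) -> float:
    """Hypergeometric upper-tail P(X >= k) for k seed genes in a pathway.

    K = pathway size on the array, n = total seed genes, N = background.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ConfigurationError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class PerturbationResult:
    pf: dict[str, float]
    acc: dict[str, float]
    t_a: float


def _propagation_matrix(members: Sequence[str], topology) -> np.ndarray:
    idx = {g: i for i, g in enumerate(members)}
    out_degree = np.zeros(len(members))
    for src, tgt, _ in topology:
        if src in idx and tgt in idx:
            out_degree[idx[src]] += 1
    B = np.zeros((len(members), len(members)))
    for src, tgt, beta in topology:
        if src in idx and tgt in idx:
            B[idx[tgt], idx[src]] += beta / out_degree[idx[src]]
    return B


def perturbation_factors(
    pathway: PathwaySpec,
    delta_e: Mapping[str, float],
    members: Sequence[str] | None = None,
) -> PerturbationResult:
    """Propagate fold-changes through the pathway topology.

    ``members`` restricts the computation to the genes measured on the
    array (topology edges to unmeasured genes are dropped and the
    downstream counts recomputed accordingly).
    """
    members = sorted(members if members is not None else pathway.members)
    if not members:
        raise ConfigurationError(f"pathway {pathway.pathway_id} has no measured members")
    B = _propagation_matrix(members, pathway.topology)
    de = np.array([float(delta_e.get(g, 0.0)) for g in members])
    A = np.eye(len(members)) - B
    if np.linalg.cond(A) > _COND_LIMIT:
        raise SingularTopologyError(
            f"pathway {pathway.pathway_id}: (I - B) is singular or near-singular"
        )
    pf = np.linalg.solve(A, de)
    acc = pf - de
    return PerturbationResult(
        pf=dict(zip(members, pf)), acc=dict(zip(members, acc)), t_a=float(acc.sum())
    )


def perturbation_p(
    pathway: PathwaySpec,
    delta_e: Mapping[str, float],
    delta_e_pool: Sequence[float],
    members: Sequence[str] | None = None,
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Bootstrap perturbation p-value; returns (P_PERT, observed t_A).

    The null distribution of t_A places the same number of non-zero
    fold-changes (resampled from the pool of all seed-gene fold-changes)
    on random pathway genes.  P_PERT is two-sided around the null
    median and lower-bounded by 1/n_boot.
    """
    if n_boot < 100:
        raise ConfigurationError("n_boot must be >= 100")
    members = sorted(members if members is not None else pathway.members)
    obs = perturbation_factors(pathway, delta_e, members)
    pool = np.asarray([v for v in delta_e_pool], dtype=float)
    n_de = sum(1 for g in members if delta_e.get(g, 0.0) != 0.0)
    if pool.size == 0 or n_de == 0:
        return 1.0, obs.t_a
    rng = np.random.default_rng(seed)
    B = _propagation_matrix(members, pathway.topology)
    inv = np.linalg.inv(np.eye(len(members)) - B)
    acc_op = (inv - np.eye(len(members))).sum(axis=0)  # t_A = acc_op . dE (linearity)
    null = np.empty(n_boot)
    for b in range(n_boot):
        de = np.zeros(len(members))
        pos = rng.choice(len(members), size=min(n_de, len(members)), replace=False)
        de[pos] = rng.choice(pool, size=pos.size, replace=True)
        null[b] = float(acc_op @ de)
    med = float(np.median(null))
    count = int((np.abs(null - med) >= abs(obs.t_a - med) - 1e-12).sum())
    return max(count / n_boot, 1.0 / n_boot), obs.t_a


def combine_global(p_nde: float, p_pert: float) -> float:
    """Combine the two evidence p-values: c = P_NDE*P_PERT, P_G = c - c ln c."""
    if not (0 < p_nde <= 1 and 0 < p_pert <= 1):
        raise ConfigurationError("both p-values must lie in (0, 1]")
    c = p_nde * p_pert
    return float(c - c * math.log(c))


def run_pathway_impact(
    pathways: Sequence[PathwaySpec],
    integration_table: pd.DataFrame,
    expression: OmicsMatrix,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
    q_threshold: float = 0.20,
) -> pd.DataFrame:
    """Full pathway-impact stage over a pathway catalogue.

    Returns a DataFrame (one row per analysable pathway, sorted by P_G)
    with columns n_de, t_a, p_nde, q_nde, p_pert, q_pert, p_g, q_g,
    significant (q_g <= threshold OR q_nde <= threshold) and a
    ``flag`` column recording skips/inversion failures.
    """
    seeds, delta_e = select_seed_genes(integration_table, expression, alpha)
    background = set(expression.feature_ids)
    pool = [delta_e[g] for g in seeds]
    rng = np.random.default_rng(seed)
    rows = []
    for pw in pathways:
        measured = sorted(pw.members & background)
        if len(measured) < MIN_MEASURED_MEMBERS:
            logger.info("skipping pathway %s: only %d measured members",
                        pw.pathway_id, len(measured))
            continue
        k = len(set(measured) & seeds)
        p_nde = overrepresentation_p(k, len(measured), len(seeds & background), len(background))
        flag = ""
        try:
            p_pert, t_a = perturbation_p(
                pw, delta_e, pool, members=measured, n_boot=n_boot,
                seed=int(rng.integers(2**31)),
            )
        except SingularTopologyError:
            flag = "inversion_failed"
            p_pert, t_a = 1.0, float("nan")
            logger.warning("pathway %s: propagation matrix singular; P_PERT set to 1",
                           pw.pathway_id)
        rows.append({
            "pathway": pw.pathway_id, "n_measured": len(measured), "n_de": k,
            "t_a": t_a, "p_nde": p_nde, "p_pert": p_pert,
            "p_g": combine_global(p_nde, p_pert), "flag": flag,
        })
    if not rows:
        raise ConfigurationError("no pathway had enough measured members")
    out = pd.DataFrame(rows).set_index("pathway")
    for col in ("p_nde", "p_pert", "p_g"):
        out["q" + col[1:]] = bh_fdr(out[col].to_numpy())
    out["significant"] = (out["q_g"] <= q_threshold) | (out["q_nde"] <= q_threshold)
    return out.sort_values(["p_g", "pathway"], kind="stable")
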