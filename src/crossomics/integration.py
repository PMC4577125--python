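"""Meta-integration of per-omics two-group association scores.

For each feature g and omics layer k a pooled two-sample t statistic
S_gk contrasts the high vs low phenotype group.  S_gk is standardised
by its permutation standard deviation (all balanced relabelings of the
group labels), giving Z_gk, whose absolute value is half-normal under
the null of no association.  The combined score

    S_meta(g) = sum_k |Z_gk|

is referred to its null distribution to obtain an integrated p-value,
which is then Benjamini-Hochberg adjusted across features.

Four null models for S_meta are provided:

``exact_convolution`` (default)
    P(sum of D iid half-normals > s) by numerical convolution of the
    half-normal density (exact closed form for D = 1).
``paper_eq2``
    The closed form 1 - [2*Phi(s/sqrt(2)) - 1]**2, valid only for
    D = 2.  For two layers this is algebraically identical to the
    convolution tail: the region |z1| + |z2| <= s rotates by 45
    degrees into the axis-aligned square [-s/sqrt(2), s/sqrt(2)]^2,
    whose standard-bivariate-normal probability is the bracket squared.
``monte_carlo``
    Simulation estimate of the same tail.
``permutation``
    Pools the permuted S_meta values across all features of the same
    layer multiplicity D and uses the empirical tail.  This inherits
    whatever correlation/scale structure the data carries and is the
    most assumption-free option.
"""

from __future__ import annotations

import itertools
import logging
import math
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .containers import ConfigurationError, DegenerateDataError, OmicsMatrix, as_layer_dict

logger = logging.getLogger(__name__)

__all__ = [
    "two_group_t",
    "permutation_sd",
    "standardize",
    "combined_score",
    "combined_pvalue",
    "bh_fdr",
    "collapse_probes",
    "integrate",
]

#: above this many distinct balanced relabelings the permutation null is sampled
EXHAUSTIVE_LIMIT = 10_000


# ---------------------------------------------------------------------------
# scalar primitives
# ---------------------------------------------------------------------------

def two_group_t(values: Sequence[float], labels: Sequence[bool]) -> float:
    """Pooled-variance two-sample t statistic, high group minus low group.

    ``labels`` is a boolean mask marking the high-phenotype samples.
    Positive values mean higher measurements in the high group.
    """
    x = np.asarray(values, dtype=float)
    mask = np.asarray(labels, dtype=bool)
    if x.shape != mask.shape:
        raise ConfigurationError("values and labels must have equal length")
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n0 < 2:
        raise ConfigurationError("each group needs at least 2 samples")
    a, b = x[mask], x[~mask]
    sp2 = (a.var(ddof=1) * (n1 - 1) + b.var(ddof=1) * (n0 - 1)) / (n1 + n0 - 2)
    if sp2 <= 0:
        raise DegenerateDataError("zero pooled variance: t statistic undefined")
    return float((a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n0)))


def _balanced_masks(n: int, n_high: int, scheme: str, n_perm: int,
                    rng: np.random.Generator | None) -> tuple[np.ndarray, bool]:
    """All (or sampled) boolean masks with ``n_high`` True out of ``n``.

    Returns (masks, exhaustive_flag).  The identity labeling is always a
    member of the null set.
    """
    total = math.comb(n, n_high)
    if scheme == "auto":
        scheme = "exhaustive" if total <= EXHAUSTIVE_LIMIT else "sampled"
    if scheme == "exhaustive":
        masks = np.zeros((total, n), dtype=bool)
        for i, idx in enumerate(itertools.combinations(range(n), n_high)):
            masks[i, list(idx)] = True
        return masks, True
    if scheme != "sampled":
        raise ConfigurationError(f"unknown permutation scheme {scheme!r}")
    if n_perm < 2:
        raise ConfigurationError("n_perm must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    masks = np.zeros((n_perm, n), dtype=bool)
    masks[0, :n_high] = True  # identity slot; caller permutes columns into place
    for i in range(n_perm):
        if i == 0:
            continue
        masks[i, rng.choice(n, size=n_high, replace=False)] = True
    return masks, False


def permutation_sd(
    values: Sequence[float],
    labels: Sequence[bool],
    scheme: str = "exhaustive",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Standard deviation of the t statistic under balanced label permutation.

    ``scheme="exhaustive"`` enumerates all C(n, n_high) distinct
    relabelings (252 for the 5+5 design); ``"sampled"`` draws ``n_perm``
    relabelings (the identity included).  The exhaustive SD uses the
    full-population ddof=0; the sampled SD uses ddof=1.
    """
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant feature vector: permutation sd undefined")
    mask = np.asarray(labels, dtype=bool)
    n, n_high = x.size, int(mask.sum())
    rng = np.random.default_rng(seed)
    masks, exhaustive = _balanced_masks(n, n_high, scheme, n_perm, rng)
    if not exhaustive:
        masks[0] = mask
    ts = _t_matrix(x[None, :], masks)[:, 0]
    return float(ts.std(ddof=0 if exhaustive else 1))


def _t_matrix(X: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Pooled t statistics for every (relabeling, feature) pair.

    X is (features x samples); masks is (perms x samples) boolean.
    Returns (perms x features).
    """
    n = X.shape[1]
    n1 = int(masks[0].sum())
    n0 = n - n1
    M = masks.astype(float)
    total = X.sum(axis=1)
    total_sq = (X ** 2).sum(axis=1)
    s1 = M @ X.T                      # perms x features, group-1 sums
    q1 = M @ (X ** 2).T
    m1 = s1 / n1
    m0 = (total[None, :] - s1) / n0
    ss1 = q1 - n1 * m1 ** 2
    ss0 = (total_sq[None, :] - q1) - n0 * m0 ** 2
    sp2 = (ss1 + ss0) / (n - 2)
    sp2 = np.maximum(sp2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(sp2 * (1 / n1 + 1 / n0))
    return t


def standardize(s_gk: float, sd_gk: float) -> float:
    """Z_gk = S_gk / sd(S_gk)."""
    if sd_gk <= 0:
        raise ConfigurationError("permutation sd must be positive")
    return s_gk / sd_gk


def combined_score(z: Sequence[float]) -> float:
    """Combined cross-omics score: sum of absolute standardised scores."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ConfigurationError("need at least one standardised score")
    if not np.isfinite(z).all():
        raise ConfigurationError("standardised scores must be finite")
    return float(np.abs(z).sum())


# ---------------------------------------------------------------------------
# null distribution of the combined score
# ---------------------------------------------------------------------------

_GRID_DX = 1e-4
_GRID_MAX = 9.0  # per-component support; half-normal sf(9) ~ 2e-19


@lru_cache(maxsize=8)
def _half_normal_sum_sf_grid(d: int) -> tuple[np.ndarray, np.ndarray]:
    """Survival function of a sum of d iid half-normals on a fine grid."""
    x = np.arange(0.0, _GRID_MAX + _GRID_DX, _GRID_DX)
    f = 2.0 * stats.norm.pdf(x)
    fh = f.copy()
    fh[0] *= 0.5  # trapezoid endpoint weight; interior convolutions start at 0
    dens = f
    for _ in range(d - 1):
        dens = signal.fftconvolve(dens if dens is not f else fh, fh)[: d * x.size] * _GRID_DX
    grid = np.arange(dens.size) * _GRID_DX
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * _GRID_DX)])
    sf = np.clip(1.0 - cdf, 0.0, 1.0)
    return grid, sf


def combined_pvalue(
    s: float,
    d: int,
    method: str = "exact_convolution",
    mc_reps: int = 1_000_000,
    seed: int | None = None,
) -> float:
    """P-value of a combined score ``s`` over ``d`` omics layers.

    Under the null each |Z_gk| is standard half-normal, so the reference
    distribution is the d-fold convolution of half-normals (see module
    docstring for the available methods).
    """
    if s < 0:
        raise ConfigurationError("combined score must be non-negative")
    if d < 1:
        raise ConfigurationError("d must be >= 1")
    if s == 0:
        return 1.0
    if method == "paper_eq2":
        if d != 2:
            raise ConfigurationError("paper_eq2 closed form is defined for d=2 only")
        inner = 2.0 * stats.norm.cdf(s / math.sqrt(2.0)) - 1.0
        return float(min(max(1.0 - inner ** 2, 0.0), 1.0))
    if method == "exact_convolution":
        if d == 1:
            return float(2.0 * stats.norm.sf(s))
        grid, sf = _half_normal_sum_sf_grid(d)
        if s >= grid[-1]:
            return float(np.finfo(float).tiny)
        p = float(np.interp(s, grid, sf))
        return max(p, np.finfo(float).tiny)
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        hits = 0
        left = int(mc_reps)
        while left > 0:
            chunk = min(left, 2_000_000)
            sums = np.abs(rng.standard_normal((d, chunk))).sum(axis=0)
            hits += int((sums >= s).sum())
            left -= chunk
        return (hits + 1) / (mc_reps + 1)
    raise ConfigurationError(f"unknown p-value method {method!r}")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def collapse_probes(probe_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level results to feature level.

    Per feature, the probe with the smallest p-value is retained; ties
    are broken by larger |score|, then lexicographic probe id.  Probes
    without a feature mapping are dropped with a warning.

    ``probe_table`` needs columns ``probe``, ``feature``, ``p``, ``score``.
    """
    req = {"probe", "feature", "p", "score"}
    if not req.issubset(probe_table.columns):
        raise ConfigurationError(f"probe table must have columns {sorted(req)}")
    tbl = probe_table.copy()
    unmapped = tbl["feature"].isna() | (tbl["feature"].astype(str) == "")
    if unmapped.any():
        logger.warning("dropping %d unmapped probes (first: %s)",
                       int(unmapped.sum()), tbl.loc[unmapped, "probe"].iloc[0])
        tbl = tbl[~unmapped]
    tbl = tbl.assign(_abs_score=tbl["score"].abs())
    tbl = tbl.sort_values(
        ["feature", "p", "_abs_score", "probe"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    out = tbl.groupby("feature", sort=True).head(1).drop(columns="_abs_score")
    return out.set_index("feature")


# ---------------------------------------------------------------------------
# full integration
# ---------------------------------------------------------------------------

def _layer_statistics(layer: OmicsMatrix, scheme: str, n_perm: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Observed t, permutation sd, permutation p and Z for every feature."""
    X = layer.values.to_numpy(dtype=float)
    mask = layer.high_mask()
    flat = X.max(axis=1) == X.min(axis=1)
    if flat.any():
        raise DegenerateDataError(
            f"constant feature(s) in layer, e.g. {layer.feature_ids[flat][0]!r}"
        )
    n, n_high = mask.size, int(mask.sum())
    masks, exhaustive = _balanced_masks(n, n_high, scheme, n_perm, rng)
    if not exhaustive:
        masks[0] = mask
    T = _t_matrix(X, masks)                       # perms x features
    t_obs = two_group_t_vec(X, mask)
    sd = T.std(axis=0, ddof=0 if exhaustive else 1)
    p_perm = (np.abs(T) >= np.abs(t_obs)[None, :]).mean(axis=0)
    z = t_obs / sd
    return pd.DataFrame(
        {"t": t_obs, "sd": sd, "z": z, "p": p_perm, "_perm_absz": list((np.abs(T) / sd).T)},
        index=layer.feature_ids,
    )


def two_group_t_vec(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Vectorised pooled t over the rows of ``X`` for one labeling."""
    return _t_matrix(X, mask[None, :])[0]


def integrate(
    layers: Mapping[str, OmicsMatrix],
    method: str = "exact_convolution",
    scheme: str = "auto",
    n_perm: int = 10_000,
    mc_reps: int = 1_000_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the full meta-integration over one or more omics layers.

    Features present in a subset of layers are integrated over the
    layers that measure them (D = that count).  Returns a DataFrame
    indexed by feature, sorted by integrated p-value, with per-layer
    columns ``t_<layer>``, ``sd_<layer>``, ``z_<layer>``, ``p_<layer>``
    plus ``n_layers``, ``s_meta``, ``p_inte``, ``q_inte``.
    """
    layers = as_layer_dict(layers)
    rng = np.random.default_rng(seed)
    per_layer = {name: _layer_statistics(m, scheme, n_perm, rng) for name, m in layers.items()}

    features = sorted(set().union(*(df.index for df in per_layer.values())))
    if not features:
        raise ConfigurationError("no features found in any layer")

    out = pd.DataFrame(index=pd.Index(features, name="feature"))
    absz = pd.DataFrame(index=out.index, columns=list(per_layer), dtype=float)
    for name, df in per_layer.items():
        for col in ("t", "sd", "z", "p"):
            out[f"{col}_{name}"] = df[col].reindex(out.index)
        absz[name] = df["z"].abs().reindex(out.index)
    out["n_layers"] = absz.notna().sum(axis=1)
    out["s_meta"] = absz.sum(axis=1, skipna=True)

    if method == "permutation":
        out["p_inte"] = _permutation_pvalues(out, per_layer, absz)
    else:
        p = np.empty(len(out))
        for i, (s, d) in enumerate(zip(out["s_meta"], out["n_layers"])):
            m = "exact_convolution" if (method == "paper_eq2" and d != 2) else method
            p[i] = combined_pvalue(float(s), int(d), method=m,
                                   mc_reps=mc_reps, seed=int(rng.integers(2**31)))
        out["p_inte"] = p
    out["q_inte"] = bh_fdr(out["p_inte"].to_numpy())
    return out.sort_values(["p_inte", "feature"], kind="stable")


def _permutation_pvalues(out: pd.DataFrame, per_layer: dict[str, pd.DataFrame],
                         absz: pd.DataFrame) -> np.ndarray:
    """Empirical p for S_meta against the pooled permuted S_meta null.

    Permuted |Z| values are pooled across all features sharing the same
    layer-membership pattern, so every feature is referred to a null of
    its own dimensionality.
    """
    p_out = np.empty(len(out))
    patterns = absz.notna().apply(lambda r: tuple(r.index[r]), axis=1)
    for pattern in patterns.unique():
        feats = out.index[patterns == pattern]
        null = None
        for name in pattern:
            block = np.stack(per_layer[name]["_perm_absz"].reindex(feats).to_list())
            null = block if null is None else null + block  # features x perms
        pool = np.sort(null.ravel())
        s = out.loc[feats, "s_meta"].to_numpy()
        ge = pool.size - np.searchsorted(pool, s, side="left")
        p_out[out.index.get_indexer(feats)] = (1 + ge) / (1 + pool.size)
    return p_out
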