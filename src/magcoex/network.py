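"""Spearman/BH coexpression network over MAG and enriched-gene profiles.

Profiles (MAG TPM rows, optionally treatment-enriched gene TPM rows) are
rank-correlated pairwise across samples. P-values use the t approximation
``t = rho * sqrt((n-2)/(1-rho^2))`` with n-2 degrees of freedom, the
convention of standard correlation routines. With only four samples the exact permutation
two-sided p of even a perfect correlation is 2/24 ≈ 0.083, which could
never clear alpha = 0.05; the t approximation (p -> 0 as rho -> 1) is the
reading under which significant edges are attainable at small n, and is
used deliberately. Its p-values at such n are optimistic — see the methods
note.

Benjamini–Hochberg is applied once over all unordered pairs in the profile
pool (genes + MAGs by default; MAG–MAG only via ``pool="mag"``). Edges are
emitted only between MAG pairs with rho > rho_min (one-sided positive:
anti-correlation never forms an edge) and adjusted p < alpha.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "spearman",
    "bh_adjust",
    "build_network",
    "target_neighborhood",
]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value.

    Ranks use the average-rank tie method; rho is the Pearson correlation
    of the ranks. Returns ``(nan, nan)`` when either vector is constant
    (rho undefined); |rho| = 1 returns p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise UsageError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, _rho_pvalue(rho, n)


def _rho_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1 - 1e-13:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_i = min over j >= i (in ascending-p order) of m * p_(j) / j,
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise UsageError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _rank_rows(mat: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, mat)


def spearman_matrix(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and p over the rows of ``profiles``.

    Constant rows yield NaN rho/p against every partner.
    """
    n = profiles.shape[1]
    if n < 3:
        raise UsageError("need at least 3 shared samples")
    mat = profiles.to_numpy(dtype=float)
    const = np.ptp(mat, axis=1) == 0
    ranks = _rank_rows(mat)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    rho_c = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho_c * np.sqrt((n - 2) / (1 - rho_c**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho_c) >= 1 - 1e-13, 0.0, p)
    p[np.isnan(rho)] = np.nan
    idx = profiles.index
    return (pd.DataFrame(rho, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx))


def build_network(
    mag_tpm,
    enriched_gene_tpm: pd.DataFrame | None = None,
    rho_min: float = 0.8,
    alpha: float = 0.05,
    pool: str = "union",
    targets: set[str] | None = None,
    samples: pd.DataFrame | None = None,
    condition: str = "treatment",
    roles: dict[str, set[str]] | None = None,
    log10_floor: float = 1e-2,
) -> nx.Graph:
    """Build the MAG coexpression network.

    Parameters
    ----------
    mag_tpm
        :class:`~magcoex.expression.MagTpmMatrix` or MAG × sample DataFrame.
    enriched_gene_tpm
        Optional gene × sample TPM of treatment-enriched genes; these join
        the correlation/BH pool but never become nodes.
    pool
        ``"union"`` — BH family is all unordered pairs among genes + MAGs
        (default); ``"mag"`` — MAG–MAG pairs only.
    targets, samples, roles
        Optional annotation inputs for node attributes (``is_target``,
        ``mean_log10_tpm`` over the given condition, ``roles``).

    Returns
    -------
    Undirected :class:`networkx.Graph` whose nodes are all MAGs and whose
    edges are MAG pairs with rho > rho_min and BH-adjusted p < alpha.
    """
    from .expression import MagTpmMatrix, mean_log10_tpm

    if pool not in ("union", "mag"):
        raise UsageError(f"unknown BH pool {pool!r}; expected 'union' or 'mag'")
    tpm = mag_tpm.tpm if isinstance(mag_tpm, MagTpmMatrix) else mag_tpm
    mag_ids = list(tpm.index)
    if len(mag_ids) < 2:
        raise UsageError("need at least 2 MAG profiles to build a network")

    if enriched_gene_tpm is not None and len(enriched_gene_tpm):
        genes = enriched_gene_tpm.loc[:, tpm.columns]
        clash = set(genes.index) & set(mag_ids)
        if clash:
            raise ValidationError(f"gene id collides with MAG id: {sorted(clash)[0]!r}")
        profiles = pd.concat([tpm, genes])
    else:
        profiles = tpm

    rho_m, p_m = spearman_matrix(profiles)

    ids = list(profiles.index)
    is_mag = np.array([i in set(mag_ids) for i in ids])
    iu, ju = np.triu_indices(len(ids), k=1)
    if pool == "mag":
        keep = is_mag[iu] & is_mag[ju]
        iu, ju = iu[keep], ju[keep]
    pvals = p_m.to_numpy()[iu, ju]
    defined = np.isfinite(pvals)
    p_adj = np.full(pvals.shape, np.nan)
    if defined.any():
        p_adj[defined] = bh_adjust(pvals[defined])

    G = nx.Graph()
    rho_arr = rho_m.to_numpy()
    magset = set(mag_ids)
    for k in range(iu.size):
        a, b = ids[iu[k]], ids[ju[k]]
        if a not in magset or b not in magset:
            continue
        rho = rho_arr[iu[k], ju[k]]
        if np.isfinite(rho) and rho > rho_min and p_adj[k] < alpha:
            G.add_edge(a, b, rho=float(rho), p_adj=float(p_adj[k]))

    targets = set(targets or ())
    if samples is not None:
        size = mean_log10_tpm(tpm, samples, condition=condition, floor=log10_floor)
    else:
        size = np.log10(tpm.clip(lower=log10_floor)).mean(axis=1)
    for mag in mag_ids:
        G.add_node(mag)
        G.nodes[mag].update(
            mag_id=mag,
            mean_log10_tpm=float(size.loc[mag]),
            roles=",".join(sorted((roles or {}).get(mag, ()))),
            is_target=mag in targets,
            connected_to_target="none",
        )
    return G


def target_neighborhood(network: nx.Graph, targets: set[str]) -> set[str]:
    """MAGs directly adjacent to at least one target MAG.

    Targets themselves are excluded. As a side effect each node's
    ``connected_to_target`` attribute is set to ``"all"`` (adjacent to
    every target present in the network), ``"subset"`` (adjacent to some
    but not all), or ``"none"``; targets get ``"target"``. Targets absent
    from the network are warned about and treated as isolated.
    """
    if not targets:
        raise UsageError("target set must be nonempty")
    present = {t for t in targets if t in network}
    for t in targets - present:
        logger.warning("target MAG %s absent from network; treated as isolated", t)
    neighborhood: set[str] = set()
    hits: dict[str, int] = {}
    for t in present:
        for nb in network.neighbors(t):
            if nb not in targets:
                hits[nb] = hits.get(nb, 0) + 1
    neighborhood = set(hits)
    for node in network.nodes:
        if node in targets:
            network.nodes[node]["connected_to_target"] = "target"
        elif node in hits:
            network.nodes[node]["connected_to_target"] = (
                "all" if present and hits[node] == len(present) else "subset"
            )
        else:
            network.nodes[node]["connected_to_target"] = "none"
    return neighborhood
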