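"""Treatment-vs-control differential expression with a moderated t-test.

The stage follows the standard empirical-Bayes linear-model workflow for
expression counts: counts are transformed to log2 counts-per-million with
a small prior count, a per-gene two-group fit gives the log2 fold change
``b_g`` and pooled residual variance ``s2_g`` on ``d_g = n - 2`` degrees of
freedom, and the gene variances are shrunk toward a common prior by
borrowing strength across genes::

    s2_post,g = (d0 * s02 + d_g * s2_g) / (d0 + d_g)
    t_mod,g   = b_g / (u * s_post,g),   u = sqrt(1/n_t + 1/n_c)
    df        = d0 + d_g

The prior degrees of freedom ``d0`` and prior variance ``s02`` are
estimated by moment-matching the log sample variances to a scaled-F
distribution (Smyth-style): across genes, ``log s2_g`` has variance
``trigamma(d_g/2) + trigamma(d0/2)``, which is inverted for ``d0``; the
mean then yields ``s02``. With only two replicates per condition — the
design this pipeline mirrors — ``d_g = 2`` and significance rests almost
entirely on the moderation; a warning is emitted in that regime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import UsageError, ValidationError
from .network import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["DEFit", "log_cpm", "moderated_t", "select_enriched"]


def log_cpm(quant: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: log2((count + prior) / (lib + 2*prior) * 1e6).

    Library size is the per-sample total of estimated counts. A sample
    with zero library size is an error.
    """
    if prior_count <= 0:
        raise UsageError("prior_count must be > 0")
    counts = quant.pivot_table(index="gene_id", columns="sample_id",
                               values="est_count", aggfunc="sum", fill_value=0.0)
    lib = counts.sum(axis=0)
    zero = lib.index[lib == 0]
    if len(zero):
        raise ValidationError(f"sample {zero[0]!r} has zero library size")
    return np.log2((counts + prior_count).div(lib + 2 * prior_count, axis=1) * 1e6)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _fit_f_dist(s2: np.ndarray, d_g: float) -> tuple[float, float]:
    """Moment-match s2_g ~ s02 * F(d_g, d0); returns (d0, s02).

    Zero sample variances carry no information about the spread of log
    variances and are excluded from the fit; if every gene has zero
    variance, d0 is +inf (complete shrinkage) with a warning.
    """
    pos = s2[s2 > 0]
    if pos.size == 0:
        logger.warning("all genes have zero residual variance; "
                       "setting prior df to +inf")
        return math.inf, float(np.mean(s2)) if s2.size else 0.0
    z = np.log(pos)
    e_mean = float(np.mean(z))
    digam = float(special.digamma(d_g / 2))
    trigam = float(special.polygamma(1, d_g / 2))
    evar = float(np.var(z, ddof=1)) - trigam if pos.size > 1 else 0.0
    if evar <= 0:
        return math.inf, math.exp(e_mean - digam + math.log(d_g / 2))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = math.exp(
        e_mean - digam + float(special.digamma(d0 / 2)) + math.log(d_g / d0)
    )
    return d0, s02


@dataclass
class DEFit:
    """Result of :func:`moderated_t`.

    ``table`` is indexed by gene_id with columns ``log2_fc``, ``s2``,
    ``t_mod``, ``df_total``, ``p`` (plus ``p_adj``/``enriched`` after
    :func:`select_enriched`). ``d0``/``s02`` are the estimated (or
    supplied) prior degrees of freedom and prior variance.
    """

    table: pd.DataFrame
    d0: float
    s02: float


def moderated_t(
    log_cpm: pd.DataFrame,
    samples: pd.DataFrame,
    d0: float | None = None,
    s02: float | None = None,
) -> DEFit:
    """Empirical-Bayes moderated t for treatment minus control.

    Parameters
    ----------
    log_cpm
        Gene × sample matrix from :func:`log_cpm`.
    samples
        Sample metadata; both conditions need >= 2 samples.
    d0, s02
        Override the estimated prior df / prior variance (``d0=0`` gives
        the classical pooled-variance t; ``d0=inf`` shrinks every gene's
        variance fully to ``s02``). Estimated by moment matching when None.
    """
    groups = {
        cond: list(samples.loc[samples["condition"] == cond, "sample_id"])
        for cond in ("treatment", "control")
    }
    for cond, ids in groups.items():
        if len(ids) < 2:
            raise UsageError(f"condition {cond!r} has {len(ids)} sample(s); need >= 2")
        missing = set(ids) - set(log_cpm.columns)
        if missing:
            raise UsageError(f"sample(s) missing from matrix: {sorted(missing)}")

    t_mat = log_cpm[groups["treatment"]].to_numpy(dtype=float)
    c_mat = log_cpm[groups["control"]].to_numpy(dtype=float)
    n_t, n_c = t_mat.shape[1], c_mat.shape[1]
    d_g = n_t + n_c - 2
    if d_g <= 2:
        logger.warning(
            "only %d residual df per gene: adjusted significance at this "
            "sample size depends heavily on variance moderation", d_g
        )

    b = t_mat.mean(axis=1) - c_mat.mean(axis=1)
    rss = ((t_mat - t_mat.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (c_mat - c_mat.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = rss / d_g
    u = math.sqrt(1.0 / n_t + 1.0 / n_c)

    d0_hat, s02_hat = _fit_f_dist(s2, d_g)
    if d0 is None:
        d0 = d0_hat
    if s02 is None:
        s02 = s02_hat

    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = math.inf
    else:
        s2_post = (d0 * s02 + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = b / (u * np.sqrt(s2_post))
    t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)  # 0/0: no change, no evidence
    if math.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.where(np.isinf(t_mod), 0.0, p)

    table = pd.DataFrame(
        {"log2_fc": b, "s2": s2, "t_mod": t_mod,
         "df_total": df_total, "p": p},
        index=log_cpm.index,
    )
    table.index.name = "gene_id"
    return DEFit(table=table, d0=float(d0), s02=float(s02))


def select_enriched(
    fit: DEFit,
    gene_meta: pd.DataFrame,
    alpha: float = 0.05,
    lfc_min: float = 0.0,
) -> set[str]:
    """Treatment-enriched genes: positive log2 fold change, BH-adjusted
    p < alpha, and coding biotype (rRNA/tRNA genes are never enriched).

    Adds ``p_adj`` and ``enriched`` columns to ``fit.table`` in place and
    returns the enriched gene ids.
    """
    if not 0 < alpha < 1:
        raise UsageError("alpha must be in (0, 1)")
    table = fit.table
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    biotype = gene_meta.set_index("gene_id")["biotype"].reindex(table.index)
    table["enriched"] = (
        (table["log2_fc"] > lfc_min)
        & (table["p_adj"] < alpha)
        & (biotype == "CDS").to_numpy()
    )
    return set(table.index[table["enriched"]])
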