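"""Gene-level and MAG-level TPM computation.

TPM (transcripts per million) length-normalizes estimated counts: per gene
the rate is ``est_count / eff_length`` and TPM is the rate scaled to sum to
1e6 within a sample. The MAG-level extension aggregates first and
normalizes after::

    q_i = sum of est_count over the MAG's coding (CDS) genes
    l_i = sum of eff_length over the same genes
    TPM_i = (q_i / l_i) / sum_j (q_j / l_j) * 1e6

Noncoding RNAs (rRNA, tRNA) are excluded from both the numerator and the
denominator: ribosomal reads would otherwise dominate whole-MAG expression.
Note this is NOT the sum of per-gene TPMs — summing counts and lengths
before forming the rate weights genes by length, and the two quantities
differ whenever gene lengths vary within a MAG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UsageError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["MagTpmMatrix", "gene_tpm", "mag_tpm", "mean_log10_tpm"]

SCALE = 1e6


@dataclass
class MagTpmMatrix:
    """MAG × sample TPM with the intermediate sums.

    Attributes
    ----------
    tpm
        MAG × sample TPM values; each column sums to 1e6 whenever any MAG
        has nonzero counts in that sample.
    q
        Summed estimated counts per MAG per sample (CDS genes only).
    l
        Summed effective lengths per MAG per sample (CDS genes only).
    """

    tpm: pd.DataFrame
    q: pd.DataFrame
    l: pd.DataFrame

    @property
    def mag_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)


def _pivot(quant: pd.DataFrame, value: str) -> pd.DataFrame:
    return quant.pivot_table(index="gene_id", columns="sample_id",
                             values=value, aggfunc="sum", fill_value=0.0)


def gene_tpm(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-gene TPM matrix (genes × samples).

    Samples with all-zero counts yield an all-zero column with a warning
    rather than dividing by zero.
    """
    counts = _pivot(quant, "est_count")
    lengths = _pivot(quant, "eff_length")
    rates = counts.div(lengths).fillna(0.0)
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("sample(s) with all-zero counts: %s",
                       ", ".join(totals.index[zero]))
        totals = totals.replace(0, np.nan)
    tpm = rates.div(totals, axis=1).fillna(0.0) * SCALE
    return tpm


def mag_tpm(quant: pd.DataFrame, gene_meta: pd.DataFrame) -> MagTpmMatrix:
    """MAG-level TPM via summed counts over summed effective lengths.

    Only CDS genes with a MAG assignment contribute; rRNA/tRNA genes and
    unbinned genes enter neither the per-MAG sums nor the denominator.
    MAGs with zero CDS genes are dropped with a warning.
    """
    meta = gene_meta.dropna(subset=["mag_id"])
    cds = meta.loc[meta["biotype"] == "CDS", ["gene_id", "mag_id"]]
    dropped = set(meta["mag_id"]) - set(cds["mag_id"])
    if dropped:
        logger.warning("MAG(s) with no CDS genes excluded: %s",
                       ", ".join(sorted(map(str, dropped))))
    if cds.empty:
        raise ValidationError("no MAG has any CDS gene; cannot aggregate")

    merged = quant.merge(cds, on="gene_id", how="inner")
    q = merged.pivot_table(index="mag_id", columns="sample_id",
                           values="est_count", aggfunc="sum", fill_value=0.0)
    l = merged.pivot_table(index="mag_id", columns="sample_id",
                           values="eff_length", aggfunc="sum", fill_value=0.0)
    rates = q.div(l).fillna(0.0)
    totals = rates.sum(axis=0)
    if (totals == 0).all():
        raise ValidationError("all MAGs have zero counts in every sample")
    zero = totals == 0
    if zero.any():
        logger.warning("sample(s) with zero MAG expression: %s",
                       ", ".join(totals.index[zero]))
        totals = totals.replace(0, np.nan)
    tpm = rates.div(totals, axis=1).fillna(0.0) * SCALE
    return MagTpmMatrix(tpm=tpm, q=q, l=l)


def mean_log10_tpm(
    mag_tpm: MagTpmMatrix | pd.DataFrame,
    samples: pd.DataFrame,
    condition: str = "treatment",
    floor: float = 1e-2,
) -> pd.Series:
    """Mean log10(TPM) per MAG over one condition's samples.

    Zero TPM values are floored at ``floor`` (default 0.01 TPM) before the
    log so fully silent MAGs remain representable; this is the node-size
    attribute of the exported network.
    """
    tpm = mag_tpm.tpm if isinstance(mag_tpm, MagTpmMatrix) else mag_tpm
    cond_samples = samples.loc[samples["condition"] == condition, "sample_id"]
    if cond_samples.empty:
        raise UsageError(f"no samples with condition {condition!r}")
    missing = set(cond_samples) - set(tpm.columns)
    if missing:
        raise UsageError(f"sample(s) absent from TPM matrix: {sorted(missing)}")
    sub = tpm[list(cond_samples)].clip(lower=floor)
    return np.log10(sub).mean(axis=1)
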