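"""Role composition and expression-fraction summaries.

These are the headline ecology statistics of the pipeline: among the MAGs
significantly correlated to the target (dechlorinating) MAGs, how many
hold each support role, and what fraction of each role's community-wide
expression is contributed by the target-correlated holders.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import UsageError
from .network import target_neighborhood
from .roles import ROLE_NAMES, RoleAssignment

logger = logging.getLogger(__name__)

__all__ = ["RoleSummary", "ExpressionFraction", "role_counts",
           "expression_fraction"]


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (display convention)."""
    q = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass
class RoleSummary:
    """Per-role counts and percentages over a reference MAG set."""

    reference_set: frozenset[str]
    counts: dict[str, int]
    pct: dict[str, float]
    n_reference: int
    n_with_any_role: int


def role_counts(
    assignments: Iterable[RoleAssignment],
    reference_set: Iterable[str],
) -> RoleSummary:
    """Count role holders within ``reference_set``.

    Percentages use the full reference set as denominator (all
    target-correlated MAGs, not just those holding a role) and are rounded
    half-up to one decimal.
    """
    ref = frozenset(reference_set)
    if not ref:
        raise UsageError("reference set must be nonempty")
    by_mag = {a.mag_id: a for a in assignments}
    roles_seen = sorted(
        set(ROLE_NAMES) | {r for a in by_mag.values() for r in a.roles}
    )
    counts = {
        role: sum(1 for m in ref if m in by_mag and role in by_mag[m].roles)
        for role in roles_seen
    }
    n_any = sum(1 for m in ref if m in by_mag and by_mag[m].roles)
    return RoleSummary(
        reference_set=ref,
        counts=counts,
        pct={role: _pct(c, len(ref)) for role, c in counts.items()},
        n_reference=len(ref),
        n_with_any_role=n_any,
    )


@dataclass
class ExpressionFraction:
    """Share of a role's total expression held by target-correlated MAGs."""

    role: str
    pct_expression_correlated: float  # percent of TPM; NaN when undefined


def expression_fraction(
    assignments: Iterable[RoleAssignment],
    mag_tpm,
    network: nx.Graph,
    targets: set[str],
    role: str,
    samples: pd.DataFrame,
    condition: str = "treatment",
) -> ExpressionFraction:
    """Percentage of the role's summed mean-condition TPM contributed by
    role holders inside the target neighborhood.

    pct = 100 * sum(mean TPM of correlated holders) / sum(mean TPM of all
    holders), mean taken over the condition's samples. Undefined (NaN, with
    a warning) when the role's total TPM is zero.
    """
    from .expression import MagTpmMatrix

    tpm = mag_tpm.tpm if isinstance(mag_tpm, MagTpmMatrix) else mag_tpm
    holders = {a.mag_id for a in assignments if role in a.roles}
    if not holders:
        raise UsageError(f"no MAG holds role {role!r}")
    cond_samples = list(samples.loc[samples["condition"] == condition, "sample_id"])
    if not cond_samples:
        raise UsageError(f"no samples with condition {condition!r}")
    neighborhood = target_neighborhood(network, set(targets))
    mean_tpm = tpm[cond_samples].mean(axis=1)
    total = float(mean_tpm.reindex(sorted(holders)).fillna(0.0).sum())
    if total == 0:
        logger.warning("role %s has zero total TPM; fraction undefined", role)
        return ExpressionFraction(role=role, pct_expression_correlated=math.nan)
    corr = float(
        mean_tpm.reindex(sorted(holders & neighborhood)).fillna(0.0).sum()
    )
    return ExpressionFraction(
        role=role, pct_expression_correlated=100.0 * corr / total
    )
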