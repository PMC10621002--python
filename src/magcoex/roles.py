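"""Functional-role assignment for MAGs from marker-gene expression.

A MAG earns an ecological support role when it carries at least one gene of
each marker family its rule requires and those genes are actually expressed
(estimated count at or above a threshold) in a minimum number of samples.
The built-in registry encodes the seven support roles relevant to
*Dehalococcoides*-centred organohalide-respiring communities: acetate/H2
production, corrinoid transport, CO metabolism, corrinoid assembly/salvage,
cobyrinate a,c-diamide production, DMB (5,6-dimethylbenzimidazole)
production, and resuscitation-promoting-factor production.

Rules are boolean AND/OR trees over marker-family names and are
user-extensible from YAML (``rules_from_yaml``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import UsageError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Family",
    "AllOf",
    "AnyOf",
    "RoleRule",
    "RoleAssignment",
    "ROLE_NAMES",
    "DEFAULT_MARKER_FAMILIES",
    "default_rules",
    "rules_from_yaml",
    "rule_families",
    "evaluate_rule",
    "gene_expressed",
    "assign_roles",
]


# ---------------------------------------------------------------------------
# Rule expression trees


@dataclass(frozen=True)
class Family:
    """Leaf: satisfied when the MAG expresses >=1 gene of this family."""

    name: str


@dataclass(frozen=True)
class AllOf:
    """Conjunction over sub-expressions."""

    terms: tuple


@dataclass(frozen=True)
class AnyOf:
    """Disjunction over sub-expressions."""

    terms: tuple


def evaluate_rule(expr, satisfied: set[str]) -> bool:
    """Evaluate an AND/OR tree against the set of satisfied family names."""
    if isinstance(expr, Family):
        return expr.name in satisfied
    if isinstance(expr, AllOf):
        return all(evaluate_rule(t, satisfied) for t in expr.terms)
    if isinstance(expr, AnyOf):
        return any(evaluate_rule(t, satisfied) for t in expr.terms)
    raise UsageError(f"not a rule expression: {expr!r}")


def rule_families(expr) -> frozenset[str]:
    """All marker-family names appearing as leaves of a rule tree."""
    if isinstance(expr, Family):
        return frozenset({expr.name})
    if isinstance(expr, (AllOf, AnyOf)):
        out: frozenset[str] = frozenset()
        for t in expr.terms:
            out |= rule_families(t)
        return out
    raise UsageError(f"not a rule expression: {expr!r}")


@dataclass(frozen=True)
class RoleRule:
    """A named role with its marker-family requirement.

    Parameters
    ----------
    role
        Role identifier (snake_case).
    requirement
        AND/OR tree over :class:`Family` leaves.
    min_samples
        Number of samples a marker gene must be expressed in before it
        counts as evidence (default 2).
    display_names
        Human-facing synonyms (e.g. the corrinoid assembler role is also
        described as corrinoid salvaging).
    """

    role: str
    requirement: AllOf | AnyOf | Family
    min_samples: int = 2
    display_names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.min_samples < 1:
            raise UsageError("min_samples must be >= 1")
        rule_families(self.requirement)  # raises if tree malformed / empty


@dataclass
class RoleAssignment:
    """Roles granted to one MAG, with the marker genes that justify them.

    ``evidence`` maps each granted role to the set of
    ``(gene_id, family, samples_expressed)`` tuples that satisfied its
    leaves, where ``samples_expressed`` is the tuple of sample ids in which
    the gene passed the expression threshold.
    """

    mag_id: str
    roles: set[str] = field(default_factory=set)
    evidence: dict[str, set[tuple]] = field(default_factory=dict)


ROLE_NAMES = (
    "acetate_h2_producer",
    "corrinoid_transporter",
    "co_metabolizer",
    "corrinoid_assembler",
    "cobyrinate_diamide_producer",
    "dmb_producer",
    "rp_producer",
)


def default_rules() -> list[RoleRule]:
    """The built-in seven-role registry.

    acetate_h2_producer
        hydrogenase AND any short-chain-fatty-acid transformation gene.
    corrinoid_transporter
        btuB AND (btuC OR btuD).
    co_metabolizer
        CO dehydrogenase.
    corrinoid_assembler
        cobS OR cobV (corrinoid assembly/salvaging).
    cobyrinate_diamide_producer
        cbiA.
    dmb_producer
        DMB synthase.
    rp_producer
        rpfB (resuscitation-promoting factor).
    """
    return [
        RoleRule(
            "acetate_h2_producer",
            AllOf((Family("hydrogenase"), Family("scfa_transformation"))),
            display_names=("acetate/H2 producer",),
        ),
        RoleRule(
            "corrinoid_transporter",
            AllOf((Family("btuB"), AnyOf((Family("btuC"), Family("btuD"))))),
            display_names=("corrinoid transporter/competitor",),
        ),
        RoleRule("co_metabolizer", Family("co_dehydrogenase"),
                 display_names=("CO metabolizer",)),
        RoleRule(
            "corrinoid_assembler",
            AnyOf((Family("cobS"), Family("cobV"))),
            display_names=("corrinoid assembler", "corrinoid salvager"),
        ),
        RoleRule("cobyrinate_diamide_producer", Family("cbiA"),
                 display_names=("cobyrinate a,c-diamide producer",)),
        RoleRule("dmb_producer", Family("dmb_synthase"),
                 display_names=("DMB producer",)),
        RoleRule("rp_producer", Family("rpfB"),
                 display_names=("RP producer",)),
    ]


DEFAULT_MARKER_FAMILIES: frozenset[str] = frozenset().union(
    *(rule_families(r.requirement) for r in default_rules())
)


# ---------------------------------------------------------------------------
# YAML rule files
#
# Grammar (one mapping per role):
#   roles:
#     corrinoid_transporter:
#       min_samples: 2
#       require: {all: [btuB, {any: [btuC, btuD]}]}
# A bare string is shorthand for {family: <name>}.


def _parse_expr(node):
    if isinstance(node, str):
        return Family(node)
    if isinstance(node, Mapping):
        if "family" in node:
            return Family(str(node["family"]))
        if "all" in node:
            terms = tuple(_parse_expr(t) for t in node["all"])
            if not terms:
                raise ValidationError("'all' requires at least one term")
            return AllOf(terms)
        if "any" in node:
            terms = tuple(_parse_expr(t) for t in node["any"])
            if not terms:
                raise ValidationError("'any' requires at least one term")
            return AnyOf(terms)
    raise ValidationError(f"cannot parse rule expression node: {node!r}")


def rules_from_yaml(path) -> list[RoleRule]:
    """Load a rule registry from YAML (see module docstring for grammar)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "roles" not in doc:
        raise ValidationError("rule file must contain a top-level 'roles' mapping")
    rules = []
    for role, body in doc["roles"].items():
        if isinstance(body, (str, list)) or "require" not in body:
            raise ValidationError(f"role {role!r} must define a 'require' expression")
        rules.append(
            RoleRule(
                role=str(role),
                requirement=_parse_expr(body["require"]),
                min_samples=int(body.get("min_samples", 2)),
            )
        )
    if not rules:
        raise ValidationError("rule file defines no roles")
    return rules


# ---------------------------------------------------------------------------
# Expression evidence


def _count_matrix(quant: pd.DataFrame) -> pd.DataFrame:
    return quant.pivot_table(
        index="gene_id", columns="sample_id", values="est_count",
        aggfunc="sum", fill_value=0.0,
    )


def gene_expressed(
    quant: pd.DataFrame,
    gene_id: str,
    min_samples: int = 2,
    min_count: float = 1.0,
) -> bool:
    """True iff the gene's estimated count is >= ``min_count`` in at least
    ``min_samples`` samples (both conditions pooled).

    Unknown genes return False with a warning; fractional kallisto counts
    below the threshold do not count as expression.
    """
    if min_count <= 0:
        raise UsageError("min_count must be > 0")
    sub = quant.loc[quant["gene_id"] == gene_id]
    if sub.empty:
        logger.warning("gene %s absent from quantification; treated as unexpressed", gene_id)
        return False
    return int((sub["est_count"] >= min_count).sum()) >= min_samples


def assign_roles(
    gene_meta: pd.DataFrame,
    quant: pd.DataFrame,
    rules: Iterable[RoleRule] | None = None,
    min_count: float = 1.0,
) -> list[RoleAssignment]:
    """Assign roles to every MAG in ``gene_meta``.

    A family leaf is satisfied for a MAG iff the MAG carries >=1 gene
    annotated with that family whose estimated count is >= ``min_count`` in
    at least the rule's ``min_samples`` samples. The rule's AND/OR tree is
    then evaluated over satisfied leaves.

    Returns one :class:`RoleAssignment` per MAG (MAG universe = all MAGs
    appearing in ``gene_meta``), including MAGs with no roles.
    """
    rules = list(default_rules() if rules is None else rules)
    if not rules:
        raise UsageError("rules must be nonempty")

    known_families = frozenset().union(*(rule_families(r.requirement) for r in rules))
    counts = _count_matrix(quant)

    # family -> min_samples thresholds actually needed
    thresholds = sorted({r.min_samples for r in rules})

    # per-MAG: family -> list of (gene_id, samples_expressed-tuple)
    mags: dict[str, dict[str, list[tuple[str, tuple[str, ...]]]]] = {}
    with_mag = gene_meta.dropna(subset=["mag_id"])
    for mag_id in with_mag["mag_id"].unique():
        mags[str(mag_id)] = {}

    annotated = with_mag.loc[with_mag["marker_families"].map(bool)]
    for row in annotated.itertuples(index=False):
        gid, mag = row.gene_id, str(row.mag_id)
        if gid in counts.index:
            expressed_in = tuple(
                counts.columns[counts.loc[gid] >= min_count]
            )
        else:
            logger.warning("annotated gene %s absent from quantification", gid)
            expressed_in = ()
        for fam in row.marker_families:
            if fam not in known_families:
                logger.debug("marker family %s not used by any rule; ignored", fam)
                continue
            mags.setdefault(mag, {}).setdefault(fam, []).append((gid, expressed_in))

    out = []
    for mag_id in sorted(mags):
        fam_genes = mags[mag_id]
        assignment = RoleAssignment(mag_id=mag_id)
        # satisfied leaves per min_samples threshold
        satisfied_at = {
            t: {
                fam
                for fam, genes in fam_genes.items()
                if any(len(samps) >= t for _, samps in genes)
            }
            for t in thresholds
        }
        for rule in rules:
            satisfied = satisfied_at[rule.min_samples]
            if evaluate_rule(rule.requirement, satisfied):
                assignment.roles.add(rule.role)
                ev = set()
                for fam in rule_families(rule.requirement) & satisfied:
                    for gid, samps in fam_genes[fam]:
                        if len(samps) >= rule.min_samples:
                            ev.add((gid, fam, samps))
                assignment.evidence[rule.role] = ev
        out.append(assignment)
    return out
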