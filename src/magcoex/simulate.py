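"""Synthetic metatranscriptome communities with planted structure.

The generator emulates the study design the pipeline targets: a sediment
community of 160 MAGs sequenced in 2 treatment + 2 control samples, with

* a *target block* of MAGs (the dechlorinators plus their planted
  partners) sharing one strictly co-monotone latent abundance trajectory,
  boosted by ``treatment_enrichment_lfc`` log2 units in treatment samples;
* an *anti block* of competitors whose trajectories are drawn to be
  uncorrelated-to-anticorrelated with the target trajectory;
* background MAGs with their own per-MAG treatment responses
  (log2 fold changes ~ Normal(0, ``background_lfc_sd``)) on top of
  community-wide replicate-bottle noise — communities respond broadly to
  the amendment, which is what makes the emitted network dense;
* per-gene negative-binomial counts with mean = MAG latent abundance ×
  gene relative-expression weight × sample depth and dispersion
  ``nb_dispersion`` (``0`` gives the deterministic noise-free limit with
  fractional counts, kallisto-style);
* inflated-count rRNA/tRNA genes, making the noncoding exclusion rule
  consequential; and
* marker genes planted per ``role_plantings`` so role assignment has a
  known answer.

Everything derives from a single seed; identical configs produce
byte-identical output tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import io as mio
from .errors import ConfigError

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticCommunity",
           "simulate", "write_community"]

# marker genes needed to satisfy each built-in role rule
_ROLE_GENES: dict[str, tuple[str, ...]] = {
    "acetate_h2_producer": ("hydrogenase", "scfa_transformation"),
    "corrinoid_transporter": ("btuB", "btuD"),
    "co_metabolizer": ("co_dehydrogenase",),
    "corrinoid_assembler": ("cobS",),
    "cobyrinate_diamide_producer": ("cbiA",),
    "dmb_producer": ("dmb_synthase",),
    "rp_producer": ("rpfB",),
}


def _default_plantings(n_mags: int) -> dict[str, frozenset[int]]:
    if n_mags < 28:
        return {}
    return {
        "acetate_h2_producer": frozenset({3, 4, 20, 21}),
        "corrinoid_transporter": frozenset({5, 22}),
        "co_metabolizer": frozenset({6, 23}),
        "corrinoid_assembler": frozenset({7, 24}),
        "cobyrinate_diamide_producer": frozenset({8, 25}),
        "dmb_producer": frozenset({9, 26}),
        "rp_producer": frozenset({27}),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults are the emulated study design."""

    seed: int = 0
    n_mags: int = 160
    n_samples_per_condition: int = 2
    genes_per_mag: tuple[int, int] = (20, 60)
    nb_dispersion: float = 0.2
    target_block: frozenset[int] | None = None
    anti_block: frozenset[int] | None = None
    n_targets: int = 3
    role_plantings: Mapping[str, frozenset[int]] | None = None
    frac_rrna: float = 0.05
    treatment_enrichment_lfc: float = 4.0
    target_scale: float = 0.08
    replicate_log_sd: float = 0.3
    background_lfc_sd: float = 1.0
    anti_log_sd: float = 0.7
    gene_log_sd: float = 1.0
    mean_gene_count: float = 100.0
    marker_mean_count: float = 80.0
    rrna_inflation: float = 50.0
    eff_length_range: tuple[float, float] = (200.0, 2000.0)
    sample_depth: tuple[float, ...] | None = None

    def resolved(self) -> "SyntheticConfig":
        """Fill block/planting defaults and validate."""
        cfg = self
        if cfg.target_block is None:
            size = 10 if cfg.n_mags >= 30 else max(2, cfg.n_mags // 3)
            cfg = replace(cfg, target_block=frozenset(range(size)))
        if cfg.anti_block is None:
            lo = max(cfg.target_block) + 1 if cfg.target_block else 0
            size = 10 if cfg.n_mags >= 30 else 0
            anti = frozenset(range(lo, min(lo + size, cfg.n_mags)))
            cfg = replace(cfg, anti_block=anti)
        if cfg.role_plantings is None:
            cfg = replace(cfg, role_plantings=_default_plantings(cfg.n_mags))
        if cfg.n_targets > len(cfg.target_block):
            cfg = replace(cfg, n_targets=len(cfg.target_block))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_mags < 2:
            raise ConfigError("need at least 2 MAGs")
        if self.n_samples_per_condition < 1:
            raise ConfigError("need at least 1 sample per condition")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if not 0 <= self.frac_rrna <= 1:
            raise ConfigError("frac_rrna must lie in [0, 1]")
        lo, hi = self.genes_per_mag
        if not 1 <= lo <= hi:
            raise ConfigError("genes_per_mag range must satisfy 1 <= lo <= hi")
        if self.target_block & self.anti_block:
            raise ConfigError("target_block and anti_block overlap")
        for name, block in (("target_block", self.target_block),
                            ("anti_block", self.anti_block)):
            if block and (min(block) < 0 or max(block) >= self.n_mags):
                raise ConfigError(f"{name} index outside [0, n_mags)")
        for role, mags in (self.role_plantings or {}).items():
            if role not in _ROLE_GENES:
                raise ConfigError(f"unknown role in plantings: {role!r}")
            if mags and (min(mags) < 0 or max(mags) >= self.n_mags):
                raise ConfigError(f"planting index outside [0, n_mags) for {role}")
        if not 1 <= self.n_targets <= len(self.target_block):
            raise ConfigError("n_targets must lie in [1, |target_block|]")
        n_samp = 2 * self.n_samples_per_condition
        if self.sample_depth is not None and len(self.sample_depth) != n_samp:
            raise ConfigError("sample_depth length must equal the sample count")


@dataclass
class GroundTruth:
    """Planted structure: latent trajectories, roles, and expected edges."""

    trajectories: pd.DataFrame  # MAG × sample latent abundance
    planted_roles: dict[str, set[str]]
    planted_edges: set[tuple[str, str]]  # sorted MAG-id pairs, target block


@dataclass
class SyntheticCommunity:
    """All pipeline inputs plus the generator's ground truth."""

    quant: pd.DataFrame  # long form: gene_id, sample_id, est_count, eff_length
    gene_meta: pd.DataFrame
    samples: pd.DataFrame
    targets: set[str]
    truth: GroundTruth
    config: SyntheticConfig


def _mag_id(i: int) -> str:
    return f"MAG{i:03d}"


def simulate(config: SyntheticConfig) -> SyntheticCommunity:
    """Generate a community; deterministic given ``config.seed``."""
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_samples_per_condition
    sample_ids = [f"T{i+1}" for i in range(k)] + [f"C{i+1}" for i in range(k)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": ["treatment"] * k + ["control"] * k,
            "replicate": [str(i + 1) for i in range(k)] * 2,
        }
    )
    n_samp = 2 * k
    depth = np.ones(n_samp) if cfg.sample_depth is None else np.asarray(
        cfg.sample_depth, dtype=float
    )
    is_treatment = np.array([1.0] * k + [0.0] * k)

    # shared target trajectory: a 2^lfc condition effect in treatment times
    # lognormal replicate-bottle noise; sample values strictly distinct
    for _ in range(1000):
        tau = rng.lognormal(0.0, cfg.replicate_log_sd, n_samp)
        tau = tau * 2.0 ** (cfg.treatment_enrichment_lfc * is_treatment)
        if len(np.unique(tau)) == n_samp:
            break
    else:
        raise ConfigError(
            "cannot draw a strictly ordered target trajectory; "
            "replicate_log_sd and treatment_enrichment_lfc both zero?"
        )
    tau_ranks = stats.rankdata(tau)

    mag_ids = [_mag_id(i) for i in range(cfg.n_mags)]
    A = np.empty((cfg.n_mags, n_samp))
    for i in range(cfg.n_mags):
        if i in cfg.target_block:
            # dechlorinators and partners are a minor community fraction at
            # baseline; keeping their share small limits the compositional
            # (closed-sum) coupling their bloom imposes on everyone else
            A[i] = cfg.target_scale * rng.lognormal(0.0, 0.5) * tau
        elif i in cfg.anti_block:
            # competitor: volatile and at best uncorrelated with the target
            while True:
                v = rng.lognormal(0.0, cfg.anti_log_sd, n_samp)
                if len(np.unique(v)) < n_samp:
                    continue
                rho = np.corrcoef(stats.rankdata(v), tau_ranks)[0, 1]
                if rho <= 0:
                    A[i] = v
                    break
        else:
            # background: own treatment response plus replicate noise
            lfc_m = rng.normal(0.0, cfg.background_lfc_sd)
            A[i] = 2.0 ** (lfc_m * is_treatment) * rng.lognormal(
                0.0, cfg.replicate_log_sd, n_samp
            )

    # genes
    gene_rows = []  # (gene_id, mag_idx, biotype, families, weight, eff_length)
    lo, hi = cfg.genes_per_mag
    len_lo, len_hi = cfg.eff_length_range
    for i in range(cfg.n_mags):
        n_g = int(rng.integers(lo, hi + 1))
        n_nc = int(round(cfg.frac_rrna * n_g))
        nc_idx = set(rng.choice(n_g, size=n_nc, replace=False)) if n_nc else set()
        weights = rng.lognormal(np.log(cfg.mean_gene_count), cfg.gene_log_sd, n_g)
        lengths = rng.uniform(len_lo, len_hi, n_g)
        for j in range(n_g):
            if j in nc_idx:
                biotype = "rRNA" if j % 2 == 0 else "tRNA"
                w = weights[j] * cfg.rrna_inflation
            else:
                biotype, w = "CDS", weights[j]
            gene_rows.append(
                (f"{_mag_id(i)}_g{j:04d}", i, biotype, frozenset(), w, lengths[j])
            )
    # planted marker genes (appended after ordinary genes, fixed order)
    for role in sorted(cfg.role_plantings):
        for i in sorted(cfg.role_plantings[role]):
            for fam in _ROLE_GENES[role]:
                w = rng.lognormal(np.log(cfg.marker_mean_count), 0.25)
                length = rng.uniform(len_lo, len_hi)
                gene_rows.append(
                    (f"{_mag_id(i)}_{role}_{fam}", i, "CDS",
                     frozenset({fam}), w, length)
                )

    gene_ids = [r[0] for r in gene_rows]
    mag_idx = np.array([r[1] for r in gene_rows])
    weights = np.array([r[4] for r in gene_rows])
    lengths = np.array([r[5] for r in gene_rows])

    mean = weights[:, None] * A[mag_idx, :] * depth[None, :]
    if cfg.nb_dispersion == 0:
        counts = mean.copy()
    else:
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, mean * cfg.nb_dispersion)
        counts = rng.poisson(lam).astype(float)

    quant = pd.DataFrame(
        {
            "gene_id": np.repeat(gene_ids, n_samp),
            "sample_id": np.tile(sample_ids, len(gene_ids)),
            "est_count": counts.ravel(),
            "eff_length": np.repeat(lengths, n_samp),
        }
    )
    gene_meta = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mag_id": [_mag_id(i) for i in mag_idx],
            "biotype": [r[2] for r in gene_rows],
            "marker_families": [r[3] for r in gene_rows],
        }
    )

    block_ids = sorted(_mag_id(i) for i in cfg.target_block)
    targets = set(block_ids[: cfg.n_targets])
    planted_edges = {
        (a, b)
        for ai, a in enumerate(block_ids)
        for b in block_ids[ai + 1:]
    }
    planted_roles: dict[str, set[str]] = {}
    for role, mags in cfg.role_plantings.items():
        for i in mags:
            planted_roles.setdefault(_mag_id(i), set()).add(role)
    truth = GroundTruth(
        trajectories=pd.DataFrame(A, index=mag_ids, columns=sample_ids),
        planted_roles=planted_roles,
        planted_edges=planted_edges,
    )
    return SyntheticCommunity(
        quant=quant, gene_meta=gene_meta, samples=samples,
        targets=targets, truth=truth, config=cfg,
    )


def write_community(community: SyntheticCommunity, out_dir) -> None:
    """Write all pipeline input files plus the ground-truth JSON.

    Emits ``quant_<sample>.tsv`` per sample (kallisto abundance dialect),
    ``gene_meta.tsv``, ``samples.tsv``, ``targets.txt`` and
    ``ground_truth.json``.
    """
    from .expression import gene_tpm

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tpm = gene_tpm(community.quant)
    for sample in community.samples["sample_id"]:
        mio.write_quant(
            community.quant, out / f"quant_{sample}.tsv",
            sample_id=sample, gene_tpm=tpm[sample],
        )
    mio.write_gene_meta(community.gene_meta, out / "gene_meta.tsv")
    mio.write_samples(community.samples, out / "samples.tsv")
    mio.write_targets(community.targets, out / "targets.txt")
    truth = community.truth
    payload = {
        "trajectories": {
            mag: {s: float(v) for s, v in row.items()}
            for mag, row in truth.trajectories.iterrows()
        },
        "planted_roles": {m: sorted(r) for m, r in sorted(truth.planted_roles.items())},
        "planted_edges": sorted(list(e) for e in truth.planted_edges),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
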