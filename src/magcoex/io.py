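"""Readers and writers for the pipeline's tabular inputs and network exports.

All tables are tab-delimited UTF-8 with a header row; paths ending in
``.gz`` are transparently (de)compressed. Quantification tables follow the
kallisto abundance dialect (``target_id, length, eff_length, est_counts,
tpm``) by default; a generic three-column dialect (``gene_id, est_count,
eff_length``) is also supported.

In-memory conventions
---------------------
quant
    long-form :class:`pandas.DataFrame` with columns ``gene_id``,
    ``sample_id``, ``est_count``, ``eff_length``.
gene_meta
    DataFrame with columns ``gene_id``, ``mag_id`` (NA when the gene is not
    binned), ``biotype`` (CDS/rRNA/tRNA), ``marker_families`` (frozenset).
samples
    DataFrame with columns ``sample_id``, ``condition``
    (treatment/control), ``replicate``.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import FormatError, UsageError, ValidationError

__all__ = [
    "BIOTYPES",
    "read_quant",
    "write_quant",
    "read_gene_meta",
    "write_gene_meta",
    "read_samples",
    "write_samples",
    "read_targets",
    "write_targets",
    "write_network",
    "read_network",
    "NETWORK_FORMATS",
]

BIOTYPES = frozenset({"CDS", "rRNA", "tRNA"})
CONDITIONS = frozenset({"treatment", "control"})

_KALLISTO_COLS = {"target_id": "gene_id", "eff_length": "eff_length",
                  "est_counts": "est_count"}
_GENERIC_COLS = {"gene_id": "gene_id", "eff_length": "eff_length",
                 "est_count": "est_count"}


def _read_tsv(path, required: Iterable[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (header row required)")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_quant(path, sample_id: str, dialect: str = "kallisto") -> pd.DataFrame:
    """Read one per-sample quantification table.

    Parameters
    ----------
    path
        TSV (optionally gzipped) in the chosen dialect.
    sample_id
        Sample label attached to every record.
    dialect
        ``"kallisto"`` (default) or ``"generic"``.

    Returns
    -------
    DataFrame with columns gene_id, sample_id, est_count, eff_length.
    """
    if dialect not in ("kallisto", "generic"):
        raise UsageError(f"unknown quant dialect: {dialect!r}")
    colmap = _KALLISTO_COLS if dialect == "kallisto" else _GENERIC_COLS
    df = _read_tsv(path, colmap)
    df = df.rename(columns=colmap)[["gene_id"] + ["est_count", "eff_length"]]
    for col in ("est_count", "eff_length"):
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric value in {col}: {exc}")
    bad = df.index[df["est_count"] < 0]
    if len(bad):
        raise ValidationError(
            f"{path}: negative est_count at row {bad[0] + 2}"  # +2: header + 1-based
        )
    bad = df.index[~(df["eff_length"] > 0)]
    if len(bad):
        raise ValidationError(f"{path}: nonpositive eff_length at row {bad[0] + 2}")
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate gene_id {df['gene_id'][dup].iloc[0]!r}"
        )
    df.insert(1, "sample_id", sample_id)
    return df.reset_index(drop=True)


def write_quant(quant: pd.DataFrame, path, sample_id: str | None = None,
                gene_tpm: pd.Series | None = None) -> None:
    """Write one sample's records in the kallisto abundance dialect.

    ``length`` is emitted equal to ``eff_length`` and ``tpm`` from
    ``gene_tpm`` when given (zeros otherwise); both are ignored on re-read.
    """
    df = quant
    if sample_id is not None:
        df = df.loc[df["sample_id"] == sample_id]
    out = pd.DataFrame(
        {
            "target_id": df["gene_id"].to_numpy(),
            "length": df["eff_length"].to_numpy(),
            "eff_length": df["eff_length"].to_numpy(),
            "est_counts": df["est_count"].to_numpy(),
        }
    )
    if gene_tpm is not None:
        out["tpm"] = gene_tpm.reindex(out["target_id"]).fillna(0.0).to_numpy()
    else:
        out["tpm"] = 0.0
    out.to_csv(path, sep="\t", index=False)


def read_gene_meta(path, vocabulary: Iterable[str] | None = None) -> pd.DataFrame:
    """Read gene→MAG membership with biotype and marker families.

    Columns: ``gene_id``, ``mag_id`` (may be empty), ``biotype``,
    ``marker_families`` (comma-separated family names, may be empty).
    Unknown families (outside ``vocabulary``, defaulting to the built-in
    rule registry's families) raise a validation error.
    """
    from .roles import DEFAULT_MARKER_FAMILIES

    vocab = frozenset(DEFAULT_MARKER_FAMILIES if vocabulary is None else vocabulary)
    df = _read_tsv(path, ["gene_id", "mag_id", "biotype", "marker_families"])
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValidationError(f"{path}: duplicate gene_id {df['gene_id'][dup].iloc[0]!r}")
    bad = df.loc[~df["biotype"].isin(BIOTYPES), "biotype"]
    if len(bad):
        raise ValidationError(f"{path}: unknown biotype {bad.iloc[0]!r}")

    def parse_fams(cell) -> frozenset[str]:
        if pd.isna(cell) or not str(cell).strip():
            return frozenset()
        fams = frozenset(f.strip() for f in str(cell).split(",") if f.strip())
        unknown = fams - vocab
        if unknown:
            raise ValidationError(
                f"{path}: marker family {sorted(unknown)[0]!r} not in vocabulary"
            )
        return fams

    df["marker_families"] = df["marker_families"].map(parse_fams)
    df["mag_id"] = df["mag_id"].where(df["mag_id"].notna() & (df["mag_id"] != ""))
    return df.reset_index(drop=True)


def write_gene_meta(gene_meta: pd.DataFrame, path) -> None:
    out = gene_meta.copy()
    out["marker_families"] = out["marker_families"].map(
        lambda fams: ",".join(sorted(fams))
    )
    out["mag_id"] = out["mag_id"].fillna("")
    out.to_csv(path, sep="\t", index=False)


def read_samples(path) -> pd.DataFrame:
    """Read sample metadata (``sample_id``, ``condition``, ``replicate``)."""
    df = _read_tsv(path, ["sample_id", "condition", "replicate"])
    dup = df["sample_id"].duplicated()
    if dup.any():
        raise ValidationError(f"{path}: duplicate sample_id {df['sample_id'][dup].iloc[0]!r}")
    bad = df.loc[~df["condition"].isin(CONDITIONS), "condition"]
    if len(bad):
        raise ValidationError(f"{path}: unknown condition {bad.iloc[0]!r}")
    df["replicate"] = df["replicate"].astype(str)
    return df.reset_index(drop=True)


def write_samples(samples: pd.DataFrame, path) -> None:
    samples[["sample_id", "condition", "replicate"]].to_csv(path, sep="\t", index=False)


def read_targets(path, mag_universe: Iterable[str] | None = None) -> set[str]:
    """Read the target MAG id list (one id per line, '#' comments allowed)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        ids = {line.strip() for line in fh
               if line.strip() and not line.startswith("#")}
    if not ids:
        raise ValidationError(f"{path}: target set is empty")
    if mag_universe is not None:
        missing = ids - set(mag_universe)
        if missing:
            raise ValidationError(
                f"{path}: target MAG {sorted(missing)[0]!r} not in MAG universe"
            )
    return ids


def write_targets(targets: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for t in sorted(targets):
            fh.write(f"{t}\n")


# ---------------------------------------------------------------------------
# Network export

NETWORK_FORMATS = ("graphml", "gexf", "tsv")


def _clean_attrs(G: nx.Graph) -> nx.Graph:
    """GraphML/GEXF writers reject None; coerce to strings."""
    H = G.copy()
    for _, data in H.nodes(data=True):
        for k, v in list(data.items()):
            if v is None:
                data[k] = ""
    return H


def write_network(network: nx.Graph, path, format: str = "graphml") -> None:
    """Export the coexpression network.

    Nodes carry ``mag_id``, ``mean_log10_tpm`` (the node-size driver:
    average log10 TPM over treatment samples), ``roles`` (comma-joined),
    ``is_target`` and ``connected_to_target``; edges carry ``rho`` and
    ``p_adj``.
    """
    if format not in NETWORK_FORMATS:
        raise UsageError(
            f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}"
        )
    if format == "graphml":
        nx.write_graphml(_clean_attrs(network), path)
    elif format == "gexf":
        nx.write_gexf(_clean_attrs(network), path)
    else:
        rows = [
            {"source": u, "target": v,
             "rho": d.get("rho"), "p_adj": d.get("p_adj")}
            for u, v, d in sorted(network.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["source", "target", "rho", "p_adj"]).to_csv(
            path, sep="\t", index=False
        )


def read_network(path, format: str = "graphml") -> nx.Graph:
    """Re-read an exported network (edge-list TSV yields edges only)."""
    if format not in NETWORK_FORMATS:
        raise UsageError(
            f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}"
        )
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "gexf":
        return nx.read_gexf(path)
    df = pd.read_csv(path, sep="\t")
    G = nx.Graph()
    for row in df.itertuples(index=False):
        G.add_edge(str(row.source), str(row.target),
                   rho=float(row.rho), p_adj=float(row.p_adj))
    return G
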