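"""Construct the disease gene-expression profile from two omics layers.

The disease profile keeps the genes called differentially expressed (status
up or down) in BOTH the transcript and the protein analysis, carrying the
transcript-level log2 fold change. Genes whose direction disagrees between
the layers are kept and flagged as discordant — the intersection is on DE
status, not on sign.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .containers import DEResult, DiseaseProfile

logger = logging.getLogger(__name__)

__all__ = ["build_profile", "write_profile", "read_profile", "scatter_table"]


class ProfileParseError(ValueError):
    """Raised when a profile file violates the format or its invariants."""


def build_profile(
    transcript_de: list[DEResult],
    protein_de: list[DEResult],
) -> DiseaseProfile:
    """Intersect transcript and protein DE calls into a disease profile.

    Gene matching is exact on the uppercased symbol. The profile LFC is the
    transcript one; provenance records both layers' lfc/status and whether
    the two directions disagree. An empty intersection yields an empty
    profile with a warning, not an error.
    """
    if not transcript_de or not protein_de:
        raise ValueError("both DE result lists must be non-empty")
    tx = {r.gene.upper(): r for r in transcript_de if r.status in ("up", "down")}
    pr = {r.gene.upper(): r for r in protein_de if r.status in ("up", "down")}
    shared = sorted(set(tx) & set(pr))
    if not shared:
        logger.warning("transcript and protein DE gene sets do not intersect; profile is empty")
    entries = {g: tx[g].lfc for g in shared}
    prov = pd.DataFrame(
        {
            "transcript_lfc": [tx[g].lfc for g in shared],
            "transcript_status": [tx[g].status for g in shared],
            "protein_lfc": [pr[g].lfc for g in shared],
            "protein_status": [pr[g].status for g in shared],
            "protein_lfc_imputed": [pr[g].lfc_imputed for g in shared],
            "discordant": [tx[g].status != pr[g].status for g in shared],
        },
        index=pd.Index(shared, name="gene"),
    )
    profile = DiseaseProfile(entries, prov.loc[list(entries)] if shared else prov)
    # reorder provenance to the profile's descending-LFC order
    profile.provenance = prov.loc[profile.genes] if shared else prov
    n_disc = int(prov["discordant"].sum()) if shared else 0
    if n_disc:
        logger.info("profile has %d gene(s) with discordant direction across omics", n_disc)
    return profile


def write_profile(profile: DiseaseProfile, path: "str | Path") -> None:
    """Write a two-column TSV (gene, lfc) plus a provenance sidecar."""
    path = Path(path)
    profile.lfc_vector().rename_axis("gene").to_csv(path, sep="\t", header=["lfc"])
    profile.provenance.to_csv(path.with_suffix(path.suffix + ".provenance.tsv"), sep="\t")


def read_profile(path: "str | Path") -> DiseaseProfile:
    """Read a profile TSV written by :func:`write_profile` (lossless)."""
    path = Path(path)
    entries: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene", "lfc"]:
            raise ProfileParseError(f"{path}: line 1: expected header 'gene\\tlfc'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ProfileParseError(f"{path}: line {lineno}: expected 2 columns")
            gene, raw = parts
            if gene in entries:
                raise ProfileParseError(f"{path}: line {lineno}: duplicate gene {gene!r}")
            try:
                entries[gene] = float(raw)
            except ValueError as exc:
                raise ProfileParseError(f"{path}: line {lineno}: bad lfc {raw!r}") from exc
    sidecar = path.with_suffix(path.suffix + ".provenance.tsv")
    prov = None
    if sidecar.exists():
        prov = pd.read_csv(sidecar, sep="\t", index_col="gene")
    return DiseaseProfile(entries, prov)


def scatter_table(
    transcript_de: list[DEResult],
    protein_de: list[DEResult],
    profile: DiseaseProfile,
) -> pd.DataFrame:
    """Cross-omics LFC scatter export: one row per gene present in both
    DE analyses, flagging profile membership (for plotting outside)."""
    tx = {r.gene.upper(): r.lfc for r in transcript_de}
    pr = {r.gene.upper(): r.lfc for r in protein_de}
    shared = sorted(set(tx) & set(pr))
    return pd.DataFrame(
        {
            "gene": shared,
            "transcript_lfc": [tx[g] for g in shared],
            "protein_lfc": [pr[g] for g in shared],
            "in_profile": [g in profile for g in shared],
        }
    )
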