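"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are TSV. Expression matrices are genes x samples with the gene
id in the first column and sample ids in the header; sample metadata is a
two-column table (sample_id, group). Signature libraries use the long
format of typical connectivity-map exports: one row per
(signature, gene) with columns signature_id, perturbagen, library, gene,
lfc.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CandidateScore,
    DEResult,
    ExpressionMatrix,
    SignatureProfile,
    SyntheticTruth,
    de_results_to_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "write_matrix", "read_matrix",
    "write_signatures", "read_signatures",
    "write_de_table", "read_de_table",
    "write_candidates",
    "write_truth", "read_truth",
]

SIGNATURE_COLUMNS = ["signature_id", "perturbagen", "library", "gene", "lfc"]


def write_matrix(mat: ExpressionMatrix, path: "str | Path", metadata_path: "str | Path") -> None:
    mat.values.rename_axis("gene").to_csv(path, sep="\t")
    pd.DataFrame({"sample_id": mat.groups.index, "group": mat.groups.values}).to_csv(
        metadata_path, sep="\t", index=False
    )


def read_matrix(path: "str | Path", metadata_path: "str | Path", kind: str = "counts") -> ExpressionMatrix:
    sep = "," if str(path).endswith(".csv") else "\t"
    values = pd.read_csv(path, sep=sep, index_col=0)
    values.index = values.index.astype(str)
    meta = pd.read_csv(metadata_path, sep="," if str(metadata_path).endswith(".csv") else "\t")
    if not {"sample_id", "group"} <= set(meta.columns):
        raise ValueError(f"{metadata_path}: metadata needs 'sample_id' and 'group' columns")
    groups = pd.Series(meta["group"].values, index=meta["sample_id"].astype(str))
    return ExpressionMatrix(values, groups, kind=kind)


def write_signatures(sigs: list[SignatureProfile], path: "str | Path") -> None:
    rows = [
        (s.signature_id, s.perturbagen, s.library, g, v)
        for s in sigs
        for g, v in s.entries.items()
    ]
    pd.DataFrame(rows, columns=SIGNATURE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_signatures(path: "str | Path") -> list[SignatureProfile]:
    """Read a long-format signature table.

    Duplicate (signature, gene) rows resolve last-write-wins with a warning.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = set(SIGNATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing signature columns {sorted(missing)}")
    sigs: dict[str, SignatureProfile] = {}
    n_dup = 0
    for row in df.itertuples(index=False):
        sid = str(row.signature_id)
        if sid not in sigs:
            sigs[sid] = SignatureProfile(
                signature_id=sid, perturbagen=str(row.perturbagen), library=str(row.library)
            )
        if str(row.gene) in sigs[sid].entries:
            n_dup += 1
        sigs[sid].entries[str(row.gene)] = float(row.lfc)
    if n_dup:
        logger.warning("%s: %d duplicate (signature, gene) row(s); last value wins", path, n_dup)
    return list(sigs.values())


def write_de_table(results: list[DEResult], path: "str | Path") -> None:
    de_results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_de_table(path: "str | Path") -> list[DEResult]:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    needed = {"gene", "lfc", "status"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: DE table needs columns {sorted(needed)}")
    out = []
    for row in df.itertuples(index=False):
        p = getattr(row, "p", np.nan)
        padj = getattr(row, "padj", np.nan)
        out.append(
            DEResult(
                gene=str(row.gene),
                lfc=float(row.lfc),
                p=None if pd.isna(p) else float(p),
                padj=None if pd.isna(padj) else float(padj),
                status=str(row.status),
                lfc_imputed=bool(getattr(row, "lfc_imputed", False)),
            )
        )
    return out


def write_candidates(scores: list[CandidateScore], path: "str | Path") -> None:
    pd.DataFrame(
        {
            "drug": [s.drug for s in scores],
            "rs": [s.rs for s in scores],
            "oc": [s.oc for s in scores],
            "a": [s.a for s in scores],
            "g": [s.g for s in scores],
            "n_signatures": [s.n_signatures for s in scores],
            "cluster": [s.cluster for s in scores],
            "bbb": [s.bbb for s in scores],
            "prior_trials": [s.prior_trials for s in scores],
            "rank": [s.rank for s in scores],
        }
    ).to_csv(path, sep="\t", index=False)


def write_truth(truth: SyntheticTruth, path: "str | Path") -> None:
    payload = {
        "de_genes": sorted(truth.de_genes),
        "planted_lfc": truth.planted_lfc,
        "drug_rho": truth.drug_rho,
        "one_group_proteins": truth.one_group_proteins,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: "str | Path") -> SyntheticTruth:
    d = json.loads(Path(path).read_text())
    return SyntheticTruth(
        de_genes=set(d["de_genes"]),
        planted_lfc=d["planted_lfc"],
        drug_rho=d["drug_rho"],
        one_group_proteins=d.get("one_group_proteins", {}),
        seed=d["seed"],
    )
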