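"""End-to-end orchestration: DE -> profile -> screen -> score -> rank.

A :class:`RunConfig` (typically loaded from YAML) names the inputs and all
thresholds; :func:`run_pipeline` writes every stage's table into a run
directory together with a machine-readable run log (config hash, seed,
package version, per-stage record counts), so each stage can be re-run
from its intermediate files and reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from . import io as rio
from .containers import DEResult
from .de import de_proteins, de_transcripts, impute_one_group_lfc, pca_outlier_screen
from .prioritize import cluster_signatures, rank_candidates, score_drugs
from .profiles import build_profile, scatter_table, write_profile
from .screen import ScreenConfig, filter_approved, screen_signatures

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "ValidationFailure", "DataError"]


class ValidationFailure(ValueError):
    """Config invalid (CLI exit code 2)."""


class DataError(ValueError):
    """Input data missing or malformed (CLI exit code 3)."""


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    # inputs (matrices or precomputed DE tables; at least one per omics)
    counts: Path | None = None
    counts_metadata: Path | None = None
    transcript_de_table: Path | None = None
    intensities: Path | None = None
    intensities_metadata: Path | None = None
    protein_de_table: Path | None = None
    signatures: Path | None = None
    approved_drugs: Path | None = None
    annotations: Path | None = None

    # thresholds
    alpha_transcript: float = 0.05
    alpha_protein: float = 0.05
    lfc_min: float = 1.0
    impute_fixed_value: float | str = "auto"
    outlier_k_sd: float = 3.0
    outlier_components: int = 2
    skip_outlier_screen: bool = False

    default_cutoff: float = -0.2
    per_library_cutoffs: dict[str, float] = Field(
        default_factory=lambda: {"lincs chemical perturbagen": -0.6}
    )
    min_overlap: int = 10

    minkowski_p: float = 2.0
    n_clusters: int = 8
    append_reference: bool = True

    bbb_min: float | None = None
    require_no_prior_trials: bool = False

    seed: int = 0

    @field_validator("alpha_transcript", "alpha_protein")
    @classmethod
    def _alpha_range(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError(f"alpha must be in (0, 1), got {v}")
        return v

    @field_validator("lfc_min")
    @classmethod
    def _lfc_min_range(cls, v: float) -> float:
        if v < 0:
            raise ValueError("lfc_min must be >= 0")
        return v

    @field_validator("default_cutoff")
    @classmethod
    def _cutoff_neg(cls, v: float) -> float:
        if v >= 0:
            raise ValueError("concordance cutoffs must be negative")
        return v

    @field_validator("bbb_min")
    @classmethod
    def _bbb_range(cls, v: float | None) -> float | None:
        if v is not None and not 0 <= v <= 1:
            raise ValueError("bbb_min must be in [0, 1]")
        return v

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            return cls(**raw)
        except Exception as exc:
            raise ValidationFailure(f"invalid config {path}: {exc}") from exc

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _transcript_stage(cfg: RunConfig, outdir: Path, log: dict) -> list[DEResult]:
    if cfg.transcript_de_table is not None:
        results = rio.read_de_table(cfg.transcript_de_table)
        log["transcript_de"] = {"source": "precomputed", "n": len(results)}
        return results
    if cfg.counts is None or cfg.counts_metadata is None:
        raise DataError("transcript stage: provide counts + counts_metadata or transcript_de_table")
    mat = rio.read_matrix(cfg.counts, cfg.counts_metadata, kind="counts")
    n_flagged = 0
    if not cfg.skip_outlier_screen and len(mat.sample_ids) >= 3:
        kept, flagged, scores = pca_outlier_screen(mat, cfg.outlier_components, cfg.outlier_k_sd)
        scores.to_csv(outdir / "transcript_pca_scores.tsv", sep="\t")
        if flagged:
            mat = mat.subset_samples(kept)
        n_flagged = len(flagged)
    results = de_transcripts(mat, cfg.alpha_transcript, cfg.lfc_min)
    rio.write_de_table(results, outdir / "transcript_de.tsv")
    log["transcript_de"] = {
        "source": "computed", "n": len(results), "outliers_removed": n_flagged,
        "n_up": sum(r.status == "up" for r in results),
        "n_down": sum(r.status == "down" for r in results),
    }
    return results


def _protein_stage(cfg: RunConfig, outdir: Path, log: dict) -> list[DEResult]:
    if cfg.protein_de_table is not None:
        results = rio.read_de_table(cfg.protein_de_table)
        log["protein_de"] = {"source": "precomputed", "n": len(results)}
        return results
    if cfg.intensities is None or cfg.intensities_metadata is None:
        raise DataError("protein stage: provide intensities + intensities_metadata or protein_de_table")
    mat = rio.read_matrix(cfg.intensities, cfg.intensities_metadata, kind="intensity")
    finite = de_proteins(mat, cfg.alpha_protein, cfg.lfc_min)
    results = impute_one_group_lfc(mat, finite, cfg.impute_fixed_value, cfg.alpha_protein, cfg.lfc_min)
    rio.write_de_table(results, outdir / "protein_de.tsv")
    log["protein_de"] = {
        "source": "computed", "n": len(results),
        "n_imputed": sum(r.lfc_imputed for r in results),
        "n_up": sum(r.status == "up" for r in results),
        "n_down": sum(r.status == "down" for r in results),
    }
    return results


def run_pipeline(cfg: RunConfig, outdir: "str | Path") -> Path:
    """Run all stages and write outputs + run log into ``outdir``.

    Stops after the profile stage (with an explicit message) when the
    omics intersection is empty. Returns the run directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_log: dict = {}

    tx = _transcript_stage(cfg, outdir, stage_log)
    pr = _protein_stage(cfg, outdir, stage_log)

    profile = build_profile(tx, pr)
    write_profile(profile, outdir / "disease_profile.tsv")
    scatter_table(tx, pr, profile).to_csv(outdir / "omics_scatter.tsv", sep="\t", index=False)
    stage_log["profile"] = {"n_genes": len(profile)}
    if len(profile) == 0:
        _write_log(cfg, outdir, stage_log, status="stopped: empty disease profile")
        logger.error("disease profile is empty; pipeline stopped after the profile stage")
        return outdir

    if cfg.signatures is None:
        _write_log(cfg, outdir, stage_log, status="stopped: no signature library provided")
        return outdir
    try:
        sigs = rio.read_signatures(cfg.signatures)
    except (ValueError, FileNotFoundError) as exc:
        raise DataError(f"screen stage: {exc}") from exc
    screen_cfg = ScreenConfig(
        default_cutoff=cfg.default_cutoff,
        per_library_cutoffs=dict(cfg.per_library_cutoffs),
        min_overlap=cfg.min_overlap,
    )
    retained = screen_signatures(profile, sigs, screen_cfg)
    if cfg.approved_drugs is not None:
        approved = {
            line.strip()
            for line in Path(cfg.approved_drugs).read_text().splitlines()
            if line.strip()
        }
        retained = filter_approved(retained, approved)
    pd.DataFrame(
        {
            "signature_id": [s.signature_id for s in retained],
            "perturbagen": [s.perturbagen for s in retained],
            "library": [s.library for s in retained],
            "n_overlap": [s.n_overlap for s in retained],
            "concordance": [s.concordance for s in retained],
        }
    ).to_csv(outdir / "screen_hits.tsv", sep="\t", index=False)
    stage_log["screen"] = {"n_input": len(sigs), "n_retained": len(retained)}
    if len(retained) < 2:
        _write_log(cfg, outdir, stage_log, status="stopped: <2 retained signatures")
        logger.warning("fewer than 2 signatures retained; skipping clustering and scoring")
        return outdir

    k = min(cfg.n_clusters, len(retained) + int(cfg.append_reference))
    clusters = cluster_signatures(profile, retained, cfg.minkowski_p, k, cfg.append_reference)
    pd.DataFrame(
        {"column": list(clusters.labels), "cluster": list(clusters.labels.values())}
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(clusters.linkage, columns=["left", "right", "height", "size"]).to_csv(
        outdir / "linkage.tsv", sep="\t", index=False
    )
    stage_log["cluster"] = {"k": k, "reference_label": clusters.reference_label,
                            "n_excluded": len(clusters.excluded)}

    scores = score_drugs(profile, retained, clusters)
    annotations = None
    if cfg.annotations is not None:
        annotations = pd.read_csv(cfg.annotations, sep="\t")
    ranked = rank_candidates(
        scores, annotations,
        require_no_prior_trials=cfg.require_no_prior_trials,
        bbb_min=cfg.bbb_min,
    )
    rio.write_candidates(ranked, outdir / "candidates.tsv")
    stage_log["rank"] = {"n_scored": len(scores), "n_ranked": len(ranked)}

    _write_log(cfg, outdir, stage_log, status="complete")
    return outdir


def _write_log(cfg: RunConfig, outdir: Path, stages: dict, status: str) -> None:
    log = {
        "status": status,
        "config_hash": cfg.config_hash(),
        "config": cfg.model_dump(mode="json"),
        "seed": cfg.seed,
        "revscreen_version": __version__,
        "stages": stages,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
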