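"""Drug-level aggregation, reversal scoring and candidate ranking.

Two indices quantify how strongly a drug reverses the disease profile:

* Regulation Score (RS): a weighted sum of per-gene reversal magnitudes.
  For gene k with disease LFC ``p_k`` and drug LFC ``d_k``,

      delta_k = |d_k - p_k|  if d_k * p_k < 0, else 0
      RS      = sum_k delta_k * |p_k| / sum_i |p_i|

  where the weight denominator runs over ALL profile genes and genes
  absent from the drug profile contribute 0. RS lies in [0, +inf); a drug
  identical to the disease profile scores 0 and the exact inverse of a
  unit-magnitude profile scores 2.

* Overall Coverage (OC = a/g): the fraction of profile genes whose drug
  LFC has strictly opposite sign (a of g profile genes).

Signatures are also hierarchically clustered (Minkowski distance, Ward
linkage) with the disease profile optionally appended as a reference
column, so reversal clusters can be read off a cut of the tree.
"""

from __future__ import annotations

import logging
from statistics import median

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import (
    CandidateScore,
    ClusterAssignment,
    DiseaseProfile,
    DrugProfile,
    InvalidParameterError,
    SignatureProfile,
)
from .screen import normalize_name

logger = logging.getLogger(__name__)

__all__ = [
    "aggregate_drug_profile",
    "regulation_score",
    "overall_coverage",
    "cluster_signatures",
    "score_drugs",
    "rank_candidates",
    "REFERENCE_COLUMN",
]

REFERENCE_COLUMN = "__disease_profile__"


def aggregate_drug_profile(sigs: list[SignatureProfile], drug: str | None = None) -> DrugProfile:
    """Collapse a drug's signatures to a per-gene median-LFC profile.

    Each gene's value is the median over the signatures where the gene is
    present; genes absent from every signature are absent from the profile.
    """
    if not sigs:
        raise InvalidParameterError("aggregate_drug_profile needs at least one signature")
    names = {s.perturbagen for s in sigs}
    if len(names) > 1:
        raise InvalidParameterError(f"signatures span multiple perturbagens: {sorted(names)}")
    if drug is None:
        drug = next(iter(names))
    per_gene: dict[str, list[float]] = {}
    for s in sigs:
        for g, v in s.entries.items():
            per_gene.setdefault(g, []).append(v)
    entries = {g: float(median(vals)) for g, vals in per_gene.items()}
    return DrugProfile(drug=drug, entries=entries, n_signatures=len(sigs))


def regulation_score(
    profile: DiseaseProfile, drug: DrugProfile
) -> tuple[float, dict[str, float]]:
    """Regulation Score of a drug profile against the disease profile.

    Returns ``(rs, per_gene_delta)`` where ``per_gene_delta`` covers every
    profile gene (0 for genes the drug does not reverse or does not cover).
    A sign product of exactly 0 contributes 0.
    """
    if len(profile) == 0:
        raise InvalidParameterError("disease profile must be non-empty")
    denom = profile.total_abs_lfc()
    rs = 0.0
    deltas: dict[str, float] = {}
    for g, p in profile.entries.items():
        d = drug.entries.get(g)
        if d is not None and d * p < 0:
            delta = abs(d - p)
        else:
            delta = 0.0
        deltas[g] = delta
        rs += delta * abs(p) / denom
    return rs, deltas


def overall_coverage(profile: DiseaseProfile, drug: DrugProfile) -> tuple[float, int, int]:
    """Overall Coverage: fraction of profile genes the drug reverses.

    ``a`` counts profile genes whose drug LFC has strictly opposite sign
    (missing genes never count); ``g`` is the profile size. Returns
    ``(a/g, a, g)``.
    """
    if len(profile) == 0:
        raise InvalidParameterError("disease profile must be non-empty")
    g = len(profile)
    a = sum(
        1
        for gene, p in profile.entries.items()
        if (d := drug.entries.get(gene)) is not None and d * p < 0
    )
    return a / g, a, g


def _pairwise_minkowski(
    M: np.ndarray, p: float
) -> np.ndarray:
    """Pairwise Minkowski distance over mutually observed rows, rescaled by
    ``(n_rows / n_observed)**(1/p)`` so sparser overlaps are not biased
    toward smaller distances. NaN marks unobserved cells."""
    n_rows, n_cols = M.shape
    D = np.zeros((n_cols, n_cols))
    obs = ~np.isnan(M)
    for i in range(n_cols):
        for j in range(i + 1, n_cols):
            both = obs[:, i] & obs[:, j]
            n_obs = int(both.sum())
            if n_obs == 0:
                D[i, j] = D[j, i] = np.nan
                continue
            diff = np.abs(M[both, i] - M[both, j])
            d = (diff**p).sum() ** (1.0 / p)
            D[i, j] = D[j, i] = d * (n_rows / n_obs) ** (1.0 / p)
    return D


def cluster_signatures(
    profile: DiseaseProfile,
    sigs: list[SignatureProfile],
    minkowski_p: float = 2.0,
    k: int = 8,
    append_reference: bool = True,
    min_mutual_genes: int = 3,
) -> ClusterAssignment:
    """Ward hierarchical clustering of signatures on profile-gene LFCs.

    The clustered matrix has one row per profile gene and one column per
    signature (plus the disease profile itself as a reference column when
    ``append_reference``). Distances are pairwise-complete Minkowski
    distances with a coverage rescale; Ward linkage uses the squared-update
    (Ward.D2) convention. Columns with fewer than ``min_mutual_genes``
    mutually observed genes against every other column are excluded (logged).
    Pairs that remain unobserved after exclusion get the matrix's maximum
    finite distance.
    """
    if len(sigs) < 2:
        raise InvalidParameterError("clustering needs at least 2 signatures")
    if minkowski_p <= 0:
        raise InvalidParameterError("minkowski_p must be positive")
    genes = profile.genes
    cols = [s.signature_id for s in sigs]
    M = np.full((len(genes), len(cols) + int(append_reference)), np.nan)
    for j, s in enumerate(sigs):
        for i, g in enumerate(genes):
            if g in s.entries:
                M[i, j] = s.entries[g]
    if append_reference:
        cols = cols + [REFERENCE_COLUMN]
        M[:, -1] = [profile[g] for g in genes]

    obs = ~np.isnan(M)
    mutual = obs.T.astype(int) @ obs.astype(int)
    np.fill_diagonal(mutual, 0)
    keep = mutual.max(axis=1) >= min_mutual_genes
    excluded = [c for c, k_ in zip(cols, keep) if not k_]
    if excluded:
        logger.warning("excluding %d column(s) with insufficient shared genes: %s", len(excluded), excluded)
    cols = [c for c, k_ in zip(cols, keep) if k_]
    M = M[:, keep]
    if len(cols) < 2:
        raise InvalidParameterError("fewer than 2 clusterable columns remain")
    if k > len(cols):
        raise InvalidParameterError(f"k={k} exceeds number of clustered columns ({len(cols)})")

    D = _pairwise_minkowski(M, minkowski_p)
    if np.isnan(D).any():
        finite_max = np.nanmax(D)
        logger.warning("some column pairs share no genes; assigning maximum distance %.3g", finite_max)
        D = np.where(np.isnan(D), finite_max, D)
    Z = hierarchy.linkage(squareform(D, checks=False), method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    assignment = {c: int(l) for c, l in zip(cols, labels)}
    ref_label = assignment.get(REFERENCE_COLUMN) if append_reference else None
    return ClusterAssignment(labels=assignment, linkage=Z, k=k, reference_label=ref_label, excluded=excluded)


def score_drugs(
    profile: DiseaseProfile,
    retained: list[SignatureProfile],
    clusters: ClusterAssignment | None = None,
) -> list[CandidateScore]:
    """Aggregate retained signatures per perturbagen and score RS/OC.

    Signatures are grouped by normalized perturbagen name; each drug's
    profile is the per-gene median over all its retained signatures.
    """
    by_drug: dict[str, list[SignatureProfile]] = {}
    display: dict[str, str] = {}
    for s in retained:
        key = normalize_name(s.perturbagen)
        by_drug.setdefault(key, []).append(s)
        display.setdefault(key, s.perturbagen)
    scores: list[CandidateScore] = []
    for key in sorted(by_drug):
        group = by_drug[key]
        dp = aggregate_drug_profile(group, drug=display[key])
        rs, _ = regulation_score(profile, dp)
        oc, a, g = overall_coverage(profile, dp)
        cluster = None
        if clusters is not None:
            labs = {clusters.labels[s.signature_id] for s in group if s.signature_id in clusters.labels}
            cluster = min(labs) if labs else None
        scores.append(
            CandidateScore(drug=display[key], rs=rs, oc=oc, a=a, g=g,
                           n_signatures=len(group), cluster=cluster)
        )
    return scores


def rank_candidates(
    scores: list[CandidateScore],
    annotations: pd.DataFrame | None = None,
    require_no_prior_trials: bool = False,
    bbb_min: float | None = None,
) -> list[CandidateScore]:
    """Order candidates by descending RS (ties: descending OC, then name).

    ``annotations`` is an optional table with a ``drug`` column and
    optionally ``bbb`` (blood-brain-barrier penetration probability) and
    ``prior_trials`` (count of prior disease trials), merged on normalized
    names. Selection filters mirror the usual candidate criteria: drop
    drugs already tried for the disease (``require_no_prior_trials``) and
    drugs unlikely to reach the tissue (``bbb_min``, conventionally 0.9).
    Ranks are assigned 1..n after filtering.
    """
    ann: dict[str, dict] = {}
    if annotations is not None:
        if "drug" not in annotations.columns:
            raise InvalidParameterError("annotation table must have a 'drug' column")
        for _, row in annotations.iterrows():
            ann[normalize_name(str(row["drug"]))] = row.to_dict()
    out = []
    for s in scores:
        rec = ann.get(normalize_name(s.drug), {})
        bbb = rec.get("bbb", s.bbb)
        prior = rec.get("prior_trials", s.prior_trials)
        out.append(
            CandidateScore(
                drug=s.drug, rs=s.rs, oc=s.oc, a=s.a, g=s.g, n_signatures=s.n_signatures,
                cluster=s.cluster,
                bbb=None if bbb is None or pd.isna(bbb) else float(bbb),
                prior_trials=None if prior is None or pd.isna(prior) else int(prior),
            )
        )
    if require_no_prior_trials:
        if any(s.prior_trials is None for s in out):
            raise InvalidParameterError(
                "filter on prior trials requested but column 'prior_trials' is missing for some drugs"
            )
        out = [s for s in out if s.prior_trials == 0]
    if bbb_min is not None:
        if any(s.bbb is None for s in out):
            raise InvalidParameterError(
                "filter on BBB probability requested but column 'bbb' is missing for some drugs"
            )
        out = [s for s in out if s.bbb >= bbb_min]
    out.sort(key=lambda s: (-s.rs, -s.oc, s.drug))
    for i, s in enumerate(out, start=1):
        s.rank = i
    return out
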