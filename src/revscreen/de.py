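"""Differential expression for transcript counts and protein intensities.

Transcripts: median-of-ratios normalization followed by a per-gene
negative-binomial Wald test of the group effect, with a gene-wise
method-of-moments dispersion estimate (floored at a small positive
constant). This is a deliberately simple reimplementation of the standard
count-based DE workflow — no dispersion shrinkage or empirical Bayes — and
the pipeline also accepts precomputed DE tables so published results can be
consumed directly.

Proteins: Welch two-sample t-test on log2 intensities; the fold change is
computed on the raw intensity scale, ``log2(mean case / mean control)``.
Proteins detected in only one group get a fixed imputed fold change
approximating the experiment's maximum observed |LFC|
(:func:`impute_one_group_lfc`).

Calls use ``status = up`` iff padj < alpha and lfc > lfc_min, ``down`` iff
padj < alpha and lfc < -lfc_min (defaults alpha=0.05, lfc_min=1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .containers import CASE, CONTROL, DEResult, ExpressionMatrix, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "adjust_pvalues",
    "pca_outlier_screen",
    "size_factors",
    "de_transcripts",
    "de_proteins",
    "impute_one_group_lfc",
]

DISPERSION_FLOOR = 1e-8


def adjust_pvalues(p: "list[float] | np.ndarray", method: str) -> np.ndarray:
    """Multiple-testing adjustment; ``method`` is ``"BH"`` or ``"bonferroni"``.

    Output preserves input order; BH is the standard step-up procedure with
    enforced monotonicity, Bonferroni is ``min(1, m*p)``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method.lower())
    if key is None:
        raise InvalidParameterError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def _status(lfc: float, padj: float | None, alpha: float, lfc_min: float) -> str:
    if padj is None or not np.isfinite(lfc):
        return "ns"
    if padj < alpha and lfc > lfc_min:
        return "up"
    if padj < alpha and lfc < -lfc_min:
        return "down"
    return "ns"


def pca_outlier_screen(
    mat: ExpressionMatrix,
    n_components: int = 2,
    k_sd: float = 3.0,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Flag samples far from their group centroid in PC space.

    Counts are log2(count+1)-transformed; intensities are log2-transformed
    with absent values filled by each gene's observed mean. A sample is
    flagged iff its Euclidean distance from its group centroid in the first
    ``n_components`` principal-component scores exceeds ``k_sd`` times the
    group's RMS distance from that centroid.

    Returns (kept sample ids, flagged sample ids, per-sample score table).
    """
    if k_sd <= 0:
        raise InvalidParameterError("k_sd must be positive")
    if len(mat.sample_ids) < 3:
        raise InvalidParameterError("PCA outlier screen needs at least 3 samples")
    if mat.kind == "counts":
        X = np.log2(mat.values.to_numpy(dtype=float) + 1.0)
    else:
        logv = np.log2(mat.values.to_numpy(dtype=float))
        row_mean = np.nanmean(np.where(np.isfinite(logv), logv, np.nan), axis=1, keepdims=True)
        row_mean = np.where(np.isfinite(row_mean), row_mean, 0.0)
        X = np.where(np.isfinite(logv), logv, row_mean)
    X = X.T  # samples x genes

    if np.allclose(X.var(axis=0).sum(), 0.0):
        logger.warning("zero-variance matrix: no PCA outliers flagged")
        scores = pd.DataFrame(
            0.0, index=mat.sample_ids, columns=[f"PC{i+1}" for i in range(n_components)]
        )
        scores["group"] = mat.groups.values
        scores["dist"] = 0.0
        scores["flagged"] = False
        return list(mat.sample_ids), [], scores

    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pcs = PCA(n_components=k, svd_solver="full").fit_transform(X - X.mean(axis=0))
    scores = pd.DataFrame(pcs, index=mat.sample_ids, columns=[f"PC{i+1}" for i in range(k)])
    scores["group"] = mat.groups.values

    flagged: list[str] = []
    dist = pd.Series(0.0, index=scores.index)
    for grp, sub in scores.groupby("group", sort=False):
        pts = sub.iloc[:, :k].to_numpy()
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        dist.loc[sub.index] = d
        rms = float(np.sqrt(np.mean(d**2)))
        if rms > 0:
            flagged.extend(sub.index[d > k_sd * rms])
    scores["dist"] = dist
    scores["flagged"] = scores.index.isin(flagged)
    kept = [s for s in mat.sample_ids if s not in set(flagged)]
    if flagged:
        logger.info("PCA screen flagged %d sample(s): %s", len(flagged), flagged)
    return kept, flagged, scores


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (the standard count normalization).

    The reference is the per-gene geometric mean across samples; each
    sample's factor is the median of count/reference over genes whose
    counts are positive in every sample.
    """
    if counts.kind != "counts":
        raise InvalidParameterError("size_factors applies to count matrices")
    vals = counts.values.to_numpy(dtype=float)
    all_pos = (vals > 0).all(axis=1)
    if not all_pos.any():
        raise InvalidParameterError(
            "size factors undefined: no gene has positive counts in every sample"
        )
    logref = np.log(vals[all_pos]).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(vals[all_pos]) - logref)
    return pd.Series(np.median(ratios, axis=0), index=counts.sample_ids, name="size_factor")


def de_transcripts(
    counts: ExpressionMatrix,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> list[DEResult]:
    """Negative-binomial Wald test per gene on normalized counts.

    Counts are divided by median-of-ratios size factors; the per-gene
    overdispersion is a pooled within-group method-of-moments estimate
    ``(var - mean) / mean^2`` floored at 1e-8. The Wald statistic tests the
    log2 ratio of group means with a delta-method standard error; p-values
    are BH-adjusted. Genes with a zero group mean or undefined statistic
    get p = 1 and status ``ns``.
    """
    case = counts.samples_in(CASE)
    ctrl = counts.samples_in(CONTROL)
    if len(case) < 2 or len(ctrl) < 2:
        raise InvalidParameterError("each group needs >= 2 samples for transcript DE")
    sf = size_factors(counts)
    norm = counts.values.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    idx_case = [counts.sample_ids.index(s) for s in case]
    idx_ctrl = [counts.sample_ids.index(s) for s in ctrl]
    n1, n0 = len(idx_case), len(idx_ctrl)
    y1, y0 = norm[:, idx_case], norm[:, idx_ctrl]
    m1, m0 = y1.mean(axis=1), y0.mean(axis=1)
    v1, v0 = y1.var(axis=1, ddof=1), y0.var(axis=1, ddof=1)

    pooled_var = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    pooled_mean = (m1 + m0) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (pooled_var - pooled_mean) / pooled_mean**2
    disp = np.where(np.isfinite(disp), disp, DISPERSION_FLOOR)
    disp = np.maximum(disp, DISPERSION_FLOOR)

    ok = (m1 > 0) & (m0 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.where(ok, np.log2(np.where(ok, m1, 1.0) / np.where(ok, m0, 1.0)), 0.0)
        # Var of a normalized count: mu/sf + disp*mu^2; delta method on log2 mean ratio
        var_mean1 = (m1[:, None] / sf.to_numpy()[None, idx_case] + disp[:, None] * m1[:, None] ** 2).sum(axis=1) / n1**2
        var_mean0 = (m0[:, None] / sf.to_numpy()[None, idx_ctrl] + disp[:, None] * m0[:, None] ** 2).sum(axis=1) / n0**2
        se = np.sqrt(var_mean1 / m1**2 + var_mean0 / m0**2) / np.log(2)
        z = np.where(ok & (se > 0), lfc / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(ok & (se > 0), 2.0 * stats.norm.sf(np.abs(z)), 1.0)

    padj = adjust_pvalues(p, "BH")
    results = []
    for g, l, pv, pa in zip(counts.gene_ids, lfc, p, padj):
        results.append(DEResult(g, float(l), float(pv), float(pa), _status(float(l), float(pa), alpha, lfc_min)))
    return results


def _group_observations(mat: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    case = mat.values[mat.samples_in(CASE)]
    ctrl = mat.values[mat.samples_in(CONTROL)]
    return case, ctrl


def de_proteins(
    intensities: ExpressionMatrix,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> list[DEResult]:
    """Welch t-test per protein on log2 intensities, Bonferroni-adjusted.

    The fold change is taken on the raw intensity scale:
    ``lfc = log2(mean case / mean control)``. Proteins with fewer than two
    observed values in either group are excluded here (one-group proteins —
    all values absent in exactly one group — are handled by
    :func:`impute_one_group_lfc`).
    """
    case, ctrl = _group_observations(intensities)
    raw_p: list[float] = []
    rows: list[tuple[str, float]] = []
    n_excluded = 0
    for gene in intensities.gene_ids:
        c = case.loc[gene].dropna()
        k = ctrl.loc[gene].dropna()
        if len(c) < 2 or len(k) < 2:
            n_excluded += 1
            continue
        lfc = float(np.log2(c.mean() / k.mean()))
        t, p = stats.ttest_ind(np.log2(c), np.log2(k), equal_var=False)
        p = 1.0 if not np.isfinite(p) else float(p)
        raw_p.append(p)
        rows.append((gene, lfc))
    if n_excluded:
        logger.info("de_proteins: %d protein(s) excluded (<2 observed values in a group)", n_excluded)
    padj = adjust_pvalues(raw_p, "bonferroni") if raw_p else np.array([])
    return [
        DEResult(g, lfc, p, float(pa), _status(lfc, float(pa), alpha, lfc_min))
        for (g, lfc), p, pa in zip(rows, raw_p, padj)
    ]


def impute_one_group_lfc(
    intensities: ExpressionMatrix,
    finite_results: list[DEResult],
    fixed_value: "float | str" = "auto",
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> list[DEResult]:
    """Assign a fixed fold change to proteins detected in only one group.

    A one-group protein has every value absent in exactly one group and at
    least two observed in the other; its ratio-based LFC is undefined, so it
    gets ``+fixed_value`` (case-only) or ``-fixed_value`` (control-only).
    ``fixed_value="auto"`` uses the maximum finite |lfc| among
    ``finite_results``, approximating the experiment's maximum observed fold
    change. Significance comes from a one-sample t-test of the observed
    group's log2 intensities against the dataset's minimum observed log2
    intensity (the detection floor), Bonferroni-adjusted across the imputed
    set; the records are flagged ``lfc_imputed``.

    Returns ``finite_results`` plus the imputed records.
    """
    if fixed_value == "auto":
        finite_lfcs = [abs(r.lfc) for r in finite_results if np.isfinite(r.lfc)]
        if not finite_lfcs:
            raise InvalidParameterError(
                "fixed_value='auto' requires at least one finite DE result; pass an explicit value"
            )
        fixed = float(max(finite_lfcs))
    else:
        fixed = float(fixed_value)
        if fixed <= 0:
            raise InvalidParameterError("fixed_value must be positive")

    case, ctrl = _group_observations(intensities)
    log_all = np.log2(intensities.values.to_numpy(dtype=float))
    floor = float(np.nanmin(log_all))

    imputed: list[DEResult] = []
    raw_p: list[float] = []
    for gene in intensities.gene_ids:
        c = case.loc[gene].dropna()
        k = ctrl.loc[gene].dropna()
        if len(k) == 0 and len(c) >= 2:
            obs, sign = c, +1.0
        elif len(c) == 0 and len(k) >= 2:
            obs, sign = k, -1.0
        else:
            continue
        t, p = stats.ttest_1samp(np.log2(obs), floor)
        p = 1.0 if not np.isfinite(p) else float(p)
        raw_p.append(p)
        imputed.append(DEResult(gene, sign * fixed, p, None, "ns", lfc_imputed=True))
    if imputed:
        padj = adjust_pvalues(raw_p, "bonferroni")
        for r, pa in zip(imputed, padj):
            r.padj = float(pa)
            r.status = _status(r.lfc, r.padj, alpha, lfc_min)
    return list(finite_results) + imputed
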