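"""Synthetic cohorts and perturbation-signature libraries with known truth.

Every downstream stage of the pipeline (differential expression, profile
construction, concordance screening, scoring) can be exercised against data
whose planted effects are recorded in a :class:`~revscreen.containers.SyntheticTruth`,
so recovery can be measured without any external download.

Models
------
* Transcript counts: negative binomial with a per-gene baseline mean drawn
  log-normally and a single dispersion shared across genes
  (``Var = mu + dispersion * mu^2``). Planted genes have their case-group
  mean scaled by ``2**lfc``.
* Protein intensities: log-normal — log2 intensity is Gaussian around a
  per-protein baseline, shifted by the planted LFC in the case group.
  A configurable fraction of planted proteins are "one-group": every value
  of the depleted group is absent, mimicking proteins detected in only one
  condition.
* Signatures: for a drug with reversal strength rho in [-1, 1], each
  signature's LFC at gene g is ``-rho * profile[g] + Normal(0, noise_sd)``,
  with each gene independently dropped with probability ``missing_prob``.
  Negative rho produces disease-mimicking signatures, useful for testing
  that clustering separates reversers from mimics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    CASE,
    CONTROL,
    DiseaseProfile,
    ExpressionMatrix,
    InvalidParameterError,
    SignatureProfile,
    SyntheticTruth,
)

__all__ = [
    "simulate_cohort_counts",
    "simulate_proteome_intensities",
    "simulate_signature_library",
]


def _check_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if v <= 0:
            raise InvalidParameterError(f"{name} must be positive, got {v}")


def _plant_effects(
    rng: np.random.Generator,
    gene_ids: list[str],
    de_fraction: float,
    lfc_magnitudes: tuple[float, float],
) -> dict[str, float]:
    if not 0 <= de_fraction <= 1:
        raise InvalidParameterError(f"de_fraction must be in [0, 1], got {de_fraction}")
    lo, hi = lfc_magnitudes
    if lo <= 0 or hi < lo:
        raise InvalidParameterError("lfc_magnitudes must be a positive (low, high) range")
    n_de = int(round(de_fraction * len(gene_ids)))
    chosen = rng.choice(len(gene_ids), size=n_de, replace=False)
    mags = rng.uniform(lo, hi, size=n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    return {gene_ids[i]: float(m * s) for i, m, s in zip(chosen, mags, signs)}


def simulate_cohort_counts(
    n_case: int,
    n_control: int,
    n_genes: int,
    de_fraction: float = 0.1,
    lfc_magnitudes: tuple[float, float] = (1.5, 4.0),
    dispersion: float = 0.1,
    baseline_log2_mean: float = 6.5,
    baseline_log2_sd: float = 1.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate an RNA-seq case/control cohort with planted DE genes.

    Baseline means are drawn log-normally (median ``2**baseline_log2_mean``
    counts, i.e. ~90 by default, spanning a few orders of magnitude, a
    realistic bulk RNA-seq spread). ``dispersion`` is the NB overdispersion
    shared by all genes.

    Returns the count matrix and the planted truth.
    """
    if n_case < 2 or n_control < 2:
        raise InvalidParameterError("n_case and n_control must each be >= 2")
    _check_positive(n_genes=n_genes, dispersion=dispersion)
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"case_{i:03d}" for i in range(n_case)] + [f"ctrl_{i:03d}" for i in range(n_control)]
    groups = pd.Series([CASE] * n_case + [CONTROL] * n_control, index=sample_ids)

    baseline = 2.0 ** rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)
    planted = _plant_effects(rng, gene_ids, de_fraction, lfc_magnitudes)
    lfc = np.array([planted.get(g, 0.0) for g in gene_ids])

    mu = np.empty((n_genes, n_case + n_control))
    mu[:, :n_case] = (baseline * 2.0 ** lfc)[:, None]
    mu[:, n_case:] = baseline[:, None]

    # NB(mean mu, Var mu + a*mu^2): size r = 1/a, p = r/(r+mu)
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    mat = ExpressionMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"), columns=sample_ids),
        groups,
        kind="counts",
    )
    truth = SyntheticTruth(de_genes=set(planted), planted_lfc=planted, seed=seed)
    return mat, truth


def simulate_proteome_intensities(
    n_case: int,
    n_control: int,
    n_proteins: int,
    de_fraction: float = 0.1,
    lfc_magnitudes: tuple[float, float] = (1.5, 4.0),
    noise_sd: float = 0.4,
    onegroup_fraction: float = 0.0,
    baseline_log2_mean: float = 20.0,
    baseline_log2_sd: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate label-free proteome intensities with planted effects.

    ``onegroup_fraction`` of the planted proteins are made "one-group":
    all values of the group opposite to the effect's sign are absent (NaN),
    emulating proteins detected in only one condition, which downstream get
    a fixed imputed fold change. ``noise_sd`` is in log2 units.
    """
    if n_case < 2 or n_control < 2:
        raise InvalidParameterError("n_case and n_control must each be >= 2")
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    if not 0 <= onegroup_fraction <= 1:
        raise InvalidParameterError(f"onegroup_fraction must be in [0, 1], got {onegroup_fraction}")
    _check_positive(n_proteins=n_proteins)
    rng = np.random.default_rng(seed)
    prot_ids = [f"P{i:05d}" for i in range(n_proteins)]
    sample_ids = [f"case_{i:02d}" for i in range(n_case)] + [f"ctrl_{i:02d}" for i in range(n_control)]
    groups = pd.Series([CASE] * n_case + [CONTROL] * n_control, index=sample_ids)

    planted = _plant_effects(rng, prot_ids, de_fraction, lfc_magnitudes)
    lfc = np.array([planted.get(p, 0.0) for p in prot_ids])
    baseline = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_proteins)

    log2_int = np.empty((n_proteins, n_case + n_control))
    log2_int[:, :n_case] = (baseline + lfc)[:, None]
    log2_int[:, n_case:] = baseline[:, None]
    log2_int += rng.normal(0.0, noise_sd, size=log2_int.shape)
    values = 2.0 ** log2_int

    planted_ids = sorted(planted)
    n_onegroup = int(round(onegroup_fraction * len(planted_ids)))
    onegroup = {}
    chosen = rng.choice(len(planted_ids), size=n_onegroup, replace=False)
    for i in chosen:
        pid = planted_ids[i]
        row = prot_ids.index(pid)
        if planted[pid] > 0:  # detected only in case: control absent
            values[row, n_case:] = np.nan
            onegroup[pid] = CASE
        else:
            values[row, :n_case] = np.nan
            onegroup[pid] = CONTROL

    mat = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(prot_ids, name="gene"), columns=sample_ids),
        groups,
        kind="intensity",
    )
    truth = SyntheticTruth(
        de_genes=set(planted), planted_lfc=planted, one_group_proteins=onegroup, seed=seed
    )
    return mat, truth


def simulate_signature_library(
    profile: DiseaseProfile,
    n_drugs: int,
    sigs_per_drug: int,
    rho_values: list[float],
    noise_sd: float = 0.3,
    missing_prob: float = 0.2,
    library_name: str = "Synthetic perturbagen",
    seed: int = 0,
) -> tuple[list[SignatureProfile], SyntheticTruth]:
    """Simulate a perturbation-signature library against a disease profile.

    Each drug has a reversal strength ``rho``; each of its signatures is
    ``-rho * profile + noise`` with per-gene dropout. ``rho = 1`` with no
    noise is an exact reverser (concordance -1); ``rho < 0`` mimics the
    disease profile instead of reversing it.
    """
    if len(profile) == 0:
        raise InvalidParameterError("profile must be non-empty")
    if len(rho_values) != n_drugs:
        raise InvalidParameterError("rho_values must have one entry per drug")
    if any(abs(r) > 1 for r in rho_values):
        raise InvalidParameterError("rho values must lie in [-1, 1]")
    if not 0 <= missing_prob <= 1:
        raise InvalidParameterError(f"missing_prob must be in [0, 1], got {missing_prob}")
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    _check_positive(n_drugs=n_drugs, sigs_per_drug=sigs_per_drug)

    rng = np.random.default_rng(seed)
    genes = profile.genes
    plfc = np.array([profile[g] for g in genes])
    sigs: list[SignatureProfile] = []
    drug_rho: dict[str, float] = {}
    for d in range(n_drugs):
        drug = f"drug_{d:03d}"
        drug_rho[drug] = float(rho_values[d])
        for s in range(sigs_per_drug):
            vals = -rho_values[d] * plfc + rng.normal(0.0, noise_sd, size=len(genes))
            keep = rng.random(len(genes)) >= missing_prob
            entries = {g: float(v) for g, v, k in zip(genes, vals, keep) if k}
            sigs.append(
                SignatureProfile(
                    signature_id=f"{drug}_sig{s:02d}",
                    perturbagen=drug,
                    library=library_name,
                    entries=entries,
                )
            )
    truth = SyntheticTruth(drug_rho=drug_rho, seed=seed)
    return sigs, truth
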