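"""Core data containers shared across the pipeline stages.

The pipeline moves through a small number of in-memory shapes:

* :class:`ExpressionMatrix` — a genes x samples matrix of counts or
  intensities with a case/control label per sample.
* :class:`DEResult` — one gene's differential-expression record.
* :class:`DiseaseProfile` — the disease gene-expression profile (gene ->
  transcript log2 fold change) built from genes differentially expressed in
  both omics layers.
* :class:`SignatureProfile` — one perturbation signature (gene -> LFC, with
  genes allowed to be absent) from a connectivity-map-style library.
* :class:`DrugProfile` — a drug-level aggregate (per-gene median LFC across
  the drug's retained signatures).
* :class:`CandidateScore` — per-drug regulation score, overall coverage and
  ranking annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "DiseaseProfile",
    "SignatureProfile",
    "DrugProfile",
    "CandidateScore",
    "ClusterAssignment",
    "SyntheticTruth",
    "InvalidParameterError",
]


class InvalidParameterError(ValueError):
    """Raised when a caller-supplied parameter is outside its valid range."""


CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample. Counts are
        non-negative integers; intensities are non-negative reals with NaN
        marking values absent from the experiment (zeros in intensity data
        are coerced to NaN on construction).
    groups
        Mapping from sample id to ``"case"`` or ``"control"``.
    kind
        ``"counts"`` or ``"intensity"``; controls log-transformation in the
        PCA screen and zero handling.
    """

    values: pd.DataFrame
    groups: pd.Series
    kind: str = "counts"

    def __post_init__(self) -> None:
        if isinstance(self.groups, Mapping):
            self.groups = pd.Series(self.groups)
        if self.kind not in ("counts", "intensity"):
            raise InvalidParameterError(f"kind must be 'counts' or 'intensity', got {self.kind!r}")
        if self.values.index.has_duplicates:
            raise InvalidParameterError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise InvalidParameterError("duplicate sample ids in expression matrix")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise InvalidParameterError(f"samples without group label: {sorted(missing)[:5]}")
        self.groups = self.groups.loc[self.values.columns]
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise InvalidParameterError(f"group labels must be 'case'/'control', got {sorted(bad)}")
        if (self.groups == CASE).sum() == 0 or (self.groups == CONTROL).sum() == 0:
            raise InvalidParameterError("both case and control groups must be non-empty")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise InvalidParameterError("expression values must be non-negative")
        if self.kind == "intensity":
            # zeros in intensity data mean "not detected"
            self.values = self.values.mask(self.values == 0)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = list(sample_ids)
        return ExpressionMatrix(self.values[keep].copy(), self.groups.loc[keep].copy(), self.kind)


@dataclass
class DEResult:
    """Differential-expression call for one gene.

    ``status`` is ``"up"`` when padj < alpha and lfc > lfc_min, ``"down"``
    when padj < alpha and lfc < -lfc_min, else ``"ns"``. ``p`` may be None
    for proteins whose fold change was imputed without a defined test.
    """

    gene: str
    lfc: float
    p: float | None
    padj: float | None
    status: str = "ns"
    lfc_imputed: bool = False


def de_results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "lfc": [r.lfc for r in results],
            "p": [np.nan if r.p is None else r.p for r in results],
            "padj": [np.nan if r.padj is None else r.padj for r in results],
            "status": [r.status for r in results],
            "lfc_imputed": [r.lfc_imputed for r in results],
        }
    )


class DiseaseProfile:
    """Ordered gene -> log2-fold-change map for the disease.

    Genes are those called differentially expressed in both omics layers;
    the stored LFC is the transcript-level one. Iteration order is
    descending LFC (deterministic tie-break on gene name).
    """

    def __init__(self, entries: Mapping[str, float], provenance: pd.DataFrame | None = None):
        items = sorted(entries.items(), key=lambda kv: (-kv[1], kv[0]))
        self.entries: dict[str, float] = dict(items)
        if provenance is None:
            provenance = pd.DataFrame(index=pd.Index(self.genes, name="gene"))
        self.provenance = provenance

    @property
    def genes(self) -> list[str]:
        return list(self.entries)

    def lfc_vector(self) -> pd.Series:
        return pd.Series(self.entries, name="lfc")

    def total_abs_lfc(self) -> float:
        return float(sum(abs(v) for v in self.entries.values()))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def __getitem__(self, gene: str) -> float:
        return self.entries[gene]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DiseaseProfile) and self.entries == other.entries

    def __repr__(self) -> str:  # pragma: no cover
        return f"DiseaseProfile({len(self)} genes)"


@dataclass
class SignatureProfile:
    """One perturbation signature: the per-gene LFC a chemical induces.

    ``entries`` may omit genes (signature platforms measure different gene
    sets); ``concordance`` is filled in by the screening stage.
    """

    signature_id: str
    perturbagen: str
    library: str
    entries: dict[str, float] = field(default_factory=dict)
    concordance: float | None = None
    n_overlap: int | None = None

    def with_concordance(self, r: float, n_overlap: int) -> "SignatureProfile":
        return replace(self, concordance=r, n_overlap=n_overlap)


@dataclass
class DrugProfile:
    """Drug-level profile: per-gene median LFC across retained signatures."""

    drug: str
    entries: dict[str, float]
    n_signatures: int

    def __post_init__(self) -> None:
        if self.n_signatures < 1:
            raise InvalidParameterError("a drug profile needs at least one signature")


@dataclass
class CandidateScore:
    """Per-drug prioritization record (regulation score + overall coverage)."""

    drug: str
    rs: float
    oc: float
    a: int
    g: int
    n_signatures: int = 0
    cluster: int | None = None
    bbb: float | None = None
    prior_trials: int | None = None
    rank: int | None = None


@dataclass
class ClusterAssignment:
    """Result of hierarchical clustering of signature columns.

    ``labels`` maps each clustered column id (signature ids plus the
    reference column id when the disease profile was appended) to a cluster
    label in 1..k. ``linkage`` is a SciPy-format merge history.
    """

    labels: dict[str, int]
    linkage: np.ndarray
    k: int
    reference_label: int | None = None
    excluded: list[str] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the synthetic generators."""

    de_genes: set[str] = field(default_factory=set)
    planted_lfc: dict[str, float] = field(default_factory=dict)
    drug_rho: dict[str, float] = field(default_factory=dict)
    one_group_proteins: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.planted_lfc) != set(self.de_genes):
            raise InvalidParameterError("planted_lfc keys must equal de_genes")
        if any(v == 0 for v in self.planted_lfc.values()):
            raise InvalidParameterError("planted effects must be nonzero")
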