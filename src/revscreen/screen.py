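"""Concordance screening of perturbation signatures against a disease profile.

Concordance is the Pearson correlation between the disease profile's LFCs
and a signature's LFCs over their shared genes; strongly negative values
mark reversal signatures. Screening retains signatures whose concordance is
strictly below a per-library cutoff (default -0.2; libraries whose
signatures overlap the profile poorly warrant a stricter cutoff such as
-0.6, mirroring connectivity-map practice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import DiseaseProfile, InvalidParameterError, SignatureProfile

logger = logging.getLogger(__name__)

__all__ = ["ScreenConfig", "concordance", "screen_signatures", "filter_approved", "normalize_name"]


def normalize_name(name: str) -> str:
    """Lowercase, trim, and collapse internal whitespace."""
    return " ".join(name.strip().lower().split())


@dataclass
class ScreenConfig:
    """Cutoffs and filters for the reversal screen.

    ``per_library_cutoffs`` keys are matched after :func:`normalize_name`;
    unknown libraries fall back to ``default_cutoff`` (logged). All cutoffs
    must be negative — the screen looks for anticorrelation only.
    """

    default_cutoff: float = -0.2
    per_library_cutoffs: dict[str, float] = field(
        default_factory=lambda: {"lincs chemical perturbagen": -0.6}
    )
    min_overlap: int = 10
    approved_list: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.per_library_cutoffs = {
            normalize_name(k): v for k, v in self.per_library_cutoffs.items()
        }
        if self.default_cutoff >= 0 or any(v >= 0 for v in self.per_library_cutoffs.values()):
            raise InvalidParameterError("all concordance cutoffs must be negative")
        if self.min_overlap < 3:
            raise InvalidParameterError("min_overlap must be >= 3")
        self.approved_list = {normalize_name(n) for n in self.approved_list}

    def cutoff_for(self, library: str) -> float:
        key = normalize_name(library)
        if key in self.per_library_cutoffs:
            return self.per_library_cutoffs[key]
        logger.debug("library %r not in cutoff table; using default %.3g", library, self.default_cutoff)
        return self.default_cutoff


def concordance(
    profile: DiseaseProfile,
    sig: SignatureProfile,
    min_overlap: int = 10,
) -> float | None:
    """Pearson correlation of profile vs signature LFCs over shared genes.

    Returns None (and logs) when fewer than ``min_overlap`` genes are shared
    or either vector is constant over the overlap — the signature is skipped
    rather than scored.
    """
    shared = [g for g in profile.genes if g in sig.entries]
    if len(shared) < min_overlap:
        logger.info(
            "signature %s skipped: overlap %d < min_overlap %d",
            sig.signature_id, len(shared), min_overlap,
        )
        return None
    x = np.array([profile[g] for g in shared])
    y = np.array([sig.entries[g] for g in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("signature %s skipped: constant vector over overlap", sig.signature_id)
        return None
    return float(stats.pearsonr(x, y).statistic)


def screen_signatures(
    profile: DiseaseProfile,
    sigs: list[SignatureProfile],
    cfg: ScreenConfig,
) -> list[SignatureProfile]:
    """Retain signatures with concordance strictly below their library cutoff.

    Returns retained signatures with ``concordance`` and ``n_overlap`` set,
    sorted by concordance ascending (strongest reversal first). Emits a
    warning when a library's median overlap with the profile is below 20%
    of the profile size — sparse overlap inflates false-positive reversal
    calls and warrants a stricter cutoff.
    """
    retained: list[SignatureProfile] = []
    overlaps: dict[str, list[int]] = {}
    for sig in sigs:
        n_shared = sum(1 for g in profile.genes if g in sig.entries)
        overlaps.setdefault(sig.library, []).append(n_shared)
        r = concordance(profile, sig, cfg.min_overlap)
        if r is None:
            continue
        if r < cfg.cutoff_for(sig.library):
            retained.append(sig.with_concordance(r, n_shared))
    for lib, ns in overlaps.items():
        if np.median(ns) < 0.2 * len(profile):
            logger.warning(
                "library %r: median profile overlap %.0f < 20%% of profile size %d; "
                "consider a stricter cutoff", lib, float(np.median(ns)), len(profile),
            )
    retained.sort(key=lambda s: (s.concordance, s.signature_id))
    return retained


def filter_approved(
    sigs: list[SignatureProfile],
    approved: set[str],
) -> list[SignatureProfile]:
    """Keep signatures whose perturbagen is on the approved-drug list.

    Matching is on normalized names (case/whitespace-insensitive). An empty
    approved set yields an empty result with a warning.
    """
    if not approved:
        logger.warning("approved-drug list is empty; all signatures filtered out")
        return []
    norm = {normalize_name(n) for n in approved}
    return [s for s in sigs if normalize_name(s.perturbagen) in norm]
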