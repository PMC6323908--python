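"""Normalized nine-criterion disease scoring for mitochondrial tRNA variants.

The score aggregates nine literature-derived pathogenicity criteria in the
Yarham tradition.  Each criterion carries a non-negative raw weight (defaults
2, 1, 1, 2, 2, 2, 2, 5, 3 in canonical row order, totalling 20); weights are
normalized by their sum so the disease score (DS) of a variant — the sum of
the normalized weights of its satisfied criteria — always lies in [0, 1].
The heaviest criterion is functional evidence from trans-mitochondrial cybrid
or mt-tRNA steady-state studies (5/20 = 0.25).

A tRNA variant with no functional-study evidence in the literature at all is
flagged VUS (Variant of Undefined Significance): the flag overrides any tier
assignment downstream, even when conservation criteria alone give DS > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateWeightsError, DomainError

#: The nine criteria, in canonical scoring-table row order.
CRITERIA = (
    "multiple_pathogenic_reports",
    "phastcons_conserved",
    "phylop_conserved",
    "heteroplasmy_evidence",
    "disease_segregation",
    "histochemical_evidence",
    "oxphos_biochemical_defect",
    "cybrid_or_steady_state_evidence",
    "single_fiber_segregation",
)

#: Criteria that require a published functional study.
FUNCTIONAL_CRITERIA = (
    "disease_segregation",
    "histochemical_evidence",
    "oxphos_biochemical_defect",
    "cybrid_or_steady_state_evidence",
    "single_fiber_segregation",
)

#: Raw Yarham-style weights in CRITERIA order (sum = 20).
DEFAULT_RAW_WEIGHTS = (2, 1, 1, 2, 2, 2, 2, 5, 3)


def normalize_weights(raw_weights: Sequence[float]) -> np.ndarray:
    """Scale raw criterion weights to sum to 1, preserving order.

    Weights are defined only up to a common scale; any all-positive rescaling
    of the input yields the same output.
    """
    w = np.asarray(raw_weights, dtype=float)
    if (w < 0).any():
        raise DomainError("criterion weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise DegenerateWeightsError("all criterion weights are zero")
    return w / total


@dataclass(frozen=True)
class CriterionWeights:
    """Raw criterion weights and their normalized form."""

    raw_weights: tuple[float, ...] = DEFAULT_RAW_WEIGHTS

    @property
    def normalized(self) -> np.ndarray:
        return normalize_weights(self.raw_weights)


@dataclass(frozen=True)
class TrnaEvidenceProfile:
    """Evidence state for one tRNA variant: each criterion is True (satisfied),
    False (investigated, not satisfied) or None (unknown / not asserted).

    ``functional_evidence_available`` records whether any functional study
    exists in the literature for the variant; when False, the five
    functional-study criteria must remain unknown (None), not False.
    """

    multiple_pathogenic_reports: Optional[bool] = None
    phastcons_conserved: Optional[bool] = None
    phylop_conserved: Optional[bool] = None
    heteroplasmy_evidence: Optional[bool] = None
    disease_segregation: Optional[bool] = None
    histochemical_evidence: Optional[bool] = None
    oxphos_biochemical_defect: Optional[bool] = None
    cybrid_or_steady_state_evidence: Optional[bool] = None
    single_fiber_segregation: Optional[bool] = None
    functional_evidence_available: bool = False

    def __post_init__(self) -> None:
        if not self.functional_evidence_available:
            asserted = [
                c for c in FUNCTIONAL_CRITERIA if getattr(self, c) is not None
            ]
            if asserted:
                raise ValueError(
                    "functional criteria asserted while functional evidence "
                    f"is flagged unavailable: {asserted}"
                )

    def satisfied(self) -> tuple[bool, ...]:
        """Satisfaction vector in CRITERIA order; unknowns count as False."""
        return tuple(getattr(self, c) is True for c in CRITERIA)


def trna_disease_score(
    profile: TrnaEvidenceProfile,
    weights: CriterionWeights | Sequence[float] = DEFAULT_RAW_WEIGHTS,
) -> float:
    """DS = sum of normalized weights over satisfied criteria, in [0, 1].

    Unknown criteria contribute nothing, so the score is a lower bound given
    incomplete evidence and is monotone in the evidence set.
    """
    if isinstance(weights, CriterionWeights):
        norm = weights.normalized
    else:
        norm = normalize_weights(weights)
    if len(norm) != len(CRITERIA):
        raise DomainError(f"expected {len(CRITERIA)} weights, got {len(norm)}")
    mask = np.asarray(profile.satisfied(), dtype=bool)
    return float(norm[mask].sum())


def flag_vus(profile: TrnaEvidenceProfile) -> bool:
    """True iff no functional evidence is available from the literature.

    A VUS flag overrides tier assignment downstream, even for profiles whose
    conservation criteria alone give DS > 0.
    """
    return not profile.functional_evidence_available
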