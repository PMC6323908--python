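"""Consensus disease scoring for non-synonymous protein-coding variants.

The disease score for a non-synonymous mtDNA variant is a consensus over the
pathogenicity probabilities reported by external predictors.  The default
consensus is the weighted mean of the available probabilities, with weights
renormalized over the non-missing entries; the predictor set and weighting are
fully configurable (see docs/methods.md for what this default does and does
not reproduce).  A variant with no predictor output at all has no defined
score and is reported as unassigned.

Only non-synonymous substitutions are eligible for this score: frameshift,
stop-gain and stop-loss variants have no disease score, and synonymous, rRNA
and regulatory variants are annotation-only records under the current scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .errors import DomainError

#: Functional classes whose variants receive a consensus disease score.
SCORED_CLASSES = frozenset({"non-synonymous"})

#: Classes explicitly excluded from disease scoring (score withheld).
WITHHELD_CLASSES = frozenset({"stop-gain", "stop-loss", "frameshift"})


@dataclass(frozen=True)
class PredictorPanel:
    """Named predictor probabilities for one variant.

    ``probabilities`` maps predictor name -> probability in [0, 1], or None
    for a predictor that produced no output.  ``weights`` maps predictor name
    -> non-negative weight; predictors absent from it get weight 1 (uniform
    default).
    """

    probabilities: Mapping[str, Optional[float]]
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in self.probabilities.items():
            if p is not None and not 0.0 <= p <= 1.0:
                raise DomainError(
                    f"predictor {name!r} probability {p} outside [0, 1]"
                )
        for name, w in self.weights.items():
            if w < 0:
                raise DomainError(f"predictor {name!r} weight {w} is negative")


def nonsyn_disease_score(panel: PredictorPanel) -> Optional[float]:
    """Weighted mean of the available predictor probabilities, in [0, 1].

    Weights are renormalized over the non-missing predictors, so dropping a
    missing predictor and rescaling the rest is a no-op.  Returns None
    (unassigned) when every predictor is missing.
    """
    names = [n for n, p in panel.probabilities.items() if p is not None]
    if not names:
        return None
    probs = np.array([panel.probabilities[n] for n in names], dtype=float)
    weights = np.array([panel.weights.get(n, 1.0) for n in names], dtype=float)
    if weights.sum() == 0:
        raise DomainError("available predictors all carry zero weight")
    return float(np.average(probs, weights=weights))


def score_eligibility(functional_class: str) -> str:
    """Whether a variant of this functional class receives a disease score.

    Non-synonymous substitutions are ``eligible``; stop-gain, stop-loss and
    frameshift records are ``ineligible`` (score withheld), as are synonymous
    and non-coding classes under the current scoring scheme.
    """
    return "eligible" if functional_class in SCORED_CLASSES else "ineligible"
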