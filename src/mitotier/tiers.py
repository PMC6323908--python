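"""Pathogenicity tier assignment from disease score and allele frequency.

A scored variant occupies one quadrant of the (DS, AF) plane, delimited by a
locus-type-specific disease-score threshold DS_T and allele-frequency
threshold AF_T:

    ==================  ==========  ==========
    Tier                DS          AF
    ==================  ==========  ==========
    Polymorphic         DS < DS_T   AF > AF_T
    Likely Polymorphic  DS < DS_T   AF <= AF_T
    Likely Pathogenic   DS >= DS_T  AF > AF_T
    Pathogenic          DS >= DS_T  AF <= AF_T
    ==================  ==========  ==========

Both comparisons are inclusive on the pathogenic side.  The shipped defaults
are DS_T = 0.43 / AF_T = 0.003264 for non-synonymous variants and DS_T = 0.35
/ AF_T = 0.005020 for tRNA variants.  A VUS flag (no functional evidence for
a tRNA variant) overrides the quadrant; a variant with no defined DS is
Unclassified.

AF_T can be re-estimated from data as an empirical quantile of the allele
frequencies of high-scoring variants (DS >= DS_T), mirroring how the shipped
constants were derived from a large genome corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError, ThresholdEstimationError
from .trna import DEFAULT_RAW_WEIGHTS

TIERS = (
    "Pathogenic",
    "Likely Pathogenic",
    "Likely Polymorphic",
    "Polymorphic",
    "VUS",
    "Unclassified",
)

#: Locus kinds with their own threshold pair.
SCORED_KINDS = ("non-synonymous", "tRNA")


@dataclass(frozen=True)
class ThresholdConfig:
    """Disease-score and allele-frequency thresholds, per scored locus kind.

    ``af_quantile`` is the empirical quantile used when AF_T is re-estimated
    from data; the shipped AF_T values are frozen constants, so classification
    is reproducible without re-estimation.
    """

    ds_t_nonsyn: float = 0.43
    ds_t_trna: float = 0.35
    af_t_nonsyn: float = 0.003264
    af_t_trna: float = 0.005020
    af_quantile: float = 0.95
    trna_raw_weights: tuple[float, ...] = DEFAULT_RAW_WEIGHTS

    def __post_init__(self) -> None:
        for name in ("ds_t_nonsyn", "ds_t_trna", "af_t_nonsyn", "af_t_trna",
                     "af_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} = {v} outside [0, 1]")

    def for_kind(self, kind: str) -> tuple[float, float]:
        """(DS_T, AF_T) for a scored locus kind."""
        if kind == "non-synonymous":
            return self.ds_t_nonsyn, self.af_t_nonsyn
        if kind == "tRNA":
            return self.ds_t_trna, self.af_t_trna
        raise ConfigurationError(f"no thresholds defined for kind {kind!r}")


DEFAULT_THRESHOLDS = ThresholdConfig()


@dataclass(frozen=True)
class TierAssignment:
    """A tier label together with the inputs and thresholds that produced it."""

    tier: str
    ds_used: Optional[float]
    af_used: Optional[float]
    ds_threshold: Optional[float]
    af_threshold: Optional[float]
    vus: bool = False


def estimate_af_threshold(
    disease_scores: Sequence[float],
    allele_frequencies: Sequence[float],
    ds_t: float,
    af_quantile: float,
) -> float:
    """Empirical AF threshold from the high-scoring variant set.

    Takes the ``af_quantile``-th empirical quantile (inverted-CDF convention:
    the smallest observed value whose empirical CDF reaches the quantile) of
    the allele frequencies of variants with DS >= ds_t.
    """
    if not 0.0 <= af_quantile <= 1.0:
        raise DomainError(f"af_quantile {af_quantile} outside [0, 1]")
    ds = np.asarray(disease_scores, dtype=float)
    af = np.asarray(allele_frequencies, dtype=float)
    if ds.shape != af.shape:
        raise ValueError("disease_scores and allele_frequencies differ in length")
    mask = (ds >= ds_t) & ~np.isnan(af)
    if not mask.any():
        raise ThresholdEstimationError(
            f"no variant with DS >= {ds_t} and a defined allele frequency"
        )
    qualifying = af[mask]
    if ((qualifying < 0) | (qualifying > 1)).any():
        raise DomainError("allele frequencies must lie in [0, 1]")
    return float(np.quantile(qualifying, af_quantile, method="inverted_cdf"))


def assign_tier(
    ds: Optional[float],
    af: Optional[float],
    locus_kind: str,
    vus_flag: bool = False,
    thresholds: ThresholdConfig = DEFAULT_THRESHOLDS,
) -> TierAssignment:
    """Assign the pathogenicity tier for one scored variant.

    ``locus_kind`` selects the threshold pair ("non-synonymous" or "tRNA").
    A VUS flag overrides everything; an undefined DS yields Unclassified;
    potential variants carry AF = 0, which always falls on the ``AF <= AF_T``
    side.  Boundary behaviour is inclusive: DS = DS_T and AF = AF_T is
    Pathogenic.
    """
    ds_t, af_t = thresholds.for_kind(locus_kind)
    if vus_flag:
        return TierAssignment("VUS", ds, af, ds_t, af_t, vus=True)
    if ds is None or (isinstance(ds, float) and np.isnan(ds)):
        return TierAssignment("Unclassified", None, af, ds_t, af_t)
    if af is None or (isinstance(af, float) and np.isnan(af)):
        raise DomainError(
            "allele frequency undefined; potential variants carry AF = 0"
        )
    if not 0.0 <= ds <= 1.0:
        raise DomainError(f"disease score {ds} outside [0, 1]")
    if not 0.0 <= af <= 1.0:
        raise DomainError(f"allele frequency {af} outside [0, 1]")
    if ds >= ds_t:
        tier = "Pathogenic" if af <= af_t else "Likely Pathogenic"
    else:
        tier = "Likely Polymorphic" if af <= af_t else "Polymorphic"
    return TierAssignment(tier, ds, af, ds_t, af_t)


def load_threshold_config(path: str | Path) -> ThresholdConfig:
    """Read a ``key=value`` config file overriding any threshold default.

    Recognized keys: ds_t_nonsyn, ds_t_trna, af_t_nonsyn, af_t_trna,
    af_quantile, trna_raw_weights (comma-separated).  Unknown keys are an
    error so typos cannot silently fall back to defaults.
    """
    overrides: dict = {}
    known = {"ds_t_nonsyn", "ds_t_trna", "af_t_nonsyn", "af_t_trna",
             "af_quantile", "trna_raw_weights"}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"malformed config line: {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ConfigurationError(f"unknown config key {key!r}")
            if key == "trna_raw_weights":
                overrides[key] = tuple(float(v) for v in value.split(","))
            else:
                overrides[key] = float(value)
    return replace(ThresholdConfig(), **overrides)
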