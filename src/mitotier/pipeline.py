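"""End-to-end annotation: enumeration -> cohort statistics -> scores -> tiers.

``annotate_cohort`` runs the full chain on a reference genome, a locus map
and a stratified genome cohort, optionally consuming a tRNA criterion table
and a non-synonymous predictor table, and returns one annotated row per
substitution in the potential space.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .enumeration import enumerate_potential, mark_observed
from .frequency import GenomeCohort, compute_cohort_stats
from .nonsyn import PredictorPanel, nonsyn_disease_score, score_eligibility
from .reference import LocusMap, ReferenceModel
from .tiers import DEFAULT_THRESHOLDS, ThresholdConfig, assign_tier
from .trna import CriterionWeights, TrnaEvidenceProfile, flag_vus, trna_disease_score

ANNOTATED_COLUMNS = [
    "position", "ref", "alt", "locus", "locus_type", "functional_class",
    "status", "af_total", "af_healthy", "af_pathologic", "nt_var", "aa_var",
    "disease_score", "vus", "tier", "ds_threshold", "af_threshold",
]


def annotate_cohort(
    reference: ReferenceModel,
    locus_map: LocusMap,
    cohort: GenomeCohort,
    trna_evidence: Optional[Mapping[tuple[int, str, str], TrnaEvidenceProfile]] = None,
    predictor_panels: Optional[Mapping[tuple[int, str, str], Mapping]] = None,
    thresholds: ThresholdConfig = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Annotate the full potential-substitution space against a cohort.

    Disease scores attach only where the scoring schemes apply: tRNA variants
    score from their criterion profile (no profile at all -> VUS), eligible
    non-synonymous variants score from their predictor panel (no panel ->
    unassigned, tier Unclassified).  Synonymous, stop-gain/stop-loss, rRNA,
    regulatory and intergenic records are annotation-only (tier Unclassified).
    """
    trna_evidence = trna_evidence or {}
    predictor_panels = predictor_panels or {}
    weights = CriterionWeights(thresholds.trna_raw_weights)

    catalogue = enumerate_potential(reference, locus_map)
    stats = compute_cohort_stats(cohort, catalogue.frame, locus_map)
    catalogue = mark_observed(catalogue, stats)
    table = catalogue.frame.merge(stats, on=["position", "ref", "alt"], how="left")

    scores, vus_flags, tier_rows = [], [], []
    for row in table.to_dict("records"):
        key = (row["position"], row["ref"], row["alt"])
        ds: Optional[float] = None
        vus = False
        kind: Optional[str] = None
        if row["locus_type"] == "tRNA":
            kind = "tRNA"
            profile = trna_evidence.get(key)
            if profile is None:
                vus = True
                ds = 0.0
            else:
                vus = flag_vus(profile)
                ds = trna_disease_score(profile, weights)
        elif score_eligibility(row["functional_class"]) == "eligible":
            kind = "non-synonymous"
            panel = predictor_panels.get(key)
            if panel is not None:
                ds = nonsyn_disease_score(PredictorPanel(panel))

        if kind is None:
            tier_rows.append(("Unclassified", np.nan, np.nan))
        else:
            af = row["af_total"] if not pd.isna(row["af_total"]) else 0.0
            assignment = assign_tier(ds, af, kind, vus, thresholds)
            tier_rows.append(
                (assignment.tier, assignment.ds_threshold, assignment.af_threshold)
            )
        scores.append(np.nan if ds is None else ds)
        vus_flags.append(vus)

    table["disease_score"] = scores
    table["vus"] = vus_flags
    table["tier"] = [t for t, _, _ in tier_rows]
    table["ds_threshold"] = [d for _, d, _ in tier_rows]
    table["af_threshold"] = [a for _, _, a in tier_rows]
    return table[ANNOTATED_COLUMNS]
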