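"""Cohort-level summaries: functional-class and tier breakdowns.

Percentages are computed from integer counts and rounded half-up; the default
rendering keeps one decimal (59.7%) and drops it when it is zero (7%), with an
optional integer rendering (9 of 70 -> 13%) for whole-percent reporting.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tiers import TIERS


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (0.05 at one decimal -> 0.1, never 0.0)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage of ``count`` in ``total``, rounded half-up."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total is undefined")
    quantum = Decimal(1).scaleb(-decimals)
    pct = Decimal(count) / Decimal(total) * 100
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def format_percent(count: int, total: int, decimals: int = 1) -> str:
    """Render a percentage: one-decimal by default ("59.7%"), integer display
    when the decimal is zero ("7%") or when decimals=0 is requested ("13%")."""
    value = percent(count, total, decimals)
    if value == int(value):
        return f"{int(value)}%"
    return f"{value}%"


def class_breakdown(functional_classes: Sequence[str]) -> pd.DataFrame:
    """Count and percentage per functional class.

    Returns a frame indexed by class with columns ``count``, ``percent``
    (one-decimal half-up) and ``display``; an empty input yields an empty
    frame (zero total), not an error.
    """
    classes = pd.Series(list(functional_classes), dtype=object)
    counts = classes.value_counts()
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(columns=["count", "percent", "display"])
    frame = counts.to_frame("count")
    frame["percent"] = [percent(c, total) for c in frame["count"]]
    frame["display"] = [format_percent(c, total) for c in frame["count"]]
    frame.index.name = "functional_class"
    return frame


def tier_breakdown(annotated: pd.DataFrame) -> dict:
    """Tier counts plus the healthy-absence fraction of Pathogenic variants.

    ``annotated`` needs a ``tier`` column; with an ``af_healthy`` column the
    summary also reports, among Pathogenic-tier variants, the fraction never
    observed in healthy genomes (af_healthy = 0).  Without health strata that
    fraction is None (unavailable), as it is when no variant is Pathogenic.
    """
    counts = annotated["tier"].value_counts()
    tier_counts = {t: int(counts.get(t, 0)) for t in TIERS}
    result: dict = {"tier_counts": tier_counts, "total": int(len(annotated))}

    frac: Optional[float] = None
    if "af_healthy" in annotated.columns:
        patho = annotated[annotated["tier"] == "Pathogenic"]
        af_h = patho["af_healthy"]
        if len(patho) > 0 and not af_h.isna().any():
            absent = int((af_h == 0).sum())
            frac = percent(absent, len(patho))
            result["pathogenic_absent_from_healthy_count"] = absent
    result["pathogenic_absent_from_healthy_percent"] = frac
    return result


def per_patient_mutation_table(
    variant_carriers: pd.DataFrame,
) -> pd.DataFrame:
    """Per-genome mutation counts from a (genome_id, position, ref, alt) table."""
    table = (
        variant_carriers.groupby("genome_id")
        .size()
        .rename("n_mutations")
        .reset_index()
        .sort_values(["n_mutations", "genome_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return table


def summary_markdown(class_frame: pd.DataFrame, tier_summary: dict) -> str:
    """Render the two breakdowns as a small Markdown report."""
    lines = ["# Cohort summary", "", "## Functional classes", ""]
    lines.append("| class | count | percent |")
    lines.append("|---|---|---|")
    for cls, row in class_frame.iterrows():
        lines.append(f"| {cls} | {int(row['count'])} | {row['display']} |")
    lines += ["", "## Pathogenicity tiers", "", "| tier | count |", "|---|---|"]
    for tier, count in tier_summary["tier_counts"].items():
        lines.append(f"| {tier} | {count} |")
    frac = tier_summary.get("pathogenic_absent_from_healthy_percent")
    lines.append("")
    if frac is None:
        lines.append("Pathogenic variants absent from healthy genomes: N/A")
    else:
        shown = int(frac) if frac == int(frac) else frac
        lines.append(f"Pathogenic variants absent from healthy genomes: {shown}%")
    return "\n".join(lines) + "\n"
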