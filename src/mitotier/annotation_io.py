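"""Interchange formats: annotated VCF, evidence tables and variant-card JSON.

The annotated VCF carries every computed attribute in namespaced INFO keys
(``HV_*``) so upstream annotations are never clobbered.  Tier labels use
underscores inside VCF INFO values (``Likely_Pathogenic``) because INFO
strings cannot contain whitespace; readers restore the canonical spaced
vocabulary.  Variant cards are JSON documents mirroring the three panels of
an interactive variant page — main info, variability, pathogenicity — with
absent attributes serialized as explicit nulls, never silently omitted.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import pysam

from .errors import DomainError
from .reference import ReferenceModel
from .trna import CRITERIA, TrnaEvidenceProfile

#: INFO keys written to annotated VCFs: key -> (Number, Type, Description).
VCF_INFO_FIELDS = {
    "HV_LOCUS": ("1", "String", "Locus name (or intergenic)"),
    "HV_CLASS": ("1", "String", "Functional class of the substitution"),
    "HV_STATUS": ("1", "String", "observed or potential"),
    "HV_AF": ("1", "Float", "Allele frequency over all genomes"),
    "HV_AF_H": ("1", "Float", "Allele frequency in healthy genomes"),
    "HV_AF_P": ("1", "Float", "Allele frequency in pathologic genomes"),
    "HV_NTVAR": ("1", "Float", "Nucleotide site variability in [0,1]"),
    "HV_AAVAR": ("1", "Float", "Amino-acid site variability in [0,1]"),
    "HV_DS": ("1", "Float", "Disease score in [0,1]"),
    "HV_TIER": ("1", "String", "Pathogenicity tier"),
}

_COLUMN_TO_INFO = {
    "locus": "HV_LOCUS",
    "functional_class": "HV_CLASS",
    "status": "HV_STATUS",
    "af_total": "HV_AF",
    "af_healthy": "HV_AF_H",
    "af_pathologic": "HV_AF_P",
    "nt_var": "HV_NTVAR",
    "aa_var": "HV_AAVAR",
    "disease_score": "HV_DS",
    "tier": "HV_TIER",
}
_INFO_TO_COLUMN = {v: k for k, v in _COLUMN_TO_INFO.items()}

_VARIANT_KEY_RE = re.compile(r"^m\.(\d+)([ACGT])>([ACGT])$")


def parse_variant_key(key: str) -> tuple[int, str, str]:
    """Parse an HGVS-like key ``m.POSREF>ALT`` into (position, ref, alt)."""
    m = _VARIANT_KEY_RE.match(key.strip())
    if m is None:
        raise ValueError(f"malformed variant key {key!r}; expected m.POSREF>ALT")
    return int(m.group(1)), m.group(2), m.group(3)


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


# ---------------------------------------------------------------------------
# Annotated VCF
# ---------------------------------------------------------------------------

def write_annotated_vcf(
    annotated: pd.DataFrame, reference: ReferenceModel, path: str | Path
) -> None:
    """Write an annotated variant table as a sorted VCF 4.2 file.

    ``annotated`` needs columns ``position, ref, alt`` plus any subset of the
    attribute columns mapped to ``HV_*`` INFO keys.  Records out of order are
    sorted with a warning; a position beyond the reference length is a contig
    mismatch and an error.  An allele frequency of zero is written as an
    explicit 0, not a missing value.
    """
    if (annotated["position"] > len(reference)).any() or (
        annotated["position"] < 1
    ).any():
        raise DomainError("record position outside the reference contig")
    if not annotated["position"].is_monotonic_increasing:
        warnings.warn("records unsorted; sorting by position", stacklevel=2)
    table = annotated.sort_values(["position", "alt"], kind="mergesort")

    header = pysam.VariantHeader()
    header.add_line(
        f"##contig=<ID={reference.name},length={len(reference)}>"
    )
    for key, (number, vtype, desc) in VCF_INFO_FIELDS.items():
        header.add_line(
            f'##INFO=<ID={key},Number={number},Type={vtype},Description="{desc}">'
        )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in table.to_dict("records"):
            rec = vcf.new_record(
                contig=reference.name,
                start=int(row["position"]) - 1,  # VCF is 1-based on disk only
                alleles=(row["ref"], row["alt"]),
            )
            for column, info_key in _COLUMN_TO_INFO.items():
                if column not in row:
                    continue
                value = row[column]
                if _is_missing(value):
                    continue
                if info_key == "HV_TIER":
                    value = str(value).replace(" ", "_")
                rec.info[info_key] = value
            vcf.write(rec)


def read_annotated_vcf(path: str | Path) -> pd.DataFrame:
    """Read an annotated VCF back into the canonical attribute table."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            row: dict = {
                "position": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
            }
            for info_key, column in _INFO_TO_COLUMN.items():
                if info_key in rec.info:
                    value = rec.info[info_key]
                    if info_key == "HV_TIER":
                        value = str(value).replace("_", " ")
                    row[column] = value
                else:
                    row[column] = None
            rows.append(row)
    frame = pd.DataFrame(rows)
    for column in ("af_total", "af_healthy", "af_pathologic",
                   "nt_var", "aa_var", "disease_score"):
        if column in frame.columns:
            frame[column] = frame[column].astype(float)
    return frame


# ---------------------------------------------------------------------------
# Evidence tables
# ---------------------------------------------------------------------------

_TRNA_HEADER = ["position", "ref", "alt", *CRITERIA, "evidence_available"]


def read_trna_evidence(path: str | Path) -> dict[tuple[int, str, str], TrnaEvidenceProfile]:
    """Read the tRNA criterion table (values yes/no/unknown) keyed by variant.

    The header is validated strictly so silently misaligned columns cannot
    corrupt criterion assignments.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns) != _TRNA_HEADER:
        raise ValueError(
            f"tRNA evidence header mismatch; expected {_TRNA_HEADER}"
        )
    decode = {"yes": True, "no": False, "unknown": None}
    profiles = {}
    for row in frame.to_dict("records"):
        values = {}
        for criterion in CRITERIA:
            cell = row[criterion]
            if cell not in decode:
                raise ValueError(
                    f"criterion {criterion} has value {cell!r}; "
                    "expected yes/no/unknown"
                )
            values[criterion] = decode[cell]
        available = row["evidence_available"]
        if available not in ("yes", "no"):
            raise ValueError("evidence_available must be yes or no")
        key = (int(row["position"]), row["ref"], row["alt"])
        profiles[key] = TrnaEvidenceProfile(
            **values, functional_evidence_available=available == "yes"
        )
    return profiles


def read_predictor_table(
    path: str | Path,
) -> dict[tuple[int, str, str], dict[str, Optional[float]]]:
    """Read the non-synonymous predictor table; missing values are ``.``."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["position", "ref", "alt"]
    if list(frame.columns[:3]) != required:
        raise ValueError("predictor table must start with position, ref, alt")
    predictors = list(frame.columns[3:])
    if not predictors:
        raise ValueError("predictor table declares no predictor columns")
    panels = {}
    for row in frame.to_dict("records"):
        key = (int(row["position"]), row["ref"], row["alt"])
        panels[key] = {
            name: None if row[name] == "." else float(row[name])
            for name in predictors
        }
    return panels


# ---------------------------------------------------------------------------
# Variant cards
# ---------------------------------------------------------------------------

def _clean(value):
    """NaN -> None so cards serialize with explicit nulls, never NaN."""
    return None if _is_missing(value) else value


def variant_card(record: Mapping, provenance: Optional[Mapping] = None) -> dict:
    """Assemble the full JSON card for one annotated variant.

    ``record`` is one row of the annotated table (mapping column -> value).
    The pathogenicity block is explicitly null for annotation-only records
    (no tier computed: synonymous, rRNA, regulatory, intergenic).
    """
    pos = int(record["position"])
    ref, alt = record["ref"], record["alt"]
    card = {
        "variant": {
            "position": pos,
            "ref": ref,
            "alt": alt,
            "hgvs": f"m.{pos}{ref}>{alt}",
        },
        "main_info": {
            "locus": _clean(record.get("locus")),
            "locus_type": _clean(record.get("locus_type")),
            "functional_class": _clean(record.get("functional_class")),
            "status": _clean(record.get("status")),
        },
        "variability": {
            "af_total": _clean(record.get("af_total")),
            "af_healthy": _clean(record.get("af_healthy")),
            "af_pathologic": _clean(record.get("af_pathologic")),
            "nt_var": _clean(record.get("nt_var")),
            "aa_var": _clean(record.get("aa_var")),
        },
    }
    tier = _clean(record.get("tier"))
    if tier is None or tier == "Unclassified":
        card["pathogenicity"] = None
    else:
        card["pathogenicity"] = {
            "disease_score": _clean(record.get("disease_score")),
            "tier": tier,
            "vus": bool(record.get("vus", False)),
            "ds_threshold": _clean(record.get("ds_threshold")),
            "af_threshold": _clean(record.get("af_threshold")),
        }
    card["provenance"] = dict(provenance) if provenance else None
    return card


def variant_card_json(
    annotated: pd.DataFrame, key: str, provenance: Optional[Mapping] = None
) -> str:
    """Serialize the card for the variant addressed by ``m.POSREF>ALT``.

    A malformed key raises ValueError; a well-formed key absent from the
    table raises KeyError, so the two failure modes stay distinguishable.
    """
    pos, ref, alt = parse_variant_key(key)
    hit = annotated[
        (annotated["position"] == pos)
        & (annotated["ref"] == ref)
        & (annotated["alt"] == alt)
    ]
    if hit.empty:
        raise KeyError(f"variant {key} not in the annotated catalogue")
    card = variant_card(hit.iloc[0].to_dict(), provenance)
    return json.dumps(card, indent=2, allow_nan=False)


def variant_list_json(annotated: pd.DataFrame) -> str:
    """Serialize a list query: per-variant summary plus a locator string
    pointing at the variant's complete card."""
    entries = []
    for record in annotated.to_dict("records"):
        pos, ref, alt = int(record["position"]), record["ref"], record["alt"]
        hgvs = f"m.{pos}{ref}>{alt}"
        entries.append(
            {
                "hgvs": hgvs,
                "locus": _clean(record.get("locus")),
                "functional_class": _clean(record.get("functional_class")),
                "tier": _clean(record.get("tier")),
                "locator": f"variant/{hgvs}",
            }
        )
    return json.dumps(entries, indent=2, allow_nan=False)
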