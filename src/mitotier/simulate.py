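"""Deterministic synthetic cohorts and evidence tables for pipeline testing.

The generator emulates the inputs the annotation pipeline consumes in
production: a cohort of complete, aligned mitochondrial genomes stratified
into healthy and pathologic individuals, a tRNA criterion table and a
non-synonymous predictor table.  Variants are planted at chosen per-stratum
allele frequencies; carrier counts are realized exactly (round(AF x N)) so the
expected tier of every planted variant is a deterministic arithmetic fact
recorded in a truth table.  Identical spec + seed give byte-identical outputs.

The default toy reference is a 600 bp mini-genome with one regulatory, one
tRNA, one rRNA and one protein-coding locus, so every locus-type annotation
regime is exercised cheaply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SimulationSpecError
from .frequency import GenomeCohort
from .reference import (
    NUCLEOTIDES,
    Locus,
    LocusMap,
    ReferenceModel,
    classify_substitution,
    translate_codon,
)
from .trna import CRITERIA, DEFAULT_RAW_WEIGHTS, FUNCTIONAL_CRITERIA

# Truth-table threshold arithmetic is written out inline (not imported from
# the tiers module) so end-to-end recovery checks pipeline against an
# independent computation of the expected tier.
_TRUTH_DS_T = {"non-synonymous": 0.43, "tRNA": 0.35}
_TRUTH_AF_T = {"non-synonymous": 0.003264, "tRNA": 0.005020}


@dataclass(frozen=True)
class PlantedVariant:
    """One variant to plant in the synthetic cohort.

    ``kind`` drives position/alt auto-selection when they are not pinned:
    "tRNA" picks a position in the tRNA locus, "non-synonymous", "synonymous"
    and "stop-gain" scan the CDS for an alt with that functional class.
    Evidence: ``trna_criteria`` maps criterion name -> True/False (None means
    no evidence row is emitted at all); ``predictors`` maps predictor name ->
    probability (None means no predictor row).
    """

    kind: str
    af_healthy: float = 0.0
    af_pathologic: float = 0.0
    position: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    trna_criteria: Optional[dict] = None
    evidence_available: bool = True
    predictors: Optional[dict] = None

    def __post_init__(self) -> None:
        for af in (self.af_healthy, self.af_pathologic):
            if not 0.0 <= af <= 1.0:
                raise SimulationSpecError(f"target AF {af} outside [0, 1]")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a synthetic study: reference size, cohort strata
    sizes, planted variants and the random seed."""

    planted: tuple[PlantedVariant, ...] = ()
    reference_length: int = 600
    n_healthy: int = 400
    n_pathologic: int = 100
    seed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_healthy + self.n_pathologic


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def toy_reference(
    seed: int = 0, length: int = 600
) -> tuple[ReferenceModel, LocusMap]:
    """Deterministic toy mini-genome with all four locus types.

    Layout (for the default 600 bp): regulatory 1-60, tRNA 61-130, rRNA
    131-260, intergenic 261-299, CDS 300-560 (plus strand, ATG start, sense
    codons, TAA stop), intergenic 561-600.  The CDS codons are sampled from
    the sense codons of the vertebrate mitochondrial code so every internal
    position admits synonymous/non-synonymous/stop-gain alternatives.
    """
    if length < 600:
        raise SimulationSpecError("toy reference needs at least 600 bp")
    rng = np.random.default_rng(seed)
    bases = list(NUCLEOTIDES)
    seq = rng.choice(bases, size=length).tolist()

    cds_start, cds_end = 300, 560  # 261 bases = 87 codons
    sense_codons = [
        a + b + c
        for a in bases for b in bases for c in bases
        if translate_codon(a + b + c) != "*"
    ]
    codons = ["ATG"]
    codons += [sense_codons[i] for i in rng.integers(0, len(sense_codons), 85)]
    codons.append("TAA")
    seq[cds_start - 1 : cds_end] = list("".join(codons))

    reference = ReferenceModel("".join(seq), circular=True, name="toy_mt")
    locus_map = LocusMap(
        [
            Locus("TOY-CR", "regulatory", 1, 60),
            Locus("TOY-TX", "tRNA", 61, 130),
            Locus("TOY-RNR", "rRNA", 131, 260),
            Locus("TOY-CDS", "CDS", cds_start, cds_end,
                  reading_frame_origin=cds_start),
        ]
    )
    return reference, locus_map


@dataclass(frozen=True)
class ResolvedPlant:
    """A planted variant with concrete position/ref/alt and truth values."""

    variant: PlantedVariant
    position: int
    ref: str
    alt: str
    functional_class: str
    carriers_healthy: int
    carriers_pathologic: int

    def truth_afs(self, spec: SimulationSpec) -> tuple[float, float, float]:
        af_h = self.carriers_healthy / spec.n_healthy if spec.n_healthy else 0.0
        af_p = (
            self.carriers_pathologic / spec.n_pathologic
            if spec.n_pathologic
            else 0.0
        )
        af_t = (self.carriers_healthy + self.carriers_pathologic) / spec.n_total
        return af_t, af_h, af_p


def _truth_disease_score(plant: PlantedVariant) -> Optional[float]:
    """Expected DS from the spec'd evidence pattern, by direct arithmetic."""
    if plant.kind == "tRNA":
        if plant.trna_criteria is None:
            return 0.0
        total = sum(DEFAULT_RAW_WEIGHTS)
        return sum(
            DEFAULT_RAW_WEIGHTS[i] / total
            for i, name in enumerate(CRITERIA)
            if plant.trna_criteria.get(name) is True
        )
    if plant.kind == "non-synonymous":
        if not plant.predictors:
            return None
        values = list(plant.predictors.values())
        return sum(values) / len(values)
    return None


def _truth_tier(plant: PlantedVariant, af_total: float) -> str:
    """Expected tier by inline threshold arithmetic."""
    if plant.kind == "tRNA":
        vus = plant.trna_criteria is None or not plant.evidence_available
        if vus:
            return "VUS"
    ds = _truth_disease_score(plant)
    if plant.kind not in _TRUTH_DS_T or ds is None:
        return "Unclassified"
    ds_t, af_t = _TRUTH_DS_T[plant.kind], _TRUTH_AF_T[plant.kind]
    if ds >= ds_t:
        return "Pathogenic" if af_total <= af_t else "Likely Pathogenic"
    return "Likely Polymorphic" if af_total <= af_t else "Polymorphic"


def resolve_spec(
    spec: SimulationSpec,
) -> tuple[ReferenceModel, LocusMap, list[ResolvedPlant]]:
    """Pin every planted variant to a concrete (position, ref, alt).

    Auto-selection is deterministic: tRNA plants take successive tRNA-locus
    positions; CDS plants scan coding positions in order for the first alt
    producing the requested functional class.  Positions are never reused.
    """
    reference, locus_map = toy_reference(spec.seed, spec.reference_length)
    L = len(reference)
    used: set[int] = set()
    trna_locus = locus_map.by_type("tRNA")[0]
    cds_locus = locus_map.by_type("CDS")[0]
    resolved = []
    for plant in spec.planted:
        position, alt = plant.position, plant.alt
        if position is not None:
            ref_base = reference.base_at(position)
            if plant.ref is not None and plant.ref != ref_base:
                raise SimulationSpecError(
                    f"planted ref {plant.ref} != reference base {ref_base} "
                    f"at m.{position}"
                )
            if alt is None:
                alt = next(b for b in NUCLEOTIDES if b != ref_base)
        elif plant.kind == "tRNA":
            position = next(
                p for p in trna_locus.positions(L) if p not in used
            )
            ref_base = reference.base_at(position)
            alt = next(b for b in NUCLEOTIDES if b != ref_base)
        else:
            # Scan the CDS (skipping start/stop codons) for the wanted class.
            position, alt = None, None
            for p in range(cds_locus.start + 3, cds_locus.end - 2):
                if p in used:
                    continue
                ref_base = reference.base_at(p)
                for b in NUCLEOTIDES:
                    if b == ref_base:
                        continue
                    fclass = classify_substitution(
                        p, ref_base, b, reference, cds_locus
                    )
                    if fclass == plant.kind:
                        position, alt = p, b
                        break
                if position is not None:
                    break
            if position is None:
                raise SimulationSpecError(
                    f"no CDS site admits a {plant.kind} substitution"
                )
            ref_base = reference.base_at(position)
        if position in used:
            raise SimulationSpecError(f"position m.{position} planted twice")
        used.add(position)
        locus = locus_map.locus_of(position, L)
        fclass = classify_substitution(position, ref_base, alt, reference, locus)
        resolved.append(
            ResolvedPlant(
                variant=plant,
                position=position,
                ref=ref_base,
                alt=alt,
                functional_class=fclass,
                carriers_healthy=_round_half_up(plant.af_healthy * spec.n_healthy),
                carriers_pathologic=_round_half_up(
                    plant.af_pathologic * spec.n_pathologic
                ),
            )
        )
    return reference, locus_map, resolved


def generate_cohort(
    spec: SimulationSpec, outdir: Optional[str | Path] = None
) -> tuple[GenomeCohort, pd.DataFrame, ReferenceModel, LocusMap]:
    """Build the cohort alignment and the truth table.

    Returns (cohort, truth, reference, locus_map); with ``outdir`` also
    writes ``cohort.fa``, ``manifest.tsv`` and ``truth.tsv``.  Carrier
    genomes are drawn without replacement per stratum with the spec seed, so
    reseeding moves carriers between genomes but never changes the truth
    table (tiers depend only on counts and evidence, both spec-fixed).
    """
    reference, locus_map, resolved = resolve_spec(spec)
    rng = np.random.default_rng(spec.seed)
    n_h, n_p = spec.n_healthy, spec.n_pathologic
    alignment = np.array(
        [list(reference.sequence)] * spec.n_total, dtype="<U1"
    )
    # Rows 0..n_h-1 healthy, the rest pathologic.
    for plant in resolved:
        if plant.carriers_healthy > 0:
            rows = rng.choice(n_h, size=plant.carriers_healthy, replace=False)
            alignment[rows, plant.position - 1] = plant.alt
        if plant.carriers_pathologic > 0:
            rows = n_h + rng.choice(
                n_p, size=plant.carriers_pathologic, replace=False
            )
            alignment[rows, plant.position - 1] = plant.alt

    ids = [f"H{i:04d}" for i in range(1, n_h + 1)] + [
        f"P{i:04d}" for i in range(1, n_p + 1)
    ]
    statuses = ["healthy"] * n_h + ["pathologic"] * n_p
    cohort = GenomeCohort(alignment, ids, statuses)

    truth_rows = []
    for plant in resolved:
        af_t, af_h, af_p = plant.truth_afs(spec)
        ds = _truth_disease_score(plant.variant)
        truth_rows.append(
            {
                "position": plant.position,
                "ref": plant.ref,
                "alt": plant.alt,
                "kind": plant.variant.kind,
                "functional_class": plant.functional_class,
                "af_total": af_t,
                "af_healthy": af_h,
                "af_pathologic": af_p,
                "disease_score": float("nan") if ds is None else ds,
                "expected_tier": _truth_tier(plant.variant, af_t),
            }
        )
    truth = pd.DataFrame(truth_rows)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "cohort.fa", "w") as fh:
            for gid, row in zip(ids, alignment):
                fh.write(f">{gid}\n{''.join(row)}\n")
        with open(outdir / "manifest.tsv", "w") as fh:
            for gid, status in zip(ids, statuses):
                fh.write(f"{gid}\t{status}\n")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        with open(outdir / "reference.fa", "w") as fh:
            fh.write(f">{reference.name}\n{reference.sequence}\n")
        with open(outdir / "loci.tsv", "w") as fh:
            for locus in locus_map:
                frame = (
                    str(locus.reading_frame_origin)
                    if locus.reading_frame_origin is not None
                    else "."
                )
                fh.write(
                    f"{locus.name}\t{locus.locus_type}\t{locus.start}\t"
                    f"{locus.end}\t{locus.strand}\t{frame}\n"
                )
    return cohort, truth, reference, locus_map


def generate_evidence_tables(
    spec: SimulationSpec, outdir: Optional[str | Path] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit the tRNA criterion table and the predictor table for the spec.

    Only planted variants with an evidence pattern get a row; unlisted
    variants drive the VUS / unassigned-score paths downstream.  Criterion
    cells are yes/no/unknown; when functional evidence is unavailable the
    five functional-study criteria stay ``unknown``.
    """
    _, _, resolved = resolve_spec(spec)
    trna_rows, predictor_rows = [], []
    predictor_names: list[str] = []
    for plant in resolved:
        v = plant.variant
        if v.kind == "tRNA" and v.trna_criteria is not None:
            row = {"position": plant.position, "ref": plant.ref, "alt": plant.alt}
            for name in CRITERIA:
                value = v.trna_criteria.get(name)
                if not v.evidence_available and name in FUNCTIONAL_CRITERIA:
                    value = None
                row[name] = {True: "yes", False: "no", None: "unknown"}[value]
            row["evidence_available"] = "yes" if v.evidence_available else "no"
            trna_rows.append(row)
        if v.kind == "non-synonymous" and v.predictors is not None:
            for name in v.predictors:
                if name not in predictor_names:
                    predictor_names.append(name)
            predictor_rows.append(
                {
                    "position": plant.position,
                    "ref": plant.ref,
                    "alt": plant.alt,
                    **v.predictors,
                }
            )

    trna_cols = ["position", "ref", "alt", *CRITERIA, "evidence_available"]
    trna_table = pd.DataFrame(trna_rows, columns=trna_cols)
    pred_cols = ["position", "ref", "alt", *predictor_names]
    predictor_table = pd.DataFrame(predictor_rows, columns=pred_cols)
    if predictor_names:
        predictor_table = predictor_table.fillna(".")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        trna_table.to_csv(outdir / "trna_evidence.tsv", sep="\t", index=False)
        predictor_table.to_csv(outdir / "predictors.tsv", sep="\t", index=False)
    return trna_table, predictor_table


def default_scenario(seed: int = 0) -> SimulationSpec:
    """A 22-variant study spanning every tier, VUS and unassigned-score case.

    tRNA plants exercise the criterion-sum score (including the exact
    DS = DS_T boundary) and both AF sides of 0.005020; non-synonymous plants
    exercise the predictor consensus around 0.43/0.003264; one stop-gain and
    one synonymous plant cover the score-withheld classes.
    """
    all_yes = {c: True for c in CRITERIA}
    conserved_only = {
        "phastcons_conserved": True,
        "phylop_conserved": True,
        "cybrid_or_steady_state_evidence": False,
    }
    ds_035 = {  # 0.1 + 0.25 = 0.35, the exact tRNA threshold
        "heteroplasmy_evidence": True,
        "cybrid_or_steady_state_evidence": True,
    }
    ds_050 = {  # 0.1 + 0.25 + 0.15 = 0.50
        "multiple_pathogenic_reports": True,
        "cybrid_or_steady_state_evidence": True,
        "single_fiber_segregation": True,
    }
    ds_075 = {  # 1.0 - 0.1 - 0.15 = 0.75
        c: True
        for c in CRITERIA
        if c not in ("heteroplasmy_evidence", "single_fiber_segregation")
    }
    ds_030 = {  # 0.1 + 0.05 + 0.05 + 0.1 = 0.30, just under threshold
        "multiple_pathogenic_reports": True,
        "phastcons_conserved": True,
        "phylop_conserved": True,
        "heteroplasmy_evidence": True,
        "oxphos_biochemical_defect": False,
    }
    all_no = {c: False for c in CRITERIA}

    t = PlantedVariant
    planted = (
        # --- tRNA, thresholds DS_T 0.35 / AF_T 0.005020 ---
        t("tRNA", af_pathologic=0.02, trna_criteria=all_yes),          # Pathogenic
        t("tRNA", af_healthy=0.0025, trna_criteria=ds_050),            # Pathogenic
        t("tRNA", af_healthy=0.0025, af_pathologic=0.01,
          trna_criteria=ds_075),                                       # Pathogenic
        t("tRNA", af_healthy=0.05, af_pathologic=0.05,
          trna_criteria=all_yes),                                      # Likely Pathogenic
        t("tRNA", af_healthy=0.05, trna_criteria=ds_035),              # Likely Pathogenic (DS = DS_T)
        t("tRNA", af_healthy=0.0025, trna_criteria=conserved_only),    # Likely Polymorphic
        t("tRNA", af_pathologic=0.02, trna_criteria=ds_030),           # Likely Polymorphic
        t("tRNA", af_healthy=0.05, trna_criteria=conserved_only),      # Polymorphic
        t("tRNA", af_healthy=0.1, trna_criteria=all_no),               # Polymorphic
        t("tRNA", af_healthy=0.01,
          trna_criteria={"phastcons_conserved": True},
          evidence_available=False),                                   # VUS despite DS > 0
        t("tRNA", af_pathologic=0.02, trna_criteria=None,
          evidence_available=False),                                   # VUS, no evidence row
        # --- non-synonymous, thresholds DS_T 0.43 / AF_T 0.003264 ---
        t("non-synonymous", af_pathologic=0.01,
          predictors={"p1": 0.9, "p2": 0.8}),                          # Pathogenic
        t("non-synonymous", af_healthy=0.0025,
          predictors={"p1": 0.43}),                                    # Pathogenic (DS = DS_T)
        t("non-synonymous", af_pathologic=0.01,
          predictors={"p1": 1.0}),                                     # Pathogenic
        t("non-synonymous", af_healthy=0.05, af_pathologic=0.05,
          predictors={"p1": 0.9, "p2": 0.8}),                          # Likely Pathogenic
        t("non-synonymous", af_healthy=0.01,
          predictors={"p1": 0.7, "p2": 0.5}),                          # Likely Pathogenic
        t("non-synonymous", af_healthy=0.0025,
          predictors={"p1": 0.2}),                                     # Likely Polymorphic
        t("non-synonymous", af_pathologic=0.01,
          predictors={"p1": 0.0}),                                     # Likely Polymorphic
        t("non-synonymous", af_healthy=0.05,
          predictors={"p1": 0.2, "p2": 0.2}),                          # Polymorphic
        t("non-synonymous", af_healthy=0.01, predictors=None),         # Unclassified (no panel)
        t("stop-gain", af_healthy=0.0025),                             # Unclassified (withheld)
        t("synonymous", af_healthy=0.01),                              # Unclassified (not scored)
    )
    return SimulationSpec(planted=planted, seed=seed)
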