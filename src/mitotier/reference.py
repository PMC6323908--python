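"""rCRS-anchored coordinate system, locus map and functional-effect calling.

The human mitochondrial genome is a 16,569 bp circular molecule conventionally
numbered 1-based against the revised Cambridge Reference Sequence (rCRS,
NC_012920.1).  Variants are single-nucleotide substitutions written
``m.POS REF>ALT``.  Protein-coding loci are translated with the vertebrate
mitochondrial genetic code (NCBI translation table 2), under which AGA/AGG are
stops and ATA codes for methionine.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import (
    CoordinateError,
    LocusTypeError,
    ReferenceMismatchError,
    UnsupportedAlleleError,
)

NUCLEOTIDES = ("A", "C", "G", "T")
_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: NCBI translation table 2 (vertebrate mitochondrial).
MT_CODON_TABLE = CodonTable.unambiguous_dna_by_id[2]
_STOP_CODONS = frozenset(MT_CODON_TABLE.stop_codons)

LOCUS_TYPES = ("CDS", "tRNA", "rRNA", "regulatory")
#: Tie-break priority when annotations overlap (lower wins).
_LOCUS_PRIORITY = {t: i for i, t in enumerate(LOCUS_TYPES)}

FUNCTIONAL_CLASSES = (
    "synonymous",
    "non-synonymous",
    "stop-gain",
    "stop-loss",
    "tRNA",
    "rRNA",
    "regulatory",
)

RCRS_LENGTH = 16_569
RCRS_ACCESSION = "NC_012920.1"


def translate_codon(codon: str) -> str:
    """Translate a codon under the vertebrate mitochondrial code; stop -> '*'."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
        raise UnsupportedAlleleError(f"cannot translate ambiguous codon {codon!r}")
    if codon in _STOP_CODONS:
        return "*"
    return MT_CODON_TABLE.forward_table[codon]


@dataclass(frozen=True)
class Locus:
    """A named genomic interval typed CDS / tRNA / rRNA / regulatory.

    Coordinates are 1-based inclusive.  A locus spanning the circular origin
    (e.g. the control region, m.16024-576) has ``start > end`` and is flagged
    ``wraps_origin``.  ``reading_frame_origin`` is the genomic position of the
    first base of codon 1 (CDS only); for minus-strand CDS it is the highest
    genomic coordinate of the reading frame.
    """

    name: str
    locus_type: str
    start: int
    end: int
    strand: str = "+"
    reading_frame_origin: Optional[int] = None
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.locus_type not in LOCUS_TYPES:
            raise LocusTypeError(f"unknown locus type {self.locus_type!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.wraps_origin and self.start > self.end:
            raise ValueError(
                f"{self.name}: start > end without wraps_origin flag"
            )

    def contains(self, position: int, length: int) -> bool:
        if self.wraps_origin:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    def positions(self, length: int) -> Iterable[int]:
        if self.wraps_origin:
            yield from range(self.start, length + 1)
            yield from range(1, self.end + 1)
        else:
            yield from range(self.start, self.end + 1)

    def span(self, length: int) -> int:
        if self.wraps_origin:
            return (length - self.start + 1) + self.end
        return self.end - self.start + 1


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide substitution anchored to a 1-based position."""

    position: int
    ref_allele: str
    alt_allele: str
    locus: Optional[Locus] = None
    functional_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("alt allele must differ from reference allele")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_allele, self.alt_allele)

    def hgvs(self) -> str:
        return f"m.{self.position}{self.ref_allele}>{self.alt_allele}"


class ReferenceModel:
    """A circular (or linear) reference genome with 1-based coordinates."""

    def __init__(self, sequence: str, circular: bool = True, name: str = "chrM"):
        sequence = sequence.upper()
        bad = set(sequence) - _VALID_BASES
        if bad:
            raise UnsupportedAlleleError(f"invalid reference bases: {sorted(bad)}")
        self.sequence = sequence
        self.circular = circular
        self.name = name

    def __len__(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise CoordinateError(
                f"position {position} outside [1, {len(self.sequence)}]"
            )
        return self.sequence[position - 1]

    @classmethod
    def from_fasta(cls, path: str | Path, circular: bool = True) -> "ReferenceModel":
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
        rec = records[0]
        return cls(str(rec.seq), circular=circular, name=rec.id)


class LocusMap:
    """Ordered collection of loci with deterministic overlap resolution."""

    def __init__(self, loci: Iterable[Locus]):
        self.loci = sorted(
            loci, key=lambda l: (_LOCUS_PRIORITY[l.locus_type], l.start, l.name)
        )

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def all_loci_at(self, position: int, length: int) -> list[Locus]:
        """Every locus containing ``position``, in tie-break order."""
        if not 1 <= position <= length:
            raise CoordinateError(f"position {position} outside [1, {length}]")
        return [l for l in self.loci if l.contains(position, length)]

    def locus_of(self, position: int, length: int) -> Locus | str:
        """Primary locus at ``position``; ``"intergenic"`` when unannotated.

        Overlaps resolve by locus-type priority CDS > tRNA > rRNA > regulatory,
        then by start coordinate.
        """
        hits = self.all_loci_at(position, length)
        return hits[0] if hits else "intergenic"

    def by_type(self, locus_type: str) -> list[Locus]:
        return [l for l in self.loci if l.locus_type == locus_type]

    @classmethod
    def from_table(cls, path: str | Path) -> "LocusMap":
        """Read a tab-separated locus table.

        Columns: name, type, start, end, strand, frame — 1-based inclusive
        coordinates; ``frame`` is the reading-frame origin for CDS rows and
        ``.`` otherwise; a row with start > end marks an origin-spanning locus.
        """
        loci = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, ltype, start, end, strand, frame = line.split("\t")
                start, end = int(start), int(end)
                loci.append(
                    Locus(
                        name=name,
                        locus_type=ltype,
                        start=start,
                        end=end,
                        strand=strand,
                        reading_frame_origin=None if frame == "." else int(frame),
                        wraps_origin=start > end,
                    )
                )
        return cls(loci)

    @classmethod
    def from_bed(cls, path: str | Path) -> "LocusMap":
        """Read a BED file (0-based half-open; converted to 1-based inclusive).

        Column 4 is ``name|type`` or just the name (type defaults to
        regulatory); strand from column 6 when present.
        """
        loci = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                start0, end0 = int(fields[1]), int(fields[2])
                name_field = fields[3] if len(fields) > 3 else "locus"
                if "|" in name_field:
                    name, ltype = name_field.split("|", 1)
                else:
                    name, ltype = name_field, "regulatory"
                strand = fields[5] if len(fields) > 5 else "+"
                loci.append(
                    Locus(
                        name=name,
                        locus_type=ltype,
                        start=start0 + 1,  # BED -> 1-based exactly once
                        end=end0,
                        strand=strand,
                    )
                )
        return cls(loci)


def _check_alleles(ref_allele: str, alt_allele: str) -> None:
    for allele in (ref_allele, alt_allele):
        if allele not in NUCLEOTIDES:
            raise UnsupportedAlleleError(f"unsupported allele {allele!r}")


def _codon_positions(locus: Locus, position: int) -> tuple[list[int], int]:
    """Genomic positions (5'->3' in reading direction) of the codon covering
    ``position``, and the within-codon index of ``position``."""
    origin = locus.reading_frame_origin
    if origin is None:
        raise LocusTypeError(f"{locus.name}: CDS locus lacks a reading-frame origin")
    if locus.strand == "+":
        offset = position - origin
        if offset < 0:
            raise CoordinateError(f"position {position} upstream of codon 1")
        first = origin + 3 * (offset // 3)
        return [first, first + 1, first + 2], offset % 3
    offset = origin - position
    if offset < 0:
        raise CoordinateError(f"position {position} upstream of codon 1")
    first = origin - 3 * (offset // 3)
    return [first, first - 1, first - 2], offset % 3


def _coding_base(reference: ReferenceModel, locus: Locus, position: int) -> str:
    """Base at a genomic position read in the locus's coding orientation.

    Positions one or two bases past the annotated 3' end are padded with 'A',
    modelling the poly-A completion of incomplete mitochondrial stop codons.
    """
    past_end = (
        position > len(reference)
        or (locus.strand == "+" and not locus.wraps_origin and position > locus.end)
        or (locus.strand == "-" and position < locus.start)
        or position < 1
    )
    if past_end:
        return "A"
    base = reference.base_at(position)
    return base if locus.strand == "+" else base.translate(_COMPLEMENT)


def classify_substitution(
    position: int,
    ref_allele: str,
    alt_allele: str,
    reference: ReferenceModel,
    locus: Locus,
) -> str:
    """Functional class of a substitution within ``locus``.

    CDS loci translate the affected codon before and after the change under
    the vertebrate mitochondrial code: identical residues -> synonymous,
    different -> non-synonymous, sense-to-stop -> stop-gain, stop-to-sense ->
    stop-loss.  Non-coding loci return their locus type.
    """
    _check_alleles(ref_allele, alt_allele)
    if reference.base_at(position) != ref_allele:
        raise ReferenceMismatchError(
            f"m.{position}: declared ref {ref_allele} != genome "
            f"{reference.base_at(position)}"
        )
    if locus.locus_type != "CDS":
        return locus.locus_type

    codon_pos, within = _codon_positions(locus, position)
    codon = "".join(_coding_base(reference, locus, p) for p in codon_pos)
    alt_in_frame = (
        alt_allele if locus.strand == "+" else alt_allele.translate(_COMPLEMENT)
    )
    mutated = codon[:within] + alt_in_frame + codon[within + 1 :]
    aa_ref = translate_codon(codon)
    aa_alt = translate_codon(mutated)
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stop-gain"
    if aa_ref == "*":
        return "stop-loss"
    return "non-synonymous"


def human_mt_locus_map() -> LocusMap:
    """The standard 1-based gene map of the human mitochondrial genome
    (coordinates of NC_012920.1), bundled as package data."""
    path = importlib.resources.files("mitotier.data") / "human_mt_loci.tsv"
    return LocusMap.from_table(str(path))


def synthetic_rcrs_like_reference(seed: int = 20_120_920) -> ReferenceModel:
    """A deterministic SYNTHETIC stand-in for the rCRS.

    Real length (16,569 bp) and the real locus coordinates apply, but the base
    content is pseudo-random: every count that depends only on genome length
    and the locus map (e.g. the 3L potential-substitution space) is exact,
    while base-level annotations are synthetic.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(NUCLEOTIDES), size=RCRS_LENGTH))
    return ReferenceModel(seq, circular=True, name=f"synthetic_{RCRS_ACCESSION}")
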