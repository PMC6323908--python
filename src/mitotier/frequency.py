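"""Allele-frequency and site-variability estimation from a genome cohort.

A cohort is a set of complete, aligned mitochondrial genomes, each labelled
``healthy`` (no disease description for the individual) or ``pathologic``.
mtDNA consensus genomes are haploid, so allele frequencies are fractions of
genomes: carriers of the alternative allele divided by genomes with a called
base at the position, within the requested stratum.  Gap and ambiguous symbols
are excluded from numerator and denominator alike.

Per-site variability scores (``nt_var`` for nucleotide columns, ``aa_var`` for
translated residue columns) lie in [0, 1]; 0 marks a fully conserved site and
higher values a lower functional constraint.  The default statistic is the
Shannon entropy of the column normalized by the log of the alphabet size
(4 nucleotides; 20 amino acids + stop), a pluggable strategy so alternative
variability formulations can be dropped in.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Callable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    InsufficientDataError,
    LocusTypeError,
    UndefinedFrequencyError,
)
from .reference import (
    NUCLEOTIDES,
    Locus,
    LocusMap,
    ReferenceModel,
    _codon_positions,
    translate_codon,
)

HEALTH_STATUSES = ("healthy", "pathologic")
Stratum = Literal["all", "healthy", "pathologic"]

#: Alphabet size for residue columns: 20 amino acids plus the stop signal.
AA_ALPHABET_SIZE = 21


def normalized_entropy(counts: Sequence[int], alphabet_size: int) -> float:
    """Shannon entropy of a symbol-count vector, normalized to [0, 1] by
    log(alphabet_size).  Zero for monomorphic columns, 1 when all
    ``alphabet_size`` symbols are equiprobable."""
    total = sum(counts)
    if total == 0:
        return 0.0
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    return h / math.log(alphabet_size)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a two-column health-status manifest (genome_id, healthy|pathologic)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["genome_id", "status"], dtype=str,
        comment="#",
    )
    return validate_manifest(df)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Validate manifest bookkeeping: known statuses, unique genome ids, and
    healthy + pathologic counts summing to the total."""
    bad = set(manifest["status"]) - set(HEALTH_STATUSES)
    if bad:
        raise ValueError(f"unknown health statuses {sorted(bad)}")
    if manifest["genome_id"].duplicated().any():
        raise ValueError("duplicate genome ids in manifest")
    counts = manifest["status"].value_counts()
    n_healthy = int(counts.get("healthy", 0))
    n_pathologic = int(counts.get("pathologic", 0))
    if n_healthy + n_pathologic != len(manifest):
        raise ValueError("stratum counts do not sum to the manifest total")
    return manifest


def manifest_counts(manifest: pd.DataFrame) -> tuple[int, int, int]:
    """(n_healthy, n_pathologic, n_total) after manifest validation."""
    validate_manifest(manifest)
    counts = manifest["status"].value_counts()
    n_h = int(counts.get("healthy", 0))
    n_p = int(counts.get("pathologic", 0))
    return n_h, n_p, n_h + n_p


class GenomeCohort:
    """Aligned complete genomes with per-genome health status.

    ``alignment`` is an (N, L) array of single characters; symbols outside
    {A, C, G, T} (gaps, N) count as uncalled.
    """

    def __init__(
        self,
        alignment: np.ndarray,
        genome_ids: Sequence[str],
        statuses: Sequence[str],
    ):
        alignment = np.asarray(alignment, dtype="<U1")
        if alignment.ndim != 2:
            raise ValueError("alignment must be a 2-D (genomes x positions) array")
        if not (len(genome_ids) == len(statuses) == alignment.shape[0]):
            raise ValueError("genome_ids, statuses and alignment rows disagree")
        bad = set(statuses) - set(HEALTH_STATUSES)
        if bad:
            raise ValueError(f"unknown health statuses {sorted(bad)}")
        self.alignment = np.char.upper(alignment)
        self.genome_ids = list(genome_ids)
        self.statuses = np.asarray(statuses)
        self._called = np.isin(self.alignment, NUCLEOTIDES)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_fasta(
        cls, fasta_path: str | Path, manifest_path: str | Path
    ) -> "GenomeCohort":
        manifest = read_manifest(manifest_path)
        status_of = dict(zip(manifest["genome_id"], manifest["status"]))
        ids, rows = [], []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if rec.id not in status_of:
                raise ValueError(f"genome {rec.id!r} missing from manifest")
            ids.append(rec.id)
            rows.append(list(str(rec.seq).upper()))
        if not rows:
            raise ValueError("empty cohort FASTA")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError("cohort genomes are not aligned to a common length")
        statuses = [status_of[i] for i in ids]
        return cls(np.array(rows), ids, statuses)

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_total(self) -> int:
        return self.alignment.shape[0]

    @property
    def n_healthy(self) -> int:
        return int((self.statuses == "healthy").sum())

    @property
    def n_pathologic(self) -> int:
        return int((self.statuses == "pathologic").sum())

    @property
    def length(self) -> int:
        return self.alignment.shape[1]

    def _stratum_mask(self, stratum: Stratum) -> np.ndarray:
        if stratum == "all":
            return np.ones(self.n_total, dtype=bool)
        if stratum in HEALTH_STATUSES:
            return self.statuses == stratum
        raise ValueError(f"unknown stratum {stratum!r}")

    # -- statistics --------------------------------------------------------

    def allele_frequency(
        self, position: int, alt_allele: str, stratum: Stratum = "all"
    ) -> float:
        """Fraction of stratum genomes with a called base at ``position`` that
        carry ``alt_allele``.  Raises when the denominator is empty rather
        than reporting a spurious zero."""
        col = self.alignment[:, position - 1]
        mask = self._stratum_mask(stratum) & self._called[:, position - 1]
        denom = int(mask.sum())
        if denom == 0:
            raise UndefinedFrequencyError(
                f"no called genomes at m.{position} in stratum {stratum!r}"
            )
        return float((col[mask] == alt_allele).sum() / denom)

    def base_counts(self, position: int, stratum: Stratum = "all") -> dict[str, int]:
        col = self.alignment[:, position - 1]
        mask = self._stratum_mask(stratum) & self._called[:, position - 1]
        return {b: int((col[mask] == b).sum()) for b in NUCLEOTIDES}

    def nt_site_variability(
        self,
        position: int,
        statistic: Callable[[Sequence[int], int], float] = normalized_entropy,
    ) -> float:
        """Nucleotide variability of the alignment column at ``position``."""
        counts = self.base_counts(position)
        if sum(counts.values()) < 2:
            raise InsufficientDataError(
                f"fewer than 2 called genomes at m.{position}"
            )
        return statistic(list(counts.values()), len(NUCLEOTIDES))

    def residue_column(self, locus: Locus, codon_index: int) -> list[str]:
        """Translated residues at 0-based ``codon_index`` of a CDS locus, one
        per genome with all three codon bases called."""
        if locus.locus_type != "CDS":
            raise LocusTypeError(f"{locus.name} is not a CDS locus")
        anchor = (
            locus.reading_frame_origin + 3 * codon_index
            if locus.strand == "+"
            else locus.reading_frame_origin - 3 * codon_index
        )
        codon_pos, _ = _codon_positions(locus, anchor)
        residues = []
        for g in range(self.n_total):
            bases = []
            for p in codon_pos:
                if not 1 <= p <= self.length or not self._called[g, p - 1]:
                    bases = None
                    break
                b = self.alignment[g, p - 1]
                if locus.strand == "-":
                    b = {"A": "T", "C": "G", "G": "C", "T": "A"}[b]
                bases.append(b)
            if bases is not None:
                residues.append(translate_codon("".join(bases)))
        return residues

    def aa_site_variability(
        self,
        locus: Locus,
        codon_index: int,
        statistic: Callable[[Sequence[int], int], float] = normalized_entropy,
    ) -> float:
        """Amino-acid variability of a translated codon column (alphabet: the
        20 amino acids plus stop)."""
        residues = self.residue_column(locus, codon_index)
        if len(residues) < 2:
            raise InsufficientDataError(
                f"fewer than 2 fully-called codons at index {codon_index}"
            )
        counts = pd.Series(residues).value_counts().tolist()
        return statistic(counts, AA_ALPHABET_SIZE)


def compute_cohort_stats(
    cohort: GenomeCohort,
    catalogue_frame: pd.DataFrame,
    locus_map: Optional[LocusMap] = None,
) -> pd.DataFrame:
    """Per-variant allele frequencies and per-site variability for every
    catalogue entry.

    Returns a frame keyed by (position, ref, alt) with columns ``af_total,
    af_healthy, af_pathologic, nt_var, aa_var``.  Stratum frequencies over an
    empty stratum and variability of under-covered sites are reported as NaN;
    ``aa_var`` is NaN outside CDS loci.
    """
    loci_by_name: Mapping[str, Locus] = (
        {l.name: l for l in locus_map} if locus_map is not None else {}
    )
    nt_cache: dict[int, float] = {}
    aa_cache: dict[tuple[str, int], float] = {}
    rows = []
    for pos, ref, alt, locus_name in catalogue_frame[
        ["position", "ref", "alt", "locus"]
    ].itertuples(index=False):
        def _af(stratum: str) -> float:
            try:
                return cohort.allele_frequency(pos, alt, stratum)
            except UndefinedFrequencyError:
                return float("nan")

        if pos not in nt_cache:
            try:
                nt_cache[pos] = cohort.nt_site_variability(pos)
            except InsufficientDataError:
                nt_cache[pos] = float("nan")
        aa_var = float("nan")
        locus = loci_by_name.get(locus_name)
        if locus is not None and locus.locus_type == "CDS":
            ci = (
                (pos - locus.reading_frame_origin) // 3
                if locus.strand == "+"
                else (locus.reading_frame_origin - pos) // 3
            )
            key = (locus.name, ci)
            if key not in aa_cache:
                try:
                    aa_cache[key] = cohort.aa_site_variability(locus, ci)
                except InsufficientDataError:
                    aa_cache[key] = float("nan")
            aa_var = aa_cache[key]
        rows.append(
            (pos, ref, alt, _af("all"), _af("healthy"), _af("pathologic"),
             nt_cache[pos], aa_var)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "position", "ref", "alt",
            "af_total", "af_healthy", "af_pathologic", "nt_var", "aa_var",
        ],
    )
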