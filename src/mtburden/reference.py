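"""Packaged rCRS reference: region map, genetic code and effect classification.

The human mitochondrial reference (NC_012920, 16,569 bp) ships with the
package as a plain FASTA together with a BED-like region map covering the 37
genes and the control region. Coordinates are 1-based inclusive throughout;
the control region wraps the origin and is stored as two segments (16024-16569
and 1-576) under the shared name ``D-loop``.

Effect classification translates the codon containing a substitution under the
vertebrate mitochondrial genetic code (NCBI translation table 2), reverse
complementing genes whose sense strand is the light strand.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .errors import AlphabetError, CoordinateError, ReferenceMismatchError

GENOME_LENGTH = 16569

VALID_BASES = frozenset("ACGT")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class RegionClass(str, enum.Enum):
    protein_coding = "protein_coding"
    rRNA = "rRNA"
    tRNA = "tRNA"
    control_region = "control_region"
    other_noncoding = "other_noncoding"


class Effect(str, enum.Enum):
    synonymous = "synonymous"
    non_synonymous = "non_synonymous"
    stop_gain = "stop_gain"
    noncoding = "noncoding"


#: severity used to resolve variants falling in overlapping genes
EFFECT_SEVERITY = {
    Effect.stop_gain: 3,
    Effect.non_synonymous: 2,
    Effect.synonymous: 1,
    Effect.noncoding: 0,
}

#: genes whose annotated span ends in an incomplete stop codon completed by
#: post-transcriptional polyadenylation; the trailing bases are listed as-is
#: and are never silently corrected.
INCOMPLETE_STOP_TAILS = {
    "MT-ND1": "TA",
    "MT-ND2": "T",
    "MT-CO3": "T",
    "MT-ND3": "T",
    "MT-ND4": "T",
    "MT-CYB": "T",
}


@dataclass(frozen=True)
class RegionRecord:
    """One annotated interval of the mitochondrial genome."""

    name: str
    region_class: RegionClass
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "heavy" (sense == reference plus strand) or "light"
    codon_offset: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= GENOME_LENGTH and 1 <= self.end <= GENOME_LENGTH):
            raise CoordinateError(
                f"region {self.name}: coordinates {self.start}-{self.end} "
                f"outside 1..{GENOME_LENGTH}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def _build_codon_table() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    assert len(code) == 64
    return code


#: total mapping of all 64 DNA codons to one-letter amino acids ('*' = STOP)
MITO_CODON_TO_AA: dict[str, str] = _build_codon_table()


@lru_cache(maxsize=1)
def load_sequence() -> str:
    """Return the packaged rCRS sequence as an uppercase string."""
    path = resources.files("mtburden.data") / "rcrs.fasta"
    lines = path.read_text().splitlines()
    seq = "".join(line.strip() for line in lines if not line.startswith(">"))
    if len(seq) != GENOME_LENGTH:
        raise ReferenceMismatchError(
            f"packaged rCRS has length {len(seq)}, expected {GENOME_LENGTH}"
        )
    return seq


@lru_cache(maxsize=1)
def build_region_map() -> tuple[RegionRecord, ...]:
    """Parse the packaged region map (37 genes + 2 control-region segments)."""
    path = resources.files("mtburden.data") / "regions.tsv"
    records = []
    for line in path.read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        name, rclass, start, end, strand, offset = line.split("\t")
        records.append(
            RegionRecord(
                name=name,
                region_class=RegionClass(rclass),
                start=int(start),
                end=int(end),
                strand=strand,
                codon_offset=None if offset == "." else int(offset),
            )
        )
    return tuple(records)


def ref_base(position: int) -> str:
    """Reference base at a 1-based rCRS position."""
    _check_position(position)
    return load_sequence()[position - 1]


def _check_position(position: int) -> None:
    if not isinstance(position, (int,)) or isinstance(position, bool):
        raise CoordinateError(f"position must be an integer, got {position!r}")
    if not 1 <= position <= GENOME_LENGTH:
        raise CoordinateError(
            f"position {position} outside valid range 1..{GENOME_LENGTH}"
        )


def locate(position: int, region_map: tuple[RegionRecord, ...] | None = None) -> list[RegionRecord]:
    """All regions containing ``position`` (empty for intergenic gaps).

    Overlapping gene pairs (e.g. MT-ATP8/MT-ATP6) yield one record each; the
    two control-region segments carry the same name, so a control-region
    position yields a single record.
    """
    _check_position(position)
    if region_map is None:
        region_map = build_region_map()
    return [rec for rec in region_map if rec.contains(position)]


def _codon_at(record: RegionRecord, position: int, sequence: str) -> tuple[str, int] | None:
    """Sense-strand codon containing ``position`` within ``record``.

    Returns (codon, index of the position within the codon) or None when the
    position falls in an incomplete terminal codon.
    """
    if record.strand == "heavy":
        idx = (position - record.start) - (record.codon_offset or 0)
    else:
        idx = (record.end - position) - (record.codon_offset or 0)
    codon_i, within = divmod(idx, 3)
    # genomic coordinates of the codon's three bases, sense order
    if record.strand == "heavy":
        first = record.start + (record.codon_offset or 0) + 3 * codon_i
        coords = [first, first + 1, first + 2]
        if coords[-1] > record.end:
            return None  # incomplete terminal codon
        codon = "".join(sequence[c - 1] for c in coords)
    else:
        first = record.end - (record.codon_offset or 0) - 3 * codon_i
        coords = [first, first - 1, first - 2]
        if coords[-1] < record.start:
            return None
        codon = "".join(_COMPLEMENT[sequence[c - 1]] for c in coords)
    return codon, within


def classify_effect(
    position: int,
    ref_base_: str,
    alt_base: str,
    region_map: tuple[RegionRecord, ...] | None = None,
    sequence: str | None = None,
) -> Effect:
    """Classify a substitution as synonymous / non_synonymous / stop_gain / noncoding.

    For positions inside protein-coding genes the containing codon is
    translated before and after the substitution (strand-aware). A position in
    two overlapping genes takes the most severe effect. Raises
    :class:`ReferenceMismatchError` when ``ref_base_`` disagrees with the
    packaged rCRS.
    """
    _check_position(position)
    ref_base_ = ref_base_.upper()
    alt_base = alt_base.upper()
    for base in (ref_base_, alt_base):
        if base not in VALID_BASES:
            raise AlphabetError(f"invalid base {base!r}; expected one of A,C,G,T")
    if sequence is None:
        sequence = load_sequence()
    if sequence[position - 1] != ref_base_:
        raise ReferenceMismatchError(
            f"ref base {ref_base_} at position {position} does not match "
            f"packaged rCRS base {sequence[position - 1]}"
        )

    best = Effect.noncoding
    for record in locate(position, region_map):
        if record.region_class is not RegionClass.protein_coding:
            continue
        located = _codon_at(record, position, sequence)
        if located is None:
            continue  # incomplete terminal codon: no complete codon exists
        codon, within = located
        if record.strand == "heavy":
            alt_codon = codon[:within] + alt_base + codon[within + 1:]
        else:
            alt_codon = codon[:within] + _COMPLEMENT[alt_base] + codon[within + 1:]
        aa_before = MITO_CODON_TO_AA[codon]
        aa_after = MITO_CODON_TO_AA[alt_codon]
        if aa_after == "*" and aa_before != "*":
            effect = Effect.stop_gain
        elif aa_before == aa_after:
            effect = Effect.synonymous
        else:
            effect = Effect.non_synonymous
        if EFFECT_SEVERITY[effect] > EFFECT_SEVERITY[best]:
            best = effect
    return best


def translate_gene(record: RegionRecord, sequence: str | None = None) -> str:
    """Translate a protein-coding record (whole codons only) — used for sanity checks."""
    if sequence is None:
        sequence = load_sequence()
    seq = sequence[record.start - 1: record.end]
    if record.strand == "light":
        seq = str(Seq(seq).reverse_complement())
    seq = seq[(record.codon_offset or 0):]
    n_codons = len(seq) // 3
    return "".join(MITO_CODON_TO_AA[seq[3 * i: 3 * i + 3]] for i in range(n_codons))


def class_position_sets(
    region_map: tuple[RegionRecord, ...] | None = None,
) -> dict[str, frozenset[int]]:
    """Distinct genome positions per region class.

    ``other_noncoding`` is the set of positions not covered by any record
    (intergenic spacers, including the light-strand replication origin).
    """
    if region_map is None:
        region_map = build_region_map()
    out: dict[str, set[int]] = {c.value: set() for c in RegionClass}
    covered: set[int] = set()
    for rec in region_map:
        pos = set(range(rec.start, rec.end + 1))
        out[rec.region_class.value] |= pos
        covered |= pos
    out["other_noncoding"] = set(range(1, GENOME_LENGTH + 1)) - covered
    return {k: frozenset(v) for k, v in out.items()}
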