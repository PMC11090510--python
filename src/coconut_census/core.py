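"""Shared domain types and coordinate conventions.

Internal coordinates are 0-based half-open throughout the package; GFF3 I/O
and the domain-hit tables use the field-standard 1-based inclusive
convention. Strand is stored per gene and all "same direction" logic uses
the strand symbol, never coordinate order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_PROTEIN_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")


class Strand(str, Enum):
    FORWARD = "+"
    REVERSE = "-"


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding feature on a contig.

    ``start``/``end`` are nucleotide coordinates, 0-based half-open.
    ``protein_length`` is in amino acids and must be >= 1 whenever a
    protein_id is attached.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_id: Optional[str] = None
    protein_length: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if self.protein_id is not None and self.protein_length < 1:
            raise ValueError(
                f"gene {self.gene_id}: protein_length must be >= 1 when a "
                "protein_id is present"
            )

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def to_external_coords(g: GeneRecord) -> tuple[int, int]:
    """Internal 0-based half-open -> external (GFF3) 1-based inclusive."""
    return g.start + 1, g.end


def from_external_coords(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """External (GFF3) 1-based inclusive -> internal 0-based half-open."""
    return start_1based - 1, end_inclusive


def intergenic_gap(a: GeneRecord, b: GeneRecord) -> int:
    """Nucleotides between two genes regardless of strand.

    Overlapping reading frames — a tight-linkage signal in real operons —
    yield a gap <= 0 and therefore satisfy any non-negative distance
    threshold.
    """
    left, right = (a, b) if a.start <= b.start else (b, a)
    return right.start - left.end


@dataclass
class Contig:
    """An ordered gene table for one replicon (no nucleotide sequence)."""

    contig_id: str
    genes: list[GeneRecord]
    length: int

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        for g in self.genes:
            if g.contig_id != self.contig_id:
                raise ValueError(
                    f"gene {g.gene_id} belongs to contig {g.contig_id}, "
                    f"not {self.contig_id}"
                )
            if g.end > self.length:
                raise ValueError(
                    f"gene {g.gene_id} [{g.start}, {g.end}) exceeds contig "
                    f"length {self.length}"
                )


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        if not _PROTEIN_RE.match(self.sequence):
            raise ValueError(
                f"protein {self.protein_id}: sequence must be uppercase "
                "20-letter amino-acid alphabet plus X"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class HitSource(str, Enum):
    PROFILE = "profile"
    MOTIF = "motif"
    COILED_COIL = "coiled_coil"


@dataclass(frozen=True)
class DomainHit:
    """An annotated domain or motif occurrence on a protein.

    ``start_aa``/``end_aa`` are 0-based half-open amino-acid coordinates.
    """

    protein_id: str
    domain_name: str
    start_aa: int
    end_aa: int
    evalue: Optional[float] = None
    source: HitSource = HitSource.PROFILE

    def __post_init__(self) -> None:
        if not (0 <= self.start_aa < self.end_aa):
            raise ValueError(
                f"hit {self.domain_name} on {self.protein_id}: require "
                f"0 <= start_aa < end_aa, got [{self.start_aa}, {self.end_aa})"
            )
        if self.evalue is not None and self.evalue < 0:
            raise ValueError(
                f"hit {self.domain_name} on {self.protein_id}: negative E-value"
            )


class MotifVariant(str, Enum):
    NXD = "NxD"
    NXXD = "NxxD"
    NXXXD = "NxxxD"
    NONE = "none"


@dataclass(frozen=True)
class SignatureMotif:
    """The McrB GTPase Nx(xx)D signature motif.

    ``position_aa`` indexes the N residue in whole-protein coordinates.
    ``follower`` is the residue immediately after the motif's aspartate —
    in the NxD clade usually, but not invariably, E or a second D.
    ``gap_from_walker_b`` is the spacing (aa) from the end of Walker B to
    the N; large spacings flag the Type I-A helical insert.
    """

    variant: MotifVariant
    position_aa: Optional[int] = None
    follower: Optional[str] = None
    gap_from_walker_b: Optional[int] = None
    diagnostic: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.variant is MotifVariant.NONE) != (self.position_aa is None):
            raise ValueError("variant=none <=> position_aa absent")


class ValidationTier(str, Enum):
    STRICT = "strict"
    RELAXED_ONE_ALIAS = "relaxed_one_alias"
    RESCUED_NO_ALIAS = "rescued_no_alias"
    ORPHAN_MANUAL = "orphan_manual"


@dataclass
class CandidateSystem:
    """A paired (or orphan) McrB/McrC locus with a validation tier."""

    mcrB_gene: Optional[GeneRecord]
    mcrC_gene: Optional[GeneRecord]
    intervening_gene_count: int
    order_reversed: bool
    tier: ValidationTier
    signature: SignatureMotif = field(
        default_factory=lambda: SignatureMotif(MotifVariant.NONE)
    )
    fused: bool = False
    contig_id: str = ""
    locus_id: str = ""

    def __post_init__(self) -> None:
        if self.mcrB_gene is None and self.mcrC_gene is None:
            raise ValueError("at least one of mcrB_gene/mcrC_gene must be present")
        if (self.mcrB_gene is None or self.mcrC_gene is None) and (
            self.intervening_gene_count != 0
        ):
            raise ValueError("intervening_gene_count must be 0 when a gene is absent")
        if not self.contig_id:
            anchor = self.mcrB_gene or self.mcrC_gene
            self.contig_id = anchor.contig_id
        if not self.locus_id:
            b = self.mcrB_gene.gene_id if self.mcrB_gene else "-"
            c = self.mcrC_gene.gene_id if self.mcrC_gene else "-"
            self.locus_id = f"{self.contig_id}:{b}|{c}"

    @property
    def genes(self) -> list[GeneRecord]:
        return [g for g in (self.mcrB_gene, self.mcrC_gene) if g is not None]
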