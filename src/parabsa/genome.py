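"""Genomic coordinate system, gene models, and marker/SNP definitions.

All coordinates are 1-based and fully closed, matching GFF3. SNP ref/alt
alleles are always given on the forward genomic strand; coding-effect logic
complements them for reverse-strand genes (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq

__all__ = [
    "Chromosome",
    "KaryotypeMap",
    "GeneModel",
    "MarkerDef",
    "SnpDef",
    "CoordinateError",
    "ModelError",
    "NoncodingPositionError",
    "extract_cds",
    "codon_lookup",
]

VALID_BASES = frozenset("ACGT")

PHENOTYPE_CHANNELS = frozenset(
    {
        "spore_color",
        "uridine_requirement",
        "arginine_requirement",
        "acidification",
        "protease",
        "hygromycin_resistance",
    }
)


class CoordinateError(ValueError):
    """A genomic coordinate falls outside its chromosome or feature bounds."""


class ModelError(ValueError):
    """A gene/karyotype model violates a structural invariant."""


class NoncodingPositionError(ValueError):
    """A position queried for codon context lies outside every CDS interval."""


@dataclass(frozen=True)
class Chromosome:
    chrom_id: str
    length_bp: int
    centromere_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ModelError(f"{self.chrom_id}: length_bp must be positive")
        if self.centromere_pos is not None and not (
            1 <= self.centromere_pos <= self.length_bp
        ):
            raise ModelError(
                f"{self.chrom_id}: centromere_pos {self.centromere_pos} outside "
                f"[1, {self.length_bp}]"
            )


@dataclass(frozen=True)
class KaryotypeMap:
    """Ordered set of chromosomes defining the coordinate system of a cross."""

    chromosomes: Tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        ids = [c.chrom_id for c in self.chromosomes]
        if len(ids) != len(set(ids)):
            raise ModelError("duplicate chrom_ids in karyotype")

    @property
    def chrom_ids(self) -> Tuple[str, ...]:
        return tuple(c.chrom_id for c in self.chromosomes)

    def length_of(self, chrom_id: str) -> int:
        for c in self.chromosomes:
            if c.chrom_id == chrom_id:
                return c.length_bp
        raise KeyError(chrom_id)

    def __contains__(self, chrom_id: str) -> bool:
        return chrom_id in self.chrom_ids

    def chrom_index(self, chrom_id: str) -> int:
        return self.chrom_ids.index(chrom_id)


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene as an ordered set of CDS intervals.

    ``cds_intervals`` are 1-based inclusive (start, end) pairs in genomic
    order regardless of strand; for reverse-strand genes the spliced CDS is
    the reverse complement of their concatenation.
    """

    gene_id: str
    chrom_id: str
    strand: str  # "+" or "-"
    cds_intervals: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.cds_intervals:
            raise ModelError(f"{self.gene_id}: no CDS intervals")
        prev_end = 0
        for start, end in self.cds_intervals:
            if start < 1 or end < start:
                raise ModelError(f"{self.gene_id}: bad interval ({start}, {end})")
            if start <= prev_end:
                raise ModelError(f"{self.gene_id}: intervals overlap or unsorted")
            prev_end = end
        if self.cds_length % 3 != 0:
            raise ModelError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_intervals)

    @property
    def span(self) -> Tuple[int, int]:
        """Genomic extent of the gene (first CDS start to last CDS end)."""
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi

    def in_cds(self, pos: int) -> bool:
        return any(start <= pos <= end for start, end in self.cds_intervals)


@dataclass(frozen=True)
class MarkerDef:
    """A classical phenotype marker locus (e.g. a spore-color gene)."""

    marker_id: str
    chrom_id: str
    pos: int
    wild_allele: str
    mutant_allele: str
    phenotype_channel: str
    epistasis_rank: int = 1  # lower = epistatically dominant within channel

    def __post_init__(self) -> None:
        if self.phenotype_channel not in PHENOTYPE_CHANNELS:
            raise ModelError(
                f"{self.marker_id}: unknown phenotype_channel "
                f"{self.phenotype_channel!r}"
            )


@dataclass(frozen=True)
class SnpDef:
    """A single-nucleotide difference between the two parental strains."""

    snp_id: str
    chrom_id: str
    pos: int
    ref_base: str
    alt_base: str
    origin_parent: str  # "A" or "B": which parent carries the alt allele

    def __post_init__(self) -> None:
        if self.ref_base not in VALID_BASES or self.alt_base not in VALID_BASES:
            raise ModelError(f"{self.snp_id}: bases must be A/C/G/T")
        if self.ref_base == self.alt_base:
            raise ModelError(f"{self.snp_id}: ref_base equals alt_base")
        if self.origin_parent not in ("A", "B"):
            raise ModelError(f"{self.snp_id}: origin_parent must be 'A' or 'B'")


def validate_markers(markers: Sequence[MarkerDef]) -> None:
    """Enforce marker-set invariants: unique positions, unique epistasis ranks."""
    seen_pos = set()
    seen_rank = set()
    for m in markers:
        key = (m.chrom_id, m.pos)
        if key in seen_pos:
            raise ModelError(f"two markers at {key}")
        seen_pos.add(key)
        rkey = (m.phenotype_channel, m.epistasis_rank)
        if rkey in seen_rank:
            raise ModelError(f"duplicate epistasis_rank in channel {rkey}")
        seen_rank.add(rkey)


def extract_cds(gene: GeneModel, genome_sequence: Mapping[str, str]) -> str:
    """Splice the coding sequence of *gene* out of the genome.

    Returns the strand-oriented CDS (reverse-complemented for '-' genes).
    """
    try:
        chrom_seq = genome_sequence[gene.chrom_id]
    except KeyError as exc:
        raise CoordinateError(f"{gene.gene_id}: chromosome {gene.chrom_id} absent") from exc
    parts = []
    for start, end in gene.cds_intervals:
        if end > len(chrom_seq):
            raise CoordinateError(
                f"{gene.gene_id}: interval ({start}, {end}) beyond chromosome "
                f"end {len(chrom_seq)}"
            )
        parts.append(chrom_seq[start - 1 : end])
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def codon_lookup(gene: GeneModel, genomic_pos: int) -> Tuple[int, int]:
    """Map a genomic position inside the CDS to (codon_index, offset_in_codon).

    Both returned values are 1-based; offset_in_codon is 1, 2 or 3 within
    the strand-oriented codon.
    """
    fwd_offset = 0  # 1-based offset within the forward-spliced CDS
    consumed = 0
    for start, end in gene.cds_intervals:
        if start <= genomic_pos <= end:
            fwd_offset = consumed + (genomic_pos - start + 1)
            break
        consumed += end - start + 1
    else:
        raise NoncodingPositionError(
            f"{gene.gene_id}: position {genomic_pos} not in CDS"
        )
    if gene.strand == "+":
        cds_offset = fwd_offset
    else:
        cds_offset = gene.cds_length - fwd_offset + 1
    codon_index = (cds_offset + 2) // 3
    offset_in_codon = cds_offset - 3 * (codon_index - 1)
    return codon_index, offset_in_codon
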