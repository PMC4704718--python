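"""Variant validation, pool conservation scan, coding-effect annotation.

The bulk-segregant logic: the causal variant of a recessive trait is
carried by every trait-positive segregant (fully conserved in the pool),
physically linked variants are conserved in all but the rare mitotic
recombinants, and unlinked variants sit near 50%. The scan therefore
orients every SNP to the mutagenized (trait) parent's allele and classifies
its pool conservation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .cross import HaploidGenotype
from .genome import GeneModel, SnpDef, codon_lookup, extract_cds
from .poolseq import SampleCalls

logger = logging.getLogger(__name__)

__all__ = [
    "SNPFilterParams",
    "ParentalSNPSet",
    "ConservationRecord",
    "CodingEffect",
    "ReferenceMismatchError",
    "validate_variants",
    "derive_parental_snpset",
    "scan_pool_conservation",
    "classify_conservation",
    "annotate_coding_effect",
    "rank_candidates",
]


class ReferenceMismatchError(ValueError):
    """A SNP's declared ref base disagrees with the genome sequence."""


@dataclass(frozen=True)
class SNPFilterParams:
    """Variant-validation thresholds.

    A variant is validated in a sample when its allele frequency is at
    least min_freq in at least min_depth overlapping reads, with no
    quality-based filtering. pool_min_freq is the reporting floor for pool
    variants.
    """

    min_freq: float = 0.7
    min_depth: int = 20
    pool_min_freq: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.min_freq <= 1.0:
            raise ValueError("min_freq must lie in (0, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 < self.pool_min_freq <= 1.0:
            raise ValueError("pool_min_freq must lie in (0, 1]")


@dataclass(frozen=True)
class ParentalSNPSet:
    """Inter-parental SNPs, each validated as alt in exactly one parent."""

    snps: Tuple[SnpDef, ...]
    shared_sites: Tuple[str, ...] = ()  # alt-validated in both parents, excluded

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)


@dataclass
class ConservationRecord:
    """Per-SNP pool conservation, oriented to the trait-parent allele."""

    snp_id: str
    chrom_id: str
    pos: int
    origin_parent: str
    pool_depth: int
    read_frequency: Optional[float]  # trait-parent allele fraction in reads
    genotype_conservation: Optional[float] = None  # truth, when genotypes known
    conservation_class: Optional[str] = None
    below_threshold: bool = False
    binom_pvalue: Optional[float] = None  # auxiliary: deviation from 0.5

    @property
    def conservation(self) -> Optional[float]:
        """Best available conservation estimate (genotype truth preferred)."""
        if self.genotype_conservation is not None:
            return self.genotype_conservation
        return self.read_frequency


@dataclass(frozen=True)
class CodingEffect:
    gene_id: Optional[str]
    codon_index: Optional[int]
    ref_codon: Optional[str]
    alt_codon: Optional[str]
    ref_aa: Optional[str]
    alt_aa: Optional[str]
    consequence: str  # missense | synonymous | nonsense | intronic | noncoding

    def __post_init__(self) -> None:
        if self.ref_codon is not None and self.alt_codon is not None:
            diff = sum(a != b for a, b in zip(self.ref_codon, self.alt_codon))
            if diff != 1:
                raise ValueError("ref/alt codons must differ at exactly one base")


def validate_variants(calls: SampleCalls, params: SNPFilterParams) -> Set[str]:
    """Return the site ids whose variant passes the frequency/depth filter.

    A site is validated iff depth >= min_depth and alt_count/depth >=
    min_freq. Zero-depth sites are never validated and are counted in a
    skip log.
    """
    validated: Set[str] = set()
    skipped = 0
    for row in calls.table.itertuples(index=False):
        if row.depth == 0:
            skipped += 1
            continue
        if row.depth >= params.min_depth and row.alt_count / row.depth >= params.min_freq:
            validated.add(row.snp_id)
    if skipped:
        logger.info("%s: skipped %d zero-depth sites", calls.sample_id, skipped)
    return validated


def derive_parental_snpset(
    calls_A: SampleCalls, calls_B: SampleCalls, params: SNPFilterParams
) -> ParentalSNPSet:
    """Inter-parental SNPs: sites validated as alt in exactly one parent.

    Sites alt-validated in both parents are shared variants relative to the
    reference, not differences between the parents; they are excluded and
    logged.
    """
    ids_A = set(calls_A.snp_ids)
    ids_B = set(calls_B.snp_ids)
    if ids_A != ids_B:
        raise ValueError("parent call tables cover different site universes")
    val_A = validate_variants(calls_A, params)
    val_B = validate_variants(calls_B, params)
    shared = sorted(val_A & val_B)
    if shared:
        logger.info("excluded %d shared variants: %s", len(shared), shared)
    snps: List[SnpDef] = []
    for row in calls_A.table.itertuples(index=False):
        sid = row.snp_id
        in_A, in_B = sid in val_A, sid in val_B
        if in_A == in_B:
            continue
        snps.append(
            SnpDef(
                snp_id=sid,
                chrom_id=row.chrom,
                pos=int(row.pos),
                ref_base=row.ref,
                alt_base=row.alt,
                origin_parent="A" if in_A else "B",
            )
        )
    return ParentalSNPSet(snps=tuple(snps), shared_sites=tuple(shared))


def scan_pool_conservation(
    snpset: ParentalSNPSet,
    pool_calls: SampleCalls,
    pool_genotypes: Optional[Sequence[HaploidGenotype]] = None,
    params: SNPFilterParams = SNPFilterParams(),
    trait_parent: str = "A",
    full_threshold: float = 0.995,
    high_threshold: float = 0.95,
) -> List[ConservationRecord]:
    """Scan the pool for conservation of the trait parent's alleles.

    read_frequency is the pool read fraction of the trait parent's allele:
    the alt fraction for SNPs originating in the trait parent, 1 - alt
    fraction for SNPs originating in the other parent. When pool member
    genotypes are supplied the exact genotype-level conservation is also
    computed and preferred for classification.
    """
    records: List[ConservationRecord] = []
    for snp in snpset:
        depth = pool_calls.depth(snp.snp_id)
        if depth == 0:
            rec = ConservationRecord(
                snp_id=snp.snp_id,
                chrom_id=snp.chrom_id,
                pos=snp.pos,
                origin_parent=snp.origin_parent,
                pool_depth=0,
                read_frequency=None,
                below_threshold=True,
            )
        else:
            alt_count = pool_calls.alt_count(snp.snp_id)
            alt_freq = alt_count / depth
            freq = alt_freq if snp.origin_parent == trait_parent else 1.0 - alt_freq
            rec = ConservationRecord(
                snp_id=snp.snp_id,
                chrom_id=snp.chrom_id,
                pos=snp.pos,
                origin_parent=snp.origin_parent,
                pool_depth=depth,
                read_frequency=freq,
                below_threshold=freq < params.pool_min_freq,
                binom_pvalue=float(
                    stats.binomtest(alt_count, depth, 0.5).pvalue
                ),
            )
        if pool_genotypes is not None:
            n = len(pool_genotypes)
            carriers = sum(
                1
                for g in pool_genotypes
                if (g.snp_alleles[snp.snp_id] == "alt")
                == (snp.origin_parent == trait_parent)
            )
            rec.genotype_conservation = carriers / n
        if rec.conservation is not None:
            rec.conservation_class = classify_conservation(
                rec, full_threshold=full_threshold, high_threshold=high_threshold
            )
        records.append(rec)
    return records


def classify_conservation(
    record: ConservationRecord,
    full_threshold: float = 0.995,
    high_threshold: float = 0.95,
) -> str:
    """Classify pool conservation: fully_conserved / high / unlinked.

    Defaults place 78/78 (1.0) in fully_conserved and 77/78 (0.987) in
    high, the two linkage classes observable in a 78-member pool with a
    single recombinant.
    """
    conservation = record.conservation
    if conservation is None:
        raise ValueError(f"{record.snp_id}: no conservation estimate available")
    if conservation >= full_threshold:
        return "fully_conserved"
    if conservation >= high_threshold:
        return "high"
    return "unlinked"


_STOP = "*"


def annotate_coding_effect(
    snp: SnpDef,
    genes: Sequence[GeneModel],
    genome_sequence: Mapping[str, str],
) -> CodingEffect:
    """Annotate a SNP's effect on the overlapping gene model, if any.

    Consequence is "noncoding" outside every gene, "intronic" inside a
    gene's span but outside its CDS, otherwise the codon substitution is
    computed on the strand-oriented CDS and translated with the standard
    genetic code.
    """
    chrom_seq = genome_sequence[snp.chrom_id]
    genome_base = chrom_seq[snp.pos - 1]
    if genome_base != snp.ref_base:
        raise ReferenceMismatchError(
            f"{snp.snp_id}: genome has {genome_base} at {snp.chrom_id}:{snp.pos}, "
            f"ref_base is {snp.ref_base}"
        )
    host = None
    for gene in genes:
        if gene.chrom_id == snp.chrom_id and gene.contains(snp.pos):
            host = gene
            if gene.in_cds(snp.pos):
                break
    if host is None:
        return CodingEffect(None, None, None, None, None, None, "noncoding")
    if not host.in_cds(snp.pos):
        return CodingEffect(host.gene_id, None, None, None, None, None, "intronic")
    codon_index, offset = codon_lookup(host, snp.pos)
    cds = extract_cds(host, genome_sequence)
    ref_codon = cds[3 * (codon_index - 1) : 3 * codon_index]
    alt_base = snp.alt_base
    if host.strand == "-":
        alt_base = str(Seq(alt_base).complement())
    alt_codon = ref_codon[: offset - 1] + alt_base + ref_codon[offset:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        consequence = "synonymous"
    elif alt_aa == _STOP:
        consequence = "nonsense"
    else:
        consequence = "missense"
    return CodingEffect(
        gene_id=host.gene_id,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
    )


_CLASS_ORDER = {"fully_conserved": 0, "high": 1, "unlinked": 2, None: 3}
# Candidate triage: protein-changing effects first, then intronic (possible
# splicing effects), then silent/intergenic changes.
_CONSEQUENCE_ORDER = {
    "missense": 0,
    "nonsense": 0,
    "intronic": 1,
    "synonymous": 2,
    "noncoding": 2,
}


def rank_candidates(
    records: Sequence[ConservationRecord],
    effects: Mapping[str, CodingEffect],
) -> List[ConservationRecord]:
    """Order SNPs by causal plausibility.

    fully_conserved before high before unlinked; within a class,
    protein-changing before intronic before noncoding; ties broken by
    descending conservation then by (chrom, pos).
    """

    def key(rec: ConservationRecord):
        effect = effects.get(rec.snp_id)
        consequence = effect.consequence if effect is not None else "noncoding"
        conservation = rec.conservation
        return (
            _CLASS_ORDER.get(rec.conservation_class, 3),
            _CONSEQUENCE_ORDER.get(consequence, 2),
            -(conservation if conservation is not None else -1.0),
            rec.chrom_id,
            rec.pos,
        )

    return sorted(records, key=key)
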