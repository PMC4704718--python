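"""Deterministic reconstruction of the mapped cross as a synthetic fixture.

Rebuilds, from a seed, the study conditions of a classical nonacidifying
mutant mapped by parasexual bulk-segregant analysis: two complementary-
marked parents differing at 52 SNPs over 8 chromosomes, a diploid, 140
haploid segregants whose marker marginals match the published distribution,
a 78-member trait-positive pool containing exactly one mitotic recombinant
on the causal chromosome, and simulated per-site sequencing of parents and
pool. The genome, gene models and segregants are synthetic: coordinates and
counts follow the study, sequence elsewhere is random but seeded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cross import (
    DiploidGenotype,
    HaploidGenotype,
    Recombinant,
    Segregant,
    assemble_segregant,
    derive_phenotypes,
    form_diploid,
    nonacidifying,
    select_pool,
    _locus_positions,
)
from .genome import Chromosome, GeneModel, KaryotypeMap, MarkerDef, SnpDef
from .linkage import GenotypeTable
from .poolseq import CoverageModel, PoolSpec, SampleCalls, simulate_sample_calls

__all__ = [
    "StudyConfig",
    "Reference",
    "ConstructionError",
    "build_reference",
    "build_parents",
    "build_segregants",
    "build_pool",
    "write_fixture",
    "MARKER_IDS",
]

MARKER_IDS = ("fwnA", "olvA", "pyrG", "argB", "nac", "prtT")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConstructionError(ValueError):
    """The configured constraint set cannot be satisfied."""


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the reconstructed cross.

    Defaults encode the study conditions: 140 segregants, a 78-member
    nonacidifying pool, 52 inter-parental SNPs with the causal G-to-C change
    at chromosome II position 1762101, two fawn/olive double mutants, one
    mitotic recombinant inside the pool, and the published marker marginals
    (64 fawn, 78 pyrG+, 64 argB+, 78 nonacidifying, 72 protease-low).
    """

    rng_seed: int = 0
    n_segregants: int = 140
    pool_size: int = 78
    n_parental_snps: int = 52
    n_double_mutants: int = 2
    n_pool_recombinants: int = 1
    causal_chrom: str = "II"
    causal_pos: int = 1762101
    # marker marginals among the segregants (parent-A-type allele counts)
    n_fawn: int = 64
    n_argB_proto: int = 64
    n_prtT_mutant: int = 72
    # sequencing defaults
    strain_depth: float = 100.0
    pool_depth: float = 300.0
    error_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.pool_size > self.n_segregants:
            raise ConstructionError("pool_size exceeds n_segregants")
        if self.n_pool_recombinants > self.pool_size:
            raise ConstructionError("more pool recombinants than pool members")
        if self.n_double_mutants > self.n_fawn:
            raise ConstructionError("more double mutants than fawn segregants")
        n_r2 = self.n_argB_proto - (self.n_fawn - self.n_double_mutants)
        if n_r2 < 0:
            raise ConstructionError(
                "argB+ marginal infeasible given fawn count and double mutants"
            )
        if (self.n_fawn - self.n_double_mutants) + self.n_double_mutants + n_r2 > self.n_segregants:
            raise ConstructionError("chromosome I class sizes exceed n_segregants")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.rng_seed, stream])


# Chromosome I geometry: fwnA and olvA on opposite arms of the centromere,
# argB distal to olvA. Crossover breakpoints used by the constrained classes.
_CHR1_BP_FWN_OLV = 650_000  # between fwnA (200 kb) and olvA (800 kb)
_CHR1_BP_OLV_ARG = 950_000  # between olvA (800 kb) and argB (1050 kb)
_CHR2_POOL_BP = 1_900_000  # between the causal site and the distal linked SNPs

# Linked-SNP window on chromosome II: three conserved sites (one intronic in
# the toy fumR gene, one intergenic, the causal missense) plus three sites
# distal to the single pool recombinant's breakpoint. Span ~1.5 Mb.
_CHR2_SNP_POS = (1_100_100, 1_400_000, 1762101, 2_100_000, 2_350_000, 2_600_000)

_LAEA_CDS = (1_761_123, 1_762_250)  # codon 327 starts at 1762101
_FUMR_CDS = ((1_099_000, 1_099_899), (1_100_300, 1_101_100))
_PRTT_CDS = (100_002, 101_201)
_PRTT_SNP_POS = 100_300  # middle base of codon 100 (CTA -> CCA)


@dataclass
class Reference:
    karyotype: KaryotypeMap
    genome: Dict[str, str]
    genes: List[GeneModel]
    markers: List[MarkerDef]
    snps: List[SnpDef]

    @property
    def causal_snp(self) -> SnpDef:
        return next(s for s in self.snps if s.snp_id == "snp_II_1762101")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def build_reference(config: StudyConfig) -> Reference:
    """Toy genome, gene models, markers and parental SNP definitions.

    The toy laeA gene carries GCC at codon 327 with its first base at the
    causal coordinate; the toy prtT gene carries a CTA codon whose middle
    base is the protease-regulator point mutation; a two-exon toy fumR gene
    hosts an intronic SNP. Sequence elsewhere is seeded random.
    """
    karyotype = KaryotypeMap(
        chromosomes=(
            Chromosome("I", 1_200_000, centromere_pos=500_000),
            Chromosome("II", 3_000_000),
            Chromosome("III", 300_000),
            Chromosome("IV", 300_000),
            Chromosome("V", 300_000),
            Chromosome("VI", 300_000),
            Chromosome("VII", 300_000),
            Chromosome("VIII", 300_000),
        )
    )
    rng = config._rng(0)
    seqs: Dict[str, np.ndarray] = {
        c.chrom_id: _random_sequence(rng, c.length_bp) for c in karyotype.chromosomes
    }
    # anchor codons: Ala327 (GCC) in laeA, Leu100 (CTA) in prtT
    seqs["II"][config.causal_pos - 1 : config.causal_pos + 2] = np.frombuffer(
        b"GCC", dtype="S1"
    )
    seqs["VI"][_PRTT_SNP_POS - 2 : _PRTT_SNP_POS + 1] = np.frombuffer(b"CTA", dtype="S1")
    genome = {c: arr.tobytes().decode() for c, arr in seqs.items()}

    genes = [
        GeneModel("laeA", "II", "+", (( _LAEA_CDS[0], _LAEA_CDS[1]),)),
        GeneModel("fumR", "II", "+", _FUMR_CDS),
        GeneModel("prtT", "VI", "+", ((_PRTT_CDS[0], _PRTT_CDS[1]),)),
    ]

    markers = [
        MarkerDef("fwnA", "I", 200_000, "fwnA+", "fwnA::hygB", "spore_color", 1),
        MarkerDef("olvA", "I", 800_000, "olvA+", "olvA::pyrG", "spore_color", 2),
        MarkerDef("argB", "I", 1_050_000, "argB+", "argB::hygB", "arginine_requirement", 1),
        MarkerDef("nac", "II", config.causal_pos, "laeA+", "laeA-A327P", "acidification", 1),
        MarkerDef("prtT", "VI", _PRTT_SNP_POS, "prtT+", "prtT-13", "protease", 1),
    ]

    snp_rng = config._rng(1)
    snps: List[SnpDef] = []

    def add_snp(chrom: str, pos: int, origin: str, alt: Optional[str] = None) -> None:
        ref = genome[chrom][pos - 1]
        if alt is None:
            choices = [b for b in "ACGT" if b != ref]
            alt = choices[int(snp_rng.integers(0, 3))]
        snps.append(SnpDef(f"snp_{chrom}_{pos}", chrom, pos, ref, alt, origin))

    # chromosome II: the six linked SNPs, all from the mutagenized parent
    for pos in _CHR2_SNP_POS:
        add_snp("II", pos, "A", alt="C" if pos == config.causal_pos else None)
    # the protease-regulator point mutation (T to C), also parent A
    add_snp("VI", _PRTT_SNP_POS, "A", alt="C")
    # remaining unlinked background SNPs spread over the other chromosomes
    n_rest = config.n_parental_snps - len(snps)
    other_chroms = [c for c in karyotype.chrom_ids if c != "II"]
    per_chrom = {c: n_rest // len(other_chroms) for c in other_chroms}
    for c in other_chroms[: n_rest % len(other_chroms)]:
        per_chrom[c] += 1
    origin_cycle = ["B", "A"]
    i = 0
    occupied = {("VI", _PRTT_SNP_POS)}
    for chrom in other_chroms:
        length = karyotype.length_of(chrom)
        k = per_chrom[chrom]
        for j in range(k):
            pos = int(round(length * (j + 1) / (k + 1)))
            while (chrom, pos) in occupied:
                pos += 1
            occupied.add((chrom, pos))
            add_snp(chrom, pos, origin_cycle[i % 2])
            i += 1
    if len(snps) != config.n_parental_snps:
        raise ConstructionError(
            f"built {len(snps)} SNPs, expected {config.n_parental_snps}"
        )
    return Reference(karyotype=karyotype, genome=genome, genes=genes,
                     markers=markers, snps=snps)


def build_parents(
    config: StudyConfig, reference: Reference
) -> Tuple[HaploidGenotype, HaploidGenotype]:
    """The two parental haploids.

    Parent A is the mutagenized, nonacidifying, protease-low, fawn strain
    (it carries the alt allele at every origin-A SNP including the causal
    site); parent B is the olive, arginine-auxotrophic partner whose olvA
    disruption carries a functional pyrG copy.
    """
    markers_A = {
        "fwnA": "mutant",
        "olvA": "wild",
        "argB": "wild",
        "nac": "mutant",
        "prtT": "mutant",
    }
    markers_B = {
        "fwnA": "wild",
        "olvA": "mutant",
        "argB": "mutant",
        "nac": "wild",
        "prtT": "wild",
    }
    snps_A = {
        s.snp_id: "alt" if s.origin_parent == "A" else "ref" for s in reference.snps
    }
    snps_B = {
        s.snp_id: "alt" if s.origin_parent == "B" else "ref" for s in reference.snps
    }
    parent_A = HaploidGenotype("MA273.1", markers_A, snps_A)
    parent_B = HaploidGenotype("JN3.2", markers_B, snps_B)
    return parent_A, parent_B


def _chromosome_origin_vectors(
    config: StudyConfig, rng: np.random.Generator
) -> Dict[str, List]:
    """Per-chromosome origin assignments honouring the marginal constraints.

    Constrained cells (chromosomes I, II, VI) are built deterministically
    from the configured counts; the assignment of classes to segregants and
    the free chromosomes are seeded random, consistent with independent
    whole-chromosome assortment.
    """
    n = config.n_segregants
    d = config.n_double_mutants
    pure_fawn = config.n_fawn - d
    n_r2 = config.n_argB_proto - pure_fawn
    pure_olive = n - pure_fawn - d - n_r2
    if pure_olive < 0:
        raise ConstructionError("chromosome I marginals infeasible")
    chr1 = (
        ["A"] * pure_fawn
        + ["B"] * pure_olive
        + [Recombinant(_CHR1_BP_FWN_OLV, "A")] * d  # fawn, olvA::pyrG, argB-
        + [Recombinant(_CHR1_BP_OLV_ARG, "B")] * n_r2  # olive, argB+
    )
    chr2 = (
        ["A"] * (config.pool_size - config.n_pool_recombinants)
        + [Recombinant(_CHR2_POOL_BP, "A")] * config.n_pool_recombinants
        + ["B"] * (n - config.pool_size)
    )
    chr6 = ["A"] * config.n_prtT_mutant + ["B"] * (n - config.n_prtT_mutant)
    vectors: Dict[str, List] = {"I": chr1, "II": chr2, "VI": chr6}
    for chrom in ("III", "IV", "V", "VII", "VIII"):
        vectors[chrom] = ["A" if x < 0.5 else "B" for x in rng.random(n)]
    # independent assortment: shuffle each chromosome's classes independently
    for chrom in ("I", "II", "VI"):
        vec = vectors[chrom]
        perm = rng.permutation(n)
        vectors[chrom] = [vec[i] for i in perm]
    return vectors


def build_segregants(
    config: StudyConfig, reference: Reference, parents: Tuple[HaploidGenotype, HaploidGenotype]
) -> Tuple[GenotypeTable, List[Segregant]]:
    """The haploid segregant collection with its classical genotype table.

    Origin codes in the table are phenotype-scored, as segregants are scored
    on plates: the fawn/olive channel cannot see a fawn double mutant's
    hidden olvA::pyrG allele, so the fwnA and olvA columns are complementary
    and the color pair shows zero nonparental segregants.
    """
    diploid = form_diploid(*parents)
    loci = _locus_positions(reference.markers, reference.snps)
    rng = config._rng(2)
    vectors = _chromosome_origin_vectors(config, rng)
    width = max(3, len(str(config.n_segregants)))
    segregants: List[Segregant] = []
    rows = []
    for i in range(config.n_segregants):
        provenance = {c: vectors[c][i] for c in reference.karyotype.chrom_ids}
        seg = assemble_segregant(
            f"seg{i + 1:0{width}d}", diploid, provenance, loci
        )
        segregants.append(seg)
        ph = derive_phenotypes(seg.genotype, reference.markers)
        fawn = ph.spore_color == "fawn"
        rows.append(
            {
                "segregant_id": seg.segregant_id,
                "fwnA": "A" if fawn else "B",
                "olvA": "A" if fawn else "B",
                "pyrG": "B" if ph.pyrG_prototroph else "A",
                "argB": "A" if ph.argB_prototroph else "B",
                "nac": "B" if ph.acidifying else "A",
                "prtT": "B" if ph.protease_full else "A",
            }
        )
    data = pd.DataFrame(rows).set_index("segregant_id")
    table = GenotypeTable(data=data[list(MARKER_IDS)])
    _check_marginals(config, table)
    return table, segregants


def phenotype_frame(
    reference: Reference, segregants: Sequence[Segregant]
) -> pd.DataFrame:
    """Phenotype channels of each segregant, indexed by segregant_id."""
    rows = []
    for seg in segregants:
        ph = derive_phenotypes(seg.genotype, reference.markers)
        rows.append(
            {
                "segregant_id": seg.segregant_id,
                "spore_color": ph.spore_color,
                "pyrG_prototroph": ph.pyrG_prototroph,
                "argB_prototroph": ph.argB_prototroph,
                "acidifying": ph.acidifying,
                "protease_full": ph.protease_full,
                "hygromycin_resistant": ph.hygromycin_resistant,
            }
        )
    return pd.DataFrame(rows).set_index("segregant_id")


def _check_marginals(config: StudyConfig, table: GenotypeTable) -> None:
    counts = {m: int((table.data[m] == "A").sum()) for m in table.markers}
    expected = {
        "fwnA": config.n_fawn,
        "olvA": config.n_fawn,
        "pyrG": config.n_segregants - config.pool_size,
        "argB": config.n_argB_proto,
        "nac": config.pool_size,
        "prtT": config.n_prtT_mutant,
    }
    for m, want in expected.items():
        if counts[m] != want:
            raise ConstructionError(
                f"marginal constraint violated for {m}: got {counts[m]}, want {want}"
            )


def build_pool(
    config: StudyConfig, reference: Reference, segregants: Sequence[Segregant]
) -> Tuple[PoolSpec, List[HaploidGenotype]]:
    """The trait-positive bulk pool: all nonacidifying segregants."""
    pool_segs = select_pool(segregants, nonacidifying, reference.markers)
    if len(pool_segs) != config.pool_size:
        raise ConstructionError(
            f"pool has {len(pool_segs)} members, expected {config.pool_size}"
        )
    spec = PoolSpec(member_ids=tuple(s.segregant_id for s in pool_segs))
    return spec, [s.genotype for s in pool_segs]


def write_fixture(config: StudyConfig, out_dir: Path | str) -> Dict[str, str]:
    """Emit the complete fixture file set and return the checksum manifest."""
    from .io import (
        write_fasta,
        write_gff3,
        write_markers,
        write_segregant_table,
        write_snps,
        write_variant_vcf,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = build_reference(config)
    parents = build_parents(config, reference)
    table, segregants = build_segregants(config, reference, parents)
    pool_spec, pool_genotypes = build_pool(config, reference, segregants)

    write_fasta(reference.genome, out / "reference.fa")
    write_gff3(reference.genes, out / "genes.gff3", reference.karyotype)
    write_markers(reference.markers, out / "markers.tsv")
    write_snps(reference.snps, out / "snps.tsv")
    write_segregant_table(
        segregants,
        table,
        phenotype_frame(reference, segregants),
        reference.karyotype,
        out / "segregants.tsv",
    )
    pd.DataFrame({"segregant_id": list(pool_spec.member_ids)}).to_csv(
        out / "pool.tsv", sep="\t", index=False, lineterminator="\n"
    )

    strain_model = CoverageModel(config.strain_depth, config.error_rate)
    pool_model = CoverageModel(config.pool_depth, config.error_rate)
    calls_A = simulate_sample_calls(
        parents[0], reference.snps, strain_model, sample_id="parent_A",
        rng=config._rng(3),
    )
    calls_B = simulate_sample_calls(
        parents[1], reference.snps, strain_model, sample_id="parent_B",
        rng=config._rng(4),
    )
    calls_pool = simulate_sample_calls(
        pool_genotypes, reference.snps, pool_model, sample_id="pool",
        rng=config._rng(5),
    )
    write_variant_vcf(calls_A, out / "calls_parent_A.vcf", reference.karyotype)
    write_variant_vcf(calls_B, out / "calls_parent_B.vcf", reference.karyotype)
    write_variant_vcf(calls_pool, out / "calls_pool.vcf", reference.karyotype)

    manifest = {}
    for path in sorted(out.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
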