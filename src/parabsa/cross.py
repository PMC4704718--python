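"""Parasexual cross simulation: diploid formation, haploidization, phenotypes.

The parasexual cycle of an asexual fungus replaces meiosis: two haploid
parents fuse into a heterokaryon, nuclei fuse into a diploid, and haploid
segregants arise by progressive random loss of one homolog of each
chromosome pair. Whole chromosomes therefore segregate as units, and the
only mechanism separating loci on one chromosome is rare mitotic
recombination, modelled here as at most one crossover per chromosome per
segregant lineage with a uniformly placed breakpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .genome import KaryotypeMap, MarkerDef, SnpDef

__all__ = [
    "HaploidGenotype",
    "DiploidGenotype",
    "Recombinant",
    "Segregant",
    "CrossConfig",
    "PhenotypeRecord",
    "SelectionImpossibleError",
    "IncompleteGenotypeError",
    "form_diploid",
    "haploidize",
    "derive_phenotypes",
    "select_pool",
]


class SelectionImpossibleError(ValueError):
    """Parents lack the complementary markers needed to select a diploid."""


class IncompleteGenotypeError(KeyError):
    """A genotype is missing the allele state of a required locus."""


@dataclass(frozen=True)
class HaploidGenotype:
    strain_id: str
    marker_alleles: Mapping[str, str]  # marker_id -> "wild" | "mutant"
    snp_alleles: Mapping[str, str]  # snp_id -> "ref" | "alt"

    def marker(self, marker_id: str) -> str:
        try:
            return self.marker_alleles[marker_id]
        except KeyError as exc:
            raise IncompleteGenotypeError(
                f"{self.strain_id}: no allele state for marker {marker_id!r}"
            ) from exc

    def is_mutant(self, marker_id: str) -> bool:
        return self.marker(marker_id) == "mutant"


@dataclass(frozen=True)
class DiploidGenotype:
    homolog_A: HaploidGenotype
    homolog_B: HaploidGenotype

    def __post_init__(self) -> None:
        if set(self.homolog_A.marker_alleles) != set(self.homolog_B.marker_alleles):
            raise ValueError("homologs reference different marker universes")
        if set(self.homolog_A.snp_alleles) != set(self.homolog_B.snp_alleles):
            raise ValueError("homologs reference different SNP universes")


@dataclass(frozen=True)
class Recombinant:
    """Single-crossover chromosome: loci at pos <= breakpoint_bp come from
    proximal_source, loci beyond it from the other homolog."""

    breakpoint_bp: int
    proximal_source: str  # "A" or "B"

    def source_at(self, pos: int) -> str:
        if pos <= self.breakpoint_bp:
            return self.proximal_source
        return "B" if self.proximal_source == "A" else "A"


ChromosomeOrigin = Union[str, Recombinant]  # "A" | "B" | Recombinant


@dataclass(frozen=True)
class Segregant:
    segregant_id: str
    genotype: HaploidGenotype
    provenance: Mapping[str, ChromosomeOrigin]  # chrom_id -> origin


@dataclass(frozen=True)
class CrossConfig:
    """Haploidization parameters.

    p_mitotic_rec is the per-chromosome, per-segregant probability that the
    inherited chromosome is a single-breakpoint mitotic recombinant rather
    than an intact parental homolog. The default 0.013 puts the expectation
    at about one crossover event on a given chromosome among a pool of 78
    segregants, matching the rarity of mitotic recombination in this system.
    """

    n_segregants: int
    p_mitotic_rec: float = 0.013
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segregants < 1:
            raise ValueError("n_segregants must be positive")
        if not 0.0 <= self.p_mitotic_rec <= 1.0:
            raise ValueError("p_mitotic_rec must lie in [0, 1]")


@dataclass(frozen=True)
class PhenotypeRecord:
    spore_color: str  # "black" | "fawn" | "olive"
    pyrG_prototroph: bool
    argB_prototroph: bool
    acidifying: bool
    protease_full: bool
    hygromycin_resistant: bool


def _locus_positions(
    markers: Sequence[MarkerDef], snps: Sequence[SnpDef]
) -> Dict[str, List[Tuple[str, int, str]]]:
    """Index loci per chromosome as (locus_id, pos, kind)."""
    idx: Dict[str, List[Tuple[str, int, str]]] = {}
    for m in markers:
        idx.setdefault(m.chrom_id, []).append((m.marker_id, m.pos, "marker"))
    for s in snps:
        idx.setdefault(s.chrom_id, []).append((s.snp_id, s.pos, "snp"))
    return idx


def form_diploid(
    parent_A: HaploidGenotype, parent_B: HaploidGenotype
) -> DiploidGenotype:
    """Fuse two complementary-marked haploids into a selectable diploid.

    Diploid selection relies on visual complementation of the spore-color
    markers (fwnA x olvA heterozygote conidiates black) and on complementary
    auxotrophies forcing a balanced heterokaryon; parents sharing a color
    marker state cannot be selected this way.
    """
    a_fwn, a_olv = parent_A.is_mutant("fwnA"), parent_A.is_mutant("olvA")
    b_fwn, b_olv = parent_B.is_mutant("fwnA"), parent_B.is_mutant("olvA")
    color_ok = (a_fwn and not a_olv and b_olv and not b_fwn) or (
        b_fwn and not b_olv and a_olv and not a_fwn
    )
    if not color_ok:
        raise SelectionImpossibleError(
            "parents must carry complementary color markers (one fwnA-mutant, "
            "one olvA-mutant)"
        )
    pheno_A = derive_phenotypes_partial(parent_A)
    pheno_B = derive_phenotypes_partial(parent_B)
    aux_ok = (
        pheno_A.pyrG_prototroph != pheno_B.pyrG_prototroph
        and pheno_A.argB_prototroph != pheno_B.argB_prototroph
    )
    if not aux_ok:
        raise SelectionImpossibleError(
            "parents must carry complementary auxotrophies to balance the "
            "heterokaryon"
        )
    return DiploidGenotype(homolog_A=parent_A, homolog_B=parent_B)


def haploidize(
    diploid: DiploidGenotype,
    config: CrossConfig,
    karyotype: KaryotypeMap,
    markers: Sequence[MarkerDef],
    snps: Sequence[SnpDef],
    rng: Optional[np.random.Generator] = None,
    id_prefix: str = "seg",
) -> List[Segregant]:
    """Generate haploid segregants by whole-chromosome loss.

    Each chromosome of each segregant is drawn independently from homolog A
    or B with probability 1/2; with probability config.p_mitotic_rec it is
    instead a single-breakpoint recombinant whose breakpoint is uniform on
    [1, length_bp) and whose proximal source is chosen uniformly.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    loci = _locus_positions(markers, snps)
    segregants = []
    width = max(3, len(str(config.n_segregants)))
    for i in range(config.n_segregants):
        provenance: Dict[str, ChromosomeOrigin] = {}
        for chrom in karyotype.chromosomes:
            if config.p_mitotic_rec > 0 and rng.random() < config.p_mitotic_rec:
                breakpoint_bp = int(rng.integers(1, chrom.length_bp))
                proximal = "A" if rng.random() < 0.5 else "B"
                provenance[chrom.chrom_id] = Recombinant(breakpoint_bp, proximal)
            else:
                provenance[chrom.chrom_id] = "A" if rng.random() < 0.5 else "B"
        seg_id = f"{id_prefix}{i + 1:0{width}d}"
        segregants.append(
            assemble_segregant(seg_id, diploid, provenance, loci)
        )
    return segregants


def assemble_segregant(
    segregant_id: str,
    diploid: DiploidGenotype,
    provenance: Mapping[str, ChromosomeOrigin],
    loci: Mapping[str, Sequence[Tuple[str, int, str]]],
) -> Segregant:
    """Derive a segregant's alleles from its per-chromosome provenance."""
    marker_alleles: Dict[str, str] = {}
    snp_alleles: Dict[str, str] = {}
    homologs = {"A": diploid.homolog_A, "B": diploid.homolog_B}
    for chrom_id, origin in provenance.items():
        for locus_id, pos, kind in loci.get(chrom_id, ()):
            source = origin.source_at(pos) if isinstance(origin, Recombinant) else origin
            parent = homologs[source]
            if kind == "marker":
                marker_alleles[locus_id] = parent.marker_alleles[locus_id]
            else:
                snp_alleles[locus_id] = parent.snp_alleles[locus_id]
    genotype = HaploidGenotype(
        strain_id=segregant_id,
        marker_alleles=marker_alleles,
        snp_alleles=snp_alleles,
    )
    return Segregant(segregant_id=segregant_id, genotype=genotype, provenance=dict(provenance))


# Color channel: the fawn gene acts upstream of the olive gene in conidial
# melanin synthesis, so fwnA-mutants are fawn regardless of olvA state.
_COLOR_OF_MARKER = {"fwnA": "fawn", "olvA": "olive"}


def derive_phenotypes(
    genotype: HaploidGenotype, markers: Sequence[MarkerDef]
) -> PhenotypeRecord:
    """Map marker alleles to the observable phenotype of a strain.

    Encodes the cross's allele semantics: the olvA disruption carries a
    functional pyrG copy, so pyrG prototrophy tracks the olvA::pyrG
    insertion (both parents are pyrG378-mutant at the native locus); the
    fwnA and argB disruptions carry hygB.
    """
    for m in markers:
        genotype.marker(m.marker_id)  # raises IncompleteGenotypeError if absent
    return derive_phenotypes_partial(genotype, markers)


def derive_phenotypes_partial(
    genotype: HaploidGenotype, markers: Sequence[MarkerDef] = ()
) -> PhenotypeRecord:
    color_markers = sorted(
        (m for m in markers if m.phenotype_channel == "spore_color"),
        key=lambda m: m.epistasis_rank,
    ) or None
    color = "black"
    if color_markers:
        for m in color_markers:
            if genotype.is_mutant(m.marker_id):
                color = _COLOR_OF_MARKER.get(m.marker_id, "fawn")
                break
    else:  # fall back to the canonical marker ids
        if genotype.is_mutant("fwnA"):
            color = "fawn"
        elif genotype.is_mutant("olvA"):
            color = "olive"
    fwn_mut = genotype.is_mutant("fwnA")
    olv_mut = genotype.is_mutant("olvA")
    arg_mut = genotype.is_mutant("argB")
    return PhenotypeRecord(
        spore_color=color,
        pyrG_prototroph=olv_mut,  # olvA::pyrG insertion restores pyrG
        argB_prototroph=not arg_mut,
        acidifying=not genotype.is_mutant("nac"),
        protease_full=not genotype.is_mutant("prtT"),
        hygromycin_resistant=fwn_mut or arg_mut,
    )


def select_pool(
    segregants: Sequence[Segregant],
    trait: Callable[[PhenotypeRecord], bool],
    markers: Sequence[MarkerDef],
) -> List[Segregant]:
    """Select the segregants whose phenotype satisfies *trait*, in order."""
    pool = [
        s for s in segregants if trait(derive_phenotypes(s.genotype, markers))
    ]
    if not pool:
        warnings.warn("trait predicate selected an empty pool", stacklevel=2)
    return pool


def nonacidifying(phenotype: PhenotypeRecord) -> bool:
    """The study's trait predicate: failure to acidify the medium."""
    return not phenotype.acidifying
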