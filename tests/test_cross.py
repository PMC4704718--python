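"""Parasexual cross simulation: diploid selection, haploidization, phenotypes."""

import numpy as np
import pytest

from parabsa.cross import (
    CrossConfig,
    HaploidGenotype,
    Recombinant,
    SelectionImpossibleError,
    derive_phenotypes,
    form_diploid,
    haploidize,
    nonacidifying,
    select_pool,
)
from parabsa.genome import Chromosome, KaryotypeMap, MarkerDef, SnpDef


@pytest.fixture(scope="module")
def diploid(parents):
    return form_diploid(*parents)


class TestFormDiploid:
    def test_study_parents_give_black_prototrophic_diploid(self, parents, reference):
        diploid = form_diploid(*parents)
        # heterozygous at both color loci: neither haplotype constraint alone
        assert diploid.homolog_A.marker_alleles == parents[0].marker_alleles
        assert diploid.homolog_B.marker_alleles == parents[1].marker_alleles

    def test_selfing_is_selection_impossible(self, parents):
        with pytest.raises(SelectionImpossibleError):
            form_diploid(parents[0], parents[0])

    def test_homolog_a_is_parent_a_allele_for_allele(self, parents):
        diploid = form_diploid(*parents)
        assert diploid.homolog_A.snp_alleles == parents[0].snp_alleles


class TestHaploidize:
    def test_no_recombination_chromosomes_are_pure(self, diploid, reference):
        config = CrossConfig(n_segregants=50, p_mitotic_rec=0.0, rng_seed=7)
        segs = haploidize(
            diploid, config, reference.karyotype, reference.markers, reference.snps
        )
        assert len(segs) == 50
        for seg in segs:
            for origin in seg.provenance.values():
                assert origin in ("A", "B")
        # loci on one chromosome are co-inherited
        chr2_snps = [s for s in reference.snps if s.chrom_id == "II"]
        for seg in segs:
            alleles = {seg.genotype.snp_alleles[s.snp_id] for s in chr2_snps}
            assert len(alleles) == 1

    def test_chromosome_inheritance_is_mendelian_half(self, diploid, reference):
        config = CrossConfig(n_segregants=2000, p_mitotic_rec=0.0, rng_seed=11)
        segs = haploidize(
            diploid, config, reference.karyotype, reference.markers, reference.snps
        )
        for chrom in reference.karyotype.chrom_ids:
            frac_A = np.mean([seg.provenance[chrom] == "A" for seg in segs])
            se = 0.5 / np.sqrt(len(segs))
            assert abs(frac_A - 0.5) < 3 * se

    def test_forced_crossover_breakpoint_fraction_matches_enumeration(self):
        """With p_rec = 1 on a 2-locus chromosome, the nonparental fraction
        equals the fraction of breakpoints falling between the loci,
        computed by exhaustive enumeration over the breakpoint grid."""
        length = 1000
        pos_x, pos_y = 300, 700
        karyotype = KaryotypeMap((Chromosome("c", length),))
        markers = [
            MarkerDef("mx", "c", pos_x, "w", "m", "acidification", 1),
            MarkerDef("my", "c", pos_y, "w", "m", "protease", 1),
        ]
        par_a = HaploidGenotype("a", {"mx": "mutant", "my": "mutant"}, {})
        par_b = HaploidGenotype("b", {"mx": "wild", "my": "wild"}, {})
        from parabsa.cross import DiploidGenotype

        diploid = DiploidGenotype(par_a, par_b)
        config = CrossConfig(n_segregants=8000, p_mitotic_rec=1.0, rng_seed=3)
        segs = haploidize(diploid, config, karyotype, markers, [])
        nonparental = np.mean(
            [
                seg.genotype.marker_alleles["mx"] != seg.genotype.marker_alleles["my"]
                for seg in segs
            ]
        )
        # breakpoints uniform on {1, ..., length-1}; loci separate iff
        # pos_x <= breakpoint < pos_y
        expected = sum(
            1 for bp in range(1, length) if pos_x <= bp < pos_y
        ) / (length - 1)
        se = np.sqrt(expected * (1 - expected) / len(segs))
        assert abs(nonparental - expected) < 4 * se

    def test_provenance_determines_alleles(self, diploid, reference):
        """Segregant invariant: every allele traces to the homolog its
        chromosome provenance records (breakpoint-aware on recombinants)."""
        config = CrossConfig(n_segregants=200, p_mitotic_rec=0.3, rng_seed=5)
        segs = haploidize(
            diploid, config, reference.karyotype, reference.markers, reference.snps
        )
        homologs = {"A": diploid.homolog_A, "B": diploid.homolog_B}
        for seg in segs:
            for snp in reference.snps:
                origin = seg.provenance[snp.chrom_id]
                source = (
                    origin.source_at(snp.pos)
                    if isinstance(origin, Recombinant)
                    else origin
                )
                assert (
                    seg.genotype.snp_alleles[snp.snp_id]
                    == homologs[source].snp_alleles[snp.snp_id]
                )

    def test_same_seed_reproduces_segregants(self, diploid, reference):
        config = CrossConfig(n_segregants=20, p_mitotic_rec=0.1, rng_seed=42)
        args = (diploid, config, reference.karyotype, reference.markers, reference.snps)
        a = haploidize(*args)
        b = haploidize(*args)
        assert [s.genotype.snp_alleles for s in a] == [s.genotype.snp_alleles for s in b]
        assert [s.provenance for s in a] == [s.provenance for s in b]


class TestPhenotypes:
    def test_mutagenized_parent_phenotype(self, parents, reference):
        ph = derive_phenotypes(parents[0], reference.markers)
        assert ph.spore_color == "fawn"
        assert not ph.pyrG_prototroph
        assert ph.argB_prototroph
        assert not ph.acidifying
        assert not ph.protease_full
        assert ph.hygromycin_resistant

    def test_partner_parent_phenotype(self, parents, reference):
        ph = derive_phenotypes(parents[1], reference.markers)
        assert ph.spore_color == "olive"
        assert ph.pyrG_prototroph  # olvA::pyrG insertion
        assert not ph.argB_prototroph
        assert ph.acidifying
        assert ph.protease_full

    def test_double_mutant_is_fawn_and_pyrg_prototroph(self, reference):
        genotype = HaploidGenotype(
            "dm",
            {"fwnA": "mutant", "olvA": "mutant", "argB": "wild", "nac": "wild",
             "prtT": "wild"},
            {},
        )
        ph = derive_phenotypes(genotype, reference.markers)
        assert ph.spore_color == "fawn"  # fwnA epistatic over olvA
        assert ph.pyrG_prototroph

    def test_all_wild_genotype_is_black_prototroph(self, reference):
        genotype = HaploidGenotype(
            "wt", {m.marker_id: "wild" for m in reference.markers}, {}
        )
        ph = derive_phenotypes(genotype, reference.markers)
        assert ph.spore_color == "black"
        assert ph.argB_prototroph
        assert ph.acidifying
        assert not ph.hygromycin_resistant
        assert not ph.pyrG_prototroph  # native locus is pyrG378 in this cross

    @pytest.mark.parametrize(
        "fwn,olv", [("wild", "wild"), ("wild", "mutant"), ("mutant", "wild"),
                    ("mutant", "mutant")]
    )
    def test_color_epistasis_never_both_colors(self, reference, fwn, olv):
        genotype = HaploidGenotype(
            "x",
            {"fwnA": fwn, "olvA": olv, "argB": "wild", "nac": "wild", "prtT": "wild"},
            {},
        )
        ph = derive_phenotypes(genotype, reference.markers)
        if fwn == "mutant":
            assert ph.spore_color == "fawn"
        elif olv == "mutant":
            assert ph.spore_color == "olive"
        else:
            assert ph.spore_color == "black"


class TestSelectPool:
    def test_trait_predicate_selects_carriers(self, segregants, reference):
        pool = select_pool(segregants, nonacidifying, reference.markers)
        carriers = [
            s
            for s in segregants
            if s.genotype.marker_alleles["nac"] == "mutant"
        ]
        assert pool == carriers

    def test_always_true_predicate_is_identity(self, segregants, reference):
        assert select_pool(segregants, lambda ph: True, reference.markers) == list(
            segregants
        )

    def test_empty_selection_warns(self, segregants, reference):
        with pytest.warns(UserWarning):
            pool = select_pool(segregants, lambda ph: False, reference.markers)
        assert pool == []
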