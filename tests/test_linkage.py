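"""Two-point marker analysis: allele tallies, PS/NPS, segregation tests."""

import itertools
import random

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parabsa.linkage import (
    GenotypeTable,
    UndefinedTestError,
    allele_distribution,
    linkage_matrix,
    pairwise_linkage,
    segregation_ratio_test,
)


def random_table(n_rows, markers, seed):
    rnd = random.Random(seed)
    data = pd.DataFrame(
        {m: [rnd.choice("AB") for _ in range(n_rows)] for m in markers},
        index=[f"seg{i}" for i in range(n_rows)],
    )
    return GenotypeTable(data=data)


class TestAlleleDistribution:
    def test_fixture_nac_marker_is_78_vs_62(self, genotype_table):
        dist = allele_distribution(genotype_table)
        assert dist.loc["nac", "count_A"] == 78  # nonacidifying
        assert dist.loc["nac", "count_B"] == 62  # acidifying

    def test_single_row_table(self):
        table = GenotypeTable(data=pd.DataFrame({"m": ["A"]}, index=["s"]))
        dist = allele_distribution(table)
        assert tuple(dist.loc["m"]) == (1, 0)

    def test_random_table_matches_brute_force_tally(self):
        table = random_table(97, ["m1", "m2", "m3"], seed=4)
        dist = allele_distribution(table)
        for m in table.markers:
            count_a = sum(1 for v in table.data[m] if v == "A")
            assert dist.loc[m, "count_A"] == count_a
            assert dist.loc[m, "count_B"] == table.N - count_a

    def test_counts_sum_to_n(self, genotype_table):
        dist = allele_distribution(genotype_table)
        assert (dist.sum(axis=1) == genotype_table.N).all()

    def test_bad_code_rejected(self):
        with pytest.raises(ValueError):
            GenotypeTable(data=pd.DataFrame({"m": ["A", "X"]}))


class TestPairwiseLinkage:
    def test_fixture_color_pair_has_zero_recombinants(self, genotype_table):
        link = pairwise_linkage(genotype_table, "fwnA", "olvA")
        assert link.nps_count == 0
        assert link.r_percent == 0.0

    def test_equal_four_combinations_give_50_percent(self):
        data = pd.DataFrame(
            {"x": ["A", "A", "B", "B"], "y": ["A", "B", "A", "B"]},
            index=list("pqrs"),
        )
        link = pairwise_linkage(GenotypeTable(data=data), "x", "y")
        assert link.r_percent == 50.0

    def test_random_tables_match_brute_force_cross_tabulation(self):
        for seed in range(5):
            table = random_table(61, ["x", "y"], seed=seed)
            link = pairwise_linkage(table, "x", "y")
            ps = sum(
                1
                for a, b in zip(table.data["x"], table.data["y"])
                if a == b
            )
            nps = table.N - ps
            assert (link.ps_count, link.nps_count) == (ps, nps)
            assert link.r_percent == pytest.approx(nps / table.N * 100)

    def test_ps_plus_nps_equals_n(self, genotype_table):
        for x, y in itertools.combinations(genotype_table.markers, 2):
            link = pairwise_linkage(genotype_table, x, y)
            assert link.ps_count + link.nps_count == genotype_table.N

    def test_missing_marker_is_key_error(self, genotype_table):
        with pytest.raises(KeyError):
            pairwise_linkage(genotype_table, "fwnA", "nope")


class TestLinkageMatrix:
    def test_three_markers_give_three_records(self):
        table = random_table(10, ["a", "b", "c"], seed=1)
        assert len(linkage_matrix(table)) == 3

    def test_six_marker_fixture_gives_15_records(self, genotype_table):
        assert len(linkage_matrix(genotype_table)) == 15

    def test_matrix_entries_equal_pairwise_calls(self, genotype_table):
        by_pair = {
            (p.marker_x, p.marker_y): p for p in linkage_matrix(genotype_table)
        }
        for (x, y), rec in by_pair.items():
            assert rec == pairwise_linkage(genotype_table, x, y)


class TestSegregationRatioTest:
    def test_exact_half_is_p_one(self):
        assert segregation_ratio_test(50, 100).p_value == pytest.approx(1.0)

    def test_extreme_outcome_closed_form(self):
        # k=0, n=10: both tails collapse to the two extreme outcomes
        assert segregation_ratio_test(0, 10).p_value == pytest.approx(
            2 * 0.5**10
        )

    @pytest.mark.parametrize("k,n", [(78, 140), (0, 1), (100, 200), (130, 200), (17, 53)])
    def test_matches_exhaustive_pmf_oracle(self, k, n):
        """Two-sided exact p-value equals the brute-force sum of pmf over
        all outcomes no more likely than the observed one."""
        pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
        expected = pmf[pmf <= pmf[k] * (1 + 1e-9)].sum()
        assert segregation_ratio_test(k, n).p_value == pytest.approx(expected)

    def test_zero_n_undefined(self):
        with pytest.raises(UndefinedTestError):
            segregation_ratio_test(0, 0)


class TestEstimatorProperties:
    def test_unlinked_recombination_estimate_is_unbiased_at_50(
        self, reference, parents
    ):
        """Mean r-hat over 200 simulated 140-segregant tables, for markers on
        different chromosomes, is within 3 SE of 50%."""
        from parabsa.cross import CrossConfig, form_diploid, haploidize

        diploid = form_diploid(*parents)
        rng = np.random.default_rng(21)
        rs = []
        n = 140
        for _ in range(200):
            config = CrossConfig(
                n_segregants=n, p_mitotic_rec=0.0,
                rng_seed=int(rng.integers(2**31)),
            )
            segs = haploidize(
                diploid, config, reference.karyotype, reference.markers, reference.snps
            )
            data = pd.DataFrame(
                {
                    "nac": [
                        "A" if s.genotype.marker_alleles["nac"] == "mutant" else "B"
                        for s in segs
                    ],
                    "prtT": [
                        "A" if s.genotype.marker_alleles["prtT"] == "mutant" else "B"
                        for s in segs
                    ],
                },
                index=[s.segregant_id for s in segs],
            )
            rs.append(pairwise_linkage(GenotypeTable(data=data), "nac", "prtT").r_percent)
        se_mean = 50.0 / np.sqrt(n) / np.sqrt(len(rs))
        assert abs(np.mean(rs) - 50.0) < 3 * se_mean

    def test_same_chromosome_r_matches_breakpoint_model(self, reference, parents):
        """E[r-hat] for two same-chromosome loci equals
        p_rec x P(breakpoint between them) under the uniform-breakpoint model."""
        from parabsa.cross import CrossConfig, form_diploid, haploidize

        diploid = form_diploid(*parents)
        p_rec = 0.4
        segs_total = 6000
        config = CrossConfig(
            n_segregants=segs_total, p_mitotic_rec=p_rec, rng_seed=33
        )
        segs = haploidize(
            diploid, config, reference.karyotype, reference.markers, reference.snps
        )
        # loci: the two chromosome II SNP extremes
        chr2 = sorted(
            (s for s in reference.snps if s.chrom_id == "II"), key=lambda s: s.pos
        )
        lo, hi = chr2[0], chr2[-1]
        nonparental = np.mean(
            [
                s.genotype.snp_alleles[lo.snp_id] != s.genotype.snp_alleles[hi.snp_id]
                for s in segs
            ]
        )
        length = reference.karyotype.length_of("II")
        p_between = (hi.pos - lo.pos) / (length - 1)
        expected = p_rec * p_between
        se = np.sqrt(expected * (1 - expected) / segs_total)
        assert abs(nonparental - expected) < 4 * se
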