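"""Classical two-point marker analysis of a segregant genotype table.

Each segregant is scored at each marker by the parental origin of its
allele ("A" or "B"). For a marker pair, a segregant is parental (PS) when
both origin codes agree and nonparental (NPS) otherwise; the recombination
frequency is NPS / N x 100%. With whole-chromosome segregation, markers on
one chromosome show r near 0 (separated only by rare mitotic crossover)
and markers on different chromosomes show r near 50%.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Tuple

import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeTable",
    "PairwiseLinkage",
    "SegregationTest",
    "UndefinedTestError",
    "allele_distribution",
    "pairwise_linkage",
    "linkage_matrix",
    "segregation_ratio_test",
]


class UndefinedTestError(ValueError):
    """Segregation test requested with zero observations."""


@dataclass
class GenotypeTable:
    """Segregant-by-marker table of parental origin codes.

    ``data`` is indexed by segregant_id with one column per marker; every
    cell is "A" or "B". ``phase`` records which combination is parental:
    it is implicit in origin coding (a segregant is parental when all its
    codes match one parent, i.e. are all equal), so phase is carried only
    as documentation of the cross's parents.
    """

    data: pd.DataFrame
    phase: Dict[str, Tuple[str, str]] | None = None  # marker -> (allele_A, allele_B)

    def __post_init__(self) -> None:
        values = set(self.data.to_numpy().ravel())
        if not values <= {"A", "B"}:
            raise ValueError(f"origin codes must be 'A'/'B', found {values - {'A', 'B'}}")

    @property
    def N(self) -> int:
        return len(self.data)

    @property
    def markers(self) -> List[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class PairwiseLinkage:
    marker_x: str
    marker_y: str
    ps_count: int
    nps_count: int
    r_percent: float
    phase_suspect: bool = False  # r > 50% suggests mis-specified phase

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_percent <= 100.0:
            raise ValueError("r_percent outside [0, 100]")


@dataclass(frozen=True)
class SegregationTest:
    marker_id: str
    k: int  # parent-A allele count
    n: int
    p_value: float


def allele_distribution(table: GenotypeTable) -> pd.DataFrame:
    """Per-marker counts of parent-A and parent-B origin codes."""
    if table.N == 0:
        raise ValueError("empty genotype table")
    counts = {
        m: (
            int((table.data[m] == "A").sum()),
            int((table.data[m] == "B").sum()),
        )
        for m in table.markers
    }
    return pd.DataFrame(counts, index=["count_A", "count_B"]).T


def pairwise_linkage(
    table: GenotypeTable, marker_x: str, marker_y: str
) -> PairwiseLinkage:
    """PS/NPS counts and recombination frequency for one marker pair."""
    for m in (marker_x, marker_y):
        if m not in table.data.columns:
            raise KeyError(m)
    same = table.data[marker_x] == table.data[marker_y]
    ps = int(same.sum())
    nps = table.N - ps
    r = nps / table.N * 100.0
    return PairwiseLinkage(
        marker_x=marker_x,
        marker_y=marker_y,
        ps_count=ps,
        nps_count=nps,
        r_percent=r,
        phase_suspect=r > 50.0,
    )


def linkage_matrix(table: GenotypeTable) -> List[PairwiseLinkage]:
    """All-pairs two-point linkage records (one per unordered pair)."""
    if len(table.markers) < 2:
        raise ValueError("need at least two markers")
    return [
        pairwise_linkage(table, x, y) for x, y in combinations(table.markers, 2)
    ]


def segregation_ratio_test(k: int, n: int, marker_id: str = "") -> SegregationTest:
    """Two-sided exact binomial test of 1:1 segregation.

    The p-value sums the probabilities of all outcomes no more likely than
    the observed count under Binomial(n, 1/2).
    """
    if n == 0:
        raise UndefinedTestError("no observations")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    p = float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
    return SegregationTest(marker_id=marker_id, k=k, n=n, p_value=p)
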