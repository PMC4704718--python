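"""Simulated per-site sequencing evidence for single strains and pools.

Stands in for short-read sequencing and mapping: per SNP site, read depth
is Poisson and the alt-allele read count is binomial around the true pool
allele frequency perturbed by a symmetric per-read error rate (miscalls
split evenly over the three non-ref bases, so a true-ref read reports alt
with probability error_rate/3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cross import HaploidGenotype
from .genome import SnpDef

__all__ = [
    "CoverageModel",
    "SampleCalls",
    "PoolSpec",
    "UndefinedFrequencyError",
    "true_pool_frequency",
    "simulate_sample_calls",
    "resolve_pool",
]

CALL_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "depth", "alt_count"]


class UndefinedFrequencyError(ValueError):
    """Allele frequency requested for an empty pool."""


@dataclass(frozen=True)
class CoverageModel:
    """Sequencing-depth and error model for one library.

    mean_depth: expected reads per site (Poisson). Defaults downstream are
    100 for single strains and 300 for the pool. error_rate: per-read
    probability of reporting a wrong base.
    """

    mean_depth: float
    error_rate: float = 0.002
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")


@dataclass
class SampleCalls:
    """Per-site depth and alt-allele counts for one sample (strain or pool)."""

    sample_id: str
    table: pd.DataFrame  # columns CALL_COLUMNS, one row per SNP site

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"call table missing columns {missing}")
        bad = self.table["alt_count"] > self.table["depth"]
        if bad.any():
            offender = self.table.loc[bad, "snp_id"].iloc[0]
            raise ValueError(f"alt_count exceeds depth at {offender}")
        self.table = self.table.reset_index(drop=True)

    def depth(self, snp_id: str) -> int:
        return int(self._row(snp_id)["depth"])

    def alt_count(self, snp_id: str) -> int:
        return int(self._row(snp_id)["alt_count"])

    def frequency(self, snp_id: str) -> float:
        row = self._row(snp_id)
        if row["depth"] == 0:
            return float("nan")
        return float(row["alt_count"] / row["depth"])

    def _row(self, snp_id: str) -> pd.Series:
        rows = self.table[self.table["snp_id"] == snp_id]
        if rows.empty:
            raise KeyError(snp_id)
        return rows.iloc[0]

    @property
    def snp_ids(self) -> List[str]:
        return list(self.table["snp_id"])


@dataclass(frozen=True)
class PoolSpec:
    """Bulk pool composition: every member contributes equal DNA mass."""

    member_ids: tuple

    def __post_init__(self) -> None:
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("pool members must be unique")


def resolve_pool(
    pool: PoolSpec, genotypes: Mapping[str, HaploidGenotype]
) -> List[HaploidGenotype]:
    """Look up the member genotypes of a PoolSpec."""
    return [genotypes[mid] for mid in pool.member_ids]


def true_pool_frequency(pool: Sequence[HaploidGenotype], snp: SnpDef) -> float:
    """Fraction of pool members carrying the alt allele at *snp*."""
    if not pool:
        raise UndefinedFrequencyError("empty pool has no allele frequency")
    m = sum(1 for g in pool if g.snp_alleles[snp.snp_id] == "alt")
    return m / len(pool)


def simulate_sample_calls(
    genotype_or_pool: Union[HaploidGenotype, Sequence[HaploidGenotype]],
    snps: Sequence[SnpDef],
    model: CoverageModel,
    sample_id: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> SampleCalls:
    """Draw per-site sequencing evidence for a strain or an equal-mass pool.

    Per site: depth ~ Poisson(mean_depth); alt_count ~ Binomial(depth, q)
    with q = p(1 - e) + (1 - p) e/3, where p is the true alt-allele
    frequency (0 or 1 for a single strain, member fraction for a pool) and
    e the per-read error rate.
    """
    if isinstance(genotype_or_pool, HaploidGenotype):
        members: Sequence[HaploidGenotype] = [genotype_or_pool]
        default_id = genotype_or_pool.strain_id
    else:
        members = list(genotype_or_pool)
        if not members:
            raise UndefinedFrequencyError("cannot sequence an empty pool")
        default_id = "pool"
    if rng is None:
        rng = np.random.default_rng(model.rng_seed)
    n = len(snps)
    p = np.array([true_pool_frequency(members, s) for s in snps])
    e = model.error_rate
    q = p * (1.0 - e) + (1.0 - p) * (e / 3.0)
    depth = rng.poisson(model.mean_depth, size=n)
    alt = rng.binomial(depth, q)
    table = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snps],
            "chrom": [s.chrom_id for s in snps],
            "pos": [s.pos for s in snps],
            "ref": [s.ref_base for s in snps],
            "alt": [s.alt_base for s in snps],
            "depth": depth.astype(int),
            "alt_count": alt.astype(int),
        }
    )
    return SampleCalls(sample_id=sample_id or default_id, table=table)
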