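"""Readers and writers for the pipeline's file formats, and the pipeline runner.

Formats: FASTA for chromosome sequences; GFF3 (CDS features with Parent
attributes) for gene models; a minimal VCF v4.2 subset (FORMAT DP:AD, AD as
"ref,alt") plus a flat tab-separated mirror for per-site calls; tab-separated
tables for markers, SNP definitions, and segregant genotypes. All tables are
UTF-8, tab-separated, LF-terminated, with a single header row; report files
begin with comment lines recording tool version, config hash, and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import seq3

from . import __version__
from .cross import HaploidGenotype, Recombinant, Segregant
from .genome import GeneModel, KaryotypeMap, MarkerDef, SnpDef
from .linkage import GenotypeTable, allele_distribution, linkage_matrix, segregation_ratio_test
from .pipeline import (
    ConservationRecord,
    SNPFilterParams,
    annotate_coding_effect,
    derive_parental_snpset,
    rank_candidates,
    scan_pool_conservation,
)
from .poolseq import CALL_COLUMNS, SampleCalls

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ConsistencyError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_markers",
    "write_markers",
    "read_snps",
    "write_snps",
    "read_variant_table",
    "write_variant_vcf",
    "write_variant_tsv",
    "read_segregant_table",
    "write_segregant_table",
    "genotypes_from_segregant_table",
    "PipelineConfig",
    "run_pipeline",
]


class ParseError(ValueError):
    """Malformed record in an input file."""


class ConsistencyError(ValueError):
    """Record violates a cross-field invariant (e.g. AD exceeding DP)."""


# ---------------------------------------------------------------------------
# FASTA / GFF3


def write_fasta(genome: Mapping[str, str], path: Path | str) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: Path | str) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(
    genes: Sequence[GeneModel], path: Path | str, karyotype: Optional[KaryotypeMap] = None
) -> None:
    lines = ["##gff-version 3"]
    if karyotype is not None:
        for c in karyotype.chromosomes:
            lines.append(f"##sequence-region {c.chrom_id} 1 {c.length_bp}")
    for gene in genes:
        lo, hi = gene.span
        lines.append(
            "\t".join(
                [
                    gene.chrom_id,
                    "parabsa",
                    "gene",
                    str(lo),
                    str(hi),
                    ".",
                    gene.strand,
                    ".",
                    f"ID={gene.gene_id}",
                ]
            )
        )
        for i, (start, end) in enumerate(gene.cds_intervals, 1):
            lines.append(
                "\t".join(
                    [
                        gene.chrom_id,
                        "parabsa",
                        "CDS",
                        str(start),
                        str(end),
                        ".",
                        gene.strand,
                        "0" if i == 1 else ".",
                        f"ID={gene.gene_id}.cds{i};Parent={gene.gene_id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: Path | str) -> List[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        intervals = sorted(
            (cds.start, cds.end)
            for cds in db.children(gene.id, featuretype="CDS")
        )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom_id=gene.seqid,
                strand=gene.strand,
                cds_intervals=tuple(intervals),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Marker / SNP tables


def write_markers(markers: Sequence[MarkerDef], path: Path | str) -> None:
    df = pd.DataFrame(
        [
            {
                "marker_id": m.marker_id,
                "chrom": m.chrom_id,
                "pos": m.pos,
                "wild_allele": m.wild_allele,
                "mutant_allele": m.mutant_allele,
                "phenotype_channel": m.phenotype_channel,
                "epistasis_rank": m.epistasis_rank,
            }
            for m in markers
        ]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_markers(path: Path | str) -> List[MarkerDef]:
    df = pd.read_csv(path, sep="\t")
    return [
        MarkerDef(
            marker_id=r.marker_id,
            chrom_id=r.chrom,
            pos=int(r.pos),
            wild_allele=r.wild_allele,
            mutant_allele=r.mutant_allele,
            phenotype_channel=r.phenotype_channel,
            epistasis_rank=int(r.epistasis_rank),
        )
        for r in df.itertuples(index=False)
    ]


def write_snps(snps: Sequence[SnpDef], path: Path | str) -> None:
    df = pd.DataFrame(
        [
            {
                "snp_id": s.snp_id,
                "chrom": s.chrom_id,
                "pos": s.pos,
                "ref": s.ref_base,
                "alt": s.alt_base,
                "origin_parent": s.origin_parent,
            }
            for s in snps
        ]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_snps(path: Path | str) -> List[SnpDef]:
    df = pd.read_csv(path, sep="\t")
    return [
        SnpDef(
            snp_id=r.snp_id,
            chrom_id=r.chrom,
            pos=int(r.pos),
            ref_base=r.ref,
            alt_base=r.alt,
            origin_parent=r.origin_parent,
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Variant call tables (minimal VCF + flat TSV mirror)

_VCF_HEADER = """##fileformat=VCFv4.2
{contigs}##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_variant_vcf(
    calls: SampleCalls, path: Path | str, karyotype: Optional[KaryotypeMap] = None
) -> None:
    contigs = ""
    if karyotype is not None:
        contigs = "".join(
            f"##contig=<ID={c.chrom_id},length={c.length_bp}>\n"
            for c in karyotype.chromosomes
        )
    lines = [_VCF_HEADER.format(contigs=contigs, sample=calls.sample_id)]
    for row in calls.table.itertuples(index=False):
        ref_count = int(row.depth) - int(row.alt_count)
        lines.append(
            f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}\t.\t"
            f"PASS\t.\tDP:AD\t{row.depth}:{ref_count},{row.alt_count}\n"
        )
    Path(path).write_text("".join(lines))


def write_variant_tsv(calls: SampleCalls, path: Path | str) -> None:
    df = calls.table[CALL_COLUMNS].copy()
    df.insert(0, "sample_id", calls.sample_id)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _read_variant_vcf(path: Path | str) -> SampleCalls:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample = vcf.samples[0] if vcf.samples else "sample"
    rows = []
    for rec in vcf:
        depth = int(rec.format("DP")[0][0])
        ad = rec.format("AD")[0]
        alt_count = int(ad[1]) if len(ad) > 1 else 0
        if int(ad[0]) + alt_count > depth:
            raise ConsistencyError(
                f"{rec.ID}: AD sum {int(ad[0]) + alt_count} exceeds DP {depth}"
            )
        rows.append(
            {
                "snp_id": rec.ID,
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
                "depth": depth,
                "alt_count": alt_count,
            }
        )
    return SampleCalls(sample_id=sample, table=pd.DataFrame(rows, columns=CALL_COLUMNS))


def _read_variant_tsv(path: Path | str) -> SampleCalls:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    sample = df["sample_id"].iloc[0] if "sample_id" in df.columns and len(df) else "sample"
    bad = df.index[df["alt_count"] > df["depth"]]
    if len(bad):
        raise ConsistencyError(f"{path}: alt_count exceeds depth at line {bad[0] + 2}")
    return SampleCalls(sample_id=str(sample), table=df[CALL_COLUMNS].copy())


def read_variant_table(path: Path | str) -> SampleCalls:
    """Read per-site calls from minimal VCF or the flat TSV mirror."""
    path = Path(path)
    first = path.open().readline()
    if first.startswith("##fileformat=VCF"):
        return _read_variant_vcf(path)
    return _read_variant_tsv(path)


# ---------------------------------------------------------------------------
# Segregant genotype table


def _provenance_code(origin) -> str:
    if isinstance(origin, Recombinant):
        return f"R:{origin.proximal_source}:{origin.breakpoint_bp}"
    return origin


def _parse_provenance(code: str):
    if code in ("A", "B"):
        return code
    if code.startswith("R:"):
        _, proximal, bp = code.split(":")
        return Recombinant(breakpoint_bp=int(bp), proximal_source=proximal)
    raise ParseError(f"bad provenance code {code!r}")


def write_segregant_table(
    segregants: Sequence[Segregant],
    table: GenotypeTable,
    phenotypes: pd.DataFrame,
    karyotype: KaryotypeMap,
    path: Path | str,
) -> None:
    """One row per segregant: marker origin codes, phenotype channels,
    provenance as a compact code per chromosome."""
    rows = []
    for seg in segregants:
        row = {"segregant_id": seg.segregant_id}
        for m in table.markers:
            row[m] = table.data.loc[seg.segregant_id, m]
        for col in phenotypes.columns:
            row[col] = phenotypes.loc[seg.segregant_id, col]
        for c in karyotype.chrom_ids:
            row[f"chrom_{c}"] = _provenance_code(seg.provenance[c])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_segregant_table(
    path: Path | str, marker_ids: Sequence[str]
) -> Tuple[GenotypeTable, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for m in marker_ids:
        if m not in df.columns:
            raise ParseError(f"{path}: missing marker column {m!r}")
    df = df.set_index("segregant_id")
    table = GenotypeTable(data=df[list(marker_ids)].copy())
    return table, df


def genotypes_from_segregant_table(
    df: pd.DataFrame,
    snps: Sequence[SnpDef],
    trait_parent: str = "A",
) -> Dict[str, HaploidGenotype]:
    """Reconstruct per-segregant SNP alleles from provenance codes.

    Parent *trait_parent* carries the alt allele at its origin SNPs and ref
    elsewhere; the other parent is complementary. The provenance code of
    each chromosome then determines each segregant's allele.
    """
    out: Dict[str, HaploidGenotype] = {}
    for seg_id, row in df.iterrows():
        alleles: Dict[str, str] = {}
        for snp in snps:
            col = f"chrom_{snp.chrom_id}"
            origin = _parse_provenance(row[col])
            source = (
                origin.source_at(snp.pos) if isinstance(origin, Recombinant) else origin
            )
            carries_alt = source == snp.origin_parent
            alleles[snp.snp_id] = "alt" if carries_alt else "ref"
        out[str(seg_id)] = HaploidGenotype(
            strain_id=str(seg_id), marker_alleles={}, snp_alleles=alleles
        )
    return out


# ---------------------------------------------------------------------------
# Pipeline configuration and runner


@dataclass
class PipelineConfig:
    """Paths and parameters for a full analysis run on a fixture directory."""

    fixture_dir: Path
    out_dir: Path
    params: SNPFilterParams = field(default_factory=SNPFilterParams)
    rng_seed: int = 0
    trait_parent: str = "A"
    marker_ids: Tuple[str, ...] = ("fwnA", "olvA", "pyrG", "argB", "nac", "prtT")

    def __post_init__(self) -> None:
        self.fixture_dir = Path(self.fixture_dir)
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        """Load a pipeline configuration from a YAML file.

        Recognized keys: fixture_dir, out_dir, rng_seed, trait_parent, and
        min_freq / min_depth / pool_min_freq (folded into SNPFilterParams).
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        params = SNPFilterParams(
            min_freq=raw.pop("min_freq", 0.7),
            min_depth=raw.pop("min_depth", 20),
            pool_min_freq=raw.pop("pool_min_freq", 0.3),
        )
        known = {"fixture_dir", "out_dir", "rng_seed", "trait_parent", "marker_ids"}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        if "marker_ids" in raw:
            raw["marker_ids"] = tuple(raw["marker_ids"])
        return cls(params=params, **raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "fixture_dir": str(self.fixture_dir),
                "min_freq": self.params.min_freq,
                "min_depth": self.params.min_depth,
                "pool_min_freq": self.params.pool_min_freq,
                "rng_seed": self.rng_seed,
                "trait_parent": self.trait_parent,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _report_header(config: PipelineConfig) -> str:
    return (
        f"# parabsa {__version__}\n"
        f"# config_sha={config.config_hash()} seed={config.rng_seed}\n"
    )


def _effect_fields(effect) -> Dict[str, str]:
    if effect is None or effect.consequence in ("noncoding",):
        return {"gene_id": ".", "consequence": effect.consequence if effect else ".",
                "codon_change": ".", "aa_change": "."}
    if effect.consequence == "intronic":
        return {"gene_id": effect.gene_id, "consequence": "intronic",
                "codon_change": ".", "aa_change": "."}
    aa_change = f"{seq3(effect.ref_aa)}{effect.codon_index}{seq3(effect.alt_aa)}"
    return {
        "gene_id": effect.gene_id,
        "consequence": effect.consequence,
        "codon_change": f"{effect.ref_codon}>{effect.alt_codon}",
        "aa_change": aa_change,
    }


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute call/filter -> conservation scan -> annotate -> rank -> linkage.

    Reads a fixture directory (layout of ``write_fixture``), writes the
    conservation report, linkage matrix, allele distribution and a JSON
    summary into config.out_dir, and returns the summary dict.
    """
    fd = config.fixture_dir
    config.out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    genome = stage("read-reference", read_fasta, fd / "reference.fa")
    genes = stage("read-annotation", read_gff3, fd / "genes.gff3")
    calls_A = stage("read-calls", read_variant_table, fd / "calls_parent_A.vcf")
    calls_B = stage("read-calls", read_variant_table, fd / "calls_parent_B.vcf")
    pool_calls = stage("read-calls", read_variant_table, fd / "calls_pool.vcf")

    snpset = stage(
        "call-snps", derive_parental_snpset, calls_A, calls_B, config.params
    )
    if not snpset.snps:
        warnings.warn("empty SNP set: no inter-parental variants validated")

    pool_genotypes = None
    seg_path = fd / "segregants.tsv"
    if seg_path.exists():
        table, seg_df = stage(
            "read-segregants", read_segregant_table, seg_path, config.marker_ids
        )
        pool_ids = pd.read_csv(fd / "pool.tsv", sep="\t")["segregant_id"].astype(str)
        genos = genotypes_from_segregant_table(
            seg_df, list(snpset), trait_parent=config.trait_parent
        )
        pool_genotypes = [genos[i] for i in pool_ids]
    else:
        table = None

    records = stage(
        "bsa-scan",
        scan_pool_conservation,
        snpset,
        pool_calls,
        pool_genotypes,
        config.params,
        trait_parent=config.trait_parent,
    )
    effects = {
        s.snp_id: stage("annotate", annotate_coding_effect, s, genes, genome)
        for s in snpset
    }
    ranked = stage("rank", rank_candidates, records, effects)

    header = _report_header(config)
    rep_rows = []
    snp_by_id = {s.snp_id: s for s in snpset}
    for rec in ranked:
        snp = snp_by_id[rec.snp_id]
        row = {
            "snp_id": rec.snp_id,
            "chrom": rec.chrom_id,
            "pos": rec.pos,
            "ref": snp.ref_base,
            "alt": snp.alt_base,
            "origin_parent": rec.origin_parent,
            "pool_depth": rec.pool_depth,
            "read_frequency": (
                f"{rec.read_frequency:.6f}" if rec.read_frequency is not None else "."
            ),
            "genotype_conservation": (
                f"{rec.genotype_conservation:.6f}"
                if rec.genotype_conservation is not None
                else "."
            ),
            "class": rec.conservation_class or ".",
            "binom_pvalue": (
                f"{rec.binom_pvalue:.3e}" if rec.binom_pvalue is not None else "."
            ),
        }
        row.update(_effect_fields(effects.get(rec.snp_id)))
        rep_rows.append(row)
    report_path = config.out_dir / "conservation_report.tsv"
    with report_path.open("w") as fh:
        fh.write(header)
        pd.DataFrame(rep_rows).to_csv(fh, sep="\t", index=False, lineterminator="\n")

    summary: Dict = {
        "tool_version": __version__,
        "config_sha": config.config_hash(),
        "seed": config.rng_seed,
        "n_snps": len(snpset),
        "shared_sites_excluded": list(snpset.shared_sites),
        "class_counts": {
            cls: sum(1 for r in records if r.conservation_class == cls)
            for cls in ("fully_conserved", "high", "unlinked")
        },
    }
    coding_ranked = [
        r
        for r in ranked
        if effects.get(r.snp_id) is not None
        and effects[r.snp_id].consequence in ("missense", "nonsense")
    ]
    if ranked:
        top = ranked[0]
        summary["top_candidate"] = {
            "snp_id": top.snp_id,
            "chrom": top.chrom_id,
            "pos": top.pos,
            **_effect_fields(effects.get(top.snp_id)),
        }
    if coding_ranked:
        top_c = coding_ranked[0]
        summary["top_coding_candidate"] = {
            "snp_id": top_c.snp_id,
            "chrom": top_c.chrom_id,
            "pos": top_c.pos,
            "class": top_c.conservation_class,
            **_effect_fields(effects.get(top_c.snp_id)),
        }

    if table is not None:
        dist = allele_distribution(table)
        dist_path = config.out_dir / "allele_distribution.tsv"
        with dist_path.open("w") as fh:
            fh.write(header)
            seg_tests = {
                m: segregation_ratio_test(
                    int(dist.loc[m, "count_A"]), table.N, marker_id=m
                ).p_value
                for m in table.markers
            }
            out = dist.copy()
            out["binom_pvalue"] = [f"{seg_tests[m]:.4f}" for m in out.index]
            out.index.name = "marker_id"
            out.to_csv(fh, sep="\t", lineterminator="\n")
        pairs = linkage_matrix(table)
        lm_path = config.out_dir / "linkage_matrix.tsv"
        with lm_path.open("w") as fh:
            fh.write(header)
            pd.DataFrame(
                [
                    {
                        "marker_x": p.marker_x,
                        "marker_y": p.marker_y,
                        "ps_count": p.ps_count,
                        "nps_count": p.nps_count,
                        "r_percent": f"{p.r_percent:.2f}",
                        "phase_suspect": p.phase_suspect,
                    }
                    for p in pairs
                ]
            ).to_csv(fh, sep="\t", index=False, lineterminator="\n")
        summary["n_segregants"] = table.N
        summary["pool_size"] = len(pool_genotypes) if pool_genotypes else None

    summary_path = config.out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    return summary
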