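"""Readers and writers for the pipeline's file formats.

Plain-text formats only: tab-separated tables for signals, designs,
phenotypes, strain means and genetic maps; FASTA for the genome; GFF3 for
gene models; VCF for SNPs (conservation score in INFO/CONS).  Coordinates
are 1-based inclusive everywhere in memory (the VCF/GFF convention); the
BED-style 0-based half-open convention is converted at the boundary if ever
read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .association import PhenotypeTable
from .ingest import SampleDesign
from .rimap import GeneticMap
from .snp import GeneModel, SnpRecord

__all__ = [
    "read_genome_fasta", "write_genome_fasta",
    "read_snp_vcf", "write_snp_vcf",
    "read_gene_models_gff", "write_gene_models_gff",
    "read_genetic_map", "write_genetic_map",
    "read_design_table", "write_design_table",
    "read_phenotype_table", "write_phenotype_table",
]


def read_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_snp_vcf(snps: list[SnpRecord], path, contig_lengths: dict[str, int] | None = None) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=CONS,Number=1,Type=Float,Description="PhastCons-style conservation score">')
    contigs = contig_lengths or {}
    for chrom in dict.fromkeys(s.chrom for s in snps):
        length = contigs.get(chrom)
        if length:
            header.add_line(f"##contig=<ID={chrom},length={length}>")
        else:
            header.add_line(f"##contig=<ID={chrom}>")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in sorted(snps, key=lambda s: (s.chrom, s.pos)):
            rec = vcf.new_record(
                contig=s.chrom, start=s.pos - 1, stop=s.pos,
                alleles=(s.ref, s.alt),
            )
            rec.info["CONS"] = float(s.conservation)
            vcf.write(rec)


def read_snp_vcf(path) -> list[SnpRecord]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            cons = float(rec.info.get("CONS", 0.0))
            out.append(SnpRecord(rec.contig, rec.pos, rec.ref, rec.alts[0], cons))
    return out


def write_gene_models_gff(genes: list[GeneModel], path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        span = (min(g.tx_start, g.cds[0]), max(g.tx_end, g.cds[1]))
        lines.append(
            f"{g.chrom}\tstrainexpr\tgene\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\tID={g.name}"
        )
        for i, (a, b) in enumerate(g.exons, 1):
            lines.append(
                f"{g.chrom}\tstrainexpr\texon\t{a}\t{b}\t.\t{g.strand}\t.\t"
                f"ID={g.name}.exon{i};Parent={g.name}"
            )
        lines.append(
            f"{g.chrom}\tstrainexpr\tCDS\t{g.cds[0]}\t{g.cds[1]}\t.\t{g.strand}\t0\t"
            f"ID={g.name}.cds;Parent={g.name}"
        )
        for kind, ivals in (("five_prime_UTR", g.utr5), ("three_prime_UTR", g.utr3)):
            for j, (a, b) in enumerate(ivals, 1):
                lines.append(
                    f"{g.chrom}\tstrainexpr\t{kind}\t{a}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={g.name}.{kind}{j};Parent={g.name}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_models_gff(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for gene in db.features_of_type("gene"):
        exons = [(f.start, f.end) for f in db.children(gene, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
        utr5 = [(f.start, f.end) for f in db.children(gene, featuretype="five_prime_UTR")]
        utr3 = [(f.start, f.end) for f in db.children(gene, featuretype="three_prime_UTR")]
        cds_span = (min(a for a, _ in cds), max(b for _, b in cds))
        out.append(
            GeneModel(gene.id, gene.seqid, gene.strand, sorted(exons), cds_span,
                      sorted(utr5), sorted(utr3))
        )
    return out


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_genetic_map(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, sep="\t", comment="#"))


def write_design_table(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index_label="individual")


def read_design_table(path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep="\t", comment="#", index_col="individual"))


def write_phenotype_table(phen: PhenotypeTable, path) -> None:
    phen.table.to_csv(path, sep="\t", index_label="strain")


def read_phenotype_table(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", comment="#", index_col="strain"))
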