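"""SNP region classification, conservation flagging and coding consequences.

Variants segregating between the two parental genomes are assigned to genic
regions — the 5' and 3' UTRs, coding exons, introns, and the 2500 bp flanks
upstream and downstream of the UTRs — in a strand-aware way (the physical
right flank of a minus-strand gene is its upstream).  Coding SNPs are
translated in situ: the CDS is spliced across exons, reverse-complemented on
the minus strand, and the affected codon is translated for both alleles by
the standard genetic code.  A per-base conservation score of 0.90 or greater
marks a site as highly conserved; conserved nonsynonymous SNPs form the
candidate list handed to external effect predictors (PolyPhen-2/SIFT/LRT),
which are pass-through annotation here, never recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

__all__ = [
    "GeneModel",
    "SnpRecord",
    "SnpConsequence",
    "GeneSnpSummary",
    "classify_region",
    "call_consequence",
    "summarize_gene",
    "FLANK_BP",
    "CONSERVATION_THRESHOLD",
]

FLANK_BP = 2500
CONSERVATION_THRESHOLD = 0.90

NONCODING_REGIONS = ("upstream2500", "utr5", "intron", "utr3", "downstream2500")
REGIONS = NONCODING_REGIONS + ("exon_cds", "exon_utr")


def _in(pos: int, interval: tuple[int, int]) -> bool:
    return interval[0] <= pos <= interval[1]


@dataclass
class GeneModel:
    """One gene's structure in 1-based inclusive coordinates."""

    name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    flank: int = FLANK_BP

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c <= b:
                raise ValueError(f"{self.name}: overlapping/unordered exons")

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def upstream_flank(self) -> tuple[int, int]:
        """2500 bp on the 5' side of the gene's orientation."""
        if self.strand == "+":
            return (self.tx_start - self.flank, self.tx_start - 1)
        return (self.tx_end + 1, self.tx_end + self.flank)

    @property
    def downstream_flank(self) -> tuple[int, int]:
        if self.strand == "+":
            return (self.tx_end + 1, self.tx_end + self.flank)
        return (self.tx_start - self.flank, self.tx_start - 1)

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions of CDS bases in coding (5'→3') order."""
        pos = [
            p
            for a, b in self.exons
            for p in range(max(a, self.cds[0]), min(b, self.cds[1]) + 1)
        ]
        return pos[::-1] if self.strand == "-" else pos

    def cds_sequence(self, genome: dict[str, str]) -> str:
        """Spliced CDS on the coding strand."""
        chrom = genome[self.chrom]
        bases = "".join(chrom[p - 1] for a, b in self.exons
                        for p in range(max(a, self.cds[0]), min(b, self.cds[1]) + 1))
        return str(Seq(bases).reverse_complement()) if self.strand == "-" else bases


@dataclass
class SnpRecord:
    """Biallelic SNP on the plus strand, 1-based, with conservation score."""

    chrom: str
    pos: int
    ref: str
    alt: str
    conservation: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if not 0.0 <= self.conservation <= 1.0:
            raise ValueError("conservation score must lie in [0, 1]")

    @property
    def conserved(self) -> bool:
        return self.conservation >= CONSERVATION_THRESHOLD


@dataclass
class SnpConsequence:
    snp: SnpRecord
    gene: str
    region: str
    conserved: bool
    coding_effect: str  # synonymous | nonsynonymous | noncoding
    aa_change: tuple[str, int, str] | None = None
    note: str = ""

    @property
    def substitution(self) -> str | None:
        """Three-letter rendering, e.g. 'Gly:26:Ala'."""
        if self.aa_change is None:
            return None
        ref, idx, alt = self.aa_change
        return f"{ref}:{idx}:{alt}"


def classify_region(snp: SnpRecord, gene: GeneModel) -> str:
    """Assign one region label; anything beyond transcript ± flank is intergenic."""
    if snp.chrom != gene.chrom:
        return "intergenic"
    pos = snp.pos
    if gene.tx_start <= pos <= gene.tx_end:
        in_exon = any(_in(pos, e) for e in gene.exons)
        if not in_exon:
            return "intron"
        if any(_in(pos, u) for u in gene.utr5):
            return "utr5"
        if any(_in(pos, u) for u in gene.utr3):
            return "utr3"
        if _in(pos, gene.cds):
            return "exon_cds"
        return "exon_utr"
    if _in(pos, gene.upstream_flank):
        return "upstream2500"
    if _in(pos, gene.downstream_flank):
        return "downstream2500"
    return "intergenic"


def call_consequence(
    snp: SnpRecord, gene: GeneModel, genome: dict[str, str]
) -> SnpConsequence:
    """Full consequence call: region, conservation flag, coding effect."""
    region = classify_region(snp, gene)
    if region != "exon_cds":
        return SnpConsequence(snp, gene.name, region, snp.conserved, "noncoding")
    ref_base = genome[snp.chrom][snp.pos - 1]
    if ref_base.upper() != snp.ref.upper():
        raise ValueError(
            f"reference mismatch at {snp.chrom}:{snp.pos}: "
            f"genome has {ref_base!r}, SNP says {snp.ref!r}"
        )
    cds_positions = gene.cds_genomic_positions()
    cds_seq = gene.cds_sequence(genome)
    idx = cds_positions.index(snp.pos)
    codon_idx = idx // 3  # 0-based codon number
    codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    alt_coding = snp.alt if gene.strand == "+" else str(Seq(snp.alt).complement())
    within = idx % 3
    alt_codon = codon[:within] + alt_coding + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return SnpConsequence(snp, gene.name, region, snp.conserved, "synonymous")
    note = "stop-gain" if alt_aa == "*" else ("stop-loss" if ref_aa == "*" else "")
    change = (
        seq3(ref_aa) if ref_aa != "*" else "Ter",
        codon_idx + 1,
        seq3(alt_aa) if alt_aa != "*" else "Ter",
    )
    return SnpConsequence(snp, gene.name, region, snp.conserved, "nonsynonymous",
                          aa_change=change, note=note)


@dataclass
class GeneSnpSummary:
    """Per-gene SNP tabulation in the published table's layout."""

    gene: str
    total: int
    total_conserved: int
    noncoding_total: int
    noncoding_conserved: int
    region_counts: dict[str, tuple[int, int]]  # region -> (n, n conserved)
    exonic: int
    exonic_conserved: int
    synonymous: int
    nonsynonymous: int
    candidates: list[SnpConsequence]


def summarize_gene(
    snps: list[SnpRecord], gene: GeneModel, genome: dict[str, str]
) -> GeneSnpSummary:
    """Count SNPs per region and collect conserved nonsynonymous candidates.

    Intergenic SNPs are excluded from all counts; totals therefore satisfy
    total = sum(region counts) and noncoding + exonic = total by construction.
    """
    consequences = [call_consequence(s, gene, genome) for s in snps]
    consequences = [c for c in consequences if c.region != "intergenic"]
    region_counts = {
        r: (
            sum(c.region == r for c in consequences),
            sum(c.region == r and c.conserved for c in consequences),
        )
        for r in REGIONS
    }
    exonic = [c for c in consequences if c.region in ("exon_cds", "exon_utr")]
    candidates = [
        c for c in consequences if c.coding_effect == "nonsynonymous" and c.conserved
    ]
    noncoding = [c for c in consequences if c.region in NONCODING_REGIONS]
    return GeneSnpSummary(
        gene=gene.name,
        total=len(consequences),
        total_conserved=sum(c.conserved for c in consequences),
        noncoding_total=len(noncoding),
        noncoding_conserved=sum(c.conserved for c in noncoding),
        region_counts=region_counts,
        exonic=len(exonic),
        exonic_conserved=sum(c.conserved for c in exonic),
        synonymous=sum(c.coding_effect == "synonymous" for c in consequences),
        nonsynonymous=sum(c.coding_effect == "nonsynonymous" for c in consequences),
        candidates=candidates,
    )
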