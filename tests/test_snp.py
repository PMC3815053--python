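"""SNP region classification, coding consequences, per-gene summaries."""

import numpy as np
import pytest
from Bio.Seq import Seq

import strainexpr as sx
from strainexpr.snp import CONSERVATION_THRESHOLD


def simple_plus_gene():
    # chr: 1..10000; exon1 101-160 (UTR5 101-130), exon2 261-320,
    # exon3 421-480 (UTR3 451-480); CDS 131..450 -> 30+60+30=120 nt = 40 codons
    return sx.GeneModel(
        "gA", "chr1", "+",
        exons=[(101, 160), (261, 320), (421, 480)],
        cds=(131, 450),
        utr5=[(101, 130)], utr3=[(451, 480)],
    )


def simple_minus_gene():
    g = simple_plus_gene()
    return sx.GeneModel("gB", "chr1", "-", exons=g.exons, cds=g.cds,
                        utr5=g.utr3, utr3=g.utr5)


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(99)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=10_000))}


class TestClassifyRegion:
    def test_boundary_one_bp_upstream_plus_strand(self):
        snp = sx.SnpRecord("chr1", 100, "A", "C", 0.5)
        assert sx.classify_region(snp, simple_plus_gene()) == "upstream2500"

    def test_same_physical_offset_is_upstream_on_minus_strand(self):
        # physically right of the transcript end: upstream after strand flip
        snp = sx.SnpRecord("chr1", 481, "A", "C", 0.5)
        assert sx.classify_region(snp, simple_minus_gene()) == "upstream2500"
        assert sx.classify_region(snp, simple_plus_gene()) == "downstream2500"

    @pytest.mark.parametrize(
        "pos, expected",
        [
            (115, "utr5"), (140, "exon_cds"), (200, "intron"),
            (300, "exon_cds"), (460, "utr3"), (2600, "downstream2500"),
            (9000, "intergenic"),
        ],
    )
    def test_region_assignment(self, pos, expected):
        snp = sx.SnpRecord("chr1", pos, "A", "C", 0.5)
        assert sx.classify_region(snp, simple_plus_gene()) == expected

    def test_other_chromosome_is_intergenic(self):
        snp = sx.SnpRecord("chr2", 140, "A", "C", 0.5)
        assert sx.classify_region(snp, simple_plus_gene()) == "intergenic"

    def test_every_in_range_snp_gets_exactly_one_region(self, genome):
        gene = simple_plus_gene()
        lo, hi = gene.upstream_flank[0], gene.downstream_flank[1]
        for pos in range(max(lo, 1), hi + 1, 7):
            ref = genome["chr1"][pos - 1]
            alt = "A" if ref != "A" else "C"
            region = sx.classify_region(sx.SnpRecord("chr1", pos, ref, alt, 0.5), gene)
            assert region != "intergenic"

    def test_generated_annotation_labels_match_classifier(self):
        genes, snps, genome, truth = sx.simulate_gene_annotation(6, seed=3)
        by_name = {g.name: g for g in genes}
        for _, row in truth.iterrows():
            snp = next(s for s in snps if s.pos == row["pos"])
            assert sx.classify_region(snp, by_name[row["gene"]]) == row["region"]


class TestCallConsequence:
    def _install_codon(self, genome, gene, codon_idx, codon):
        seq = list(genome["chr1"])
        positions = gene.cds_genomic_positions()[codon_idx * 3: codon_idx * 3 + 3]
        bases = codon if gene.strand == "+" else str(Seq(codon).complement())
        for p, b in zip(positions, bases):
            seq[p - 1] = b
        return {"chr1": "".join(seq)}

    @pytest.mark.parametrize("make_gene", [simple_plus_gene, simple_minus_gene])
    def test_gly26ala_case(self, genome, make_gene):
        """Codon 26 GGC→GCC is Gly:26:Ala on either strand."""
        gene = make_gene()
        g = self._install_codon(genome, gene, 25, "GGC")
        pos = gene.cds_genomic_positions()[25 * 3 + 1]
        alt = "C" if gene.strand == "+" else "G"
        ref = g["chr1"][pos - 1]
        snp = sx.SnpRecord("chr1", pos, ref, alt, 0.95)
        out = sx.call_consequence(snp, gene, g)
        assert out.coding_effect == "nonsynonymous"
        assert out.substitution == "Gly:26:Ala"
        assert out.conserved

    def test_third_position_wobble_synonymous(self, genome):
        gene = simple_plus_gene()
        g = self._install_codon(genome, gene, 9, "GGT")
        pos = gene.cds_genomic_positions()[9 * 3 + 2]
        snp = sx.SnpRecord("chr1", pos, g["chr1"][pos - 1], "C", 0.2)
        out = sx.call_consequence(snp, gene, g)
        assert out.coding_effect == "synonymous"
        assert out.aa_change is None

    def test_reference_mismatch_rejected(self, genome):
        gene = simple_plus_gene()
        pos = 140
        wrong = "A" if genome["chr1"][pos - 1] != "A" else "C"
        alt = "G" if wrong != "G" else "T"
        snp = sx.SnpRecord("chr1", pos, wrong, alt, 0.5)
        with pytest.raises(ValueError, match="mismatch"):
            sx.call_consequence(snp, gene, genome)

    def test_stop_gain_noted(self):
        gene = simple_plus_gene()
        seq = list("A" * 10_000)
        g = {"chr1": "".join(seq)}
        g = self._install_codon(g, gene, 5, "TAC")  # Tyr
        pos = gene.cds_genomic_positions()[5 * 3 + 2]
        snp = sx.SnpRecord("chr1", pos, "C", "A", 0.5)  # TAC -> TAA stop
        out = sx.call_consequence(snp, gene, g)
        assert out.coding_effect == "nonsynonymous"
        assert out.note == "stop-gain"

    @pytest.mark.parametrize("make_gene", [simple_plus_gene, simple_minus_gene])
    def test_full_protein_retranslation_oracle(self, genome, make_gene):
        """Agreement with an oracle that rebuilds both whole proteins."""
        rng = np.random.default_rng(7)
        gene = make_gene()
        positions = gene.cds_genomic_positions()
        for _ in range(300):
            pos = int(rng.choice(positions))
            ref = genome["chr1"][pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            snp = sx.SnpRecord("chr1", pos, ref, alt, 0.5)
            out = sx.call_consequence(snp, gene, genome)
            # oracle: mutate the genome, re-splice, translate both proteins
            mutated = {"chr1": genome["chr1"][: pos - 1] + alt + genome["chr1"][pos:]}
            prot_ref = str(Seq(gene.cds_sequence(genome)).translate())
            prot_alt = str(Seq(gene.cds_sequence(mutated)).translate())
            if prot_ref == prot_alt:
                assert out.coding_effect == "synonymous"
            else:
                assert out.coding_effect == "nonsynonymous"
                (idx,) = [i for i, (a, b) in enumerate(zip(prot_ref, prot_alt))
                          if a != b]
                assert out.aa_change[1] == idx + 1

    def test_strand_involution(self, genome):
        """Reverse-complementing the world flips the strand but not the call."""
        gene = simple_plus_gene()
        L = len(genome["chr1"])
        rc = {"chr1": str(Seq(genome["chr1"]).reverse_complement())}

        def flip(iv):
            return (L - iv[1] + 1, L - iv[0] + 1)

        flipped = sx.GeneModel(
            "gA", "chr1", "-",
            exons=[flip(e) for e in gene.exons],
            cds=flip(gene.cds),
            utr5=[flip(u) for u in gene.utr5],
            utr3=[flip(u) for u in gene.utr3],
        )
        rng = np.random.default_rng(8)
        for _ in range(100):
            pos = int(rng.choice(gene.cds_genomic_positions()))
            ref = genome["chr1"][pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            out1 = sx.call_consequence(
                sx.SnpRecord("chr1", pos, ref, alt, 0.5), gene, genome)
            fpos = L - pos + 1
            fref = str(Seq(ref).complement())
            falt = str(Seq(alt).complement())
            out2 = sx.call_consequence(
                sx.SnpRecord("chr1", fpos, fref, falt, 0.5), flipped, rc)
            assert out1.coding_effect == out2.coding_effect
            assert out1.aa_change == out2.aa_change


class TestSummarizeGene:
    def test_empty_snp_list(self, genome):
        s = sx.summarize_gene([], simple_plus_gene(), genome)
        assert s.total == 0 and s.nonsynonymous == 0 and not s.candidates

    def test_constructed_counts(self, genome):
        gene = simple_plus_gene()
        g = TestCallConsequence()._install_codon(genome, gene, 25, "GGC")
        nonsyn_pos = gene.cds_genomic_positions()[25 * 3 + 1]
        snps = [
            sx.SnpRecord("chr1", 50, g["chr1"][49], "A" if g["chr1"][49] != "A" else "C", 0.2),
            sx.SnpRecord("chr1", 60, g["chr1"][59], "A" if g["chr1"][59] != "A" else "C", 0.95),
            sx.SnpRecord("chr1", 99, g["chr1"][98], "A" if g["chr1"][98] != "A" else "C", 0.2),
            sx.SnpRecord("chr1", 200, g["chr1"][199], "A" if g["chr1"][199] != "A" else "C", 0.5),
            sx.SnpRecord("chr1", 210, g["chr1"][209], "A" if g["chr1"][209] != "A" else "C", 0.5),
            sx.SnpRecord("chr1", nonsyn_pos, g["chr1"][nonsyn_pos - 1], "C", 0.95),
        ]
        s = sx.summarize_gene(snps, gene, g)
        assert s.region_counts["upstream2500"] == (3, 1)
        assert s.region_counts["intron"] == (2, 0)
        assert s.region_counts["exon_cds"] == (1, 1)
        assert s.nonsynonymous == 1 and len(s.candidates) == 1
        assert s.candidates[0].substitution == "Gly:26:Ala"

    def test_totals_match_brute_force_recount(self):
        genes, snps, genome, _ = sx.simulate_gene_annotation(4, seed=5)
        for gene in genes:
            s = sx.summarize_gene(snps, gene, genome)
            cons = [sx.call_consequence(x, gene, genome) for x in snps]
            cons = [c for c in cons if c.region != "intergenic"]
            assert s.total == len(cons)
            assert s.total == sum(n for n, _ in s.region_counts.values())
            assert s.noncoding_total + s.exonic == s.total
            assert s.synonymous + s.nonsynonymous == s.region_counts["exon_cds"][0]
            assert s.total_conserved == sum(c.conserved for c in cons)

    def test_conservation_threshold_inclusive(self):
        assert sx.SnpRecord("chr1", 1, "A", "C", 0.90).conserved
        assert not sx.SnpRecord("chr1", 1, "A", "C", 0.899).conserved
        assert CONSERVATION_THRESHOLD == 0.90
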