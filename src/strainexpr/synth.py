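"""Synthetic assay worlds with the statistical structure the analysis assumes.

The study's raw data are unpublished, so every downstream stage is exercised
against generated data whose ground truth is recorded exactly as drawn.  The
emulated design follows the study: 8 inbred strains, three to four mice per
strain (drawn 3 or 4 with equal probability when unspecified), technical
replicate wells per lysate, three reference genes, and a multiplicative
per-well loading factor shared by all probes in a well — the artifact the
reference-gene regression is supposed to remove.

Latent (log-scale) expression for gene *g*, strain *s*, mouse *i*, well *w*:

    L = mu_g + A_s + B_i + eps_w,
    Var(A) = h2_g,  Var(B) = 1 - h2_g - residual_sd^2,  Var(eps) = residual_sd^2

so Var(A) / (Var(A) + Var(B) + Var(eps)) = h2_g exactly.  The raw well
signal is ``background_mean + load_w * exp(L)`` with ``load_w`` log-normal.
All effects are normal draws: the machinery under test is normal-theory
ANOVA, so the generator matches its assumptions by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .association import PhenotypeTable
from .ingest import SampleDesign, SignalMatrix
from .rimap import GeneticMap
from .snp import GeneModel, SnpRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_signals",
    "simulate_latent_expression",
    "simulate_phenotypes",
    "simulate_gene_annotation",
    "simulate_genetic_map",
]

REFERENCE_NAMES = ("Gapdh", "Hprt1", "Actb")


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world for the signal simulation.

    ``h2`` may be a scalar (all genes) or a per-gene sequence; it is the
    target broad-sense heritability of the latent expression.  ``residual_sd``
    is the per-well (technical) noise SD on the latent log-signal scale;
    ``well_load_sd`` the SD of the log loading factor.
    """

    n_strains: int = 8
    mice_per_strain: int | Sequence[int] | None = None  # None: draw 3 or 4
    tech_reps: int = 3
    n_genes: int = 20
    n_reference_genes: int = 3
    h2: float | Sequence[float] = 0.5
    background_mean: float = 50.0
    background_sd: float = 2.0
    n_background_wells: int = 4
    well_load_sd: float = 0.2
    residual_sd: float = 0.1
    seed: int = 0

    def h2_per_gene(self) -> np.ndarray:
        h2 = np.broadcast_to(np.asarray(self.h2, dtype=float), (self.n_genes,))
        return h2.copy()

    def validate(self) -> None:
        for name in ("n_strains", "tech_reps", "n_genes", "n_reference_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        h2 = self.h2_per_gene()
        if (h2 < 0).any() or (h2 >= 1).any():
            raise ValueError("per-gene h2 must lie in [0, 1)")
        if (h2 > 0).any():
            counts = self._mice_counts_static()
            if counts is not None and min(counts) < 2:
                raise ValueError(
                    "mice_per_strain must be >= 2 when any h2 > 0 "
                    "(within-strain variance inestimable)"
                )
        if (self.residual_sd**2 > 1 - h2).any():
            raise ValueError("residual_sd^2 must not exceed 1 - h2 for any gene")

    def _mice_counts_static(self) -> list[int] | None:
        if self.mice_per_strain is None:
            return None
        if np.isscalar(self.mice_per_strain):
            return [int(self.mice_per_strain)] * self.n_strains
        counts = [int(c) for c in self.mice_per_strain]
        if len(counts) != self.n_strains:
            raise ValueError("per-strain mouse counts must match n_strains")
        return counts

    def mice_counts(self, rng: np.random.Generator) -> list[int]:
        counts = self._mice_counts_static()
        if counts is None:
            counts = list(rng.choice([3, 4], size=self.n_strains))
        if min(counts) < 1:
            raise ValueError("mice_per_strain must be >= 1")
        return counts


@dataclass
class SyntheticTruth:
    """Everything the generator drew, recorded exactly.

    Downstream recovery tests read only this object; they never re-derive
    the generating quantities.
    """

    mu: pd.Series                      # gene -> latent grand mean
    strain_effects: pd.DataFrame       # genes × strains (A_s)
    variance_fractions: pd.Series      # gene -> configured h2
    individual_effects: pd.DataFrame   # genes × individuals (B_i)
    well_load: pd.Series               # well -> multiplicative load factor
    phenotype_means: pd.DataFrame | None = None  # strains × phenotypes

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.mu.to_csv(path / "mu.tsv", sep="\t", header=["mu"], index_label="gene")
        self.strain_effects.to_csv(path / "strain_effects.tsv", sep="\t",
                                   index_label="gene")
        self.variance_fractions.to_csv(path / "variance_fractions.tsv", sep="\t",
                                       header=["h2"], index_label="gene")
        self.individual_effects.to_csv(path / "individual_effects.tsv", sep="\t",
                                       index_label="gene")
        self.well_load.to_csv(path / "well_load.tsv", sep="\t", header=["load"],
                              index_label="well_id")
        if self.phenotype_means is not None:
            self.phenotype_means.to_csv(path / "phenotype_means.tsv", sep="\t",
                                        index_label="strain")

    @classmethod
    def from_dir(cls, path) -> "SyntheticTruth":
        path = Path(path)
        phen = None
        if (path / "phenotype_means.tsv").exists():
            phen = pd.read_csv(path / "phenotype_means.tsv", sep="\t",
                               index_col="strain")
        return cls(
            mu=pd.read_csv(path / "mu.tsv", sep="\t", index_col="gene")["mu"],
            strain_effects=pd.read_csv(path / "strain_effects.tsv", sep="\t",
                                       index_col="gene"),
            variance_fractions=pd.read_csv(path / "variance_fractions.tsv", sep="\t",
                                           index_col="gene")["h2"],
            individual_effects=pd.read_csv(path / "individual_effects.tsv", sep="\t",
                                           index_col="gene"),
            well_load=pd.read_csv(path / "well_load.tsv", sep="\t",
                                  index_col="well_id")["load"],
            phenotype_means=phen,
        )


def _name_truth_axes(truth: SyntheticTruth) -> None:
    for obj in (truth.mu, truth.strain_effects, truth.variance_fractions,
                truth.individual_effects):
        obj.index.name = "gene"
    truth.well_load.index.name = "well_id"


def _design(config: SimulationConfig, rng: np.random.Generator):
    strains = [f"STR{i + 1:02d}" for i in range(config.n_strains)]
    counts = config.mice_counts(rng)
    rows = []
    for strain, n in zip(strains, counts):
        for m in range(n):
            rows.append(
                {
                    "individual": f"{strain}_m{m + 1}",
                    "strain": strain,
                    "sex": "F" if rng.random() < 0.5 else "M",
                    "n_tech_reps": config.tech_reps,
                }
            )
    design = pd.DataFrame(rows).set_index("individual")
    return SampleDesign(design), strains


def _gene_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    targets = [f"G{i + 1:03d}" for i in range(config.n_genes)]
    refs = [
        REFERENCE_NAMES[i] if i < len(REFERENCE_NAMES) else f"Ref{i + 1}"
        for i in range(config.n_reference_genes)
    ]
    return targets, refs


def simulate_latent_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SampleDesign, SyntheticTruth]:
    """Individual-level latent expression (no well/signal layer).

    Values are mu_g + A_s + B_i with Var(A) = h2 and Var(B) = 1 - h2; this
    is the direct input for estimator-calibration studies.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design, strains = _design(config, rng)
    targets, _ = _gene_names(config)
    h2 = config.h2_per_gene()
    mu = pd.Series(rng.normal(5.3, 0.3, size=len(targets)), index=targets, name="mu")
    A = pd.DataFrame(
        rng.normal(0.0, np.sqrt(h2)[:, None], size=(len(targets), len(strains))),
        index=targets, columns=strains,
    )
    individuals = design.individuals
    B = pd.DataFrame(
        rng.normal(0.0, np.sqrt(1.0 - h2)[:, None],
                   size=(len(targets), len(individuals))),
        index=targets, columns=individuals,
    )
    strain_of = design.table["strain"]
    values = pd.DataFrame(
        {
            g: [mu[g] + A.loc[g, strain_of[i]] + B.loc[g, i] for i in individuals]
            for g in targets
        },
        index=pd.Index(individuals, name="individual"),
    )
    truth = SyntheticTruth(
        mu=mu, strain_effects=A,
        variance_fractions=pd.Series(h2, index=targets, name="h2"),
        individual_effects=B,
        well_load=pd.Series(dtype=float, name="load"),
    )
    _name_truth_axes(truth)
    return values, design, truth


def simulate_signals(
    config: SimulationConfig,
) -> tuple[SignalMatrix, SampleDesign, SyntheticTruth]:
    """Raw well × probe signals with background wells and load factors."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    design, strains = _design(config, rng)
    targets, refs = _gene_names(config)
    h2 = config.h2_per_gene()
    individuals = design.individuals
    strain_of = design.table["strain"]

    mu = pd.Series(rng.normal(5.3, 0.3, size=len(targets)), index=targets, name="mu")
    A = pd.DataFrame(
        rng.normal(0.0, np.sqrt(h2)[:, None], size=(len(targets), len(strains))),
        index=targets, columns=strains,
    )
    var_b = np.clip(1.0 - h2 - config.residual_sd**2, 0.0, None)
    B = pd.DataFrame(
        rng.normal(0.0, np.sqrt(var_b)[:, None],
                   size=(len(targets), len(individuals))),
        index=targets, columns=individuals,
    )
    # references: abundant, tight housekeeping transcripts.  Their per-well
    # technical noise scales with residual_sd (zero when targets are
    # noise-free) but at a quarter of the target level, so the reference
    # regression reads the load factor nearly cleanly.
    mu_ref = pd.Series(rng.normal(6.0, 0.1, size=len(refs)), index=refs)
    ref_ind = pd.DataFrame(
        rng.normal(0.0, 0.05, size=(len(refs), len(individuals))),
        index=refs, columns=individuals,
    )
    ref_well_sd = 0.25 * config.residual_sd

    well_rows = []
    signal_rows = {}
    loads = {}
    for i in individuals:
        for r in range(config.tech_reps):
            well_id = f"{i}_t{r + 1}"
            load = float(np.exp(rng.normal(0.0, config.well_load_sd)))
            loads[well_id] = load
            well_rows.append(
                {"well_id": well_id, "sample_id": i, "strain": strain_of[i],
                 "sex": design.table.loc[i, "sex"], "tech_rep": r + 1,
                 "is_background": False}
            )
            eps_t = rng.normal(0.0, config.residual_sd, size=len(targets))
            eps_r = rng.normal(0.0, ref_well_sd, size=len(refs))
            sig = {}
            for gi, g in enumerate(targets):
                latent = mu[g] + A.loc[g, strain_of[i]] + B.loc[g, i] + eps_t[gi]
                sig[g] = config.background_mean + load * float(np.exp(latent))
            for ri, g in enumerate(refs):
                latent = mu_ref[g] + ref_ind.loc[g, i] + eps_r[ri]
                sig[g] = config.background_mean + load * float(np.exp(latent))
            signal_rows[well_id] = sig
    for b in range(config.n_background_wells):
        well_id = f"BG_{b + 1}"
        well_rows.append(
            {"well_id": well_id, "sample_id": pd.NA, "strain": pd.NA, "sex": pd.NA,
             "tech_rep": pd.NA, "is_background": True}
        )
        signal_rows[well_id] = {
            g: config.background_mean + float(rng.normal(0.0, config.background_sd))
            for g in targets + refs
        }

    wells = pd.DataFrame(well_rows).set_index("well_id")
    signals = pd.DataFrame.from_dict(signal_rows, orient="index")[targets + refs]
    signals = signals.loc[wells.index]
    truth = SyntheticTruth(
        mu=mu, strain_effects=A,
        variance_fractions=pd.Series(h2, index=targets, name="h2"),
        individual_effects=B,
        well_load=pd.Series(loads, name="load"),
    )
    _name_truth_axes(truth)
    return SignalMatrix(signals, wells), design, truth


def simulate_phenotypes(
    truth: SyntheticTruth,
    coupling: dict[str, tuple[str, float]],
    seed: int = 0,
    noise_sd: float = 1.0,
) -> PhenotypeTable:
    """Strain-level phenotypes coupled to gene strain effects.

    ``coupling`` maps a phenotype name to ``(gene, r)``: the strain phenotype
    is ``r * z + sqrt(1 - r^2) * noise`` where ``z`` is the gene's z-scored
    strain-effect vector, so the strain-level correlation is ``r`` in
    expectation.  ``ear_healing`` is mapped to ``1 + 0.4 * value`` mm and
    clipped to [0, 2] (clipping events logged); ``cartilage_score`` to
    ``2 + 0.8 * value``.  ``noise_sd=0`` makes the coupling exact.
    """
    rng = np.random.default_rng(seed)
    strains = list(truth.strain_effects.columns)
    table = {}
    for pheno, (gene, r) in coupling.items():
        if gene not in truth.strain_effects.index:
            raise KeyError(f"unknown gene {gene!r} in coupling")
        if not -1.0 <= r <= 1.0:
            raise ValueError("target correlation must lie in [-1, 1]")
        effects = truth.strain_effects.loc[gene].to_numpy(dtype=float)
        sd = effects.std(ddof=1)
        z = (effects - effects.mean()) / sd if sd > 0 else np.zeros_like(effects)
        noise = rng.normal(0.0, noise_sd, size=len(strains))
        latent = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * noise
        if pheno == "ear_healing":
            raw = 1.0 + 0.4 * latent
            clipped = np.clip(raw, 0.0, 2.0)
            n_clip = int((raw != clipped).sum())
            if n_clip:
                logger.warning("ear_healing: %d strain values clipped to [0, 2]",
                               n_clip)
            table[pheno] = clipped
        elif pheno == "cartilage_score":
            table[pheno] = 2.0 + 0.8 * latent
        else:
            table[pheno] = latent
    phen = pd.DataFrame(table, index=pd.Index(strains, name="strain"))
    truth.phenotype_means = phen.copy()
    return PhenotypeTable(phen)


# --- gene / SNP / genome simulation -------------------------------------------

_CODING_SPANS = (150, 400, 152)  # CDS bases per exon; total 702 = 234 codons
_UTR5_LEN, _UTR3_LEN = 150, 148
_INTRONS = (500, 600)
_GENE_PITCH = 15_000
_CHROM = "chr1"


def _set_codon(genome: list[str], gene: GeneModel, codon_index: int, codon: str) -> None:
    """Write a coding-strand codon into the genome (strand-aware)."""
    from Bio.Seq import Seq

    positions = gene.cds_genomic_positions()[codon_index * 3 : codon_index * 3 + 3]
    bases = codon if gene.strand == "+" else str(Seq(codon).complement())
    for pos, base in zip(positions, bases):
        genome[pos - 1] = base


def simulate_gene_annotation(
    n_genes: int, seed: int = 0
) -> tuple[list[GeneModel], list[SnpRecord], dict[str, str], pd.DataFrame]:
    """Synthetic chromosome with gene models, SNPs and ground-truth labels.

    Genes alternate strands; every region class receives SNPs.  Each gene
    carries two constructed coding SNPs with known effect: a third-position
    synonymous change at codon 10 (GGT→GGC) and the Gly→Ala second-position
    change at codon 26 (GGC→GCC).  Returns (genes, snps, genome, truth) where
    truth rows give the generated region and coding-effect label per SNP.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_len = _GENE_PITCH * n_genes + 10_000
    genome = list(rng.choice(list("ACGT"), size=chrom_len))

    genes: list[GeneModel] = []
    snps: list[SnpRecord] = []
    truth_rows: list[dict] = []

    for gi in range(n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        start = 4000 + gi * _GENE_PITCH
        e1 = (start, start + _UTR5_LEN + _CODING_SPANS[0] - 1)
        e2s = e1[1] + _INTRONS[0] + 1
        e2 = (e2s, e2s + _CODING_SPANS[1] - 1)
        e3s = e2[1] + _INTRONS[1] + 1
        e3 = (e3s, e3s + _CODING_SPANS[2] + _UTR3_LEN - 1)
        cds = (e1[0] + _UTR5_LEN, e3[0] + _CODING_SPANS[2] - 1)
        left_utr = [(e1[0], e1[0] + _UTR5_LEN - 1)]
        right_utr = [(cds[1] + 1, e3[1])]
        if strand == "+":
            utr5, utr3 = left_utr, right_utr
        else:  # 5' UTR is on the physical right of a minus-strand gene
            utr5, utr3 = right_utr, left_utr
        name = f"G{gi + 1:03d}"
        gene = GeneModel(name, _CHROM, strand, [e1, e2, e3], cds, utr5, utr3)
        genes.append(gene)

        # constructed coding SNPs with known truth
        _set_codon(genome, gene, 9, "GGT")   # codon 10: Gly
        _set_codon(genome, gene, 25, "GGC")  # codon 26: Gly
        gdict = {_CHROM: "".join(genome)}
        pos_list = gene.cds_genomic_positions()

        def plus_strand(base: str) -> str:
            from Bio.Seq import Seq

            return base if strand == "+" else str(Seq(base).complement())

        syn_pos = pos_list[9 * 3 + 2]  # third base of codon 10: GGT -> GGC
        snp = SnpRecord(_CHROM, syn_pos, gdict[_CHROM][syn_pos - 1],
                        plus_strand("C"), round(float(rng.uniform(0, 1)), 3))
        snps.append(snp)
        truth_rows.append({"gene": name, "pos": snp.pos, "region": "exon_cds",
                           "coding_effect": "synonymous", "substitution": None})

        nonsyn_pos = pos_list[25 * 3 + 1]  # second base of codon 26: GGC -> GCC
        snp = SnpRecord(_CHROM, nonsyn_pos, gdict[_CHROM][nonsyn_pos - 1],
                        plus_strand("C"), round(float(rng.uniform(0.9, 1.0)), 3))
        snps.append(snp)
        truth_rows.append({"gene": name, "pos": snp.pos, "region": "exon_cds",
                           "coding_effect": "nonsynonymous",
                           "substitution": "Gly:26:Ala"})

        # random SNPs in every other region class, labels by construction
        placements = [
            ("upstream2500", gene.upstream_flank, 2),
            ("utr5", utr5[0], 1),
            ("intron", (e1[1] + 1, e2[0] - 1), 2),
            ("utr3", utr3[0], 1),
            ("downstream2500", gene.downstream_flank, 2),
        ]
        for region, (lo, hi), count in placements:
            for pos in rng.choice(np.arange(lo, hi + 1), size=count, replace=False):
                pos = int(pos)
                ref = genome[pos - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                cons = round(float(rng.uniform(0.85, 1.0) if rng.random() < 0.3
                                   else rng.uniform(0, 0.85)), 3)
                snps.append(SnpRecord(_CHROM, pos, ref, alt, cons))
                truth_rows.append({"gene": name, "pos": pos, "region": region,
                                   "coding_effect": "noncoding",
                                   "substitution": None})

    genome_dict = {_CHROM: "".join(genome)}
    truth = pd.DataFrame(truth_rows)
    return genes, snps, genome_dict, truth


def simulate_genetic_map(
    n_lines: int, markers_per_chrom: int, seed: int = 0, n_chrom: int = 2
) -> GeneticMap:
    """Random RI genetic map with a forced discordant first interval.

    Lines carry mostly homozygous LL/SS blocks with occasional residual
    heterozygosity (LS); the first line's first two markers on the first
    chromosome are forced to LL, SS so that genes between them exercise the
    unassigned case.
    """
    if n_lines < 2 or markers_per_chrom < 2:
        raise ValueError("need >=2 lines and >=2 markers per chromosome")
    rng = np.random.default_rng(seed)
    lines = [f"RIL{i + 1:02d}" for i in range(n_lines)]
    rows = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        positions = np.sort(
            rng.choice(np.arange(1, 50_000_000), size=markers_per_chrom, replace=False)
        )
        genos = {}
        for line in lines:
            # blocky genotypes: switch state with prob 0.3 between markers
            state = str(rng.choice(["LL", "SS"]))
            col = []
            for _ in range(markers_per_chrom):
                if rng.random() < 0.3:
                    state = str(rng.choice(["LL", "SS", "LS"], p=[0.475, 0.475, 0.05]))
                col.append(state)
            genos[line] = col
        for m in range(markers_per_chrom):
            row = {"chrom": chrom, "marker": f"{chrom}_mk{m + 1:03d}",
                   "position": int(positions[m])}
            for line in lines:
                row[line] = genos[line][m]
            rows.append(row)
    table = pd.DataFrame(rows)
    first = table["chrom"] == "chr1"
    idx = table.index[first][:2]
    table.loc[idx[0], lines[0]] = "LL"
    table.loc[idx[1], lines[0]] = "SS"
    return GeneticMap(table)
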