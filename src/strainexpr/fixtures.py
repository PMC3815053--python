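"""Typed copies of the published summary tables, shipped as data files.

The study's raw expression and phenotype data are unpublished; what is
reproducible from print are the per-gene variance components, heritabilities,
one-tailed confidence bounds and phenotype correlations (67 mRNAs, 6
miRNAs), and the per-gene SNP/genotype tabulation.  Sub-threshold p-values
printed as "<0.001" parse to 5e-4 — only the 0.05 significance cut is ever
applied to them.  The mRNA table's one-tailed CI column contains a known
printing anomaly: across the four consecutive rows Mmp1a/Mmp3/Mmp13/Mmp9 the
printed bounds are cyclically shifted relative to the ICC formula; those
rows store both the printed and the formula-consistent value, flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["PaperFixture", "load_fixture"]

_P_BELOW_DETECTION = 5e-4  # numeric stand-in for printed "<0.001"


def _read(name: str) -> pd.DataFrame:
    with resources.files("strainexpr.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def _parse_p(col: pd.Series) -> pd.Series:
    return col.map(
        lambda v: _P_BELOW_DETECTION if isinstance(v, str) and v.startswith("<")
        else float(v)
    )


@dataclass
class PaperFixture:
    mrna: pd.DataFrame     # 67 genes: Vb, Vw, Vt, H2, ci95 (printed), p_strain, r/p × 2
    mirna: pd.DataFrame    # 6 miRNAs, same layout
    snps: pd.DataFrame     # per-gene SNP counts and RI genotypes

    @property
    def ri_lines(self) -> list[str]:
        return [c.removeprefix("gt_") for c in self.snps.columns
                if c.startswith("gt_")]


def load_fixture() -> PaperFixture:
    mrna = _read("table1_mrna.tsv")
    mrna["p_strain_printed"] = mrna["p_strain"]
    mrna["p_strain"] = _parse_p(mrna["p_strain"])
    mrna["ci_shifted"] = mrna["ci_shifted"].astype(bool)
    mrna = mrna.set_index("gene")

    mirna = _read("table2_mirna.tsv")
    mirna["p_strain_printed"] = mirna["p_strain"]
    mirna["p_strain"] = _parse_p(mirna["p_strain"])
    mirna = mirna.set_index("gene")

    snps = _read("table3_snps.tsv").set_index("gene")
    return PaperFixture(mrna, mirna, snps)
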