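"""Expression–phenotype association at the strain level.

Healing is scored per strain (ear-wound area healed in mm out of a 2-mm
punch; articular-cartilage regeneration grade), so correlations are Pearson
r between strain-mean expression and strain phenotype.  The p-value comes
from the t transform t = r sqrt(n-2)/sqrt(1-r^2); the directional (one-
tailed) convention is the default and the tail is recorded in every record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .heritability import VarianceDecomposition
from .normalize import StrainMeans

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeTable",
    "CorrelationRecord",
    "correlate",
    "dual_phenotype_selection",
    "assemble_summary",
]


@dataclass
class PhenotypeTable:
    """Per-strain healing phenotypes."""

    table: pd.DataFrame  # index: strain; columns: phenotype names

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("one row per strain required")
        if "ear_healing" in self.table.columns:
            v = self.table["ear_healing"].dropna()
            if ((v < 0) | (v > 2)).any():
                raise ValueError("ear_healing must lie in [0, 2] mm")

    @property
    def phenotypes(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class CorrelationRecord:
    gene: str
    phenotype: str
    r: float
    p: float
    n: int
    tail: str = "one"
    flagged: bool = False


def _pearson_p(r: float, n: int, tail: str) -> float:
    if n < 3 or not np.isfinite(r):
        return math.nan
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    if tail == "two":
        return 2.0 * float(stats.t.sf(abs(t), n - 2))
    return float(stats.t.sf(abs(t), n - 2))


def correlate(
    strain_means: StrainMeans,
    phenotypes: PhenotypeTable,
    tail: str = "one",
) -> list[CorrelationRecord]:
    """Pairwise-complete Pearson correlation per gene × phenotype."""
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    shared = strain_means.values.index.intersection(phenotypes.table.index)
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared strains, found {len(shared)}")
    expr = strain_means.values.loc[shared]
    phen = phenotypes.table.loc[shared]
    out: list[CorrelationRecord] = []
    for gene in expr.columns:
        for name in phen.columns:
            pair = pd.concat([expr[gene], phen[name]], axis=1).dropna()
            n = len(pair)
            if n < 3 or pair.iloc[:, 0].nunique() < 2 or pair.iloc[:, 1].nunique() < 2:
                out.append(CorrelationRecord(gene, name, math.nan, math.nan, n,
                                             tail, flagged=True))
                continue
            r = float(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1])
            out.append(CorrelationRecord(gene, name, r, _pearson_p(r, n, tail), n, tail))
    return out


def dual_phenotype_selection(
    records: list[CorrelationRecord], alpha: float = 0.05
) -> pd.DataFrame:
    """Genes significant (p <= alpha) for *both* phenotypes.

    Returns a frame indexed by gene (sorted) with each phenotype's r sign.
    """
    phenos = sorted({r.phenotype for r in records})
    if len(phenos) < 2:
        raise ValueError("records must cover both phenotypes")
    by_gene: dict[str, dict[str, CorrelationRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene, {})[rec.phenotype] = rec
    rows = []
    for gene in sorted(by_gene):
        recs = by_gene[gene]
        if all(
            p in recs and np.isfinite(recs[p].p) and recs[p].p <= alpha
            for p in phenos
        ):
            rows.append([gene] + [math.copysign(1, recs[p].r) for p in phenos])
    return pd.DataFrame(rows, columns=["gene", *[f"sign_{p}" for p in phenos]]
                        ).set_index("gene")


def assemble_summary(
    decomps: list[VarianceDecomposition],
    correlations: list[CorrelationRecord],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One row per gene: variance components, H2, CI, P, and r/P per phenotype.

    Mirrors the published heritability-and-correlation table layout; the
    significance 'bolding' is rendered as boolean flag columns at ``alpha``.
    Genes present in only one input get missing cells and a warning.
    """
    herit = pd.DataFrame(
        {
            "gene": [d.gene for d in decomps],
            "Vb": [d.Vb for d in decomps],
            "Vw": [d.Vw for d in decomps],
            "Vt": [d.Vt for d in decomps],
            "H2": [d.H2 for d in decomps],
            "CI95_one_tailed": [d.ci95_one_tailed_upper for d in decomps],
            "P": [d.p_strain for d in decomps],
        }
    ).set_index("gene")
    herit["H2_significant"] = herit["P"] < alpha

    corr = pd.DataFrame(
        [(c.gene, c.phenotype, c.r, c.p) for c in correlations],
        columns=["gene", "phenotype", "r", "p"],
    )
    wide = corr.pivot(index="gene", columns="phenotype")
    wide.columns = [f"{stat}_{pheno}" for stat, pheno in wide.columns]
    only = set(herit.index) ^ set(wide.index)
    if only:
        logger.warning("%d genes present in only one input", len(only))
    summary = herit.join(wide, how="outer")
    for c in [c for c in summary.columns if c.startswith("p_")]:
        summary[f"sig{c[1:]}"] = summary[c] <= alpha
    return summary.loc[[g for g in herit.index if g in summary.index]
                       + sorted(set(wide.index) - set(herit.index))]
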