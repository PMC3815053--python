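"""Broad-sense heritability of expression traits in inbred strain panels.

Fully inbred strains replicate a genotype, so the between-strain variance
component of a random-effects ANOVA captures all genetic variance and

    H2 = Vb / (Vb + Vw)

is a broad-sense heritability.  The estimator is method-of-moments on the
one-way ANOVA mean squares (not REML): with ``N`` strains, ``M`` mice and
``n_i`` mice in strain *i*,

    n0 = (M - sum(n_i^2) / M) / (N - 1)
    Vw = MS_within
    Vb = (MS_between - MS_within) / n0

Negative ``Vb`` (hence negative H2) is retained in point estimates — it is
informative about sampling noise around zero — but the estimate is truncated
at zero inside the interval computation.  The standard error of H2 treats it
as an intraclass correlation with ``k`` observations per group:

    SE(t) = (1 - t') (1 + (k - 1) t') sqrt(2 / (k (k - 1) (N - 1))),
    t' = max(t, 0)

and the one-tailed upper confidence bound is ``t' + z(1 - alpha) * SE``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import SampleDesign

__all__ = [
    "VarianceDecomposition",
    "PairwiseComparison",
    "anova_components",
    "fit_strain_anova",
    "heritability_interval",
    "tukey_hsd",
    "heritability_table",
]

#: one-tailed 95% normal quantile used throughout the reporting convention
Z_ONE_TAILED_95 = 1.645


@dataclass
class VarianceDecomposition:
    """Per-gene variance components and heritability summary."""

    gene: str
    Vb: float
    Vw: float
    H2: float
    k: float
    N: int
    SE_H2: float
    ci95_one_tailed_upper: float
    p_strain: float
    F: float = math.nan
    df_between: int = 0
    df_within: int = 0
    flagged: bool = False
    note: str = ""

    @property
    def Vt(self) -> float:
        return self.Vb + self.Vw

    def significant(self, alpha: float = 0.05) -> bool:
        return bool(np.isfinite(self.p_strain) and self.p_strain < alpha)


@dataclass
class PairwiseComparison:
    gene: str
    strain_a: str
    strain_b: str
    mean_diff: float
    p_adjusted: float
    reject: bool


def _group_values(y: pd.Series, design: SampleDesign) -> dict[str, np.ndarray]:
    strains = design.table.loc[y.index, "strain"]
    return {s: y[strains == s].to_numpy(dtype=float) for s in strains.unique()}


def anova_components(groups: Sequence[np.ndarray]) -> dict:
    """One-way random-effects ANOVA components from raw group arrays.

    Returns mean squares, the unbalanced coefficient ``n0``, variance
    components and the strain F-test.  Negative Vb is not clamped.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    N = len(groups)
    ns = np.array([len(g) for g in groups])
    M = int(ns.sum())
    if N < 2:
        raise ValueError("need at least two strains")
    if M == N:
        raise ValueError("all strains are singletons; within-strain variance inestimable")
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = N - 1, M - N
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    n0 = (M - float(np.sum(ns**2)) / M) / df_b
    Vw = ms_within
    Vb = (ms_between - ms_within) / n0
    if ms_within > 0:
        F = ms_between / ms_within
        p = float(stats.f.sf(F, df_b, df_w))
    else:
        # zero within variance: infinite F if any between spread, else undefined
        F = math.inf if ms_between > 0 else math.nan
        p = 0.0 if ms_between > 0 else math.nan
    return {
        "N": N,
        "M": M,
        "n0": n0,
        "ms_between": ms_between,
        "ms_within": ms_within,
        "df_between": df_b,
        "df_within": df_w,
        "Vb": Vb,
        "Vw": Vw,
        "F": F,
        "p": p,
    }


def heritability_interval(
    h2: float, k: float, N: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Intraclass-correlation SE and one-tailed upper confidence bound.

    ``k`` is the (effective) number of mice per strain, ``N`` the number of
    strains.  The point estimate is truncated at zero inside both the SE and
    the bound's centre, so a negative heritability still yields a positive
    upper bound (the estimate is compatible with zero).
    """
    if k <= 1 or N <= 1:
        raise ValueError("heritability interval needs k > 1 and N > 1")
    t = max(float(h2), 0.0)
    se = (1.0 - t) * (1.0 + (k - 1.0) * t) * math.sqrt(2.0 / (k * (k - 1.0) * (N - 1)))
    z = Z_ONE_TAILED_95 if alpha == 0.05 else float(stats.norm.ppf(1.0 - alpha))
    return se, t + z * se


def fit_strain_anova(
    y: pd.Series,
    design: SampleDesign,
    include_sex: bool = False,
    k: float | None = None,
    alpha: float = 0.05,
    gene: str = "",
) -> VarianceDecomposition:
    """Random-effects strain ANOVA for one gene's per-individual expression.

    ``y`` is indexed by individual id.  With ``include_sex`` the sex means are
    subtracted before the one-way fit (sex as a fixed effect, removed prior to
    the strain decomposition).  ``k`` defaults to M/N, the mean number of mice
    per strain.
    """
    y = y.dropna().astype(float)
    if include_sex:
        sex = design.table.loc[y.index, "sex"]
        y = y - y.groupby(sex).transform("mean") + y.mean()
    groups = _group_values(y, design)
    comp = anova_components(list(groups.values()))
    Vb, Vw = comp["Vb"], comp["Vw"]
    Vt = Vb + Vw
    k_eff = comp["M"] / comp["N"] if k is None else float(k)
    if Vt == 0:
        return VarianceDecomposition(
            gene=gene, Vb=Vb, Vw=Vw, H2=math.nan, k=k_eff, N=comp["N"],
            SE_H2=math.nan, ci95_one_tailed_upper=math.nan, p_strain=comp["p"],
            F=comp["F"], df_between=comp["df_between"], df_within=comp["df_within"],
            flagged=True, note="zero total variance; H2 undefined",
        )
    h2 = Vb / Vt
    se, upper = heritability_interval(h2, k_eff, comp["N"], alpha=alpha)
    return VarianceDecomposition(
        gene=gene, Vb=Vb, Vw=Vw, H2=h2, k=k_eff, N=comp["N"], SE_H2=se,
        ci95_one_tailed_upper=upper, p_strain=comp["p"], F=comp["F"],
        df_between=comp["df_between"], df_within=comp["df_within"],
    )


def tukey_hsd(
    y: pd.Series,
    design: SampleDesign,
    family_alpha: float = 0.05,
    gene: str = "",
) -> list[PairwiseComparison]:
    """All-pairs strain comparisons with studentized-range adjusted p-values.

    Uses the ANOVA's pooled MS_within; unbalanced pairs use the Tukey–Kramer
    standard error sqrt(MSw/2 * (1/n_i + 1/n_j)).
    """
    y = y.dropna().astype(float)
    groups = _group_values(y, design)
    comp = anova_components(list(groups.values()))
    msw, df_w, N = comp["ms_within"], comp["df_within"], comp["N"]
    names = sorted(groups)
    out: list[PairwiseComparison] = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ga, gb = groups[a], groups[b]
            diff = float(ga.mean() - gb.mean())
            se = math.sqrt(msw / 2.0 * (1.0 / len(ga) + 1.0 / len(gb)))
            if se == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, N, df_w))
            out.append(
                PairwiseComparison(gene, a, b, diff, p, p < family_alpha)
            )
    return out


def heritability_table(
    expr: "ExpressionTable",
    include_sex: bool = False,
    k: float | None = None,
    alpha: float = 0.05,
) -> list[VarianceDecomposition]:
    """Per-gene variance decomposition over a normalized expression table.

    Genes are processed in input column order; per-gene failures become
    flagged records rather than aborting the run.
    """
    records: list[VarianceDecomposition] = []
    for gene in expr.values.columns:
        y = expr.values[gene]
        try:
            records.append(
                fit_strain_anova(
                    y, expr.design, include_sex=include_sex, k=k, alpha=alpha,
                    gene=gene,
                )
            )
        except ValueError as exc:
            records.append(
                VarianceDecomposition(
                    gene=gene, Vb=math.nan, Vw=math.nan, H2=math.nan,
                    k=math.nan, N=0, SE_H2=math.nan,
                    ci95_one_tailed_upper=math.nan, p_strain=math.nan,
                    flagged=True, note=str(exc),
                )
            )
    return records


def decompositions_frame(records: list[VarianceDecomposition]) -> pd.DataFrame:
    """Tabular view mirroring the published table layout."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "Vb": [r.Vb for r in records],
            "Vw": [r.Vw for r in records],
            "Vt": [r.Vt for r in records],
            "H2": [r.H2 for r in records],
            "CI95_one_tailed": [r.ci95_one_tailed_upper for r in records],
            "P": [r.p_strain for r in records],
            "flagged": [r.flagged for r in records],
        }
    )
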