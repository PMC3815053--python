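"""Regression-residual normalization against reference genes.

Instead of expressing targets as ratios to housekeeping genes (which
amplifies measurement error and manufactures correlation with the
denominator), each target gene's signal is regressed on the reference-gene
signals (Gapdh, Hprt1, Actb in the original panel) by ordinary least squares
with an intercept, across all measurement rows jointly.  The residuals are
the normalized expression: whatever multiplicative well-loading or lysate-
amount factor inflates a well inflates the references identically, so the
regression removes it.  Residuals are averaged per individual afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .ingest import SampleDesign

logger = logging.getLogger(__name__)

__all__ = ["ExpressionTable", "StrainMeans", "residual_normalize", "strain_lsmeans",
           "ratio_compare"]


@dataclass
class ExpressionTable:
    """Per-individual normalized expression (residual units, mean ≈ 0)."""

    values: pd.DataFrame            # rows: individuals, columns: target genes
    design: SampleDesign
    coefficients: pd.DataFrame | None = None  # audit: per-gene OLS betas + R2

    def __post_init__(self) -> None:
        missing = [i for i in self.values.index if i not in self.design.table.index]
        if missing:
            raise ValueError(f"individuals absent from design: {missing[:3]}")


@dataclass
class StrainMeans:
    """Strain × gene least-square means (sex-adjusted when sex was modeled)."""

    values: pd.DataFrame            # rows: strains, columns: genes
    include_sex: bool = False


def residual_normalize(
    signals: pd.DataFrame,
    reference_genes: list[str],
    design: SampleDesign,
) -> ExpressionTable:
    """Normalize target signals by OLS residuals on reference-gene signals.

    ``signals`` is the collapsed (or per-well) long table with columns
    individual, probe, signal — one regression row per measurement unit.
    Rows missing any reference value are excluded (logged).  Residuals are
    averaged per individual.
    """
    if not reference_genes:
        raise ValueError("need at least one reference gene")
    wide_index = ["individual"] + (["well_id"] if "well_id" in signals.columns else [])
    wide = signals.pivot_table(index=wide_index, columns="probe", values="signal",
                               aggfunc="first", sort=False)
    wide.columns.name = None
    absent = [g for g in reference_genes if g not in wide.columns]
    if absent:
        raise ValueError(f"reference genes not in table: {absent}")
    targets = [c for c in wide.columns if c not in reference_genes]

    complete = wide[reference_genes].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("%d rows dropped: missing reference values", n_dropped)
    wide = wide[complete]
    if len(wide) <= len(reference_genes) + 1:
        raise ValueError("too few rows to fit the reference regression")

    X = np.column_stack([np.ones(len(wide))] +
                        [wide[g].to_numpy(dtype=float) for g in reference_genes])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name which reference columns are linearly dependent
        dep = []
        for j, g in enumerate(reference_genes, start=1):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                dep.append(g)
        raise ValueError(f"collinear reference genes: {dep or reference_genes}")

    resid = {}
    audit = []
    for gene in targets:
        y = wide[gene].to_numpy(dtype=float)
        ok = np.isfinite(y)
        beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        r = np.full(len(y), np.nan)
        r[ok] = y[ok] - X[ok] @ beta
        resid[gene] = r
        tss = float(((y[ok] - y[ok].mean()) ** 2).sum())
        rss = float((r[ok] ** 2).sum())
        audit.append([gene, *beta, 1.0 - rss / tss if tss > 0 else np.nan])
    resid_df = pd.DataFrame(resid, index=wide.index)
    individuals = resid_df.index.get_level_values("individual") if len(wide_index) > 1 \
        else resid_df.index
    per_ind = resid_df.groupby(individuals, sort=False).mean()
    per_ind = per_ind.loc[[i for i in design.table.index if i in per_ind.index]]
    coef = pd.DataFrame(
        audit, columns=["gene", "intercept", *reference_genes, "R2"]
    ).set_index("gene")
    return ExpressionTable(per_ind, design, coefficients=coef)


def strain_lsmeans(expr: ExpressionTable, include_sex: bool = False) -> StrainMeans:
    """Least-square mean expression per strain.

    With ``include_sex`` the model is gene ~ sex + strain (both fixed for
    estimation) and each strain's LS mean averages the two sex levels with
    equal weight; otherwise it is the arithmetic strain mean.  Strains with
    zero individuals are excluded with a warning.
    """
    design = expr.design.table.loc[expr.values.index]
    strains = sorted(design["strain"].unique())
    if not include_sex:
        means = expr.values.groupby(design["strain"]).mean().loc[strains]
        means.index.name = "strain"
        return StrainMeans(means, include_sex=False)

    sexes = sorted(design["sex"].dropna().unique())
    if len(sexes) < 2:
        logger.warning("only one sex present; LS means reduce to strain means")
    out = {}
    for gene in expr.values.columns:
        df = pd.DataFrame({
            "y": expr.values[gene].to_numpy(dtype=float),
            "strain": design["strain"].to_numpy(),
            "sex": design["sex"].to_numpy(),
        }).dropna()
        fit = smf.ols("y ~ C(strain) + C(sex)", data=df).fit()
        grid = pd.DataFrame(
            [(s, x) for s in strains for x in sexes], columns=["strain", "sex"]
        )
        pred = fit.predict(grid)
        out[gene] = pred.groupby(grid["strain"]).mean()
    values = pd.DataFrame(out).loc[strains]
    values.index.name = "strain"
    return StrainMeans(values, include_sex=True)


def ratio_compare(signals: pd.DataFrame, reference_genes: list[str]) -> pd.DataFrame:
    """Diagnostic-only ratio normalization (target / geometric mean of refs).

    Provided for comparison with the residual scheme; never on the default
    analysis path because ratios amplify measurement error.
    """
    wide = signals.pivot_table(index="individual", columns="probe", values="signal",
                               aggfunc="mean", sort=False)
    wide.columns.name = None
    refs = wide[reference_genes]
    if (refs <= 0).any().any():
        raise ValueError("ratio comparison requires positive reference signals")
    geo = np.exp(np.log(refs).mean(axis=1))
    targets = [c for c in wide.columns if c not in reference_genes]
    return wide[targets].div(geo, axis=0)
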