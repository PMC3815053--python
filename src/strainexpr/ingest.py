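"""Raw multiplex-signal ingest: background subtraction, replicate collapsing,
and technical repeatability.

A *well* is one hybridization reaction of one tissue lysate, read for every
probe in the panel simultaneously; technical replicates are separate wells of
the same lysate, and background wells contain no lysate.  The ingest
convention follows the bench workflow: average signals are noted, background
is subtracted, and only then are signals normalized downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SignalMatrix",
    "SampleDesign",
    "RepeatabilityRecord",
    "read_signal_table",
    "write_signal_table",
    "subtract_background",
    "collapse_technical_replicates",
    "repeatability",
]

SIGNAL_COLUMNS = ["well_id", "sample_id", "probe", "signal", "is_background"]
WELL_META = ["sample_id", "strain", "sex", "tech_rep", "is_background"]


@dataclass
class SampleDesign:
    """Individual → strain/sex assignment (the ANOVA factor labels)."""

    table: pd.DataFrame  # index: individual id; columns: strain, sex, n_tech_reps

    def __post_init__(self) -> None:
        if "strain" not in self.table.columns or "sex" not in self.table.columns:
            raise ValueError("design table needs 'strain' and 'sex' columns")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate individual id in design: {dup!r}")
        bad = set(self.table["sex"].dropna()) - {"F", "M"}
        if bad:
            raise ValueError(f"sex must be 'F' or 'M', got {sorted(bad)}")
        if self.table["strain"].isna().any():
            raise ValueError("every individual needs a strain")

    @property
    def strains(self) -> list[str]:
        return sorted(self.table["strain"].unique())

    @property
    def individuals(self) -> list[str]:
        return list(self.table.index)


@dataclass
class SignalMatrix:
    """Wells × probes signal matrix with per-well metadata.

    ``signals`` is indexed by well id; ``wells`` carries sample_id, strain,
    sex, tech_rep and the is_background flag per well.
    """

    signals: pd.DataFrame
    wells: pd.DataFrame
    background_subtracted: bool = False
    n_negative_after_subtraction: int = 0

    def __post_init__(self) -> None:
        if not self.signals.index.equals(self.wells.index):
            raise ValueError("signals and well metadata must share the well index")
        if self.signals.columns.has_duplicates:
            raise ValueError("duplicate probe names")
        if not np.isfinite(self.signals.to_numpy(dtype=float)).all():
            raise ValueError("non-finite signal values")
        fg = self.wells[~self.wells["is_background"]]
        if fg["sample_id"].isna().any():
            raise ValueError("non-background wells must map to an individual")

    @property
    def probes(self) -> list[str]:
        return list(self.signals.columns)

    def copy(self) -> "SignalMatrix":
        return SignalMatrix(
            self.signals.copy(), self.wells.copy(),
            self.background_subtracted, self.n_negative_after_subtraction,
        )


@dataclass
class RepeatabilityRecord:
    """Technical repeatability of one probe's assay.

    ``t_rep`` is the intraclass correlation of repeat measures: the variance
    between individuals as a proportion of the between- plus within-individual
    (between-replicate) variance.  A negative between-individual component is
    reported as-is.
    """

    gene: str
    t_rep: float
    between_individual_variance: float
    within_individual_variance: float


def read_signal_table(path, design: pd.DataFrame | None = None) -> SignalMatrix:
    """Read a long-format delimited signal table into a ``SignalMatrix``.

    Expected columns: well_id, sample_id, probe, signal, is_background, and
    optionally strain, sex, tech_rep (else taken from ``design`` keyed by
    sample_id).  Background wells leave sample_id empty.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str},
                     float_precision="round_trip")
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"signal table {path} missing columns: {missing}")
    bad = pd.to_numeric(df["signal"], errors="coerce").isna() & df["signal"].notna()
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(f"non-numeric signal at row {row}: {df.loc[row].to_dict()}")
    df["signal"] = pd.to_numeric(df["signal"])
    df["is_background"] = df["is_background"].map(
        lambda v: bool(v) if isinstance(v, (bool, np.bool_))
        else str(v).strip().lower() in ("true", "1", "yes")
    )

    # a well must belong to a single sample
    per_well = df.groupby("well_id")["sample_id"].nunique(dropna=True)
    multi = per_well[per_well > 1]
    if len(multi):
        raise ValueError(f"well {multi.index[0]!r} assigned to multiple individuals")

    wide = df.pivot_table(index="well_id", columns="probe", values="signal",
                          aggfunc="first", sort=False)
    wide = wide.loc[pd.unique(df["well_id"])]  # preserve row order of first appearance
    wide.columns.name = None

    meta_cols = [c for c in ["sample_id", "strain", "sex", "tech_rep", "is_background"]
                 if c in df.columns]
    meta = df.drop_duplicates("well_id").set_index("well_id")[meta_cols]
    meta = meta.loc[wide.index]
    if "tech_rep" in meta.columns:
        meta["tech_rep"] = pd.to_numeric(meta["tech_rep"],
                                         errors="coerce").astype("Int64")
    for col in WELL_META:
        if col not in meta.columns:
            meta[col] = pd.NA
    if design is not None:
        joined = meta.join(design, on="sample_id", rsuffix="_design")
        for col in ("strain", "sex"):
            if f"{col}_design" in joined.columns:
                meta[col] = meta[col].where(meta[col].notna(), joined[f"{col}_design"])
    return SignalMatrix(wide, meta[WELL_META])


def write_signal_table(m: SignalMatrix, path) -> None:
    """Write a ``SignalMatrix`` back to the documented long format."""
    long = (
        m.signals.reset_index(names="well_id")
        .melt(id_vars="well_id", var_name="probe", value_name="signal")
    )
    long = long.merge(m.wells.reset_index(names="well_id"), on="well_id")
    long = long.sort_values(["well_id", "probe"], kind="stable")
    cols = ["well_id", "sample_id", "strain", "sex", "tech_rep", "probe",
            "signal", "is_background"]
    long[cols].to_csv(path, sep="\t", index=False)


def subtract_background(m: SignalMatrix) -> SignalMatrix:
    """Subtract each probe's mean background-well signal from all sample wells.

    Negative results are retained (flooring at zero would bias low
    expressors under the translation-tolerant residual normalization) and
    counted in ``n_negative_after_subtraction``.
    """
    bg = m.signals[m.wells["is_background"]]
    if bg.empty:
        raise ValueError("no background wells present")
    if bg.isna().all().any():
        probe = bg.columns[bg.isna().all()][0]
        raise ValueError(f"probe {probe!r} has no background signal")
    corrected = m.signals.sub(bg.mean(axis=0), axis=1)
    fg_mask = ~m.wells["is_background"]
    n_neg = int((corrected[fg_mask] < 0).sum().sum())
    if n_neg:
        logger.warning("%d signals negative after background subtraction", n_neg)
    return SignalMatrix(corrected, m.wells.copy(), background_subtracted=True,
                        n_negative_after_subtraction=n_neg)


def collapse_technical_replicates(m: SignalMatrix) -> pd.DataFrame:
    """Average technical-replicate wells per individual × probe.

    Returns a long table (individual, strain, sex, probe, signal, n_reps).
    Individuals with no well for a probe get a missing value, which
    propagates downstream (pairwise-complete handling), never imputation.
    """
    fg = m.signals[~m.wells["is_background"]]
    meta = m.wells[~m.wells["is_background"]]
    stacked = fg.stack(future_stack=True).rename("signal").reset_index()
    stacked.columns = ["well_id", "probe", "signal"]
    stacked = stacked.merge(
        meta[["sample_id", "strain", "sex"]].reset_index(names="well_id"),
        on="well_id",
    )
    grouped = (
        stacked.groupby(["sample_id", "strain", "sex", "probe"], dropna=False,
                        sort=False)["signal"]
        .agg(signal="mean", n_reps="count")
        .reset_index()
        .rename(columns={"sample_id": "individual"})
    )
    n_missing = int(grouped["signal"].isna().sum())
    if n_missing:
        logger.warning("%d individual×probe cells missing after collapse", n_missing)
    return grouped


def repeatability(m: SignalMatrix) -> list[RepeatabilityRecord]:
    """Between- vs within-individual variance decomposition per probe.

    Same method-of-moments estimator as the heritability module, with the
    individual as the grouping factor and technical-replicate wells as the
    repeated measures.
    """
    from .heritability import anova_components  # shared estimator

    fg = m.signals[~m.wells["is_background"]]
    samples = m.wells.loc[fg.index, "sample_id"]
    counts = samples.value_counts()
    if len(counts) < 2:
        raise ValueError("repeatability needs at least two individuals")
    if (counts < 2).all():
        raise ValueError("all individuals single-replicate; within variance undefined")
    out = []
    for probe in fg.columns:
        groups = [g.dropna().to_numpy() for _, g in fg[probe].groupby(samples)]
        comp = anova_components(groups)
        vb, vw = comp["Vb"], comp["Vw"]
        t = vb / (vb + vw) if (vb + vw) > 0 else math.nan
        out.append(RepeatabilityRecord(probe, t, vb, vw))
    return out
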