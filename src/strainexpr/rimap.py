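"""Recombinant-inbred flanking-marker genotype inference.

Each RI line is a fixed mosaic of the two parental genomes (LL = both
chromosomes from the large parental line, SS = small, LS = residual
heterozygosity).  A gene's genotype in a line is read off the genetic map:
find the nearest informative marker at or left of the gene start and at or
right of the gene end; if both agree, that is the call; if they disagree the
gene straddles a recombination breakpoint and no genotype is assigned
(rendered "?" in reports).  A marker inside the gene decides directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["GeneticMap", "GenotypeCall", "infer_genotype", "genotype_matrix"]

VALID_GENOTYPES = {"LL", "SS", "LS"}


@dataclass
class GeneticMap:
    """Ordered markers per chromosome with per-line genotypes.

    ``table`` columns: chrom, marker, position, then one column per RI line
    holding LL/SS/LS (missing allowed, flagged and skipped at inference).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "marker", "position"}
        if not required <= set(self.table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        for chrom, sub in self.table.groupby("chrom"):
            pos = sub["position"].to_numpy()
            if (pos[1:] <= pos[:-1]).any():
                raise ValueError(f"markers not strictly ordered on {chrom}")
        bad = (
            self.table[self.lines]
            .apply(lambda c: ~(c.isin(VALID_GENOTYPES) | c.isna()))
            .any()
        )
        if bad.any():
            raise ValueError(f"invalid genotype codes in line(s) {list(bad[bad].index)}")

    @property
    def lines(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("chrom", "marker", "position")]

    def chromosome(self, chrom: str) -> pd.DataFrame:
        sub = self.table[self.table["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} absent from map")
        return sub.sort_values("position")


@dataclass
class GenotypeCall:
    gene: str
    line: str
    call: str  # LL | SS | LS | unassigned
    flank_left: str | None = None
    flank_right: str | None = None
    note: str = ""


def infer_genotype(
    gene: str,
    chrom: str,
    start: int,
    end: int,
    gmap: GeneticMap,
    line: str,
) -> GenotypeCall:
    """Nearest-informative-flank genotype call for one gene in one line."""
    if line not in gmap.lines:
        raise KeyError(f"line {line!r} not in map")
    sub = gmap.chromosome(chrom)
    geno = sub[["marker", "position", line]].dropna(subset=[line])
    n_skipped = len(sub) - len(geno)
    note = f"{n_skipped} missing markers skipped" if n_skipped else ""

    inside = geno[(geno["position"] >= start) & (geno["position"] <= end)]
    if len(inside):
        row = inside.iloc[0]
        return GenotypeCall(gene, line, row[line], row["marker"], row["marker"],
                            note="marker inside gene" + ("; " + note if note else ""))

    left = geno[geno["position"] <= start].tail(1)
    right = geno[geno["position"] >= end].head(1)
    if left.empty and right.empty:
        return GenotypeCall(gene, line, "unassigned",
                            note="no informative flanking markers")
    if left.empty or right.empty:
        row = (right if left.empty else left).iloc[0]
        side = "right" if left.empty else "left"
        return GenotypeCall(
            gene, line, row[line],
            flank_left=None if left.empty else row["marker"],
            flank_right=row["marker"] if left.empty else None,
            note=f"single-flank ({side}, chromosome end)"
            + ("; " + note if note else ""),
        )
    lrow, rrow = left.iloc[0], right.iloc[0]
    if lrow[line] == rrow[line]:
        return GenotypeCall(gene, line, lrow[line], lrow["marker"], rrow["marker"],
                            note=note)
    return GenotypeCall(gene, line, "unassigned", lrow["marker"], rrow["marker"],
                        note="flanking genotypes disagree" + ("; " + note if note else ""))


def genotype_matrix(genes: pd.DataFrame, gmap: GeneticMap) -> pd.DataFrame:
    """Genes × lines genotype calls with deterministic (sorted) order.

    ``genes`` columns: gene, chrom, start, end.  Per-gene failures become
    'error' cells rather than aborting; 'unassigned' renders as '?' when
    written by the pipeline.  The result carries per-line genotype counts in
    ``DataFrame.attrs['counts']``.
    """
    rows = {}
    for _, g in genes.sort_values("gene").iterrows():
        row = {}
        for line in gmap.lines:
            try:
                row[line] = infer_genotype(
                    g["gene"], g["chrom"], int(g["start"]), int(g["end"]), gmap, line
                ).call
            except KeyError as exc:
                row[line] = "error"
        rows[g["gene"]] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    counts = {
        line: out[line].value_counts().to_dict() for line in out.columns
    }
    out.attrs["counts"] = counts
    return out
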