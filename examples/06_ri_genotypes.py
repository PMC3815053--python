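"""Inferring RI-line genotypes from flanking genetic-map markers.

Each recombinant-inbred line is a mosaic of the two parental genomes (LL /
SS, occasionally LS).  A gene between two markers of equal genotype inherits
it; between discordant markers the call is withheld (rendered '?'), because
a recombination breakpoint lies somewhere in the interval.
"""

import pandas as pd

import strainexpr as sx

gmap = sx.simulate_genetic_map(n_lines=4, markers_per_chrom=12, seed=9)
print("genetic map, chr1 head:")
print(gmap.table.head(4).to_string(index=False))

genes = pd.DataFrame({
    "gene": ["gA", "gB", "gC"],
    "chrom": "chr1",
    "start": [2_000_000, 20_000_000, 40_000_000],
    "end": [2_050_000, 20_100_000, 40_050_000],
})
calls = sx.genotype_matrix(genes, gmap).replace("unassigned", "?")
print("\ngenotype matrix (genes × RI lines):")
print(calls.to_string())

# the simulated map forces a discordant first interval for line 1
first_two = gmap.chromosome("chr1").head(2)
line = gmap.lines[0]
mid = (int(first_two["position"].iloc[0]) + int(first_two["position"].iloc[1])) // 2
call = sx.infer_genotype("demo", "chr1", mid, mid + 1000, gmap, line)
print(f"\ngene between {first_two[line].iloc[0]}/{first_two[line].iloc[1]} "
      f"flanks in {line}: call = {call.call!r} ({call.note})")
print("'?' matches the published convention for unassignable genotypes.")
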