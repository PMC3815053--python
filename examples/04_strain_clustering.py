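"""Ward clustering of strains with bootstrap support and fold-change tiers.

Two groups of strains with strongly different expression profiles play the
roles of healers and nonhealers; Ward minimum-variance clustering recovers
the split and gene-resampling bootstrap quantifies its stability.
"""

import numpy as np
import pandas as pd

import strainexpr as sx

rng = np.random.default_rng(5)
strains = ["SM/J", "C57BL/6J", "LGXSM-5", "LGXSM-35",
           "LG/J", "LGXSM-6", "MRL/MpJ", "LGXSM-33"]
profile = rng.normal(0.0, 0.4, size=(8, 15))
profile[4:] += 2.0  # the second four strains share an expression shift
means = sx.StrainMeans(pd.DataFrame(profile, index=pd.Index(strains, name="strain")))

fc = sx.fold_change(means, reference="C57BL/6J")
print("Fold-change tiers vs C57BL/6J (1..7, 4 = no change), first 5 genes:")
print(fc.tiers.iloc[:, :5].to_string())

tree = sx.bootstrap_support(sx.standardize_genes(means.values), B=1000, seed=6)
print("\nDendrogram (Newick; internal labels = bootstrap support):")
print(tree.to_newick())

clusters = sx.classify_clusters(tree, 2)
print("\nTwo-cluster cut:")
for label in sorted(clusters.unique()):
    print(f"  cluster {label}:", sorted(clusters.index[clusters == label]))
print("\nA support of 1.0 on the top split mirrors the study's 100%")
print("bootstrap support (1000 iterations) separating healer from nonhealer")
print("strains.")
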