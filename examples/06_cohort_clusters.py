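"""Group a cross-sectional cohort into metabolic phenotypes by
signature-space clustering.

Generates a synthetic 120-sample cohort with independent latent AMPK and
HIF-1 activities, computes both activity signatures, and k-means-groups
the samples in the 2-D signature plane; each cluster is annotated by its
centroid quadrant.
"""

import numpy as np
import pandas as pd

from metabostate import (
    CohortDesign,
    activity_signature,
    default_gene_sets,
    generate_expression,
    signature_clusters,
)

gene_sets = default_gene_sets()
design = CohortDesign(n_subjects=120, seed=5)
expr, truth = generate_expression(design, gene_sets,
                                  rng=np.random.default_rng(5))

sig = pd.DataFrame({
    "ampk": activity_signature(expr, gene_sets.ampk_targets).scores,
    "hif1": activity_signature(expr, gene_sets.hif1_targets).scores,
})
res = signature_clusters(sig, k=4, seed=0)

counts = pd.Series(res.labels).value_counts().sort_index()
for cid, n in counts.items():
    c = res.centroids.loc[cid]
    print(f"cluster {cid}: {n:3d} samples, centroid "
          f"({c['ampk']:+.2f}, {c['hif1']:+.2f}) -> {res.quadrants[cid]}")

print("\nQuadrants of the (AMPK, HIF-1) plane map to phenotypes: (+,-) "
      "OXPHOS-like, (-,+) glycolysis-like, (+,+) hybrid, (-,-) low/low-"
      "like.  A real cohort clustered this way reveals what fraction of "
      "samples sit in the metabolically inactive corner.")
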