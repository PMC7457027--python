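"""Score a longitudinal treated cohort for AMPK/HIF-1 activity.

Generates a synthetic 7-subject expression time course in which 6
subjects' latent AMPK and HIF-1 activities both decline under treatment
(one subject declines only on the HIF-1 axis), then recovers that
structure with the PC1 activity signatures.
"""

import numpy as np

from metabostate import default_gene_sets, generate_patient_course, signature_trajectory

gene_sets = default_gene_sets()
expr, truth = generate_patient_course(gene_sets=gene_sets,
                                      rng=np.random.default_rng(0))

res = signature_trajectory(expr, truth[["subject", "time"]], gene_sets)
print(res.flags)
print(f"\nsubjects decreasing on both axes: {res.both_decrease_count} of "
      f"{len(res.flags)}")
print("\nEach row is one subject; a True flag means the signature at the "
      "last time point is below the first.  Both-axis decline is the "
      "transcriptomic fingerprint of drift toward the low/low state.")
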