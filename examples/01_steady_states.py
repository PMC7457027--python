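"""Find the stable metabolic states of the baseline circuit.

The AMPK:HIF-1:ROS circuit shipped with the package is multistable: the
same parameter set supports an OXPHOS state (high pAMPK, high glucose
oxidation/FAO), a glycolysis state (high HIF-1, high glycolytic rate), a
hybrid state (both regulators active) and a metabolically inactive
low/low state.
"""

import numpy as np

from metabostate import baseline_parameters, default_solver, find_steady_states

params = baseline_parameters()
recs = find_steady_states(params, rng=np.random.default_rng(0),
                          settings=default_solver())

print(f"{'stable':>6} {'A (nM)':>8} {'H (nM)':>8} {'G1':>7} {'G2':>7} {'F':>7}")
for r in recs:
    print(f"{str(r.stable):>6} {r.state.A:8.1f} {r.state.H:8.1f} "
          f"{r.rates.G1:7.3f} {r.rates.G2:7.3f} {r.rates.F:7.3f}")

print("\nEach stable row is one reachable metabolic phenotype; pathway "
      "rates are in mM/min.  High A with high G1/F is the OXPHOS state, "
      "high H with high G2 the glycolysis state, both high the hybrid, "
      "and the row with low A, H, G1 and G2 is the low/low state.")
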