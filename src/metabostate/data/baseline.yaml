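# Frozen baseline for the AMPK:HIF-1:ROS regulatory-metabolic circuit.
#
# Units: A, H in nM with production in nM/h; Rmt, Rnox in mM with
# production declared in mM/min (converted to mM/h on load); all
# degradation rates in 1/h; metabolic pathway rates G1/G2/F in mM/min.
#
# This parameterization was calibrated to place the circuit in a
# four-state multistable regime (OXPHOS "O", glycolysis "W", hybrid
# "W/O" and metabolically inactive "L/L") that is robust under the
# +/-25% random-parameter ensembles used downstream.  Two positive
# feedback loops provide the bistability of each axis: A -> (G1+F) ->
# mtROS -> A, and H -> noxROS -| degradation of H; mutual inhibition
# between A and H couples the axes.
baseline:
  A:    {g: 60.0, k: 0.3}           # pAMPK, nM/h and 1/h
  H:    {g: 25.0, k: 0.25}          # HIF-1; k_H is the scenario knob (0.25 / 0.45)
  Rmt:  {g_mm_per_min: 45.0, k: 300.0}   # mtROS; g is the scenario knob (45 / 30)
  Rnox: {g_mm_per_min: 2.0,  k: 60.0}    # noxROS
  rates:
    G1: {basal: 0.15, atp_yield: 29.0}   # glucose oxidation, mM/min
    G2: {basal: 0.30, atp_yield: 2.0}    # glycolysis
    F:  {basal: 0.08, atp_yield: 106.0}  # fatty-acid oxidation

topology:
  # regulatory layer
  - {source: H,    target: A,    arm: production,  x0: 250.0, n: 2, lam: 0.8}
  - {source: Rmt,  target: A,    arm: production,  x0: 30.0,  n: 4, lam: 4.0}
  - {source: A,    target: H,    arm: production,  x0: 500.0, n: 2, lam: 0.7}
  - {source: Rnox, target: H,    arm: degradation, x0: 4.5,   n: 4, lam: 0.2}
  - {source: OX,   target: Rmt,  arm: production,  x0: 0.55,  n: 4, lam: 5.0}
  - {source: H,    target: Rnox, arm: production,  x0: 220.0, n: 4, lam: 5.0}
  # metabolic layer (quasi-steady-state rate regulation)
  - {source: A, target: G1, arm: production, x0: 380.0, n: 4, lam: 6.0}
  - {source: H, target: G1, arm: production, x0: 250.0, n: 2, lam: 0.4}
  - {source: H, target: G2, arm: production, x0: 220.0, n: 4, lam: 6.0}
  - {source: A, target: G2, arm: production, x0: 380.0, n: 2, lam: 0.4}
  - {source: A, target: F,  arm: production, x0: 380.0, n: 4, lam: 6.0}

solver:
  n_starts: 100
  tol: 1.0e-9
  dedup_rtol: 1.0e-3
  stability_eig_threshold: -1.0e-8
  max_iter: 80
  box_lo: 1.0e-3
  box_hi: 1.0e2
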