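"""Divergent initial drug responses that converge to idling.

Simulates the three shipped presets of the three-state (H/I/L)
population model: same transition chain toward the low/low (L) state,
different death rates of the starting high/high (H) state.  Early
drug-induced proliferation (DIP) rates differ in sign; all converge to
near-zero net growth with ongoing division.
"""

from metabostate import dip_rate, is_idling, simulate, subclone_presets
from metabostate.population import (
    DEFAULT_HORIZON_HOURS,
    DEFAULT_INITIAL_FRACTIONS,
    division_death_fluxes,
)

print(f"{'preset':<10} {'early DIP/h':>12} {'late DIP/h':>12} "
      f"{'idling':>7} {'late div flux':>14}")
for name, preset in subclone_presets().items():
    tr = simulate(preset, DEFAULT_INITIAL_FRACTIONS, DEFAULT_HORIZON_HOURS)
    early = dip_rate(tr, (0.0, 48.0))
    late = dip_rate(tr, (750.0, 1000.0))
    div = division_death_fluxes(tr)["division"].iloc[-1]
    print(f"{name:<10} {early:>12.4f} {late:>12.5f} {str(is_idling(tr)):>7} "
          f"{div:>14.2f}")

print("\nEarly DIP rates are negative / ~zero / positive, late DIP rates "
      "all sit within 0.005/h of zero while the division flux stays "
      "positive: the populations idle -- they divide and die at matched "
      "rates rather than going quiescent.")
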