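"""Enzyme placement and metabolic channeling.

A three-enzyme pathway (influx -> M2 -> M3 -> M4 -> M5 -> export) is run
with identical totals, rates and seed but different enzyme placements:
ordered membrane stacks (A), an unordered membrane layer (B), uniform
enzymes (C), and a space-free Gillespie reference (D).  A small instance
for illustration; the acceptance suite runs the full comparison scale.
"""

import crowdcell as cc

results = {}
for mode in ("channel_A", "layer_B", "random_C", "wellmixed_D"):
    setup = cc.preset_channeling(mode, D_metabolite=1.0, cell_radius=1.5,
                                 n_enzymes_each=12_000, influx_rate=150.0,
                                 t_end=1.5, seed=7)
    series = setup.run()
    produced = cc.product_formed(setup, series, 1.0)
    m5_late = series.count("M5")[series.times >= 1.0].mean()
    results[mode] = (produced, m5_late)
    print(f"{mode:11s}: product formed by 1 s = {produced:5.0f}   "
          f"intracellular M5 late = {m5_late:6.2f}")

print("Membrane-localized enzymes (A, B) convert the incoming substrate "
      "near its entry point; with uniform enzymes (C) the final "
      "metabolite is made deep in the cell and accumulates "
      f"({results['random_C'][1]:.1f} molecules) compared to the "
      f"space-free reference ({results['wellmixed_D'][1]:.2f}).")
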