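"""Steady-state response profiles of the E/I rate model presets.

The approach preset (strong recurrent excitation, weak inhibition) rises
monotonically with input strength, with a rapid jump once the input pushes
the excitatory population past its soft threshold. The withdrawal preset
(weak excitation, strong inhibition) first decreases as inhibition engages,
then plateaus once the inhibitory population saturates.
"""

import numpy as np

from columnscope import ratemodel as rm

grid = np.linspace(0.0, 100.0, 101)
for name in ("approach", "withdrawal"):
    params = rm.preset(name)
    prof = rm.response_profile(params, grid)
    check = rm.response_profile(params, grid, solver="fixed_point")
    agree = np.abs(prof["r_e"] - check["r_e"]).max()
    print(f"\n{name} preset -> regime: {rm.classify_profile(prof)} "
          f"(two solvers agree to {agree:.1e})")
    for i in range(0, 101, 20):
        row = prof.iloc[i]
        print(f"  I = {row['I']:5.1f}: r_E* = {row['r_e']:7.2f}, "
              f"r_I* = {row['r_i']:8.2f}")

# r_E*(I) is the model's stand-in for the BOLD amplitude of a column as a
# face approaches (stronger input I ~ closer face).
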