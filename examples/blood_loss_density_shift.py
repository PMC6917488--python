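"""Simulate the canonical blood-loss parameter shift and map where density moves.

Applies D_v x4, alpha x2, v_c x0.9 (jointly and each in isolation) to the
baseline steady state for two days and reports how probability mass moves:
into the low-u tail (older cells retained by delayed clearance), out of the
distribution mode, and into the high-volume low-hemoglobin corner where new
cells appear (the production signature of the D_v rise).
"""

import json

from rbcpop.pipeline import RunConfig, run_fig3_scenario

report = run_fig3_scenario(RunConfig(shift_days=2.0))
for name in ("joint", "alpha_only", "Dv_only", "vc_only"):
    v = report["variants"][name]
    print(f"{name:11s}: low-u tail mass {v['low_u_mass_delta']:+.4f}  "
          f"mode mass {v['mode_mass_delta']:+.4f}  "
          f"young-corner relative change {100 * v['young_corner_rel_delta']:+.1f}%")
print("\nPositive low-u deltas = older cells accumulating below the clearance "
      "threshold; the D_v-only young-corner rise is the early production signature.")
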