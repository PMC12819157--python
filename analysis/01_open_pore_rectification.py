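#!/usr/bin/env python
"""Open-pore IV curves and rectification versus lumen-charge position.

Computes the IV curves of the three shipped pore configurations (wt-like,
neutral lumen, single mid-pore ring), their rectification factors beta at
+/-100 mV, and a scan of beta as a single charged ring (either sign) is moved
along the pore axis.  The scan reproduces the hallmark of charge-controlled
rectification: the strongest effect comes from charges near -- but not at --
the pore mouths, and the neutral pore is ohmic to numerical precision.

Writes results/iv_curves.tsv and results/beta_position_scan.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from aerogate.pore_transport import (
    charge_position_scan,
    iv_curve,
    rectification_factor,
)
from aerogate.synthetic_data import load_pore

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

sweep = np.linspace(-0.2, 0.2, 81)
frames = []
for name in ("wt_like", "neutral", "single_ring"):
    pore = load_pore(name)
    iv = iv_curve(pore, sweep)
    beta = rectification_factor(iv)
    g = iv.interp(0.1) / 0.1
    print(f"{name:12s}  G(+100 mV) = {g * 1e9:6.3f} nS   beta = {beta:+.4f}")
    frames.append(pd.DataFrame({"pore": name, "voltage_V": iv.voltages,
                                "current_A": iv.currents}))
pd.concat(frames).to_csv(OUT / "iv_curves.tsv", sep="\t", index=False)

positions = np.linspace(0.0, 10.0, 41)
neutral = load_pore("neutral")
scan = pd.DataFrame({
    "z_nm": positions,
    "beta_negative_ring": charge_position_scan(neutral, -1, positions),
    "beta_positive_ring": charge_position_scan(neutral, +1, positions),
})
scan.to_csv(OUT / "beta_position_scan.tsv", sep="\t", index=False)

bn = scan["beta_negative_ring"].to_numpy()
peak = positions[np.argmax(np.abs(bn))]
print(f"\nbeta(z) scan: strongest rectification from a ring at z = {peak:.2f} nm "
      f"(|beta| = {np.max(np.abs(bn)):.3f}); at the mouth itself "
      f"|beta| = {abs(bn[0]):.3f} -- near-mouth charges dominate, "
      "mouth charges act mostly on the reservoir.")
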