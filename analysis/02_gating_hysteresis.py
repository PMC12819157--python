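#!/usr/bin/env python
"""Ensemble gating under a 0.1 Hz sinusoid: the hysteresis-loop experiment.

Simulates 26 wt-like negative-gating pores through 50 sweep cycles of the
0.1 Hz / 200 mV sinusoid, then runs the full a.c. analysis: per-cycle pore
count, per-pore normalized loop, closed-state probability p(phase), closing
rates k_X per polarity, and the rectification factor from the pre-gating
branch.  The recovered quantities are compared against the generating model
(the rate-equation oracle).

Writes results/hysteresis_loop.tsv and results/gating_summary.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from aerogate.gating_kinetics import closed_probability_ode, closing_rate_at
from aerogate.synthetic_data import generate_scenario, load_scenario
from aerogate.trace_analysis import analyze, normalized_loop

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

cfg = load_scenario("wt_fig2c")
open_iv = cfg.open_iv()
trace = generate_scenario(cfg, open_iv=open_iv)
summary = analyze(trace, open_iv, cfg.protocol)
loop = normalized_loop(trace, open_iv, cfg.protocol)

t, v = cfg.protocol.samples()
one = t < cfg.protocol.period
_, p_ode = closed_probability_ode(cfg.rate_model, (t[one], v[one]))
k_oracle = float(np.max(np.asarray(closing_rate_at(cfg.rate_model, v[one]))
                        * (1 - p_ode)))

pd.DataFrame({
    "phase": summary.phase,
    "voltage_V": summary.voltage,
    "normalized_current": loop["ratio"],
    "p_closed": summary.p,
    "p_closed_ode": np.interp(summary.phase * cfg.protocol.period, t[one], p_ode),
}).to_csv(OUT / "hysteresis_loop.tsv", sep="\t", index=False)

doc = {
    "n_pores_true": cfg.n_pores,
    "n_pores_estimated": summary.n_pores_mean,
    "n_cycles": summary.n_cycles,
    "k_x_negative_per_s": summary.k_x_negative,
    "k_x_positive_per_s": summary.k_x_positive,
    "k_x_oracle_per_s": k_oracle,
    "beta_recovered": summary.beta,
    "beta_open_pore": trace.ground_truth["beta_open_pore"],
}
(OUT / "gating_summary.json").write_text(json.dumps(doc, indent=1))

print(f"N_p estimated {summary.n_pores_mean:.2f} (true {cfg.n_pores}); "
      f"{summary.n_cycles} cycles retained")
print(f"k_X(-) = {summary.k_x_negative:.3f} /s  vs rate-equation oracle "
      f"{k_oracle:.3f} /s;  k_X(+) = {summary.k_x_positive:.3f} /s "
      "(no positive gating, as configured)")
print(f"beta recovered {summary.beta:+.4f} vs open-pore "
      f"{trace.ground_truth['beta_open_pore']:+.4f}")
print("The loop is pinched at the origin and hysteretic only in the "
      "negative half -- the memristive signature of polarity-specific gating.")
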