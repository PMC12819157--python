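# aerogate

Nonlinear ion transport in β-barrel protein nanopores: open-pore
rectification from lumen charge, voltage-driven stochastic gating, and the
alternating-voltage analysis that quantifies both.

β-barrel nanopores (aerolysin, α-haemolysin, MspA) are the workhorses of
single-molecule sensing, yet their ionic transport is strongly nonlinear:
the open-pore current rectifies between voltage polarities, and beyond a
critical voltage the pore stochastically collapses into a low-conductance
"gated" state. `aerogate` is a Python package for scientists who want to
model, simulate and analyze these behaviours quantitatively:

- **`aerogate.pore_transport`** — 1D steady-state electrodiffusion through a
  cylindrical pore decorated with screened charged-residue rings. Exact
  flux quadrature J_s = D_s c₀ (e^{z_s eV/kT} − 1) / ∫ e^{W_s(z)} dz gives IV
  curves, concentration profiles, and the rectification factor
  **β = (I₊ − |I₋|)/(I₊ + |I₋|)** at ±100 mV.
- **`aerogate.gating_kinetics`** — two-state stochastic gating with a hard
  critical voltage V_c, exponential voltage acceleration of closing, and a
  heterogeneous gated state (each closing event draws a conductance ratio ε
  from a truncated normal, mean 0.14). Simulates single pores and
  ensembles under arbitrary protocols: memristive hysteresis loops,
  ergodicity comparisons, synaptic potentiation/depression pulse trains.
- **`aerogate.trace_analysis`** — the ensemble a.c. pipeline: per-cycle pore
  count N_p by low-voltage regression, per-pore normalized loops, the
  closed-state probability **p = (1 − I_ens/I_O)/(1 − ε)**, the closing rate
  **k_X = max dp/dt** per polarity, and β; plus two-level segmentation of
  constant-voltage traces.
- **`aerogate.md_current`** — ionic current from framewise ion trajectories,
  I(t) = (1/(Δt·L_p)) Σ Q_ion Δz_ion, with a cumulative-charge regression
  for the average and a drift-diffusion generator for validation.
- **`aerogate.synthetic_data`** — named protocols and fully seeded scenarios
  with ground-truth sidecars.

## Worked example

```python
import numpy as np
from aerogate.pore_transport import iv_curve, rectification_factor
from aerogate.synthetic_data import load_pore, load_scenario, generate_scenario
from aerogate.trace_analysis import analyze

# open-pore IV of a wild-type-like pore (negative ring near the trans mouth)
pore = load_pore("wt_like")
iv = iv_curve(pore, np.linspace(-0.2, 0.2, 81))
print(f"G = {iv.interp(0.1) / 0.1 * 1e9:.2f} nS, beta = {rectification_factor(iv):+.3f}")

# simulate 26 gating pores for 50 cycles of a 0.1 Hz sinusoid, then analyze
cfg = load_scenario("wt_fig2c")
trace = generate_scenario(cfg)
summary = analyze(trace, cfg.open_iv(), cfg.protocol)
print(f"N_p = {summary.n_pores_mean:.2f}, k_X(-) = {summary.k_x_negative:.2f} /s, "
      f"beta = {summary.beta:+.3f}")
```

prints

```
G = 1.92 nS, beta = -0.145
N_p = 26.01, k_X(-) = 2.11 /s, beta = -0.145
```

i.e. the analysis recovers the true pore count (26), the rectification of
the generating transport model, and a closing rate within a few percent of
the rate-equation maximum max_t[k_close(V(t))(1 − p(t))] = 2.04 /s.

The same machinery is exposed on the command line (`aerogate iv`, `beta`,
`gate-sim`, `analyze`, `generate`, `synapse`) and as narrative drivers under
`analysis/` (`01_open_pore_rectification.py` … `05_md_current.py`), which
write their tables to `results/`.

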