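# Methods

`aerogate` models nonlinear ion transport through β-barrel protein nanopores
(aerolysin-like: a roughly cylindrical lumen of ~0.7 nm radius and ~10 nm
length in 1 M KCl) at three levels: a continuum electrodiffusion model of the
*open* pore, a stochastic two-state kinetic model of voltage-driven *gating*,
and the analysis pipeline that extracts gating observables from alternating-
voltage recordings. A fourth component estimates ionic current from framewise
ion trajectories of the kind produced by atomistic simulation. A synthetic-
data module ties the first two together into fully seeded, ground-truthed
recordings on which the analysis pipeline can be validated end to end.

## Open-pore electrodiffusion (`pore_transport`)

The pore is a cylinder of radius *a* and length *L*; *z* = 0 is the cis
entrance, *z* = *L* the trans entrance, positive voltage drives cations from
cis to trans, and positive current is cation flux cis→trans. Charged residue
rings on the wall (valence *q*, multiplicity *m*, axial position *z_i*)
create an on-axis screened-Coulomb energy landscape for each ion species
*s* ∈ {cation, anion} (units of kT):

    W_s(z) = z_s eV (1 − z/L) / kT  +  Σ_i z_s q_i m_i ℓ_B exp(−d_i/λ) / d_i,
    d_i = sqrt((z − z_i)² + a²),

with Bjerrum length ℓ_B = 0.7 nm and screening length λ defaulting to the
Debye length of the electrolyte (0.30 nm in 1 M at 298 K). The applied
potential is a uniform field across the pore; access resistance and Donnan
edge potentials are neglected. Potentials are clipped at ±50 kT (with a
warning) to avoid overflow.

The steady-state Nernst–Planck flux through a 1D landscape has the exact
quadrature solution

    J_s = D_s c₀ (e^{z_s eV/kT} − 1) / ∫₀ᴸ e^{W_s(z)} dz,

evaluated with composite Simpson quadrature on a uniform grid (512 points by
default; doubling the grid changes currents by ~1e-10 relative). The
boundary Boltzmann factors carry only the *applied* potential: the reservoirs
stay equilibrated with bulk, so a ring potential that leaks past a pore mouth
belongs to the interior integral, not to the Dirichlet data. This choice is
what reproduces the experimental observation that charges near — but not
exactly at — a pore mouth dominate rectification: a mouth charge reshapes the
reservoir, not the pore. For rings more than a few screening lengths inside
the pore the two conventions are identical. Total current is
I = πa² e (J₊ − J₋).

Concentration profiles follow from the same solution,
c_s(z) = e^{−W_s}[c₀ e^{z_s eV/kT} − (J_s/D_s)∫₀ᶻ e^{W_s}], and show the
mechanism of rectification directly: ions accumulate downstream of potential
wells and upstream of barriers, so the lumen ion content — and the
conductance — depends on the polarity of the driving field.

Exact consequences used as tests: a charge-free pore is ohmic with
conductance σπa²/L, σ = N_A e²c₀(D₊+D₋)/kT (2.3 nS for the default geometry
in 1 M KCl, i.e. the "2 nS bulk cylinder" to one digit); I(V; q) = −I(−V; −q)
for equal diffusivities; mirroring all charges point-reflects the IV curve;
mirror-symmetric charge sets cannot rectify. The rectification factor is
β = (I₊ − |I₋|)/(I₊ + |I₋|) with I± read at ±100 mV by interpolation.

The model deliberately omits 3D electrostatics, dielectric self-energy,
ion–ion correlations and specific binding. One visible consequence: absolute
conductances of charged pores sit only slightly below the bulk-cylinder
value, whereas measured β-barrel pores fall short of it severalfold. The
package therefore treats conductance *ratios* and the sign/shape of β as the
meaningful outputs, not absolute conductances of particular mutants.

## Two-state gating (`gating_kinetics`)

Gating is modelled phenomenologically as a memoryless two-state process per
pore. Closing is activated only beyond a critical voltage V_c of the pore's
gating polarity, with exponential voltage acceleration:

    k_close(V) = A exp((|V| − V_c)/v_e)   for matching polarity and |V| > V_c,
    k_close = 0 otherwise.

(The functional form above V_c is a modelling choice; only the hard threshold
and the monotone acceleration matter for the behaviours tested.) Reopening
proceeds at a constant rate k_open wherever the voltage does not hold the
pore shut: for a polarity-specific gater the condition is one-sided (a
negative gater reopens whenever V > −V_w for a window width V_w), so that a
moderately negative holding bias (−90 mV, with V_w = 50 mV and V_c = 100 mV)
neither closes nor opens pores while positive pulses reopen them — the
regime the synaptic pulse protocols exploit. For polarity "both"/"none" the
window is symmetric in |V|.

The closed state is not one conductance level: every closing event draws a
fresh gated/open conductance ratio ε from a truncated normal on (0, 1) with
mean 0.14 and sd 0.05 — the gated state conducts 14% of the open-pore
current on average, with large event-to-event spread. The sd is a
phenomenological placeholder (overridable); the mean is the quantity the
analysis pipeline assumes and recovers.

Ensembles are simulated by per-step Bernoulli switching with probability
1 − e^{−k dt} per sample step, realized *exactly* by inverse-sampling the
cumulative per-step hazard (a searchsorted per event rather than a draw per
step), which makes traces bit-reproducible from the seed at any ensemble
size. If max(k)·dt would exceed 0.05 the state evolution runs on an
internally refined grid. Ensemble current is Σ pores of the open-pore IV
current at the instantaneous voltage (closed pores scaled by their ε_i) plus
additive Gaussian noise. The ensemble-mean closed probability obeys
dp/dt = k_close(V)(1−p) − k_open(V)p, integrated with an exact exponential
update per step; the Monte Carlo ensemble agrees with this rate equation
within binomial sampling error, which is the simulator's primary invariant.

## a.c. analysis (`trace_analysis`)

The pipeline mirrors how ensemble gating recordings are quantified:

1. **Cycle segmentation.** Periodic recordings are split at protocol phase
   zero-crossings and resampled to a 2048-point phase grid.
2. **Pore count.** Within |V| < 50 mV (where no gating occurs) each cycle's
   current is regressed on the single-pore open IV; the slope is N_p.
   Cycles with N_p ≤ 0 or R² < 0.5 are excluded — a numeric proxy for the
   experimental exclusion of mixed-orientation insertions and unstable
   membranes.
3. **Normalization.** Retained cycles are divided by their N_p and averaged
   with weights N_p; dividing by the single-pore open current gives the
   normalized ensemble current, which under the two-state assumption equals
   1 − p(1 − ε).
4. **Closed probability.** p = (1 − I_ens/I_O)/(1 − ε) with ε = 0.14 assumed.
   The ratio is ill-defined near V = 0, so samples with |V| < 20 mV are
   masked (the width is a package default; it is not dictated by the data
   model). Reported p is clipped to [0, 1]; the raw values are kept for QC.
5. **Closing rate.** k_X per polarity is the maximum of dp/dt over the
   rising-|V| part of the cycle, with the derivative from a second-order
   local-polynomial (Savitzky–Golay) smoother, window 1/64 cycle — wide
   enough to control noise amplification, narrow enough that the logistic
   max-slope benchmark 1/(4τ) is recovered within 5%. Masked samples plus a
   half-window margin are excluded from the maxima; k_X is reported in 1/s.
6. **Rectification.** β is read from the rising-|V| (pre-gating) branches of
   the per-pore loop at ±100 mV, because the return branch of a gating cycle
   is conductance-suppressed; for non-gating recordings both branches agree
   and β matches the transport model to ~1e-3.

For constant-voltage recordings, `level_segmentation` splits the current
histogram at the minimum between its two highest modes (fallback: midpoint of
extreme quantiles), keeps contiguous runs ≥ 5 ms as levels, labels the family
with the larger |mean| as open, and reports per-event gated/open ratios.

**Ergodicity metric.** The time-average/ensemble-average comparison reduces
both recordings to per-pore normalized loops, smooths both with the same
1/64-cycle local-quadratic window, and takes the maximum absolute difference
outside the ±20 mV mask. Smoothing is part of the metric's definition: raw
50-sample averages carry ~0.09 binomial noise at p = 0.5, which would swamp
the 0.05 equivalence tolerance regardless of whether gating is ergodic. The
shipped ergodicity scenario uses a sharp gater whose closing/reopening time
jitter (~20 ms/~12 ms) lies well inside the 156 ms smoothing window at
0.1 Hz, so the smoothed comparison is informative; a 40 mV critical-voltage
mismatch between the two sides blows the discrepancy past 0.9.

## Trajectory current (`md_current`)

For framewise ion snapshots the instantaneous current is the charge-weighted
axial displacement of ions inside the lumen,
I(t) = (1/(Δt L_p)) Σ Q_ion[z_ion(t+Δt) − z_ion(t)], with Δt = 0.2 ns and
L_p = 9 nm by default; ions are counted when inside the lumen bounds at the
first frame of the pair (configurable to "both frames"), and ions absent
from either frame contribute nothing. The average current is the slope of a
linear regression of cumulative transferred charge against time, with an
optional equilibration trim. A full translocation transfers exactly one
elementary charge (telescoping identity), and the drift-diffusion generator
(biased walks with reinjection under fresh ion ids, so wrap jumps never enter
the sum) reproduces the analytic I = N e v/L_p. Periodic-box unwrapping of
real simulation output is out of scope; trajectories are exchanged as plain
TSV with a JSON header.

## Synthetic data (`synthetic_data`)

Protocol presets encode the study conditions: triangle 2 Hz ±200 mV
(open-pore IV extraction), sine 0.1 Hz ±200 mV (gating hysteresis; 50 cycles
for cycle-averaged loops), and the pulse trains +110 mV/5 ms and
−110 mV/10 ms with 10 ms waits and a −90 mV baseline, 30 pulses (synaptic
potentiation/depression). Periodic protocols sample at 10 kHz, pulse trains
at 50 kHz. Shipped scenarios: `dc_gater` (one wt-like pore at −160 mV,
closing at ~1 /s, no reopening, 2% noise — the closed-state-ratio recovery
experiment), `wt_fig2c` (26 negative-gating pores, V_c = 120 mV, 50 cycles),
`ergodicity` (sharp gater, see above), `neutral_fig2a` (6 ohmic pores), and
`synapse` (200 strong gaters, V_c = 100 mV, fast closing/reopening). Every
generated trace carries a ground-truth sidecar (rate-equation p(t), realized
closed fractions, all ε draws, open-pore β, N_p) sufficient to score any
analysis without rerunning the simulator; noise sd 0 reproduces the
simulator output exactly.

Scenario rate parameters are not measured quantities: the critical voltages,
prefactors and e-fold widths are chosen once so that the simulated
phenomenology matches the qualitative record (negative-polarity gating well
developed within a 0.1 Hz cycle, pinched hysteresis, baseline-inert synapse
operation) while every quantitative claim in the tests is made against the
generating model itself, not against those choices.

What the synthetic data do *not* emulate: capacitive/RC membrane transients,
1/f noise, baseline drift, pore insertion/loss during a recording, and
mixed-orientation insertions. Passing the round-trip tests therefore shows
the pipeline is correct and well-calibrated under its stated assumptions,
not that it is robust to every artefact of real recordings.

## Problem sizes

Defaults used by the test suite and the acceptance script: 200 five-second
d.c. traces at 5 kHz for the closed-state-ratio recovery; 50 cycles at
10 kHz for the hysteresis round trip; 50 cycles / 50 pores for the
ergodicity comparison; 10 seeds × 1500 frames × 60 ions for the trajectory
estimator; 10 seeds × 30 pulses × 200 pores for the synapse curves. These
sizes put the statistical tolerances (3× standard error and the stated
percentage bands) comfortably above discretization error while keeping the
whole suite in the tens of seconds.
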