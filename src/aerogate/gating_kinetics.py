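"""Voltage-driven two-state gating of single pores and pore ensembles.

Gating is described at the kinetic level: each pore is either open or closed
(gated), closing is activated only beyond a critical voltage ``V_c`` of the
pore's gating polarity with a rate that grows exponentially with overvoltage,

    k_close(V) = closing_prefactor * exp((|V| - V_c) / closing_efold_voltage),

and reopening proceeds at a constant rate once the driving voltage is released.
For a polarity-specific gater the reopening condition is one-sided: a pore
that closes at negative voltages reopens whenever the voltage is not strongly
negative (``V > -reopening_window``), which makes small and opposite-polarity
voltages both restorative -- this is what lets positive pulses re-open a
negatively gated ensemble while a moderately negative holding bias leaves it
untouched.  For ``polarity`` "both" or "none" the window is symmetric in |V|.

The closed state is not a single conductance level: each closing event draws a
fresh gated/open conductance ratio ``eps`` from a truncated normal
distribution (mean 0.14 by default), reproducing the observed diversity of
closed-state currents.

Ensemble simulation uses per-step exponential-probability Bernoulli switching
(p = 1 - exp(-k dt) per sample step), realized exactly by inverse-sampling the
cumulative per-step hazard, so traces are reproducible bit-for-bit from the
seed at any ensemble size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.stats import truncnorm

from .pore_transport import IVCurve
from .protocols import VoltageProtocol
from .traces import CurrentTrace

Polarity = Literal["negative", "positive", "both", "none"]

#: per-step switching probability ceiling enforced by internal grid refinement
MAX_RATE_DT = 0.05


class GatingError(ValueError):
    """Invalid gating model or simulation request."""


@dataclass(frozen=True)
class RateModel:
    """Voltage-dependent closing/opening rates of a two-state gating pore."""

    polarity: Polarity = "negative"
    critical_voltage: float = 0.12  # V, active polarity
    closing_prefactor: float = 2.0  # 1/s, rate right at V_c
    closing_efold_voltage: float = 0.04  # V
    opening_rate: float = 30.0  # 1/s when reopening is allowed
    reopening_window: float = 0.08  # V
    critical_voltage_positive: Optional[float] = None  # 'both' only, defaults to V_c

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive", "both", "none"):
            raise GatingError(f"unknown polarity {self.polarity!r}")
        if self.critical_voltage <= 0:
            raise GatingError("critical_voltage must be positive")
        for name in ("closing_prefactor", "closing_efold_voltage", "opening_rate",
                     "reopening_window"):
            if getattr(self, name) < 0:
                raise GatingError(f"{name} must be >= 0")

    @property
    def vc_positive(self) -> float:
        return (self.critical_voltage_positive
                if self.critical_voltage_positive is not None
                else self.critical_voltage)


def closing_rate_at(model: RateModel, voltage) -> np.ndarray | float:
    """Closing rate k_close(V) in 1/s; zero below V_c or at the wrong polarity."""
    v = np.asarray(voltage, float)
    k = np.zeros_like(v)
    if model.polarity in ("negative", "both") and model.closing_prefactor > 0:
        active = (v < 0) & (np.abs(v) > model.critical_voltage)
        k = np.where(
            active,
            model.closing_prefactor
            * np.exp((np.abs(v) - model.critical_voltage)
                     / model.closing_efold_voltage),
            k,
        )
    if model.polarity in ("positive", "both") and model.closing_prefactor > 0:
        active = (v > 0) & (v > model.vc_positive)
        k = np.where(
            active,
            model.closing_prefactor
            * np.exp((v - model.vc_positive) / model.closing_efold_voltage),
            k,
        )
    return k if np.ndim(voltage) else float(k)


def opening_rate_at(model: RateModel, voltage) -> np.ndarray | float:
    """Reopening rate k_open(V) in 1/s (one-sided window for polarity gaters)."""
    v = np.asarray(voltage, float)
    if model.polarity == "negative":
        allowed = v > -model.reopening_window
    elif model.polarity == "positive":
        allowed = v < model.reopening_window
    else:
        allowed = np.abs(v) < model.reopening_window
    k = np.where(allowed, model.opening_rate, 0.0)
    return k if np.ndim(voltage) else float(k)


@dataclass(frozen=True)
class ClosedStateDistribution:
    """Distribution of the gated/open conductance ratio eps on (0, 1).

    Truncated normal; the default mean 0.14 encodes that the gated state
    conducts 14% of the open-pore current on average, with substantial
    event-to-event spread (sd 0.05).
    """

    mean_ratio: float = 0.14
    sd_ratio: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.mean_ratio < 1:
            raise GatingError("mean_ratio must lie in (0, 1)")
        if self.sd_ratio < 0:
            raise GatingError("sd_ratio must be >= 0")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sd_ratio == 0:
            return np.full(size, self.mean_ratio)
        a = (0.0 - self.mean_ratio) / self.sd_ratio
        b = (1.0 - self.mean_ratio) / self.sd_ratio
        return truncnorm.rvs(a, b, loc=self.mean_ratio, scale=self.sd_ratio,
                             size=size, random_state=rng)


def closed_probability_ode(
    model: RateModel,
    protocol: VoltageProtocol | tuple[np.ndarray, np.ndarray],
    p0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-mean closed probability p(t) under the protocol.

    Integrates dp/dt = k_close(V)(1-p) - k_open(V) p with rates piecewise
    constant over each sample step (exact exponential update per step).
    Returns (time, p).
    """
    if not 0.0 <= p0 <= 1.0:
        raise GatingError("p0 must lie in [0, 1]")
    t, v = protocol.samples() if isinstance(protocol, VoltageProtocol) else protocol
    kc = np.asarray(closing_rate_at(model, v))
    ko = np.asarray(opening_rate_at(model, v))
    if not (np.all(np.isfinite(kc)) and np.all(np.isfinite(ko))):
        raise GatingError("non-finite gating rates")
    dt = np.diff(t)
    p = np.empty_like(kc)
    p[0] = p0
    ktot = kc + ko
    with np.errstate(invalid="ignore"):
        pinf = np.where(ktot > 0, kc / np.where(ktot > 0, ktot, 1.0), 0.0)
    decay = np.exp(-ktot[:-1] * dt)
    for n in range(t.size - 1):
        if ktot[n] > 0:
            p[n + 1] = pinf[n] + (p[n] - pinf[n]) * decay[n]
        else:
            p[n + 1] = p[n]
    return t, np.clip(p, 0.0, 1.0)


def _per_step_log_survival(k: np.ndarray, dt: float) -> np.ndarray:
    """Cumulative hazard ladder D with D[j] = sum of k dt over steps < j."""
    d = np.empty(k.size + 1)
    d[0] = 0.0
    np.cumsum(k * dt, out=d[1:])
    return d


def simulate_ensemble(
    n_pores: int,
    model: RateModel,
    closed_dist: ClosedStateDistribution,
    open_iv: IVCurve,
    protocol: VoltageProtocol,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    initial_closed_fraction: float = 0.0,
) -> CurrentTrace:
    """Stochastic current trace of ``n_pores`` identical gating pores.

    Each pore switches open<->closed with per-step probability 1 - exp(-k dt);
    a fresh conductance ratio eps is drawn at every closing event.  The trace
    current is sum over pores of the open-pore IV current at the instantaneous
    voltage, scaled by eps for closed pores, plus additive Gaussian noise.

    The returned trace carries a ``ground_truth`` dict with the true closed
    fraction per sample, all eps draws, and the generating parameters.
    """
    if n_pores < 1:
        raise GatingError("n_pores must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t, v = protocol.samples()
    lo, hi = open_iv.span()
    if v.min() < lo or v.max() > hi:
        raise GatingError("protocol voltage exceeds the span of the open-pore IV")
    dt = float(t[1] - t[0])
    kc = np.asarray(closing_rate_at(model, v))
    ko = np.asarray(opening_rate_at(model, v))
    kmax = max(kc.max(), ko.max(), 0.0)
    refine = max(1, int(np.ceil(kmax * dt / MAX_RATE_DT)))
    if refine > 1:
        tf = np.arange((t.size - 1) * refine + 1) * (dt / refine)
        vf = protocol.voltage_at(tf)
        kc = np.asarray(closing_rate_at(model, vf))
        ko = np.asarray(opening_rate_at(model, vf))
    n_steps = kc.size
    dc = _per_step_log_survival(kc, dt / refine)
    do = _per_step_log_survival(ko, dt / refine)

    closed_count = np.zeros(n_steps, dtype=np.int32)
    eps_sum = np.zeros(n_steps)
    eps_draws: list[float] = []
    n_closed0 = int(round(np.clip(initial_closed_fraction, 0.0, 1.0) * n_pores))
    for pore in range(n_pores):
        idx = 0
        is_closed = pore < n_closed0
        while idx < n_steps:
            if not is_closed:
                # exact inverse-sampling of the per-step Bernoulli chain
                target = dc[idx] + rng.exponential()
                j = int(np.searchsorted(dc, target, side="right"))
                idx, is_closed = j, True
            else:
                eps = float(closed_dist.draw(rng, 1)[0])
                eps_draws.append(eps)
                target = do[idx] + rng.exponential()
                j = min(int(np.searchsorted(do, target, side="right")), n_steps)
                closed_count[idx:j] += 1
                eps_sum[idx:j] += eps
                idx, is_closed = j, False
    if refine > 1:
        closed_count = closed_count[::refine]
        eps_sum = eps_sum[::refine]
    i_open = open_iv.interp(v)
    current = i_open * ((n_pores - closed_count) + eps_sum)
    if noise_sd > 0:
        current = current + rng.normal(0.0, noise_sd, size=current.size)
    meta = {
        "protocol_kind": protocol.kind,
        "protocol_frequency_hz": protocol.frequency,
        "protocol_amplitude_v": protocol.amplitude,
        "n_pores": n_pores,
        "noise_sd_a": noise_sd,
        "rate_model": {
            "polarity": model.polarity,
            "critical_voltage": model.critical_voltage,
            "closing_prefactor": model.closing_prefactor,
            "closing_efold_voltage": model.closing_efold_voltage,
            "opening_rate": model.opening_rate,
            "reopening_window": model.reopening_window,
        },
        "epsilon_mean": closed_dist.mean_ratio,
        "epsilon_sd": closed_dist.sd_ratio,
    }
    gt = {
        "closed_fraction": closed_count / n_pores,
        "epsilon_draws": np.asarray(eps_draws),
        "n_pores": n_pores,
    }
    return CurrentTrace(time_s=t, voltage_v=v, current_a=current,
                        metadata=meta, ground_truth=gt)


def run_pulse_protocol(
    n_pores: int,
    model: RateModel,
    closed_dist: ClosedStateDistribution,
    open_iv: IVCurve,
    protocol: VoltageProtocol,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    initial_closed_fraction: float = 1.0,
) -> dict[str, np.ndarray]:
    """Synaptic pulse experiment: conductance versus pulse number.

    Runs the ensemble under a pulse train and samples the membrane conductance
    at the baseline voltage during the second half of each inter-pulse wait.
    Conductance is normalized by the fully-closed ensemble conductance
    ``n_pores * mean_eps * G_O(V_baseline)``, so the closed plateau sits at 1
    and the fully open plateau at 1/mean_eps.

    Returns arrays: pulse number (1-based), normalized conductance, and the
    raw mean baseline current per pulse.
    """
    if protocol.kind != "pulse_train":
        raise GatingError("run_pulse_protocol needs a pulse_train protocol")
    trace = simulate_ensemble(n_pores, model, closed_dist, open_iv, protocol,
                              noise_sd=noise_sd, seed=seed,
                              initial_closed_fraction=initial_closed_fraction)
    v_base = protocol.baseline
    if v_base == 0.0:
        raise GatingError("baseline voltage must be non-zero to read conductance")
    g_open_base = float(open_iv.interp(v_base)) / v_base
    g_closed = n_pores * closed_dist.mean_ratio * g_open_base
    cycle = protocol.pulse_width + protocol.inter_pulse_wait
    t = trace.time_s
    g_norm = np.empty(protocol.n_pulses)
    i_base = np.empty(protocol.n_pulses)
    for k in range(protocol.n_pulses):
        w0 = k * cycle + protocol.pulse_width + 0.5 * protocol.inter_pulse_wait
        w1 = (k + 1) * cycle
        sel = (t >= w0) & (t < w1)
        if not np.any(sel):
            raise GatingError("inter-pulse wait too short for the sample rate")
        i_base[k] = float(np.mean(trace.current_a[sel]))
        g_norm[k] = (i_base[k] / v_base) / g_closed
    return {"pulse": np.arange(1, protocol.n_pulses + 1),
            "normalized_conductance": g_norm,
            "baseline_current_a": i_base}


def ergodicity_check(
    model: RateModel,
    closed_dist: ClosedStateDistribution,
    open_iv: IVCurve,
    protocol_one_cycle: VoltageProtocol,
    n_cycles: int = 50,
    n_pores: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
    v_mask: float = 0.02,
    smooth_window_frac: float = 1.0 / 64.0,
    model_ensemble: RateModel | None = None,
) -> dict:
    """Time average of one pore vs ensemble average of many pores.

    Simulates (a) a single pore over ``n_cycles`` cycles and (b) ``n_pores``
    pores over one cycle of the same periodic protocol, reduces both to
    smoothed per-pore normalized current loops I/I_O on a common phase grid,
    and returns the maximum absolute discrepancy outside the |V| < v_mask
    region together with both loops.  ``model_ensemble`` lets the ensemble
    side run a deliberately different rate model (negative control).
    """
    from dataclasses import replace as _replace

    from . import trace_analysis as ta

    if not protocol_one_cycle.is_periodic:
        raise GatingError("ergodicity check needs a periodic protocol")
    period = protocol_one_cycle.period
    proto_long = _replace(protocol_one_cycle, duration=n_cycles * period)
    proto_one = _replace(protocol_one_cycle, duration=period)
    rng = np.random.default_rng(seed)
    trace_time = simulate_ensemble(1, model, closed_dist, open_iv, proto_long,
                                   noise_sd=noise_sd, seed=rng)
    trace_ens = simulate_ensemble(n_pores, model_ensemble or model, closed_dist,
                                  open_iv, proto_one, noise_sd=noise_sd, seed=rng)
    loop_t = ta.normalized_loop(trace_time, open_iv, proto_long,
                                smooth_window_frac=smooth_window_frac)
    loop_e = ta.normalized_loop(trace_ens, open_iv, proto_one,
                                smooth_window_frac=smooth_window_frac)
    mask = np.abs(loop_t["voltage"]) >= v_mask
    disc = np.abs(loop_t["ratio"] - loop_e["ratio"])[mask]
    return {
        "max_discrepancy": float(disc.max()),
        "phase": loop_t["phase"],
        "voltage": loop_t["voltage"],
        "ratio_time_average": loop_t["ratio"],
        "ratio_ensemble_average": loop_e["ratio"],
        "compared_mask": mask,
    }
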