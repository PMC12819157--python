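"""Analysis of a.c. and d.c. nanopore recordings.

The a.c. pipeline mirrors how ensemble gating experiments are quantified:

1. split a periodic recording into cycles and resample each onto a common
   phase grid;
2. per cycle, estimate the number of pores ``N_p`` by regressing the ensemble
   current on the single-pore open IV inside a small window around V = 0
   where no gating occurs (slope = N_p); implausible cycles are excluded;
3. average the per-pore-normalized cycles (weights N_p) and divide by the
   single-pore open current to get the normalized ensemble current
   I_ens/I_O = 1 - p (1 - eps);
4. invert the two-state relation to the closed probability
   p = (1 - I_ens/I_O) / (1 - eps), masked near V = 0 where the ratio is
   ill-defined;
5. the closing rate k_X per polarity is the maximum of dp/dt over the
   rising-|V| part of the cycle, with the derivative taken by a local
   quadratic (Savitzky-Golay) smoother;
6. the rectification factor beta is read off the rising-|V| (pre-gating)
   branch of the per-pore loop at the +/-100 mV reference.

For constant-voltage recordings, ``level_segmentation`` splits the current
histogram into an open and a gated mode and reports per-event gated/open
current ratios and dwell times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, savgol_filter

from .pore_transport import IVCurve
from .protocols import VoltageProtocol
from .traces import CurrentTrace


class AnalysisError(ValueError):
    """Analysis cannot proceed on the given input."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the a.c. analysis pipeline."""

    epsilon: float = 0.14  # assumed gated/open conductance ratio
    v_mask: float = 0.02  # V; half-width of the ill-defined region around V=0
    np_window: float = 0.05  # V; window for the N_p regression
    min_r2: float = 0.5  # cycles with a worse N_p fit are excluded
    derivative_window_frac: float = 1.0 / 64.0  # smoother window, cycles
    vref: float = 0.1  # V; rectification reference voltage
    n_phase: int = 2048  # samples of the common phase grid


@dataclass
class CycleSet:
    """Per-cycle currents resampled onto a common phase grid."""

    phase: np.ndarray  # (n_phase,) in [0, 1)
    voltage: np.ndarray  # protocol voltage on the phase grid
    currents: np.ndarray  # (n_cycles, n_phase)
    cycle_duration: float  # s
    protocol: VoltageProtocol

    @property
    def n_cycles(self) -> int:
        return self.currents.shape[0]


@dataclass
class GatingSummary:
    """Output of the full a.c. analysis."""

    phase: np.ndarray
    voltage: np.ndarray
    p: np.ndarray  # clipped to [0, 1]; NaN where masked
    p_raw: np.ndarray  # unclipped, for QC
    mask: np.ndarray  # True where p is reported
    k_x_negative: float
    k_x_positive: float
    beta: float
    n_cycles: int
    n_pores_mean: float
    qc: dict = field(default_factory=dict)


def expected_current_ratio(p, epsilon: float):
    """Two-state forward model: I_ens/I_O = 1 - p (1 - eps)."""
    return 1.0 - np.asarray(p) * (1.0 - epsilon)


def segment_cycles(
    trace: CurrentTrace, protocol: VoltageProtocol, n_phase: int = 2048
) -> CycleSet:
    """Split a periodic recording at protocol phase zero-crossings.

    Each complete cycle is resampled onto an ``n_phase``-point phase grid by
    linear interpolation; partial trailing cycles are discarded.
    """
    if not protocol.is_periodic:
        raise AnalysisError("cycle segmentation needs a periodic protocol")
    t = trace.time_s - trace.time_s[0]
    period = protocol.period
    n_cycles = int(np.floor((t[-1] + trace.dt) / period + 1e-9))
    if n_cycles < 1:
        raise AnalysisError("trace shorter than one protocol cycle")
    phase = np.arange(n_phase) / n_phase
    currents = np.empty((n_cycles, n_phase))
    for c in range(n_cycles):
        tq = (c + phase) * period
        currents[c] = np.interp(tq, t, trace.current_a)
    voltage = protocol.voltage_at(phase * period)
    return CycleSet(phase=phase, voltage=voltage, currents=currents,
                    cycle_duration=period, protocol=protocol)


def estimate_pore_count(
    cycle_current: np.ndarray,
    voltage: np.ndarray,
    open_iv: IVCurve,
    window: float = 0.05,
) -> tuple[float, float]:
    """Number of pores in one cycle from the low-voltage linear regression.

    The ensemble current inside |V| < window (where no gating takes place) is
    regressed against the single-pore IV current; the slope is N_p.  Returns
    (N_p, R^2); raises if the slope is non-positive.
    """
    sel = np.abs(voltage) < window
    if np.count_nonzero(sel) < 20:
        raise AnalysisError("fewer than 20 samples inside the N_p window")
    x = np.asarray(open_iv.interp(voltage[sel]))
    y = np.asarray(cycle_current[sel], float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    if slope <= 0:
        raise AnalysisError("non-positive pore-count slope (no pores?)")
    return float(slope), r2


def normalized_ensemble_current(
    cycles: CycleSet,
    open_iv: IVCurve,
    window: float = 0.05,
    min_r2: float = 0.5,
) -> dict:
    """Weighted per-pore loop and its ratio to the single-pore open current.

    Each retained cycle is divided by its own N_p estimate; cycles are then
    averaged with weights N_p.  Returns the per-pore current loop, the open
    current I_O on the phase grid, the ratio I_ens/I_O, per-cycle N_p, and
    the retained-cycle mask.
    """
    n_p = np.full(cycles.n_cycles, np.nan)
    r2 = np.full(cycles.n_cycles, np.nan)
    retained = np.zeros(cycles.n_cycles, dtype=bool)
    for c in range(cycles.n_cycles):
        try:
            n_p[c], r2[c] = estimate_pore_count(
                cycles.currents[c], cycles.voltage, open_iv, window
            )
        except AnalysisError:
            continue
        retained[c] = r2[c] >= min_r2
    if not np.any(retained):
        raise AnalysisError("all cycles excluded by the N_p quality filter")
    w = n_p[retained]
    per_pore = cycles.currents[retained] / w[:, None]
    i_pore = np.average(per_pore, axis=0, weights=w)
    i_open = np.asarray(open_iv.interp(cycles.voltage))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(i_open != 0, i_pore / np.where(i_open != 0, i_open, 1.0),
                         np.nan)
    return {"i_pore": i_pore, "i_open": i_open, "ratio": ratio,
            "n_p": n_p, "r2": r2, "retained": retained}


def closed_probability(
    ratio: np.ndarray,
    epsilon: float,
    voltage: np.ndarray | None = None,
    v_mask: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert the two-state relation: p = (1 - I_ens/I_O) / (1 - eps).

    Returns (p clipped to [0,1], raw unclipped p, mask).  The mask is False
    where |V| < v_mask (the ratio is ill-defined around the origin) and the
    reported p is NaN there.
    """
    if not 0.0 < epsilon < 1.0:
        raise AnalysisError("epsilon must lie in (0, 1)")
    p_raw = (1.0 - np.asarray(ratio, float)) / (1.0 - epsilon)
    mask = np.isfinite(p_raw)
    if voltage is not None:
        mask &= np.abs(np.asarray(voltage)) >= v_mask
    p = np.clip(p_raw, 0.0, 1.0)
    p[~mask] = np.nan
    return p, p_raw, mask


def _fill_masked(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Linear interpolation across masked runs (used before smoothing)."""
    out = np.asarray(values, float).copy()
    idx = np.arange(out.size)
    if not np.any(mask):
        raise AnalysisError("everything is masked")
    out[~mask] = np.interp(idx[~mask], idx[mask], out[mask])
    return out


def _smooth_window(n_phase: int, window_frac: float) -> int:
    w = max(5, int(round(n_phase * window_frac)))
    return w + 1 if w % 2 == 0 else w


def closing_rate(
    p: np.ndarray,
    mask: np.ndarray,
    voltage: np.ndarray,
    cycle_duration: float,
    window_frac: float = 1.0 / 64.0,
) -> dict[str, float]:
    """Maximum dp/dt (1/s) per polarity over the rising-|V| part of the cycle.

    The derivative is estimated by a second-order Savitzky-Golay filter with a
    window of ``window_frac`` of a cycle; masked samples (and a half-window
    margin around them) are excluded from the maxima.  Rates are floored at 0.
    """
    n = p.size
    w = _smooth_window(n, window_frac)
    if w >= n:
        raise AnalysisError("derivative window larger than the phase grid")
    filled = _fill_masked(p, mask)
    dt = cycle_duration / n
    dpdt = savgol_filter(filled, w, polyorder=2, deriv=1, delta=dt, mode="wrap")
    # dilate the excluded region by half a window so edge artefacts don't win
    bad = ~mask
    half = w // 2
    kernel = np.ones(2 * half + 1)
    bad = np.convolve(bad.astype(float), kernel, mode="same") > 0
    dv = np.gradient(voltage)
    rising_neg = (voltage < 0) & (dv < 0) & ~bad
    rising_pos = (voltage > 0) & (dv > 0) & ~bad
    k_neg = float(dpdt[rising_neg].max()) if np.any(rising_neg) else 0.0
    k_pos = float(dpdt[rising_pos].max()) if np.any(rising_pos) else 0.0
    return {"k_x_negative": max(k_neg, 0.0), "k_x_positive": max(k_pos, 0.0)}


def _branch_current(i_pore, voltage, phase, sel, vq: float) -> float:
    v, i = voltage[sel], i_pore[sel]
    order = np.argsort(v)
    return float(np.interp(vq, v[order], i[order]))


def rectification_from_loop(
    i_pore: np.ndarray, voltage: np.ndarray, phase: np.ndarray, vref: float = 0.1
) -> float:
    """beta of the per-pore loop using the rising-|V| (pre-gating) branches."""
    dv = np.gradient(voltage)
    rising_pos = (voltage >= 0) & (dv > 0)
    rising_neg = (voltage <= 0) & (dv < 0)
    if voltage[rising_pos].max(initial=-np.inf) < vref or \
            voltage[rising_neg].min(initial=np.inf) > -vref:
        raise AnalysisError(f"loop does not span +/-{vref} V on the rising branches")
    i_pos = _branch_current(i_pore, voltage, phase, rising_pos, vref)
    i_neg = _branch_current(i_pore, voltage, phase, rising_neg, -vref)
    denom = i_pos + abs(i_neg)
    if denom == 0:
        raise AnalysisError("zero total current at the reference voltages")
    return (i_pos - abs(i_neg)) / denom


def normalized_loop(
    trace: CurrentTrace,
    open_iv: IVCurve,
    protocol: VoltageProtocol,
    smooth_window_frac: float = 1.0 / 64.0,
    v_mask: float = 0.02,
    n_phase: int = 2048,
    np_window: float = 0.05,
) -> dict:
    """Cycle-averaged, per-pore normalized, smoothed I/I_O loop vs phase."""
    cycles = segment_cycles(trace, protocol, n_phase)
    norm = normalized_ensemble_current(cycles, open_iv, np_window)
    mask = np.abs(cycles.voltage) >= v_mask
    filled = _fill_masked(norm["ratio"], mask & np.isfinite(norm["ratio"]))
    w = _smooth_window(n_phase, smooth_window_frac)
    smooth = savgol_filter(filled, w, polyorder=2, mode="wrap")
    return {"phase": cycles.phase, "voltage": cycles.voltage, "ratio": smooth,
            "mask": mask, "n_p": norm["n_p"], "retained": norm["retained"]}


# -- d.c. level segmentation -------------------------------------------------

@dataclass
class Level:
    """A contiguous constant-current stretch of a d.c. trace."""

    mean_current_a: float
    dwell_s: float
    label: str  # "open" or "gated"


@dataclass
class LevelSegmentation:
    levels: list[Level]
    threshold_a: float | None
    open_mean_a: float
    event_ratios: np.ndarray  # per gated event: gated mean / open mean

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.event_ratios)) if self.event_ratios.size else np.nan


def _histogram_threshold(current: np.ndarray) -> float | None:
    """Current threshold at the minimum between the two highest modes.

    Returns None when the histogram is effectively unimodal.
    """
    counts, edges = np.histogram(current, bins=128)
    smooth = gaussian_filter1d(counts.astype(float), sigma=1.5)
    prominence = max(3.0, 0.002 * current.size)
    peaks, _ = find_peaks(smooth, prominence=prominence)
    if peaks.size < 2:
        return None
    top2 = peaks[np.argsort(smooth[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(smooth[lo:hi + 1]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[valley])


def level_segmentation(
    trace: CurrentTrace, min_dwell_s: float = 0.005
) -> LevelSegmentation:
    """Two-level (open/gated) segmentation of a constant-voltage trace.

    The current histogram is split at the minimum between its two highest
    modes (fallback: midpoint of the extreme quantiles); contiguous runs of at
    least ``min_dwell_s`` become levels.  The level family with the larger
    absolute mean current is "open".  A unimodal histogram yields a single
    open level and no gated events.
    """
    i = trace.current_a
    thr = _histogram_threshold(i)
    if thr is None:
        return LevelSegmentation(
            levels=[Level(float(i.mean()), trace.duration, "open")],
            threshold_a=None, open_mean_a=float(i.mean()),
            event_ratios=np.empty(0),
        )
    upper = i > thr
    mean_upper = i[upper].mean() if np.any(upper) else 0.0
    mean_lower = i[~upper].mean() if np.any(~upper) else 0.0
    open_is_upper = abs(mean_upper) >= abs(mean_lower)
    is_open = upper if open_is_upper else ~upper
    open_mean = float(i[is_open].mean())

    min_run = max(1, int(round(min_dwell_s * trace.sample_rate)))
    edges = np.flatnonzero(np.diff(is_open.astype(np.int8))) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [i.size]))
    levels: list[Level] = []
    ratios: list[float] = []
    for a, b in zip(starts, ends):
        if b - a < min_run:
            continue
        label = "open" if is_open[a] else "gated"
        mean = float(i[a:b].mean())
        levels.append(Level(mean, (b - a) * trace.dt, label))
        if label == "gated" and open_mean != 0:
            ratios.append(mean / open_mean)
    return LevelSegmentation(levels=levels, threshold_a=thr, open_mean_a=open_mean,
                             event_ratios=np.asarray(ratios))


# -- full pipeline ------------------------------------------------------------

def analyze(
    trace: CurrentTrace,
    open_iv: IVCurve,
    protocol: VoltageProtocol,
    config: AnalysisConfig = AnalysisConfig(),
) -> GatingSummary:
    """Run the full a.c. pipeline: cycles -> N_p -> p(phase) -> k_X -> beta."""
    try:
        cycles = segment_cycles(trace, protocol, config.n_phase)
    except AnalysisError as err:
        raise AnalysisError(f"cycle segmentation: {err}") from err
    try:
        norm = normalized_ensemble_current(cycles, open_iv, config.np_window,
                                           config.min_r2)
    except AnalysisError as err:
        raise AnalysisError(f"pore-count normalization: {err}") from err
    p, p_raw, mask = closed_probability(norm["ratio"], config.epsilon,
                                        cycles.voltage, config.v_mask)
    try:
        rates = closing_rate(np.where(mask, p, np.nan), mask, cycles.voltage,
                             cycles.cycle_duration, config.derivative_window_frac)
    except AnalysisError as err:
        raise AnalysisError(f"closing-rate estimation: {err}") from err
    try:
        beta = rectification_from_loop(norm["i_pore"], cycles.voltage,
                                       cycles.phase, config.vref)
    except AnalysisError as err:
        raise AnalysisError(f"rectification: {err}") from err
    retained = norm["retained"]
    qc = {
        "n_cycles_total": cycles.n_cycles,
        "n_cycles_excluded": int(np.sum(~retained)),
        "r2": norm["r2"].tolist(),
        "n_p": norm["n_p"].tolist(),
        "v_mask": config.v_mask,
        "np_window": config.np_window,
    }
    return GatingSummary(
        phase=cycles.phase, voltage=cycles.voltage, p=p, p_raw=p_raw, mask=mask,
        k_x_negative=rates["k_x_negative"], k_x_positive=rates["k_x_positive"],
        beta=beta, n_cycles=int(np.sum(retained)),
        n_pores_mean=float(np.nanmean(norm["n_p"][retained])), qc=qc,
    )
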