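"""Synthetic electrophysiology: protocols, scenarios, and fixtures.

This module composes the transport model (open-pore IV), the two-state gating
simulator, and a Gaussian noise model into named, fully seeded scenarios that
emulate the study's recordings: triangular 2 Hz / 200 mV sweeps for open-pore
IV extraction, 0.1 Hz / 200 mV sinusoids for gating hysteresis, constant-bias
single-pore gating traces, and the potentiation / depression pulse trains
(+110 mV / 5 ms and -110 mV / 10 ms pulses, 10 ms waits, -90 mV baseline).

Every generated trace carries a ground-truth record (the generating model, the
ensemble-mean closed probability from the rate ODE, the realized closed
fraction, all eps draws, and the open-pore rectification factor) sufficient to
score any downstream analysis without rerunning the simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np

from . import protocols as proto
from .gating_kinetics import (
    ClosedStateDistribution,
    RateModel,
    closed_probability_ode,
    simulate_ensemble,
)
from .pore_transport import (
    Electrolyte,
    IVCurve,
    LumenCharge,
    PoreGeometry,
    TransportProblem,
    iv_curve,
    rectification_factor,
)
from .protocols import VoltageProtocol
from .traces import CurrentTrace, read_trace, write_trace  # noqa: F401  (re-export)


class ScenarioError(ValueError):
    """Unknown or inconsistent scenario configuration."""


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian measurement noise.

    ``relative_sd`` scales with the largest open-pore ensemble current of the
    scenario; ``gaussian_sd_a`` is absolute and wins when both are set.
    """

    gaussian_sd_a: float | None = None
    relative_sd: float = 0.0
    baseline_offset_a: float = 0.0

    def sd_for(self, max_ensemble_current_a: float) -> float:
        if self.gaussian_sd_a is not None:
            return self.gaussian_sd_a
        return self.relative_sd * abs(max_ensemble_current_a)


# -- pore configs -------------------------------------------------------------

def pore_from_dict(doc: dict[str, Any]) -> TransportProblem:
    geom = doc.get("geometry", {})
    elec = doc.get("electrolyte", {})
    return TransportProblem(
        geometry=PoreGeometry(
            radius_nm=geom.get("radius_nm", 0.7),
            length_nm=geom.get("length_nm", 10.0),
        ),
        charges=tuple(
            LumenCharge(c["z_nm"], int(c["valence"]), int(c.get("multiplicity", 7)))
            for c in doc.get("charges", [])
        ),
        electrolyte=Electrolyte(
            concentration_molar=elec.get("molar", 1.0),
            temperature_k=elec.get("temperature_K", 298.0),
            diffusion_cation_m2s=elec.get("D_cation", 1.957e-9),
            diffusion_anion_m2s=elec.get("D_anion", 2.032e-9),
        ),
        screening_length_nm=doc.get("screening_length_nm"),
        bjerrum_length_nm=doc.get("bjerrum_length_nm", 0.7),
    )


def pore_to_dict(problem: TransportProblem) -> dict[str, Any]:
    return {
        "geometry": {
            "radius_nm": problem.geometry.radius_nm,
            "length_nm": problem.geometry.length_nm,
        },
        "charges": [
            {"z_nm": c.axial_position_nm, "valence": c.valence,
             "multiplicity": c.multiplicity}
            for c in problem.charges
        ],
        "electrolyte": {
            "molar": problem.electrolyte.concentration_molar,
            "temperature_K": problem.electrolyte.temperature_k,
            "D_cation": problem.electrolyte.diffusion_cation_m2s,
            "D_anion": problem.electrolyte.diffusion_anion_m2s,
        },
        "screening_length_nm": problem.screening_length_nm,
        "bjerrum_length_nm": problem.bjerrum_length_nm,
    }


def _fixture_text(name: str) -> str:
    return resources.files("aerogate.fixtures").joinpath(name).read_text()


def load_pore(name_or_path: str | Path) -> TransportProblem:
    """Load a pore config by fixture name ('wt_like') or JSON file path."""
    p = Path(name_or_path)
    if p.suffix == ".json" and p.exists():
        return pore_from_dict(json.loads(p.read_text()))
    try:
        return pore_from_dict(json.loads(_fixture_text(f"pore_{name_or_path}.json")))
    except FileNotFoundError as err:
        raise ScenarioError(f"unknown pore fixture {name_or_path!r}") from err


# -- protocols ----------------------------------------------------------------

_PROTOCOL_PRESETS: dict[str, dict[str, Any]] = {
    # triangular forcing at 2 Hz, 200 mV (open-pore IV extraction)
    "fig2a": dict(kind="triangle", amplitude=0.2, frequency=2.0, duration=5.0,
                  sample_rate=1.0e4),
    # sinusoidal forcing at 0.1 Hz, 200 mV (gating hysteresis)
    "fig2c": dict(kind="sinusoid", amplitude=0.2, frequency=0.1, duration=10.0,
                  sample_rate=1.0e4),
    # potentiation: +110 mV / 5 ms pulses, 10 ms waits, -90 mV baseline, 30 pulses
    "fig6_potentiation": dict(kind="pulse_train", amplitude=0.11, pulse_width=5e-3,
                              inter_pulse_wait=10e-3, n_pulses=30, baseline=-0.09,
                              sample_rate=5.0e4),
    # depression: -110 mV / 10 ms pulses, same waits and baseline
    "fig6_depression": dict(kind="pulse_train", amplitude=-0.11, pulse_width=10e-3,
                            inter_pulse_wait=10e-3, n_pulses=30, baseline=-0.09,
                            sample_rate=5.0e4),
}


def make_protocol(kind: str, **overrides: Any) -> VoltageProtocol:
    """Build a protocol from a named preset or a generic kind.

    Presets: 'fig2a' (triangle 2 Hz +/-200 mV), 'fig2c' (sine 0.1 Hz
    +/-200 mV), 'fig6_potentiation', 'fig6_depression'.  Generic kinds:
    'sinusoid', 'triangle', 'constant', 'pulse_train'.
    """
    if kind in _PROTOCOL_PRESETS:
        params = {**_PROTOCOL_PRESETS[kind], **overrides}
        return VoltageProtocol(**params)
    if kind in ("sinusoid", "triangle", "constant", "pulse_train"):
        return VoltageProtocol(kind=kind, **overrides)
    raise ScenarioError(f"unknown protocol preset or kind {kind!r}")


# -- scenarios ----------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """A fully specified synthetic recording."""

    name: str
    pore: TransportProblem
    n_pores: int
    rate_model: RateModel
    closed_state: ClosedStateDistribution
    protocol: VoltageProtocol
    noise: NoiseModel
    seed: int
    iv_sweep: tuple[float, float, int] = (-0.25, 0.25, 101)
    initial_closed_fraction: float = 0.0
    raw: dict[str, Any] = field(default_factory=dict)

    def open_iv(self) -> IVCurve:
        vmin, vmax, n = self.iv_sweep
        return iv_curve(self.pore, np.linspace(vmin, vmax, n))


def scenario_from_dict(doc: dict[str, Any]) -> ScenarioConfig:
    if "seed" not in doc:
        raise ScenarioError("scenario config must carry a seed")
    pore_doc = doc.get("pore", "wt_like")
    pore = load_pore(pore_doc) if isinstance(pore_doc, str) else pore_from_dict(pore_doc)
    rm = doc.get("rate_model", {})
    cs = doc.get("closed_state", {})
    pr = dict(doc.get("protocol", {}))
    preset = pr.pop("preset", None)
    protocol = make_protocol(preset, **pr) if preset else make_protocol(
        pr.pop("kind"), **pr)
    nz = doc.get("noise", {})
    sweep = doc.get("iv_sweep", {})
    return ScenarioConfig(
        name=doc.get("name", "scenario"),
        pore=pore,
        n_pores=int(doc.get("n_pores", 1)),
        rate_model=RateModel(**rm),
        closed_state=ClosedStateDistribution(**cs),
        protocol=protocol,
        noise=NoiseModel(
            gaussian_sd_a=nz.get("gaussian_sd_a"),
            relative_sd=nz.get("relative_sd", 0.0),
            baseline_offset_a=nz.get("baseline_offset_a", 0.0),
        ),
        seed=int(doc["seed"]),
        iv_sweep=(sweep.get("vmin", -0.25), sweep.get("vmax", 0.25),
                  sweep.get("n", 101)),
        initial_closed_fraction=float(doc.get("initial_closed_fraction", 0.0)),
        raw=doc,
    )


def load_scenario(name_or_path: str | Path) -> ScenarioConfig:
    """Load a scenario by fixture name ('dc_gater') or JSON file path."""
    p = Path(name_or_path)
    if p.suffix == ".json" and p.exists():
        return scenario_from_dict(json.loads(p.read_text()))
    try:
        doc = json.loads(_fixture_text(f"scenario_{name_or_path}.json"))
    except FileNotFoundError as err:
        raise ScenarioError(f"unknown scenario fixture {name_or_path!r}") from err
    return scenario_from_dict(doc)


def generate_scenario(
    config: ScenarioConfig,
    seed: int | None = None,
    open_iv: IVCurve | None = None,
) -> CurrentTrace:
    """Simulate a scenario; the trace carries a full ground-truth record.

    ``seed`` overrides the config seed; ``open_iv`` bypasses the transport
    model (useful when the same IV is reused across many traces).
    """
    rng_seed = config.seed if seed is None else seed
    if open_iv is None:
        open_iv = config.open_iv()
    t, v = config.protocol.samples()
    max_i = float(np.max(np.abs(open_iv.interp(v)))) * config.n_pores
    noise_sd = config.noise.sd_for(max_i)
    trace = simulate_ensemble(
        config.n_pores, config.rate_model, config.closed_state, open_iv,
        config.protocol, noise_sd=noise_sd, seed=rng_seed,
        initial_closed_fraction=config.initial_closed_fraction,
    )
    if config.noise.baseline_offset_a:
        trace.current_a = trace.current_a + config.noise.baseline_offset_a
    _, p_ode = closed_probability_ode(config.rate_model, (t, v),
                                      p0=config.initial_closed_fraction)
    beta_sweep = np.linspace(-0.15, 0.15, 31)
    true_beta = rectification_factor(iv_curve(config.pore, beta_sweep))
    trace.metadata.update({"scenario": config.name, "seed": rng_seed,
                           "noise_sd_a": noise_sd})
    trace.ground_truth.update({
        "p_ode": p_ode,
        "beta_open_pore": true_beta,
        "epsilon_mean": config.closed_state.mean_ratio,
        "epsilon_sd": config.closed_state.sd_ratio,
    })
    return trace


def list_fixtures() -> list[str]:
    return sorted(
        p.name for p in resources.files("aerogate.fixtures").iterdir()
        if p.name.endswith(".json")
    )
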