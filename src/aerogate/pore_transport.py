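"""Open-pore electrodiffusion through a charged-lumen cylindrical nanopore.

A beta-barrel pore (aerolysin-like) is modelled as a cylinder of radius ``a``
and length ``L`` whose wall carries discrete rings of charged residues.  Each
ring creates a screened electrostatic well or barrier in the one-dimensional
energy landscape ``W_s(z)`` seen by a diffusing ion of species ``s``; an applied
voltage adds a linear (uniform-field) term.  The steady-state Nernst--Planck
flux through such a landscape has the exact one-dimensional quadrature solution

    J_s = D_s * c0 * (exp(z_s eV/kT) - 1) / integral_0^L exp(W_s(z)) dz

(``W`` in units of kT, equal bulk concentrations ``c0`` on both sides, and
boundary Boltzmann factors carrying only the applied potential because the
reservoirs stay equilibrated with bulk), which reduces to the ohmic
Goldman-type limit when the landscape is purely linear.  Rectification arises because ions accumulate downstream of wells and
upstream of barriers, so the lumen ion content -- and hence the conductance --
depends on voltage polarity.

Conventions: ``z = 0`` is the cis entrance, ``z = L`` the trans entrance.
Positive applied voltage drives cations from cis to trans, and positive current
means cation flux cis -> trans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    NM,
    VACUUM_PERMITTIVITY,
    WATER_RELATIVE_PERMITTIVITY,
)

Species = Literal["cation", "anion"]

#: potentials beyond this magnitude (kT) are clipped to avoid overflow
POTENTIAL_CLIP_KT = 50.0

#: default number of axial grid points for the quadrature
DEFAULT_GRID_POINTS = 512


class TransportError(ValueError):
    """Invalid transport problem or operating point."""


@dataclass(frozen=True)
class PoreGeometry:
    """Cylindrical pore: radius and length in nm (radius < length)."""

    radius_nm: float = 0.7
    length_nm: float = 10.0

    def __post_init__(self) -> None:
        if not (self.radius_nm > 0 and self.length_nm > 0):
            raise TransportError("pore radius and length must be positive")
        if not self.radius_nm < self.length_nm:
            raise TransportError("pore radius must be smaller than its length")

    @property
    def area_m2(self) -> float:
        return np.pi * (self.radius_nm * NM) ** 2


@dataclass(frozen=True)
class LumenCharge:
    """A ring of identical charged residues on the pore wall.

    ``axial_position_nm`` is measured from the cis entrance; ``valence`` is the
    signed charge per residue in units of e; ``multiplicity`` is the number of
    copies in the ring (7 for a heptameric pore).
    """

    axial_position_nm: float
    valence: int
    multiplicity: int = 7

    def __post_init__(self) -> None:
        if self.valence == 0:
            raise TransportError("lumen charge valence must be non-zero")
        if self.multiplicity < 1:
            raise TransportError("multiplicity must be >= 1")


@dataclass(frozen=True)
class Electrolyte:
    """Symmetric 1:1 electrolyte (KCl-like)."""

    concentration_molar: float = 1.0
    temperature_k: float = 298.0
    diffusion_cation_m2s: float = 1.957e-9  # K+ at 25 C
    diffusion_anion_m2s: float = 2.032e-9  # Cl- at 25 C

    def __post_init__(self) -> None:
        for name in (
            "concentration_molar",
            "temperature_k",
            "diffusion_cation_m2s",
            "diffusion_anion_m2s",
        ):
            if not getattr(self, name) > 0:
                raise TransportError(f"{name} must be positive")

    @property
    def number_density_m3(self) -> float:
        """Bulk number density of each ion species, particles/m^3."""
        return self.concentration_molar * 1e3 * AVOGADRO

    def diffusion(self, species: Species) -> float:
        return (
            self.diffusion_cation_m2s
            if species == "cation"
            else self.diffusion_anion_m2s
        )


def debye_length(
    electrolyte: Electrolyte, relative_permittivity: float = WATER_RELATIVE_PERMITTIVITY
) -> float:
    """Debye screening length in nm for a symmetric 1:1 electrolyte.

    lambda_D = sqrt(eps_r eps_0 kB T / (2 NA e^2 c0)); ~0.30 nm in 1 M at 298 K.
    """
    c0 = electrolyte.number_density_m3
    lam2 = (
        relative_permittivity
        * VACUUM_PERMITTIVITY
        * BOLTZMANN
        * electrolyte.temperature_k
        / (2.0 * c0 * ELEMENTARY_CHARGE**2)
    )
    return float(np.sqrt(lam2) / NM)


@dataclass(frozen=True)
class TransportProblem:
    """Pore geometry + lumen charges + electrolyte.

    ``screening_length_nm`` defaults to the Debye length of the electrolyte;
    ``bjerrum_length_nm`` sets the strength of the screened ring wells
    (0.7 nm in water at room temperature).
    """

    geometry: PoreGeometry = field(default_factory=PoreGeometry)
    charges: tuple[LumenCharge, ...] = ()
    electrolyte: Electrolyte = field(default_factory=Electrolyte)
    screening_length_nm: float | None = None
    bjerrum_length_nm: float = 0.7

    def __post_init__(self) -> None:
        object.__setattr__(self, "charges", tuple(self.charges))
        L = self.geometry.length_nm
        for ch in self.charges:
            if not 0.0 <= ch.axial_position_nm <= L:
                raise TransportError(
                    f"charge at z={ch.axial_position_nm} nm outside [0, {L}] nm"
                )
        if self.screening_length_nm is not None and not self.screening_length_nm > 0:
            raise TransportError("screening length must be positive")
        if not self.bjerrum_length_nm > 0:
            raise TransportError("Bjerrum length must be positive")

    @property
    def effective_screening_nm(self) -> float:
        if self.screening_length_nm is not None:
            return self.screening_length_nm
        return debye_length(self.electrolyte)

    def with_charges(self, charges: Iterable[LumenCharge]) -> "TransportProblem":
        return replace(self, charges=tuple(charges))

    def mirrored(self) -> "TransportProblem":
        """Reflect all charges through the pore midpoint (z -> L - z)."""
        L = self.geometry.length_nm
        return self.with_charges(
            replace(c, axial_position_nm=L - c.axial_position_nm) for c in self.charges
        )

    def charge_conjugated(self) -> "TransportProblem":
        """Flip the sign of every lumen charge."""
        return self.with_charges(replace(c, valence=-c.valence) for c in self.charges)


@dataclass(frozen=True)
class SpeciesPotential:
    """Dimensionless energy landscape W_s(z)/kT on a uniform axial grid."""

    grid_nm: np.ndarray
    values_kt: np.ndarray

    def __post_init__(self) -> None:
        if self.grid_nm.size < 2 or self.grid_nm.size != self.values_kt.size:
            raise TransportError("potential grid and values must match, size >= 2")
        if not np.all(np.diff(self.grid_nm) > 0):
            raise TransportError("potential grid must be strictly increasing")
        if not np.all(np.isfinite(self.values_kt)):
            raise TransportError("potential values must be finite")


@dataclass(frozen=True)
class IVCurve:
    """Sampled current-voltage relation (V in volts, I in amperes)."""

    voltages: np.ndarray
    currents: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, float)
        i = np.asarray(self.currents, float)
        if v.size != i.size or v.size < 2:
            raise TransportError("IV curve needs matching arrays of size >= 2")
        if not np.all(np.diff(v) > 0):
            raise TransportError("IV voltages must be strictly increasing")
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "currents", i)

    def interp(self, voltage):
        """Linearly interpolated current at the given voltage(s)."""
        v = np.asarray(voltage, float)
        if np.any(v < self.voltages[0]) or np.any(v > self.voltages[-1]):
            raise TransportError("voltage outside the span of the IV curve")
        return np.interp(v, self.voltages, self.currents)

    def span(self) -> tuple[float, float]:
        return float(self.voltages[0]), float(self.voltages[-1])


def species_valence(species: Species) -> int:
    if species == "cation":
        return 1
    if species == "anion":
        return -1
    raise TransportError(f"unknown species {species!r}")


def species_potential(
    problem: TransportProblem,
    species: Species,
    voltage: float,
    n_grid: int = DEFAULT_GRID_POINTS,
) -> SpeciesPotential:
    """Energy landscape (units of kT) of one ion species at a given voltage.

    The landscape is the sum of a linear uniform-field term
    ``z_s e V (1 - z/L) / kT`` (access resistance neglected) and, for each
    charged ring, an on-axis screened-Coulomb well/barrier
    ``z_s q_i m_i l_B exp(-d_i/lambda) / d_i`` with
    ``d_i = sqrt((z - z_i)^2 + a^2)``.
    """
    if abs(voltage) > 1.0:
        raise TransportError("|voltage| must be <= 1 V")
    if n_grid < 2:
        raise TransportError("grid must have at least 2 points")
    geom = problem.geometry
    L = geom.length_nm
    z = np.linspace(0.0, L, n_grid)
    zs = species_valence(species)
    kT = BOLTZMANN * problem.electrolyte.temperature_k
    w = zs * ELEMENTARY_CHARGE * voltage * (1.0 - z / L) / kT
    lam = problem.effective_screening_nm
    lb = problem.bjerrum_length_nm
    a = geom.radius_nm
    for ch in problem.charges:
        d = np.sqrt((z - ch.axial_position_nm) ** 2 + a**2)
        w = w + zs * ch.valence * ch.multiplicity * lb * np.exp(-d / lam) / d
    if np.any(np.abs(w) > POTENTIAL_CLIP_KT):
        warnings.warn(
            f"species potential exceeds +/-{POTENTIAL_CLIP_KT} kT; clipping",
            RuntimeWarning,
            stacklevel=2,
        )
        w = np.clip(w, -POTENTIAL_CLIP_KT, POTENTIAL_CLIP_KT)
    return SpeciesPotential(grid_nm=z, values_kt=w)


def _boundary_factor(
    problem: TransportProblem, species: Species, voltage: float
) -> float:
    """exp of the applied-potential part of W at the cis boundary.

    The reservoirs stay equilibrated with bulk, so the Dirichlet data for the
    flux quadrature carry only the applied potential (z_s eV/kT at cis, 0 at
    trans); the ring potentials enter solely through the interior integral.
    This is what makes a charge sitting exactly at a pore mouth act mostly on
    the reservoir rather than on the pore.
    """
    zs = species_valence(species)
    kT = BOLTZMANN * problem.electrolyte.temperature_k
    return float(np.exp(zs * ELEMENTARY_CHARGE * voltage / kT))


def _species_flux(
    problem: TransportProblem, species: Species, voltage: float, n_grid: int
) -> float:
    """Steady-state particle flux density (particles / m^2 / s), cis -> trans."""
    from scipy.integrate import simpson

    pot = species_potential(problem, species, voltage, n_grid=n_grid)
    ew = np.exp(pot.values_kt)
    denom = simpson(ew, x=pot.grid_nm * NM)
    c0 = problem.electrolyte.number_density_m3
    d = problem.electrolyte.diffusion(species)
    return d * c0 * (_boundary_factor(problem, species, voltage) - 1.0) / denom


def steady_state_current(
    problem: TransportProblem, voltage: float, n_grid: int = DEFAULT_GRID_POINTS
) -> float:
    """Steady-state ionic current (A) through the pore at a fixed voltage."""
    jc = _species_flux(problem, "cation", voltage, n_grid)
    ja = _species_flux(problem, "anion", voltage, n_grid)
    return problem.geometry.area_m2 * ELEMENTARY_CHARGE * (jc - ja)


def iv_curve(
    problem: TransportProblem,
    voltages: Sequence[float],
    n_grid: int = DEFAULT_GRID_POINTS,
) -> IVCurve:
    """Current at each voltage of a sorted sweep (deterministic)."""
    v = np.asarray(voltages, float)
    if not np.all(np.diff(v) > 0):
        raise TransportError("voltages must be strictly increasing")
    i = np.array([steady_state_current(problem, float(vv), n_grid) for vv in v])
    return IVCurve(voltages=v, currents=i)


def rectification_factor(iv: IVCurve, vref: float = 0.1) -> float:
    """Rectification factor beta = (I+ - |I-|) / (I+ + |I-|) at +/- vref.

    beta is confined to [-1, 1]; beta > 0 means larger current magnitude at
    positive voltage.  Currents at exactly +/- vref are obtained by linear
    interpolation of the IV samples.
    """
    lo, hi = iv.span()
    if lo > -vref or hi < vref:
        raise TransportError(f"IV curve does not span +/-{vref} V")
    i_pos = float(iv.interp(vref))
    i_neg = float(iv.interp(-vref))
    denom = i_pos + abs(i_neg)
    if denom == 0:
        raise TransportError("zero total current at the reference voltages")
    return (i_pos - abs(i_neg)) / denom


def concentration_profile(
    problem: TransportProblem,
    species: Species,
    voltage: float,
    n_grid: int = DEFAULT_GRID_POINTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state concentration profile c_s(z) in mol/L along the pore axis.

    Returns (grid_nm, concentration_molar); both boundaries sit at the bulk
    concentration (up to the residual ring potential at the mouths, which is
    negligible for interior charges).
    """
    from scipy.integrate import cumulative_trapezoid

    pot = species_potential(problem, species, voltage, n_grid=n_grid)
    w = pot.values_kt
    ew = np.exp(w)
    z_m = pot.grid_nm * NM
    c0 = problem.electrolyte.number_density_m3
    d = problem.electrolyte.diffusion(species)
    b0 = _boundary_factor(problem, species, voltage)
    # trapezoid here (not Simpson) so the trans boundary closes exactly
    j = d * c0 * (b0 - 1.0) / np.trapezoid(ew, z_m)
    cum = cumulative_trapezoid(ew, z_m, initial=0.0)
    c = np.exp(-w) * (c0 * b0 - (j / d) * cum)
    return pot.grid_nm, c / (1e3 * AVOGADRO)


def charge_position_scan(
    base_problem: TransportProblem,
    valence: int,
    positions_nm: Sequence[float],
    multiplicity: int = 7,
    vref: float = 0.1,
    n_voltages: int = 41,
    n_grid: int = DEFAULT_GRID_POINTS,
) -> np.ndarray:
    """Rectification factor as one charged ring is moved along the pore.

    For each position, a single ring of the given valence and multiplicity is
    added to the base problem and beta of the resulting IV curve is computed.
    A zero valence is allowed here and means "no ring added".
    """
    L = base_problem.geometry.length_nm
    positions = np.asarray(positions_nm, float)
    if np.any(positions < 0) or np.any(positions > L):
        raise TransportError("scan positions must lie within [0, L]")
    sweep = np.linspace(-1.5 * vref, 1.5 * vref, n_voltages)
    betas = np.empty(positions.size)
    for k, z in enumerate(positions):
        if valence == 0:
            prob = base_problem
        else:
            prob = base_problem.with_charges(
                (*base_problem.charges, LumenCharge(float(z), valence, multiplicity))
            )
        betas[k] = rectification_factor(iv_curve(prob, sweep, n_grid), vref)
    return betas


def write_iv_tsv(iv: IVCurve, path) -> None:
    """Two-column TSV (voltage_V, current_A) with '#' header lines."""
    import pandas as pd
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# aerogate IV curve\n")
        fh.write("# sign convention: positive current = cation flux cis->trans\n")
        pd.DataFrame({"voltage_V": iv.voltages, "current_A": iv.currents}).to_csv(
            fh, sep="\t", index=False, float_format="%.9e"
        )


def read_iv_tsv(path) -> IVCurve:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != ["voltage_V", "current_A"]:
        raise TransportError("IV TSV must have columns voltage_V, current_A")
    return IVCurve(df["voltage_V"].to_numpy(), df["current_A"].to_numpy())


def ideal_conductivity(electrolyte: Electrolyte) -> float:
    """Nernst-Einstein bulk conductivity sigma = NA e^2 c (D+ + D-) / kT, S/m."""
    kT = BOLTZMANN * electrolyte.temperature_k
    return (
        electrolyte.number_density_m3
        * ELEMENTARY_CHARGE**2
        * (electrolyte.diffusion_cation_m2s + electrolyte.diffusion_anion_m2s)
        / kT
    )


def bulk_cylinder_conductance(
    geometry: PoreGeometry, electrolyte: Electrolyte
) -> float:
    """Conductance (S) of a cylinder of bulk electrolyte: sigma * pi a^2 / L."""
    return ideal_conductivity(electrolyte) * geometry.area_m2 / (geometry.length_nm * NM)
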