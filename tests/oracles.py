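"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths they check: the steady-state
electrodiffusion oracle solves the Nernst-Planck conservation law
d/dz [ D (c' + c W') ] = 0 by a finite-difference tridiagonal solve in the
Slotboom variable u = c e^W, instead of the closed-form flux quadrature.
"""

import numpy as np
from scipy.linalg import solve_banded

from aerogate.constants import BOLTZMANN, ELEMENTARY_CHARGE, NM
from aerogate.pore_transport import (
    TransportProblem,
    species_potential,
    species_valence,
)


def fd_species_flux(problem: TransportProblem, species: str, voltage: float,
                    n_grid: int = 8193) -> float:
    """Finite-difference steady-state particle flux density (1/m^2/s).

    Dirichlet data: reservoir equilibrium with bulk, i.e. u(0) = c0 exp(z_s
    eV/kT), u(L) = c0 (u = c e^W absorbs the ring potential at the mouths).
    """
    pot = species_potential(problem, species, voltage, n_grid=n_grid)
    w = pot.values_kt
    z = pot.grid_nm * NM
    h = z[1] - z[0]
    c0 = problem.electrolyte.number_density_m3
    d = problem.electrolyte.diffusion(species)
    kT = BOLTZMANN * problem.electrolyte.temperature_k
    zs = species_valence(species)
    u0 = c0 * np.exp(zs * ELEMENTARY_CHARGE * voltage / kT)
    uL = c0
    # interior unknowns u_1 .. u_{n-2}; mobility e^{-W} at midpoints
    mob = np.exp(-0.5 * (w[:-1] + w[1:]))  # length n-1
    n = w.size
    offdiag = mob[1:-1]  # couples neighbouring interior unknowns
    diag = -(mob[:-1] + mob[1:])
    rhs = np.zeros(n - 2)
    rhs[0] -= mob[0] * u0
    rhs[-1] -= mob[-1] * uL
    ab = np.zeros((3, n - 2))
    ab[0, 1:] = offdiag
    ab[1, :] = diag
    ab[2, :-1] = offdiag
    u = solve_banded((1, 1), ab, rhs)
    u_full = np.concatenate(([u0], u, [uL]))
    # flux from every interior face, should be constant
    j_faces = -d * mob * (u_full[1:] - u_full[:-1]) / h
    return float(np.mean(j_faces))


def fd_current(problem: TransportProblem, voltage: float,
               n_grid: int = 8193) -> float:
    jc = fd_species_flux(problem, "cation", voltage, n_grid)
    ja = fd_species_flux(problem, "anion", voltage, n_grid)
    return problem.geometry.area_m2 * ELEMENTARY_CHARGE * (jc - ja)
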