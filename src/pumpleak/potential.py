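"""Zero-current closure: solving the membrane potential.

Bulk electroneutrality requires the summed charge flux across the
membrane to vanish at every instant.  The cotransporters are
electroneutral and drop out, leaving the channel fluxes and the pump
(which moves gamma Na+ out per 1 K+ in, i.e. a net outward charge flux
of beta*[Na]i*(1 - 1/gamma)).  The dimensionless potential u is the root
of that one-dimensional equation, found by bracketed Brent iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .model import RT_F, CellState, Medium, TransportParams, _u_over_g

__all__ = ["PotentialSolution", "BracketError", "net_charge_flux", "solve_potential"]


class BracketError(RuntimeError):
    """The charge-flux equation does not change sign over the bracket."""


@dataclass(frozen=True)
class PotentialSolution:
    u: float
    U: float  # mV, = RT_F * u
    residual: float
    iterations: int


def _charge_flux(
    u: float,
    nai: float,
    ki: float,
    cli: float,
    na0: float,
    k0: float,
    cl0: float,
    pna: float,
    pk: float,
    pcl: float,
    pump_charge: float,
) -> float:
    w = _u_over_g(u)
    eu = math.exp(u)
    return (
        pna * w * (nai * eu - na0)
        + pk * w * (ki * eu - k0)
        - pcl * w * (cli - cl0 * eu)
        - pump_charge
    )


def net_charge_flux(
    u: float,
    state: CellState,
    params: TransportParams,
    medium: Medium,
    beta: float | None = None,
) -> float:
    """Net charge flux (umol min^-1 ml^-1) through channels and pump at u.

    J_Na,ch + J_K,ch - J_Cl,ch - beta*[Na]i*(1 - 1/gamma); the
    electroneutral cotransporters contribute nothing.
    """
    b = params.beta if beta is None else beta
    return _charge_flux(
        u,
        state.na,
        state.k,
        state.cl,
        medium.na0,
        medium.k0,
        medium.cl0,
        params.pna,
        params.pk,
        params.pcl,
        b * state.na * (1.0 - 1.0 / params.gamma),
    )


def solve_potential(
    state: CellState,
    params: TransportParams,
    medium: Medium,
    bracket: tuple[float, float] = (-10.0, 5.0),
    tol: float = 1e-12,
    u_prev: float | None = None,
    beta: float | None = None,
) -> PotentialSolution:
    """Solve the zero-net-charge-flux condition for the dimensionless potential.

    Brent's method on `bracket` (u in [-10, 5] ~ U in [-267, +133] mV by
    default); if the flux does not change sign there the bracket is
    widened once by a factor of 2 before failing.  With `u_prev` given
    (trajectory context) a tight bracket around the previous potential is
    tried first, which also selects the root nearest the previous step.
    """
    b = params.beta if beta is None else beta
    args = (
        state.na,
        state.k,
        state.cl,
        medium.na0,
        medium.k0,
        medium.cl0,
        params.pna,
        params.pk,
        params.pcl,
        b * state.na * (1.0 - 1.0 / params.gamma),
    )

    def f(u: float) -> float:
        return _charge_flux(u, *args)

    candidates: list[tuple[float, float]] = []
    if u_prev is not None:
        candidates.append((u_prev - 0.3, u_prev + 0.3))
    lo, hi = bracket
    candidates.append((lo, hi))
    candidates.append((2.0 * lo, 2.0 * hi))

    last_endpoints = None
    for blo, bhi in candidates:
        flo, fhi = f(blo), f(bhi)
        last_endpoints = (blo, flo, bhi, fhi)
        if flo == 0.0:
            return PotentialSolution(blo, RT_F * blo, 0.0, 0)
        if fhi == 0.0:
            return PotentialSolution(bhi, RT_F * bhi, 0.0, 0)
        if flo * fhi < 0.0:
            u, res = brentq(f, blo, bhi, xtol=tol, full_output=True)
            return PotentialSolution(u, RT_F * u, f(u), res.iterations)
    blo, flo, bhi, fhi = last_endpoints
    raise BracketError(
        f"no sign change of the charge flux over u in [{blo:g}, {bhi:g}]: "
        f"f({blo:g}) = {flo:.6g}, f({bhi:g}) = {fhi:.6g}"
    )
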