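"""Inverse problems of the balanced state.

Given a resting measurement ([Na]i, [K]i, [Cl]i, water content, pump
rate coefficient) in a known medium, the two balance constraints yield
the impermeant-osmolyte concentration and mean valence in closed form,
and, for an assigned set of cotransport coefficients and a resting
membrane potential, the three channel permeability coefficients follow
from the requirement that every ion's net flux vanish.  OSOR (the ratio
of ouabain-sensitive to ouabain-resistant K+/Rb+ influx) is computed
from the unidirectional flux decomposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import (
    CellState,
    DomainError,
    FluxTable,
    Medium,
    ParameterError,
    TransportParams,
    _u_over_g,
    cotransporter_fluxes,
)

__all__ = [
    "RestingMeasurement",
    "PermeabilityFit",
    "InconsistentMeasurementError",
    "impermeant_properties",
    "state_from_measurement",
    "fit_permeabilities",
    "compute_osor",
]


class InconsistentMeasurementError(DomainError):
    """The measured concentrations cannot satisfy both balance constraints."""


@dataclass(frozen=True)
class RestingMeasurement:
    """A cell population's measured resting characteristics in a known medium."""

    na_i: float
    k_i: float
    cl_i: float
    v_over_a: float
    beta: float
    medium: Medium
    gamma: float = 1.5
    osor_measured: float | None = None

    def __post_init__(self) -> None:
        if min(self.na_i, self.k_i, self.cl_i) <= 0.0:
            raise ParameterError("measured concentrations must be > 0")
        if not self.v_over_a > 0.0:
            raise ParameterError("v_over_a must be > 0")
        if self.beta < 0.0:
            raise ParameterError("beta must be >= 0")


def impermeant_properties(m: RestingMeasurement) -> tuple[float, float]:
    """Impermeant-osmolyte valence and concentration from a resting measurement.

    Osmotic balance gives the impermeant concentration
    a_conc = osmolarity - ([Na]i + [K]i + [Cl]i); electroneutrality then
    fixes the mean valence z = ([Cl]i - [Na]i - [K]i)/a_conc.  Both are
    invariant under purely osmotic volume jumps (contents fixed, water
    rescaling all concentrations together).
    """
    ions = m.na_i + m.k_i + m.cl_i
    a_conc = m.medium.osmolarity() - ions
    if a_conc <= 0.0:
        raise InconsistentMeasurementError(
            f"internal ion osmolarity {ions:g} mOsm is not below the medium's "
            f"{m.medium.osmolarity():g} mOsm: impermeant osmolyte concentration "
            "would be non-positive"
        )
    z = (m.cl_i - m.na_i - m.k_i) / a_conc
    return z, a_conc


def state_from_measurement(m: RestingMeasurement) -> CellState:
    """CellState (A normalised to 1 mmol) consistent with the measurement."""
    z, a_conc = impermeant_properties(m)
    a = m.v_over_a * a_conc / 1000.0  # = 1 when v_over_a matches the osmotic v
    return CellState(
        qna=m.na_i * m.v_over_a,
        qk=m.k_i * m.v_over_a,
        qcl=m.cl_i * m.v_over_a,
        z=z,
        v=m.v_over_a,
        a=a,
    )


@dataclass(frozen=True)
class PermeabilityFit:
    pna: float
    pk: float
    pcl: float
    feasible: bool
    infeasible_ions: tuple[str, ...] = ()
    indeterminate_ions: tuple[str, ...] = ()

    def as_params(self, m: RestingMeasurement, inc: float, ikc: float, inkcc: float) -> TransportParams:
        if not self.feasible:
            raise DomainError(
                f"permeability fit infeasible for ions {self.infeasible_ions + self.indeterminate_ions}"
            )
        return TransportParams(
            pna=self.pna,
            pk=self.pk,
            pcl=self.pcl,
            beta=m.beta,
            gamma=m.gamma,
            inc=inc,
            ikc=ikc,
            inkcc=inkcc,
        )


def fit_permeabilities(
    m: RestingMeasurement,
    inc: float = 0.0,
    ikc: float = 0.0,
    inkcc: float = 0.0,
    u: float = 0.0,
) -> PermeabilityFit:
    """Channel permeabilities making the measured state a fixed point at potential u.

    Each steady-state flux balance is linear in its own permeability
    coefficient, so the solution is closed-form:
    pX = (required channel net flux of X) / (GHK concentration factor).
    A negative solution means no passive channel can close that ion's
    balance (flagged infeasible); a vanishing concentration factor with a
    vanishing residual flux (e.g. Cl at Donnan equilibrium with no
    cotransport) leaves the coefficient undetermined (flagged).
    """
    if u == 0.0:
        raise ParameterError("the resting potential u must be nonzero for the fit")
    if min(inc, ikc, inkcc) < 0.0:
        raise ParameterError("cotransport coefficients must be >= 0")
    state = state_from_measurement(m)
    probe = TransportParams(
        pna=0.0, pk=0.0, pcl=0.0, beta=m.beta, gamma=m.gamma, inc=inc, ikc=ikc, inkcc=inkcc
    )
    cot = cotransporter_fluxes(probe, m.medium, state)
    jnc, jkc, jnkcc = cot["nc"].net, cot["kc"].net, cot["nkcc"].net
    w = _u_over_g(u)
    eu = math.exp(u)
    # channel net flux per unit permeability
    phi_na = w * (m.na_i * eu - m.medium.na0)
    phi_k = w * (m.k_i * eu - m.medium.k0)
    phi_cl = w * (m.cl_i - m.medium.cl0 * eu)
    # required channel net fluxes
    need_na = m.beta * m.na_i - jnc - jnkcc
    need_k = -m.beta * m.na_i / m.gamma - jkc - jnkcc
    need_cl = -jnc - jkc - 2.0 * jnkcc

    scale = max(abs(need_na), abs(need_k), abs(need_cl), 1e-3)
    values: dict[str, float] = {}
    infeasible: list[str] = []
    indeterminate: list[str] = []
    for ion, phi, need in (("na", phi_na, need_na), ("k", phi_k, need_k), ("cl", phi_cl, need_cl)):
        if abs(phi) < 1e-12:
            values[ion] = 0.0
            indeterminate.append(ion)
            if abs(need) > 1e-9 * scale:
                infeasible.append(ion)
            continue
        p = need / phi
        if p < 0.0:
            infeasible.append(ion)
            p = 0.0 if p > -1e-15 else p
        values[ion] = p
    return PermeabilityFit(
        pna=values["na"],
        pk=values["k"],
        pcl=values["cl"],
        feasible=not infeasible and not indeterminate,
        infeasible_ions=tuple(infeasible),
        indeterminate_ions=tuple(indeterminate),
    )


def compute_osor(table: FluxTable) -> float:
    """Ratio of pump-mediated to passive unidirectional K+ influx.

    Mirrors the ouabain-sensitive / ouabain-resistant Rb+ influx ratio:
    pump K influx over the summed channel, KC and NKCC K influxes.
    Returns inf for a pump-only K uptake and nan when there is no K
    influx at all (undefined).
    """
    pump = table.pathway("k", "pump").influx
    passive = (
        table.pathway("k", "channel").influx
        + table.pathway("k", "kc").influx
        + table.pathway("k", "nkcc").influx
    )
    if passive <= 0.0:
        return math.inf if pump > 0.0 else math.nan
    return pump / passive
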