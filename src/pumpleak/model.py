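"""Core state types and flux laws of the pump-leak ion homeostasis model.

The cell is treated as a single well-mixed compartment exchanging Na+, K+
and Cl- with an infinite external medium through five pathways:
electroconductive channels (Goldman-type constant-field fluxes), the Na/K
ATPase pump with fixed flux stoichiometry gamma, and the electroneutral
cation-chloride cotransporters NC (1Na:1Cl), KC (1K:1Cl) and NKCC
(1Na:1K:2Cl).  Water moves freely, so osmotic balance holds at every
instant; macroscopic electroneutrality is maintained by the membrane
potential, which adjusts so that the summed charge flux through channels
and pump is zero (see :mod:`pumpleak.potential`).

Units
-----
Concentrations are mM (= umol per ml cell water).  Ion contents are
carried per unit of intracellular impermeant osmolyte A, in umol per mmol
of A (numerically equal to mmol per mol A as printed in the source
tables).  Cell water volume is per unit A, ml/mmol.  Fluxes are
umol * min^-1 * (ml cell water)^-1.  The thermal voltage RT/F is fixed at
26.7 mV (37 C).
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field, fields, replace
from typing import NamedTuple

__all__ = [
    "RT_F",
    "IONS",
    "PATHWAYS",
    "ParameterError",
    "DomainError",
    "Medium",
    "CellState",
    "TransportParams",
    "PathwayFlux",
    "FluxTable",
    "channel_fluxes",
    "pump_fluxes",
    "cotransporter_fluxes",
    "electrochemical_potentials",
    "content_derivatives",
    "flux_table",
]

#: Thermal voltage RT/F in mV at 37 C, as used throughout the model.
RT_F = 26.7

IONS = ("na", "k", "cl")
PATHWAYS = ("channel", "pump", "nc", "kc", "nkcc")


class ParameterError(ValueError):
    """A rate coefficient, concentration or stoichiometry is out of range."""


class DomainError(ValueError):
    """An operation was evaluated outside its mathematical domain."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Medium:
    """External medium composition, mM.

    ``b0`` is the concentration of membrane-impermeant non-electrolytes
    (sucrose, mannitol and the like, plus whatever balances the nominal
    osmolarity of the culture medium).
    """

    na0: float
    k0: float
    cl0: float
    b0: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0.0) or not math.isfinite(v):
                raise ParameterError(f"Medium.{f.name} must be finite and >= 0, got {v!r}")
        if self.osmolarity() <= 0.0:
            raise ParameterError("medium osmolarity must be positive")

    def osmolarity(self) -> float:
        """Total external osmolarity, mOsm (= na0 + k0 + cl0 + b0)."""
        return self.na0 + self.k0 + self.cl0 + self.b0

    def add_nacl(self, delta: float) -> "Medium":
        """Medium with `delta` mM NaCl added."""
        return replace(self, na0=self.na0 + delta, cl0=self.cl0 + delta)

    def add_nonelectrolyte(self, delta: float) -> "Medium":
        """Medium with `delta` mM impermeant non-electrolyte (e.g. sucrose) added."""
        return replace(self, b0=self.b0 + delta)


@dataclass(frozen=True)
class CellState:
    """Intracellular state: ion contents per unit impermeant osmolyte A.

    ``qna``, ``qk``, ``qcl`` are umol per mmol A; ``v`` is cell water per
    unit A, ml/mmol; ``z`` the mean valence of the impermeant osmolytes;
    ``a`` the amount of A (mmol), kept at 1 as the normalisation unit.
    Concentrations follow as q/v (mM).
    """

    qna: float
    qk: float
    qcl: float
    z: float
    v: float
    a: float = 1.0

    def __post_init__(self) -> None:
        if min(self.qna, self.qk, self.qcl) < 0.0:
            raise ParameterError("ion contents must be >= 0")
        if not self.v > 0.0:
            raise ParameterError(f"cell water volume must be positive, got {self.v!r}")
        if not self.a > 0.0:
            raise ParameterError("impermeant osmolyte amount must be positive")

    # concentration accessors, mM
    @property
    def na(self) -> float:
        return self.qna / self.v

    @property
    def k(self) -> float:
        return self.qk / self.v

    @property
    def cl(self) -> float:
        return self.qcl / self.v

    @property
    def a_conc(self) -> float:
        """Impermeant osmolyte concentration in cell water, mM."""
        return 1000.0 * self.a / self.v

    def osmolarity(self) -> float:
        """Total intracellular osmolarity, mOsm."""
        return self.na + self.k + self.cl + self.a_conc

    def charge_imbalance(self) -> float:
        """Relative electroneutrality residual (0 for a consistent state)."""
        total = self.qna + self.qk + self.qcl
        return (self.qna + self.qk - self.qcl + self.z * 1000.0 * self.a) / total

    def is_consistent(self, tol: float = 1e-9) -> bool:
        return abs(self.charge_imbalance()) < tol

    @classmethod
    def from_concentrations(
        cls, na: float, k: float, cl: float, medium: Medium, a: float = 1.0
    ) -> "CellState":
        """Build a state from measured concentrations, closing both balances.

        Water volume follows from osmotic balance with `medium`; the
        impermeant-osmolyte valence z follows from electroneutrality.
        """
        if min(na, k, cl) < 0.0:
            raise ParameterError("concentrations must be >= 0")
        rest = medium.osmolarity() - (na + k + cl)
        if rest <= 0.0:
            raise DomainError(
                "internal ion osmolarity exceeds the medium osmolarity: "
                "no room for impermeant osmolytes"
            )
        v = 1000.0 * a / rest
        z = (cl - na - k) / rest
        return cls(qna=na * v, qk=k * v, qcl=cl * v, z=z, v=v, a=a)

    def with_volume_balanced(self, medium: Medium) -> "CellState":
        """State with v recomputed so internal osmolarity equals the medium's."""
        v = (self.qna + self.qk + self.qcl + 1000.0 * self.a) / medium.osmolarity()
        return replace(self, v=v)


@dataclass(frozen=True)
class TransportParams:
    """Rate coefficients of the five transport pathways.

    pna/pk/pcl: channel permeability coefficients, min^-1.
    beta: pump rate coefficient, min^-1 (Na efflux via the pump = beta*[Na]i).
    gamma: pump Na:K flux stoichiometry (3:2 -> 1.5).
    inc/ikc: NC and KC cotransport rate coefficients, ml*umol^-1*min^-1.
    inkcc: NKCC rate coefficient, ml^3*umol^-3*min^-1.
    kb: linear pump-decay coefficient, min^-1 (beta(t) = beta*(1 - kb*t), clamped at 0).
    """

    pna: float
    pk: float
    pcl: float
    beta: float
    gamma: float = 1.5
    inc: float = 0.0
    ikc: float = 0.0
    inkcc: float = 0.0
    kb: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ParameterError(f"TransportParams.{f.name} must be finite")
            if f.name != "kb" and v < 0.0:
                raise ParameterError(f"TransportParams.{f.name} must be >= 0, got {v!r}")
        if not self.gamma > 0.0:
            raise ParameterError("gamma must be > 0")

    def beta_at(self, t: float) -> float:
        """Pump rate coefficient at time t (min) under linear decay, clamped at 0."""
        return max(0.0, self.beta * (1.0 - self.kb * t))

    def scaled(self, multipliers: Mapping[str, float]) -> "TransportParams":
        """New parameter set with the named coefficients multiplied."""
        allowed = {f.name for f in fields(self)} - {"gamma", "kb"}
        changes = {}
        for name, factor in multipliers.items():
            if name not in allowed:
                raise ParameterError(f"unknown or non-scalable parameter {name!r}")
            if not factor > 0.0:
                raise ParameterError(f"multiplier for {name!r} must be > 0")
            changes[name] = getattr(self, name) * factor
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# flux laws


def _u_over_g(u: float) -> float:
    # u / (1 - e^u); removable singularity at u = 0 handled by a 3-term
    # Taylor expansion (limit -1).  Always negative.
    if abs(u) < 1e-4:
        return -(1.0 - 0.5 * u + u * u / 12.0)
    return u / (-math.expm1(u))


class PathwayFlux(NamedTuple):
    """Unidirectional decomposition of one pathway's flux for one ion."""

    influx: float
    efflux: float

    @property
    def net(self) -> float:
        return self.influx + self.efflux


def channel_fluxes(
    p: float, u: float, ci: float, co: float, valence: int = 1
) -> PathwayFlux:
    """Constant-field (Goldman-type) channel flux for a monovalent ion.

    Net flux is p*u*(ci*e^u - co)/g for a cation and p*u*(ci - co*e^u)/g
    for an anion, with g = 1 - e^u.  The unidirectional split assigns the
    external-concentration term to the influx and the internal one to the
    efflux, so influx >= 0 and efflux <= 0 for any u.  At u -> 0 both
    reduce to the Fick limit net = p*(co - ci).
    """
    if p < 0.0:
        raise ParameterError(f"permeability must be >= 0, got {p!r}")
    if ci < 0.0 or co < 0.0:
        raise ParameterError("concentrations must be >= 0")
    if not math.isfinite(u):
        raise ParameterError("dimensionless potential must be finite")
    if valence not in (1, -1):
        raise ParameterError(f"valence must be +1 or -1, got {valence!r}")
    w = _u_over_g(u)  # < 0 for all u
    eu = math.exp(u)
    if valence == 1:
        return PathwayFlux(influx=-p * co * w, efflux=p * ci * eu * w)
    return PathwayFlux(influx=-p * co * eu * w, efflux=p * ci * w)


def pump_fluxes(beta: float, nai: float, gamma: float = 1.5) -> tuple[float, float]:
    """Na/K pump fluxes: (Na efflux = -beta*[Na]i, K influx = beta*[Na]i/gamma)."""
    if beta < 0.0 or nai < 0.0:
        raise ParameterError("beta and [Na]i must be >= 0")
    if not gamma > 0.0:
        raise ParameterError("gamma must be > 0")
    na_efflux = -beta * nai
    return na_efflux, beta * nai / gamma


def cotransporter_fluxes(
    params: TransportParams, medium: Medium, state: CellState
) -> dict[str, PathwayFlux]:
    """Unidirectional NC, KC and NKCC turnover fluxes (per carried ion pair).

    Each cotransporter's flux is the rate coefficient times the difference
    of external and internal concentration products; the influx is the
    external-product term, the efflux the internal one.  The returned flux
    is per transport event: Na and Cl each receive the NC flux, K and Cl
    the KC flux, and Na, K get the NKCC flux with Cl getting twice it.
    """
    nai, ki, cli = state.na, state.k, state.cl
    nc = PathwayFlux(
        influx=params.inc * medium.na0 * medium.cl0,
        efflux=-params.inc * nai * cli,
    )
    kc = PathwayFlux(
        influx=params.ikc * medium.k0 * medium.cl0,
        efflux=-params.ikc * ki * cli,
    )
    nkcc = PathwayFlux(
        influx=params.inkcc * medium.na0 * medium.k0 * medium.cl0 * medium.cl0,
        efflux=-params.inkcc * nai * ki * cli * cli,
    )
    return {"nc": nc, "kc": kc, "nkcc": nkcc}


class Potentials(NamedTuple):
    """Transmembrane electrochemical potential differences, mV."""

    mu_na: float
    mu_k: float
    mu_cl: float
    mu_nc: float
    mu_kc: float
    mu_nkcc: float


def electrochemical_potentials(state: CellState, medium: Medium, U: float) -> Potentials:
    """Per-ion electrochemical potential differences and cotransporter driving forces.

    mu_X = 26.7*ln([X]i/[X]o) + U for cations, - U for Cl-.  A
    cotransporter's driving force is the sum over its carried ions, with
    Cl counted twice for NKCC; its sign gives the direction of net
    coupled transport.
    """
    pairs = (
        (state.na, medium.na0),
        (state.k, medium.k0),
        (state.cl, medium.cl0),
    )
    for ci, co in pairs:
        if ci <= 0.0 or co <= 0.0:
            raise DomainError("electrochemical potentials need strictly positive concentrations")
    mu_na = RT_F * math.log(state.na / medium.na0) + U
    mu_k = RT_F * math.log(state.k / medium.k0) + U
    mu_cl = RT_F * math.log(state.cl / medium.cl0) - U
    return Potentials(
        mu_na=mu_na,
        mu_k=mu_k,
        mu_cl=mu_cl,
        mu_nc=mu_na + mu_cl,
        mu_kc=mu_k + mu_cl,
        mu_nkcc=mu_na + mu_k + 2.0 * mu_cl,
    )


def content_derivatives(
    state: CellState,
    params: TransportParams,
    medium: Medium,
    u: float,
    beta: float | None = None,
) -> tuple[float, float, float]:
    """Time derivatives of the ion contents (umol min^-1 per mmol A).

    Each is the cell water volume times the summed per-ml net fluxes:
    Na gets channel + pump + NC + NKCC; K gets channel + pump + KC + NKCC;
    Cl gets channel + NC + KC + 2*NKCC.  `beta` overrides the static pump
    rate coefficient (used by the integrator for time-decayed pumps).
    """
    b = params.beta if beta is None else beta
    nai, ki, cli = state.na, state.k, state.cl
    jna_ch = channel_fluxes(params.pna, u, nai, medium.na0, valence=1).net
    jk_ch = channel_fluxes(params.pk, u, ki, medium.k0, valence=1).net
    jcl_ch = channel_fluxes(params.pcl, u, cli, medium.cl0, valence=-1).net
    cot = cotransporter_fluxes(params, medium, state)
    jnc, jkc, jnkcc = cot["nc"].net, cot["kc"].net, cot["nkcc"].net
    na_pump, k_pump = pump_fluxes(b, nai, params.gamma)
    v = state.v
    dqna = v * (jna_ch + na_pump + jnc + jnkcc)
    dqk = v * (jk_ch + k_pump + jkc + jnkcc)
    dqcl = v * (jcl_ch + jnc + jkc + 2.0 * jnkcc)
    return dqna, dqk, dqcl


# ---------------------------------------------------------------------------
# flux table (per-ion, per-pathway decomposition)


@dataclass(frozen=True)
class FluxTable:
    """All unidirectional and net fluxes at one instant, plus potentials.

    Layout mirrors the ion x pathway tables of the source model: for each
    ion (na, k, cl) and pathway (channel, pump, nc, kc, nkcc) an
    (influx >= 0, efflux <= 0) pair, with net = influx + efflux, together
    with the membrane potential and the electrochemical driving forces.
    """

    fluxes: Mapping[tuple[str, str], PathwayFlux]
    u: float
    U: float
    mu: Potentials

    def pathway(self, ion: str, pathway: str) -> PathwayFlux:
        return self.fluxes[(ion, pathway)]

    def net(self, ion: str, pathway: str) -> float:
        return self.fluxes[(ion, pathway)].net

    def total_net(self, ion: str) -> float:
        return sum(self.fluxes[(ion, p)].net for p in PATHWAYS)

    def to_frame(self):
        """Flux table as a pandas DataFrame (ion x pathway rows)."""
        import pandas as pd

        rows = []
        for ion in IONS:
            for p in PATHWAYS:
                fl = self.fluxes[(ion, p)]
                rows.append(
                    {
                        "ion": ion,
                        "pathway": p,
                        "influx": fl.influx,
                        "efflux": fl.efflux,
                        "net": fl.net,
                    }
                )
            rows.append(
                {
                    "ion": ion,
                    "pathway": "total",
                    "influx": math.nan,
                    "efflux": math.nan,
                    "net": self.total_net(ion),
                }
            )
        return pd.DataFrame(rows)


def flux_table(
    state: CellState,
    params: TransportParams,
    medium: Medium,
    u: float,
    beta: float | None = None,
) -> FluxTable:
    """Assemble the full per-ion, per-pathway flux decomposition at potential u."""
    b = params.beta if beta is None else beta
    nai, ki, cli = state.na, state.k, state.cl
    cot = cotransporter_fluxes(params, medium, state)
    na_pump, k_pump = pump_fluxes(b, nai, params.gamma)
    zero = PathwayFlux(0.0, 0.0)
    nkcc = cot["nkcc"]
    fluxes: dict[tuple[str, str], PathwayFlux] = {
        ("na", "channel"): channel_fluxes(params.pna, u, nai, medium.na0, valence=1),
        ("na", "pump"): PathwayFlux(influx=0.0, efflux=na_pump),
        ("na", "nc"): cot["nc"],
        ("na", "kc"): zero,
        ("na", "nkcc"): nkcc,
        ("k", "channel"): channel_fluxes(params.pk, u, ki, medium.k0, valence=1),
        ("k", "pump"): PathwayFlux(influx=k_pump, efflux=0.0),
        ("k", "nc"): zero,
        ("k", "kc"): cot["kc"],
        ("k", "nkcc"): nkcc,
        ("cl", "channel"): channel_fluxes(params.pcl, u, cli, medium.cl0, valence=-1),
        ("cl", "pump"): zero,
        ("cl", "nc"): cot["nc"],
        ("cl", "kc"): cot["kc"],
        ("cl", "nkcc"): PathwayFlux(2.0 * nkcc.influx, 2.0 * nkcc.efflux),
    }
    mu = electrochemical_potentials(state, medium, RT_F * u)
    return FluxTable(fluxes=fluxes, u=u, U=RT_F * u, mu=mu)
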