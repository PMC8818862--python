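"""Flat YAML run configuration using the model's conventional symbol names.

Keys follow the software symbols of the source model's parameter table
(`na`, `k`, `cl` for internal concentrations; `na0`, `k0`, `cl0`, `B0`
for the medium; `pna`, `pk`, `pcl`, `beta`, `gamma`, `inc`, `ikc`,
`inkcc`, `kb` for transport; `kv`, `hp`, `dt`, `duration` for the
protocol; optional `U` for the resting potential used by the
permeability fit).  Unknown keys are rejected by name.  A run may give
either a single top-level protocol or a `segments` list; each segment
may change the medium explicitly or via `kv` (the new/old osmolarity
ratio, realised by adding impermeant non-electrolyte), and may carry
`multipliers`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import Medium, ParameterError, TransportParams
from .dynamics import ProtocolSegment
from .scenarios import COTRANSPORTER_SETS, NORMAL_MEDIUM, U937_MEASUREMENT

__all__ = ["RunConfig", "ConfigError", "load_config", "loads_config", "dump_config", "builtin_config"]

log = logging.getLogger("pumpleak")


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the key."""


_STATE_KEYS = {"na", "k", "cl"}
_MEDIUM_KEYS = {"na0", "k0", "cl0", "B0"}
_PARAM_KEYS = {"pna", "pk", "pcl", "beta", "gamma", "inc", "ikc", "inkcc", "kb"}
_PROTOCOL_KEYS = {"kv", "hp", "dt", "duration"}
_OTHER_KEYS = {"U", "seed", "out", "segments"}
_TOP_KEYS = _STATE_KEYS | _MEDIUM_KEYS | _PARAM_KEYS | _PROTOCOL_KEYS | _OTHER_KEYS
_SEGMENT_KEYS = _MEDIUM_KEYS | {"kv", "hp", "dt", "duration", "multipliers"}

_REQUIRED = ("na", "k", "cl", "na0", "k0", "cl0", "pna", "pk", "pcl", "beta")


@dataclass(frozen=True)
class RunConfig:
    """A validated run: initial concentrations, medium, parameters, protocol."""

    na: float
    k: float
    cl: float
    medium: Medium
    params: TransportParams
    segments: tuple[ProtocolSegment, ...]
    U: float | None = None
    seed: int | None = None
    out: str | None = None

    def to_dict(self) -> dict:
        d: dict = {
            "na": self.na,
            "k": self.k,
            "cl": self.cl,
            "na0": self.medium.na0,
            "k0": self.medium.k0,
            "cl0": self.medium.cl0,
            "B0": self.medium.b0,
        }
        for key in _PARAM_KEYS:
            d[key] = getattr(self.params, key)
        if self.U is not None:
            d["U"] = self.U
        if self.seed is not None:
            d["seed"] = self.seed
        if self.out is not None:
            d["out"] = self.out
        segs = []
        for s in self.segments:
            seg: dict = {"duration": s.duration, "dt": s.dt, "hp": s.hp}
            if s.medium is not None:
                seg.update(na0=s.medium.na0, k0=s.medium.k0, cl0=s.medium.cl0, B0=s.medium.b0)
            if s.multipliers:
                seg["multipliers"] = dict(s.multipliers)
            segs.append(seg)
        d["segments"] = segs
        return d


def _number(raw: object, key: str) -> float:
    if isinstance(raw, bool) or not isinstance(raw, (int, float)):
        raise ConfigError(f"key {key!r}: expected a number, got {raw!r}")
    v = float(raw)
    if not math.isfinite(v):
        raise ConfigError(f"key {key!r}: value must be finite, got {raw!r}")
    return v


def _segment_from(raw: dict, base_medium: Medium, index: str, dt: float, hp: int) -> ProtocolSegment:
    unknown = set(raw) - _SEGMENT_KEYS
    if unknown:
        raise ConfigError(f"segment {index}: unknown key(s) {sorted(unknown)!r}")
    if "duration" not in raw:
        raise ConfigError(f"segment {index}: missing required key 'duration'")
    duration = _number(raw["duration"], f"segment {index}.duration")
    if not duration > 0.0:
        raise ConfigError(f"segment {index}: duration must be > 0, got {duration!r}")
    medium = None
    explicit = _MEDIUM_KEYS & set(raw)
    if explicit:
        medium = Medium(
            na0=_number(raw.get("na0", base_medium.na0), "na0"),
            k0=_number(raw.get("k0", base_medium.k0), "k0"),
            cl0=_number(raw.get("cl0", base_medium.cl0), "cl0"),
            b0=_number(raw.get("B0", base_medium.b0), "B0"),
        )
        if "kv" in raw:
            log.warning(
                "segment %s: both kv and an explicit medium given; the explicit medium wins",
                index,
            )
    elif "kv" in raw:
        kv = _number(raw["kv"], "kv")
        if not kv > 0.0:
            raise ConfigError(f"segment {index}: kv must be > 0")
        # osmolarity rescale via impermeant non-electrolyte addition/removal
        delta = (kv - 1.0) * base_medium.osmolarity()
        if base_medium.b0 + delta < 0.0:
            raise ConfigError(f"segment {index}: kv {kv!r} would need negative B0")
        medium = base_medium.add_nonelectrolyte(delta)
    multipliers = raw.get("multipliers", {})
    if not isinstance(multipliers, dict):
        raise ConfigError(f"segment {index}: multipliers must be a mapping")
    multipliers = {k: _number(v, f"multipliers.{k}") for k, v in multipliers.items()}
    return ProtocolSegment(
        duration=duration,
        medium=medium,
        multipliers=multipliers,
        dt=_number(raw.get("dt", dt), "dt"),
        hp=int(raw.get("hp", hp)),
    )


def loads_config(text: str) -> RunConfig:
    """Parse and validate a YAML config from a string."""
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of keys to values")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown key(s): {sorted(unknown)!r}")
    missing = [k for k in _REQUIRED if k not in raw]
    if missing:
        raise ConfigError(f"missing required key(s): {missing!r}")

    numbers = {k: _number(v, k) for k, v in raw.items() if k not in ("segments", "out", "seed")}
    for key in _PARAM_KEYS & set(numbers):
        if key != "kb" and numbers[key] < 0.0:
            raise ConfigError(f"key {key!r}: rate coefficient must be >= 0, got {numbers[key]!r}")

    medium = Medium(
        na0=numbers["na0"],
        k0=numbers["k0"],
        cl0=numbers["cl0"],
        b0=numbers.get("B0", 0.0),
    )
    try:
        params = TransportParams(
            pna=numbers["pna"],
            pk=numbers["pk"],
            pcl=numbers["pcl"],
            beta=numbers["beta"],
            gamma=numbers.get("gamma", 1.5),
            inc=numbers.get("inc", 0.0),
            ikc=numbers.get("ikc", 0.0),
            inkcc=numbers.get("inkcc", 0.0),
            kb=numbers.get("kb", 0.0),
        )
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc

    dt = numbers.get("dt", 0.01)
    hp = int(raw.get("hp", 100))
    segments: list[ProtocolSegment]
    if "segments" in raw:
        if not isinstance(raw["segments"], list) or not raw["segments"]:
            raise ConfigError("'segments' must be a non-empty list")
        segments = []
        base = medium
        for i, seg_raw in enumerate(raw["segments"]):
            if not isinstance(seg_raw, dict):
                raise ConfigError(f"segment {i}: must be a mapping")
            seg = _segment_from(seg_raw, base, str(i), dt, hp)
            if seg.medium is None and i == 0:
                seg = ProtocolSegment(
                    duration=seg.duration, medium=base, multipliers=seg.multipliers, dt=seg.dt, hp=seg.hp
                )
            if seg.medium is not None:
                base = seg.medium
            segments.append(seg)
    else:
        duration = numbers.get("duration", 240.0)
        proto_medium = medium
        if "kv" in numbers:
            kv = numbers["kv"]
            delta = (kv - 1.0) * medium.osmolarity()
            if medium.b0 + delta < 0.0:
                raise ConfigError(f"kv {kv!r} would need negative B0")
            proto_medium = medium.add_nonelectrolyte(delta)
        segments = [ProtocolSegment(duration=duration, medium=proto_medium, dt=dt, hp=hp)]

    return RunConfig(
        na=numbers["na"],
        k=numbers["k"],
        cl=numbers["cl"],
        medium=medium,
        params=params,
        segments=tuple(segments),
        U=numbers.get("U"),
        seed=raw.get("seed"),
        out=raw.get("out"),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration file."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    return loads_config(p.read_text())


def dump_config(cfg: RunConfig, path: str | Path | None = None) -> str:
    """Serialise a RunConfig to YAML (repr-precision floats, lossless round-trip)."""
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def builtin_config(name: str) -> RunConfig:
    """Named reference configs: `table2_<set>` with set in full_set/nc/nc_kc/nc_nkcc.

    Each describes the U937 reference cell in normal medium with the
    published cotransporter coefficients and printed permeabilities, and
    a default 240-min protocol in the normal medium.
    """
    aliases = {
        "table2_full_set": "NC+KC+NKCC",
        "table2_nc": "NC",
        "table2_nc_kc": "NC+KC",
        "table2_nc_nkcc": "NC+NKCC",
    }
    if name not in aliases:
        raise ConfigError(f"unknown builtin config {name!r}; expected one of {sorted(aliases)}")
    cs = COTRANSPORTER_SETS[aliases[name]]
    m = U937_MEASUREMENT
    pna, pk, pcl = cs.printed_p
    return RunConfig(
        na=m.na_i,
        k=m.k_i,
        cl=m.cl_i,
        medium=NORMAL_MEDIUM,
        params=TransportParams(
            pna=pna, pk=pk, pcl=pcl, beta=m.beta, gamma=m.gamma,
            inc=cs.inc, ikc=cs.ikc, inkcc=cs.inkcc,
        ),
        segments=(ProtocolSegment(duration=240.0, medium=NORMAL_MEDIUM),),
        U=cs.U_rest,
    )
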