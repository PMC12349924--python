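"""Force-field and run-protocol parameter sets.

Defaults reproduce the three-bead solvent-free lipid model (full-strength
shifted WCA core, tail-tail cosine attraction, FENE bonds, head-tail2
straightening spring) and the published run protocol (Langevin thermostat
at T = 1.1 eps/kB with tc = 0.5 tau, in-plane Berendsen barostat at zero
tension with tc = 5 tau, dt = 0.005 tau).
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .units import UnitSystem, paper_units

__version__ = "0.1.0"


class ParameterError(ValueError):
    """Invalid or unknown parameter."""


@dataclass
class ForceFieldParams:
    """Constants of the pair and bonded potentials, in reduced units.

    ``eps_rep``/``rep_shifted`` carry the repulsion-strength variant: the
    default is the full-strength truncated-and-shifted WCA core of the
    original solvent-free model; setting ``eps_rep = 0.01`` with
    ``rep_shifted = False`` reproduces the literally printed (and
    mechanically unstable) variant for documentation purposes.
    """

    b_head_head: float = 0.95
    b_head_tail: float = 0.95
    b_tail_tail: float = 1.0
    eps_rep: float = 1.0
    rep_shifted: bool = True
    rc: float = 2.0 ** (1.0 / 6.0)     # onset of the tail-tail cosine taper
    wc: float = 1.7                    # taper width; sets cohesion/fluidity
    k_fene: float = 30.0
    r_inf: float = 1.5
    k_bend: float = 10.0
    r0_bend: float = 4.0
    eps_np: float = 0.2                # nanoparticle-membrane adhesion
    b_np: float = 2.0 ** (7.0 / 6.0)   # ~2.2449 sigma
    rcut_np: float = 3.0 * 2.0 ** (7.0 / 6.0)
    # phenomenological ligand-receptor attraction (receptor heads to spike
    # beads); no published value — chosen so receptors co-rotate visibly
    eps_receptor: float = 2.0
    b_cargo_cargo: float = 2.0

    def __post_init__(self) -> None:
        if self.wc <= 0:
            raise ParameterError("wc must be positive")
        if self.r_inf <= 0:
            raise ParameterError("r_inf must be positive")
        if self.rcut_np <= self.b_np:
            raise ParameterError("rcut_np must exceed b_np")
        for name in ("b_head_head", "b_head_tail", "b_tail_tail", "rc"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


@dataclass
class ProtocolParams:
    """Integration, thermostat/barostat and scene-level run settings."""

    dt: float = 0.005
    thermostat_tc: float = 0.5
    barostat_tc: float = 5.0
    temperature: float = 1.1
    box_xy: float = 20.0
    box_z: float = 400.0
    n_steps: int = 10_000
    seed: int = 0
    rotation_frequency: float = 1.0 / 5000.0
    robot_enabled: bool = True
    robot_static: bool = False
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    cargo_count: int = 100
    cargo_diameter: float = 2.0
    frame_interval: int = 1000
    barostat_enabled: bool = True
    thermostat_enabled: bool = True
    receptor_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt > 0.005 + 1e-12:
            raise ParameterError(
                "dt must be in (0, 0.005] tau (0.005 is the tested maximum)"
            )
        if self.barostat_enabled and self.barostat_tc < 10 * self.dt:
            raise ParameterError("barostat_tc must be at least 10*dt")
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")
        if self.n_steps < 0 or self.cargo_count < 0:
            raise ParameterError("counts must be non-negative")
        if not 0.0 <= self.receptor_fraction <= 1.0:
            raise ParameterError("receptor_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# TOML configuration
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "forcefield": ForceFieldParams,
    "protocol": ProtocolParams,
}

_UNITS_FIELDS = {"sigma_SI", "tau_SI", "epsilon_SI", "boltzmann_SI"}


@dataclass
class RunConfig:
    """Fully resolved configuration of one run."""

    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    units: UnitSystem = field(default_factory=paper_units)
    # builder geometry (robot + bilayer), kept as a plain dict of overrides
    builder: dict[str, Any] = field(default_factory=dict)


def _apply_section(cls, data: dict[str, Any], section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ParameterError(
            f"unknown key(s) in [{section}]: {sorted(unknown)}; "
            f"known keys: {sorted(known)}"
        )
    if "rotation_axis" in data:
        data = dict(data)
        data["rotation_axis"] = tuple(data["rotation_axis"])
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML run configuration; unknown sections or keys are errors."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    allowed = {"units", "forcefield", "protocol", "builder"}
    unknown = set(raw) - allowed
    if unknown:
        raise ParameterError(
            f"unknown section(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    cfg = RunConfig()
    if "units" in raw:
        data = raw["units"]
        bad = set(data) - _UNITS_FIELDS
        if bad:
            raise ParameterError(f"unknown key(s) in [units]: {sorted(bad)}")
        cfg.units = UnitSystem(**{**_unit_defaults(), **data})
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            setattr(cfg, section, _apply_section(cls, raw[section], section))
    if "builder" in raw:
        from .builder import BUILDER_KEYS

        bad = set(raw["builder"]) - BUILDER_KEYS
        if bad:
            raise ParameterError(f"unknown key(s) in [builder]: {sorted(bad)}")
        cfg.builder = dict(raw["builder"])
    return cfg


def _unit_defaults() -> dict[str, float]:
    u = paper_units()
    return {
        "sigma_SI": u.sigma_SI,
        "tau_SI": u.tau_SI,
        "epsilon_SI": u.epsilon_SI,
        "boltzmann_SI": u.boltzmann_SI,
    }


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    d = {
        "units": dataclasses.asdict(cfg.units),
        "forcefield": dataclasses.asdict(cfg.forcefield),
        "protocol": dataclasses.asdict(cfg.protocol),
        "builder": dict(cfg.builder),
    }
    d["protocol"]["rotation_axis"] = list(d["protocol"]["rotation_axis"])
    return d


def write_manifest(
    path: str | Path,
    cfg: RunConfig,
    seed: int,
    extra: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Write the reproducibility manifest (resolved parameters + seed)."""
    manifest = {
        "code_version": __version__,
        "seed": int(seed),
        "config": config_to_dict(cfg),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
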