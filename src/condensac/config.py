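"""Declarative run configuration: typed validation, TOML round-trip, freezing.

A run is characterised by the loop statistics (uniform or Poisson loops of
mean length ``L_loop_beads``), the soft-repulsion amplitude ``A_kBT`` that
stands in for topoisomerase II activity, the bridge count and affinities,
and the scenario flag (control, condensin knockouts, fragile-site
perturbations, sister chromatids).  Every run writes a frozen copy of the
resolved configuration plus the RNG seed so any trajectory can be
regenerated bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .units import ConfigurationError, UnitSystem

SCHEMA_VERSION = 1

LOOP_MODES = ("uniform", "poisson")
SCENARIOS = ("control", "condI_KO", "condII_KO", "cfs_removal", "cfs_merge", "sisters")

#: minimum loop length in beads (10 kbp); shorter loops would put a
#: loop-closure spring between already-bonded neighbours
MIN_LOOP_BEADS = 5


@dataclass
class RunConfig:
    """Complete declarative description of one simulation run."""

    loop_mode: str = "uniform"
    L_loop_beads: int = 40          # 40/50/60 sigma = 80/100/120 kbp
    n_loops: int = 350              # single chromatids carry 300-400 loops
    A_kBT: float = 10.0             # soft amplitude, one of {1, 10, 100}
    n_bridges: int = 500
    eps_weak_kBT: float = 3.0       # bridge - generic chromatin
    eps_strong_kBT: float = 8.0     # bridge - loop anchor
    eps_bridge_bridge_kBT: float = 1.0
    dt_tau: float = 0.01
    gamma: float = 1.0
    seed: int = 0
    box_side_sigma: float = 0.0     # 0 -> auto-size from the initial bottlebrush
    scenario: str = "control"
    phase_durations: dict = field(
        default_factory=lambda: {"equilibration": 200.0, "compaction": 1000.0}
    )
    snapshot_stride_tau: float = 10.0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.loop_mode not in LOOP_MODES:
            raise ConfigurationError(f"loop_mode must be one of {LOOP_MODES}")
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"scenario must be one of {SCENARIOS}")
        if self.L_loop_beads < MIN_LOOP_BEADS:
            raise ConfigurationError(
                f"L_loop_beads must be >= {MIN_LOOP_BEADS} (got {self.L_loop_beads})"
            )
        if self.n_loops < 1:
            raise ConfigurationError("n_loops must be >= 1")
        if self.n_bridges < 0:
            raise ConfigurationError("n_bridges must be >= 0")
        for name in ("eps_weak_kBT", "eps_strong_kBT", "eps_bridge_bridge_kBT"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not self.dt_tau > 0:
            raise ConfigurationError("dt_tau must be positive")
        if not self.A_kBT >= 0:
            raise ConfigurationError("A_kBT must be non-negative")
        if self.box_side_sigma < 0:
            raise ConfigurationError("box_side_sigma must be >= 0 (0 = auto)")
        for key, value in self.phase_durations.items():
            if value < 0:
                raise ConfigurationError(f"phase duration {key!r} must be >= 0")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _format_toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    raise TypeError(f"unsupported TOML value {value!r}")


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration as a flat TOML document."""
    lines = []
    for key, value in config.to_dict().items():
        if isinstance(value, dict):
            continue
        lines.append(f"{key} = {_format_toml_value(value)}")
    lines.append("")
    lines.append("[phase_durations]")
    for key, value in config.phase_durations.items():
        lines.append(f"{key} = {_format_toml_value(value)}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> RunConfig:
    """Read a TOML configuration file, applying typed validation."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    version = raw.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigurationError(
            f"config schema version {version} not supported (expected {SCHEMA_VERSION})"
        )
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    return RunConfig(**raw)


def default_units() -> UnitSystem:
    return UnitSystem()
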