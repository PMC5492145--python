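"""Structured run configuration.

One YAML mapping drives a whole analysis run; CLI flags override single
fields.  Every tunable has a recorded default so the provenance block can
echo the full effective configuration, and any stochastic stage requires
an explicit seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigError
from .model import ChannelDefinition


@dataclass
class EstimatorParams:
    block_ns: float = 500.0
    n_boot: int = 1000


@dataclass
class CutoffParams:
    coordination: float = 2.8  # Å, metal–donor
    salt_bridge: float = 4.0  # Å, N···O
    occupancy_min: float = 0.5
    persistence: int = 25  # frames


@dataclass
class HydrationParams:
    window_ns: float = 50.0


@dataclass
class RunConfig:
    """Validated configuration for :func:`flexmd.pipeline.run_pipeline`."""

    seed: int
    outdir: str
    stages: list[str] = field(default_factory=lambda: ["flux", "conductance"])
    simulate: dict | None = None  # {"kind": "channel"|"ligase", "config": {...}}
    topology: str | None = None
    trajectory: str | None = None
    dt: float | None = None  # ns per frame when reading trajectories
    channel: dict = field(default_factory=dict)
    ion_species: list[str] = field(default_factory=lambda: ["K", "CL"])
    water_residue: str = "HOH"
    regions: list[dict] = field(default_factory=list)
    estimator: EstimatorParams = field(default_factory=EstimatorParams)
    cutoffs: CutoffParams = field(default_factory=CutoffParams)
    hydration: HydrationParams = field(default_factory=HydrationParams)

    KNOWN_STAGES = (
        "flux", "conductance", "hydration", "rmsd", "coordination",
        "saltbridges",
    )

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("field 'seed': mandatory for any stochastic step")
        for s in self.stages:
            if s not in self.KNOWN_STAGES:
                raise ConfigError(
                    f"field 'stages': unknown stage {s!r} "
                    f"(known: {', '.join(self.KNOWN_STAGES)})"
                )
        if self.simulate is None and self.trajectory is None:
            raise ConfigError(
                "field 'simulate'/'trajectory': provide either a generator "
                "block or input files"
            )
        if self.simulate is not None:
            kind = self.simulate.get("kind")
            if kind not in ("channel", "ligase"):
                raise ConfigError(
                    f"field 'simulate.kind': must be 'channel' or 'ligase', "
                    f"got {kind!r}"
                )
        if self.channel:
            # validates z_lo < z_hi etc. before any computation
            self.channel_definition()

    def channel_definition(self) -> ChannelDefinition:
        allowed = {"z_lo", "z_hi", "voltage", "pore_radius", "axis_xy"}
        unknown = set(self.channel) - allowed
        if unknown:
            raise ConfigError(f"field 'channel': unknown keys {sorted(unknown)}")
        kw = dict(self.channel)
        if "axis_xy" in kw:
            kw["axis_xy"] = tuple(kw["axis_xy"])
        return ChannelDefinition(**kw)

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        for name, sub in (
            ("estimator", EstimatorParams),
            ("cutoffs", CutoffParams),
            ("hydration", HydrationParams),
        ):
            if name in data and isinstance(data[name], dict):
                extra = set(data[name]) - set(sub.__dataclass_fields__)
                if extra:
                    raise ConfigError(
                        f"field {name!r}: unknown keys {sorted(extra)}"
                    )
                data[name] = sub(**data[name])
        if "seed" not in data:
            raise ConfigError("field 'seed': mandatory for any stochastic step")
        if "outdir" not in data:
            raise ConfigError("field 'outdir': required")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path!r} is not a mapping")
        return cls.from_dict(data)
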