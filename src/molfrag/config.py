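"""Declarative run configuration (YAML).

A run config names the host structure, the fragment specs, nonbonded
and grouping parameters, restraint settings with ramp schedules, target
histogram files, and the protocol stages. Example::

    pdb: bundle.pdb
    nonbonded: {delta: 1.0, switch_on: 10.0, cutoff: 12.0, dielectric: 1.0}
    fragments:
      - {kind: cd_bridge, sites: [106, 406]}
      - {kind: dummy_label, sites: [1], n_copies: 25}
    grouping: {cutoff: 12.0, max_groups: 255}
    restraints:
      anchor_k_bridge: 50.0
      anchor_k_label: 10.0
      salt_bridge_k: 10.0
      ramps:
        bridge_on: [[0, 5000, 0.0, 1.0]]
    histogram: {K: 500.0, sigma: 1.1, delta_r: 1.0, n_bins: 60}
    targets:
      - {sites: [1, 120], file: pair_1_120.hist}
    protocol:
      seed: 1
      stages:
        - {mode: minimize, n_steps: 1000, tol: 1.0e-4}
        - {mode: dynamics, n_steps: 10000, temperature: 300, dt: 1.0}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import Protocol, Stage
from .restraints import RampSchedule
from .system import FragmentSpec


class ConfigError(ValueError):
    pass


@dataclass
class NonbondedConfig:
    delta: float = 1.0
    switch_on: float = 10.0
    cutoff: float = 12.0
    dielectric: float = 1.0


@dataclass
class GroupingConfig:
    cutoff: float = 12.0
    max_groups: int = 255


@dataclass
class RestraintConfig:
    anchor_k_bridge: float = 50.0
    anchor_k_label: float = 10.0
    salt_bridge_k: float = 10.0
    secondary_k: float = 5.0
    backbone_positional_k: float = 100.0
    ramps: dict[str, RampSchedule] = field(default_factory=dict)


@dataclass
class HistogramConfig:
    K: float = 500.0
    sigma: float = 1.1
    delta_r: float = 1.0
    n_bins: int = 60


@dataclass
class TargetConfig:
    sites: tuple[int, int]
    path: Path


@dataclass
class RunConfig:
    pdb: Path | None
    fragments: list[FragmentSpec]
    nonbonded: NonbondedConfig
    grouping: GroupingConfig
    restraints: RestraintConfig
    histogram: HistogramConfig
    targets: list[TargetConfig]
    protocol: Protocol
    helix_ranges: list[tuple[int, int]] = field(default_factory=list)
    label_seed: int = 0


def _fragment_spec(d: dict) -> FragmentSpec:
    try:
        return FragmentSpec(
            kind=d["kind"],
            host_sites=tuple(d["sites"]),
            mutations=tuple(d.get("mutations", ())),
            n_copies=int(d.get("n_copies", 1)),
        )
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"bad fragment spec {d}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path.name}: top level must be a mapping")
    base = path.parent

    nb = NonbondedConfig(**raw.get("nonbonded", {}))
    grouping = GroupingConfig(**raw.get("grouping", {}))
    rest_raw = dict(raw.get("restraints", {}))
    ramps = {
        name: RampSchedule([tuple(stage) for stage in stages])
        for name, stages in rest_raw.pop("ramps", {}).items()
    }
    restraints = RestraintConfig(ramps=ramps, **rest_raw)
    hist = HistogramConfig(**raw.get("histogram", {}))
    fragments = [_fragment_spec(d) for d in raw.get("fragments", [])]
    targets = [
        TargetConfig(sites=tuple(t["sites"]), path=base / t["file"])
        for t in raw.get("targets", [])
    ]
    proto_raw = raw.get("protocol", {})
    stages = [Stage(**s) for s in proto_raw.get("stages", [])]
    protocol = Protocol(stages=stages, seed=int(proto_raw.get("seed", 0)))
    pdb = raw.get("pdb")
    return RunConfig(
        pdb=base / pdb if pdb else None,
        fragments=fragments,
        nonbonded=nb,
        grouping=grouping,
        restraints=restraints,
        histogram=hist,
        targets=targets,
        protocol=protocol,
        helix_ranges=[tuple(h) for h in raw.get("helix_ranges", [])],
        label_seed=int(raw.get("label_seed", 0)),
    )
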