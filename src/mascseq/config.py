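"""Run configuration: nested sections, defaults, strict validation.

A run is fully specified by one YAML file (any subset of keys; missing keys
take documented defaults) plus a seed. Unknown keys are rejected, and all
constraint violations are reported together so a config can be fixed in one
pass.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ArraySection",
    "SimSection",
    "DemuxSection",
    "StatsSection",
    "RunConfig",
    "ConfigError",
    "validate_config",
]


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


@dataclass
class ArraySection:
    n_barcoded: int = 1934
    n_frame: int = 66
    pitch_um: float = 150.0
    spot_diameter_um: float = 100.0
    barcode_length: int = 18
    umi_length: int = 9
    min_hamming: int = 3
    r1_length: int = 31
    r2_length: int = 121


@dataclass
class SimSection:
    n_genes: int = 200
    transcript_length_min: int = 300
    transcript_length_max: int = 1500
    rrna_fraction: float = 0.05
    n_single: int = 194
    n_double: int = 40
    n_cluster: int = 20
    budget_low: int = 1250
    budget_high: int = 6250
    dispersion: float = 0.3
    expression_sigma: float = 1.2
    leakage_fraction: float = 0.05
    pcr_duplicate_mean: float = 2.0
    substitution_error_rate: float = 0.001
    antisense_fraction: float = 0.0
    low_quality_fraction: float = 0.0


@dataclass
class DemuxSection:
    max_mismatch: int = 1
    require_unique_best: bool = True
    window_bp: int = 250
    umi_max_mismatch: int = 1
    min_mean_q: float = 20.0
    homopolymer_max_run: int = 15
    min_r2_len: int = 30
    min_match: int = 30
    seed_k: int = 17


@dataclass
class StatsSection:
    depth_fractions: list[float] = field(
        default_factory=lambda: [0.05, 0.1, 0.25, 0.5, 0.75, 1.0]
    )
    category_pairs: list[list[str]] = field(
        default_factory=lambda: [
            ["single", "background"],
            ["double", "single"],
            ["cluster", "double"],
        ]
    )
    top_n_genes: int = 10


@dataclass
class RunConfig:
    array: ArraySection = field(default_factory=ArraySection)
    sim: SimSection = field(default_factory=SimSection)
    demux: DemuxSection = field(default_factory=DemuxSection)
    stats: StatsSection = field(default_factory=StatsSection)
    seed: int = 1

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


_SECTIONS = {"array": ArraySection, "sim": SimSection, "demux": DemuxSection, "stats": StatsSection}


def _build_section(cls: type, data: Any, name: str, problems: list[str]) -> Any:
    if data is None:
        data = {}
    if not isinstance(data, dict):
        problems.append(f"section {name!r} must be a mapping")
        return cls()
    known = {f.name: f for f in fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in known:
            problems.append(f"unknown key {name}.{key}")
            continue
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        problems.append(f"section {name!r}: {exc}")
        return cls()


def config_from_dict(data: dict[str, Any] | None) -> RunConfig:
    """Build a RunConfig, rejecting unknown keys and collecting all problems."""
    problems: list[str] = []
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError(["top-level config must be a mapping"])
    sections: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTIONS:
            sections[key] = _build_section(_SECTIONS[key], value, key, problems)
        elif key == "seed":
            sections["seed"] = value
        else:
            problems.append(f"unknown key {key}")
    cfg = RunConfig(**{k: v for k, v in sections.items()})
    problems.extend(_cross_field_problems(cfg))
    if problems:
        raise ConfigError(problems)
    return cfg


def _cross_field_problems(cfg: RunConfig) -> list[str]:
    p: list[str] = []
    a, s, d, st = cfg.array, cfg.sim, cfg.demux, cfg.stats
    if not isinstance(cfg.seed, int):
        p.append("seed must be an integer")
    if a.n_barcoded < 0 or a.n_frame < 0:
        p.append("array spot counts must be >= 0")
    if a.barcode_length + a.umi_length > a.r1_length:
        p.append("array.barcode_length + array.umi_length must fit in array.r1_length")
    if a.min_hamming < 1:
        p.append("array.min_hamming must be >= 1")
    occupied = s.n_single + s.n_double + s.n_cluster
    if occupied > a.n_barcoded:
        p.append(
            f"sim occupancy n_single+n_double+n_cluster = {occupied} exceeds the "
            f"{a.n_barcoded} barcoded spots on the array"
        )
    if s.n_genes < 1:
        p.append("sim.n_genes must be >= 1")
    if s.transcript_length_min > s.transcript_length_max:
        p.append("sim.transcript_length_min must be <= sim.transcript_length_max")
    if s.transcript_length_min < a.r2_length:
        p.append(
            f"sim.transcript_length_min ({s.transcript_length_min}) must be >= the "
            f"R2 read length ({a.r2_length})"
        )
    if not (0 < s.budget_low <= s.budget_high):
        p.append("sim budgets must satisfy 0 < budget_low <= budget_high")
    for name in (
        "rrna_fraction",
        "leakage_fraction",
        "substitution_error_rate",
        "antisense_fraction",
        "low_quality_fraction",
    ):
        v = getattr(s, name)
        if not (0.0 <= v <= 1.0):
            p.append(f"sim.{name} must be a probability in [0, 1]")
    if s.pcr_duplicate_mean < 0:
        p.append("sim.pcr_duplicate_mean must be >= 0")
    if s.dispersion < 0:
        p.append("sim.dispersion must be >= 0")
    if d.max_mismatch < 0:
        p.append("demux.max_mismatch must be >= 0")
    if d.window_bp <= 0:
        p.append("demux.window_bp must be positive")
    if d.umi_max_mismatch not in (0, 1):
        p.append("demux.umi_max_mismatch must be 0 or 1")
    if min(d.min_mean_q, d.homopolymer_max_run, d.min_r2_len, d.min_match, d.seed_k) <= 0:
        p.append("demux thresholds must be positive")
    if not st.depth_fractions or any(not (0 < f <= 1) for f in st.depth_fractions):
        p.append("stats.depth_fractions must be fractions in (0, 1]")
    if sorted(set(st.depth_fractions)) != list(st.depth_fractions):
        p.append("stats.depth_fractions must be strictly increasing")
    if st.top_n_genes < 1:
        p.append("stats.top_n_genes must be >= 1")
    for pair in st.category_pairs:
        if len(pair) != 2:
            p.append(f"stats.category_pairs entry {pair!r} must name exactly two categories")
    return p


def validate_config(path: str | Path | None) -> RunConfig:
    """Load + validate a YAML config file; ``None``/empty file -> full defaults."""
    if path is None:
        return config_from_dict({})
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) if raw.strip() else {}
    return config_from_dict(data)
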