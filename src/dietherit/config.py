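"""Pipeline configuration: YAML loading, validation, defaults, round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .qc import QCConfig
from .simdata import DEFAULT_K_DISTRIBUTION, ItemSpec


@dataclass
class SimulationConfig:
    n_individuals: int = 500
    n_snps: int = 500
    ld_rho: float = 0.8
    rho_range: tuple[float, float] | None = (0.1, 0.95)
    block_snps: int = 25
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2: float = 0.5
    n_causal: int = 50
    items: list[dict] = field(default_factory=lambda: [
        {"name": "coffee", "kind": "quantity", "prevalence": 0.7, "icc": 0.7},
        {"name": "tea", "kind": "quantity", "prevalence": 0.6, "icc": 0.6},
        {"name": "chocolate", "kind": "binary", "prevalence": 0.3, "icc": 0.15},
        {"name": "porridge", "kind": "binary", "prevalence": 0.2, "icc": 0.4},
    ])
    k_distribution: tuple[float, ...] = DEFAULT_K_DISTRIBUTION
    qc_violation_rate: float = 0.02

    def item_specs(self) -> list[ItemSpec]:
        return [ItemSpec(**d) for d in self.items]


@dataclass
class DerivationConfig:
    category_precision: int = 0
    donor_map: dict[str, str] = field(default_factory=dict)
    min_interior: int = 50


@dataclass
class GeneticsConfig:
    maf_min: float = 0.005
    mac_min: int = 10
    miss_max: float = 0.10
    window_bp: int = 500_000
    p_threshold: float = 5e-8
    meff_method: str = "galwey"


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "results/pipeline"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    derivation: DerivationConfig = field(default_factory=DerivationConfig)
    genetics: GeneticsConfig = field(default_factory=GeneticsConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["maf_range"] = list(d["simulation"]["maf_range"])
        d["simulation"]["k_distribution"] = list(d["simulation"]["k_distribution"])
        if d["simulation"]["rho_range"] is not None:
            d["simulation"]["rho_range"] = list(d["simulation"]["rho_range"])
        return d

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


_BLOCKS = {
    "simulation": SimulationConfig,
    "qc": QCConfig,
    "derivation": DerivationConfig,
    "genetics": GeneticsConfig,
}

# keys that must be stated explicitly whenever their block appears at all
_REQUIRED_IN_BLOCK = {"simulation": ("n_individuals", "n_snps")}


def _build_block(name: str, raw: dict):
    cls = _BLOCKS[name]
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown key(s) in {name!r} block: {sorted(unknown)}")
    for req in _REQUIRED_IN_BLOCK.get(name, ()):
        if req not in raw:
            raise KeyError(f"missing required key {name}.{req}")
    kwargs = dict(raw)
    if name == "simulation":
        if "maf_range" in kwargs:
            kwargs["maf_range"] = tuple(kwargs["maf_range"])
        if "k_distribution" in kwargs:
            kwargs["k_distribution"] = tuple(kwargs["k_distribution"])
        if kwargs.get("rho_range") is not None:
            kwargs["rho_range"] = tuple(kwargs["rho_range"])
    return cls(**kwargs)


def config_from_dict(raw: dict) -> PipelineConfig:
    known_top = {"seed", "output_dir"} | set(_BLOCKS)
    unknown = set(raw) - known_top
    if unknown:
        raise KeyError(f"unknown top-level key(s): {sorted(unknown)}")
    if "seed" not in raw:
        raise KeyError("missing required key: seed")
    kwargs: dict = {"seed": int(raw["seed"])}
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    for name in _BLOCKS:
        if name in raw:
            kwargs[name] = _build_block(name, raw[name] or {})
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config {p}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"config {p} must be a mapping")
    return config_from_dict(raw)
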