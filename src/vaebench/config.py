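"""Benchmark configuration: one human-editable YAML file drives a run.

Unknown keys are rejected so typos fail loudly rather than silently
falling back to defaults. `example_config()` returns a fully-populated
config whose values document the defaults inline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .training import DEFAULT_GRID

__all__ = ["BenchmarkConfig", "load_config", "save_config", "example_config"]


@dataclass
class BenchmarkConfig:
    """Everything one benchmark run needs, serializable to YAML."""

    # dataset: either paths to expression+metadata tables, or synthetic parameters
    expression_path: str | None = None
    metadata_path: str | None = None
    synthetic: dict = field(default_factory=lambda: {
        "n_samples": 600, "n_genes": 300, "n_clusters": 6, "d_true": 10,
        "cluster_separation": 10.0, "noise_sd": 1.0, "censor_frac": 0.3,
    })
    # preprocessing
    top_k_genes: int | None = None  # None: keep all genes
    # grid axes (missing axes fall back to the full default grid)
    grid: dict = field(default_factory=dict)
    # training settings
    max_epochs: int = 1000
    patience: int = 3
    n_restarts: int = 10
    batch_size: int = 128
    base_seed: int = 0
    train_frac: float = 0.7
    # evaluation toggles
    evaluate_clustering: bool = True
    evaluate_survival: bool = True
    evaluate_disentanglement: bool = False
    # per-variant loss-term weights (overrides of the documented defaults)
    variant_weights: dict = field(default_factory=dict)
    output_dir: str = "results"

    def grid_axes(self) -> dict:
        g = dict(DEFAULT_GRID)
        g.update(self.grid)
        return g


_FIELDS = set(BenchmarkConfig.__dataclass_fields__)


def load_config(path) -> BenchmarkConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return BenchmarkConfig(**raw)


def save_config(cfg: BenchmarkConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


def example_config() -> str:
    """YAML text of the default configuration (shipped documentation)."""
    return yaml.safe_dump(asdict(BenchmarkConfig()), sort_keys=False)
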