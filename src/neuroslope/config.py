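"""Flat YAML pipeline configuration shared by all CLI stages."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

from .model import HyperParams
from .simdata import SimConfig


@dataclass
class PipelineConfig:
    """Everything the pipeline stages need, round-trippable through YAML."""

    out_dir: str = "neuroslope_out"
    seed: int = 0

    # simulation
    sim: SimConfig = field(default_factory=SimConfig)

    # pairing
    match_window_days: float = 45.0
    min_visits: int = 3
    min_gap_months: float = 6.0
    max_gap_months: float = 24.0
    change_threshold: float = 4.0

    # model
    hyperparams: HyperParams = field(default_factory=HyperParams)
    split_fraction: float = 0.7
    train_diagnosis: str = "CN"  # subjects whose pairs train the model; "" = all

    # QC
    max_missing: float = 0.02
    min_maf: float = 0.01
    hwe_p_min: float = 1e-6
    min_info: float = 0.1
    kinship_threshold: float = 0.0884
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.2
    n_pcs: int = 10

    # association / clumping
    model_number: int = 1
    p_lead: float = 1e-5
    r2_clump: float = 0.6
    r2_indep: float = 0.1
    merge_kb: float = 250.0
    ld_window_kb: float = 1000.0

    def __post_init__(self) -> None:
        if self.min_gap_months >= self.max_gap_months:
            raise ValueError("min_gap_months must be < max_gap_months")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")
        for name in ("max_missing", "min_maf", "hwe_p_min", "min_info", "prune_r2",
                     "r2_clump", "r2_indep"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be within [0, 1]")
        # propagate the global seed to the stage configs unless overridden
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**_tuplify(self.sim))
        if isinstance(self.hyperparams, dict):
            hp = dict(self.hyperparams)
            if "conv_widths" in hp:
                hp["conv_widths"] = tuple(hp["conv_widths"])
            self.hyperparams = HyperParams(**hp)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _tuplify(d: dict) -> dict:
    """YAML has no tuples; restore the tuple-typed SimConfig fields."""
    out = dict(d)
    for key in ("volume_shape", "maf_range", "dx_cutpoints"):
        if out.get(key) is not None:
            out[key] = tuple(out[key])
    for key in ("aging_region", "disease_region"):
        if out.get(key) is not None:
            out[key] = tuple(tuple(b) for b in out[key])
    if out.get("causal_snps") is not None:
        out["causal_snps"] = tuple((int(i), float(b)) for i, b in out["causal_snps"])
    return out


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj
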