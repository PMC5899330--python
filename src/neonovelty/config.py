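"""Pipeline configuration: one human-readable file (YAML or JSON) holding
the fixed analysis constants. Unknown keys are rejected."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .novelty import NoveltyConfig


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    strong_binding_threshold: float = 500.0  # nM
    fold_change_threshold: float = 5.0
    epitope_lengths: tuple[int, ...] = (9,)
    window_k: int = 9
    # provenance only: blastp E-value cap of the original search protocol.
    # The exact exhaustive search never discards hits, so this is unused.
    evalue_cap: float = 200000.0
    # per-length anchor-mask overrides, e.g. {9: (2, 9)}; default rule is
    # {2, length} for every length
    anchor_overrides: dict = field(default_factory=dict)
    response_threshold_pct: float = 10.0
    model_terms: tuple[str, ...] | None = None  # None = full additive model
    seed: int = 0

    def novelty(self) -> NoveltyConfig:
        return NoveltyConfig(
            strong_binding_threshold=self.strong_binding_threshold,
            fold_change_threshold=self.fold_change_threshold,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epitope_lengths"] = list(self.epitope_lengths)
        d["model_terms"] = list(self.model_terms) if self.model_terms else None
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        data = dict(data)
        if "epitope_lengths" in data:
            data["epitope_lengths"] = tuple(data["epitope_lengths"])
        if data.get("model_terms") is not None:
            data["model_terms"] = tuple(data["model_terms"])
        if "anchor_overrides" in data and data["anchor_overrides"]:
            data["anchor_overrides"] = {
                int(k): tuple(v) for k, v in data["anchor_overrides"].items()
            }
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        data = self.to_dict()
        if str(path).endswith(".json"):
            Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
        else:
            Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
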