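"""Pipeline-wide configuration: every stage threshold in one declarative object.

Defaults reproduce the published analysis settings exactly (log(e) <= -2.0,
intensity sum > 20,000, sentinel 10, >= 3 PSMs, p <= 0.01, fold-change calls at
1.2 / 0.83, enrichment at p <= 0.05, 6 profile clusters).  A YAML file mirrors
the dataclass layout; ``--set section.key=value`` overrides individual fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .quant import PurityMatrix, QuantConfig
from .simulate import SyntheticConfig


@dataclass(frozen=True)
class PipelineConfig:
    quant: QuantConfig = field(default_factory=QuantConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    up_threshold: float = 1.2
    down_threshold: float = 0.83
    enrich_p: float = 0.05
    k_clusters: int = 6
    purity_path: str | None = None  # None = the built-in default purity matrix
    channel_conditions: tuple[int, int, int, int] = (0, 50, 100, 200)  # mM, channel order
    seed: int = 0

    def validate(self) -> None:
        self.quant.validate()
        self.synthetic.validate()
        if not self.down_threshold < 1 < self.up_threshold:
            raise ConfigurationError(
                "fold-change thresholds must satisfy down < 1 < up, got "
                f"{self.down_threshold}, {self.up_threshold}"
            )
        if not 0 < self.enrich_p <= 1:
            raise ConfigurationError("enrich_p must be in (0, 1]")
        if self.k_clusters < 1:
            raise ConfigurationError("k_clusters must be >= 1")
        if len(self.channel_conditions) != 4:
            raise ConfigurationError("channel_conditions must list 4 conditions")

    def purity(self) -> PurityMatrix:
        if self.purity_path is None:
            return PurityMatrix.default()
        return PurityMatrix.from_tsv(self.purity_path)

    def condition_of_comparison(self) -> dict[str, int]:
        from .quant import comparison_channels

        out = {}
        for comp in self.quant.comparisons:
            ni, _ = comparison_channels(comp)
            out[comp] = self.channel_conditions[ni]
        return out

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # non-scalar synthetic fields need explicit treatment
        syn = d["synthetic"]
        syn.pop("purity", None)
        if self.synthetic.purity is not None:
            syn["purity"] = [list(row) for row in self.synthetic.purity.matrix]
        if syn.get("true_log2_fc") is not None:
            syn["true_log2_fc"] = {k: list(v) for k, v in syn["true_log2_fc"].items()}
        d["quant"]["comparisons"] = list(self.quant.comparisons)
        d["channel_conditions"] = list(self.channel_conditions)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        quant = dict(data.pop("quant", {}) or {})
        if "comparisons" in quant:
            quant["comparisons"] = tuple(quant["comparisons"])
        syn = dict(data.pop("synthetic", {}) or {})
        if syn.get("purity") is not None:
            syn["purity"] = PurityMatrix(syn["purity"])
        if "channel_conditions" in data:
            data["channel_conditions"] = tuple(data["channel_conditions"])
        try:
            cfg = cls(
                quant=QuantConfig(**quant),
                synthetic=SyntheticConfig(**syn),
                **data,
            )
        except TypeError as exc:
            raise ConfigurationError(f"unknown configuration key: {exc}") from None
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def with_overrides(self, overrides: dict[str, str]) -> "PipelineConfig":
        """Apply dotted-key string overrides, e.g. {'quant.p_max': '0.05'}."""
        data = self.to_dict()
        for key, raw in overrides.items():
            parts = key.split(".")
            node = data
            for p in parts[:-1]:
                if p not in node or not isinstance(node[p], dict):
                    raise ConfigurationError(f"unknown configuration section {p!r} in {key!r}")
                node = node[p]
            leaf = parts[-1]
            if leaf not in node:
                raise ConfigurationError(f"unknown configuration key {key!r}")
            node[leaf] = yaml.safe_load(raw)
        return PipelineConfig.from_dict(data)
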