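"""Run configuration shared by the orchestrator and the CLI.

A :class:`RunConfig` carries everything a per-pair run needs: which
backends serve each channel, ablation flags, path-search limits, batch
size, and failure policy.  It can be loaded from a YAML/JSON file whose
keys mirror the CLI flags; flags override file values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .errors import ConfigError
from .search import (DEFAULT_N_RESULTS, DEFAULT_POSITIVE_KEYWORDS,
                     DEFAULT_STRONG_KEYWORDS)

CHANNELS = ("ai", "kg", "search")


@dataclass
class RunConfig:
    # knowledge-graph channel
    kg_edges: str | None = None          # path to edge-list TSV/CSV
    max_hops: int = 4
    path_cap: int = 10_000
    # search channel
    search_backend: str = "fixture"      # fixture | live
    search_fixture: str | dict | None = None
    search_endpoint: str = "https://api.bing.microsoft.com/v7.0/search"
    search_n: int = DEFAULT_N_RESULTS
    positive_keywords: tuple[str, ...] = DEFAULT_POSITIVE_KEYWORDS
    strong_keywords: tuple[str, ...] = DEFAULT_STRONG_KEYWORDS
    # ML channel
    ai_backend: str = "mock"             # mock | lookup | deeppurpose
    ai_lookup: str | dict | None = None
    ai_seed: int = 0
    # text generation
    llm_backend: str = "template"        # template | live:<label>
    # fusion
    weights: dict[str, float] = field(default_factory=dict)
    # orchestration
    ablate: frozenset[str] = frozenset()
    batch_size: int = 10
    failure_policy: str = "skip"         # skip | fail
    # test/simulate-only hook pinning graph-channel scores for known pairs;
    # refused in normal mode so pinned values never pose as computed evidence
    mode: str = "normal"                 # normal | test | simulate
    kg_score_override: dict[tuple[str, str], float] | None = None

    def __post_init__(self):
        self.ablate = frozenset(self.ablate)
        bad = self.ablate - set(CHANNELS)
        if bad:
            raise ConfigError(f"unknown channels in ablate: {sorted(bad)}")
        if self.failure_policy not in ("skip", "fail"):
            raise ConfigError(f"failure_policy must be skip|fail, got {self.failure_policy!r}")
        if self.mode not in ("normal", "test", "simulate"):
            raise ConfigError(f"mode must be normal|test|simulate, got {self.mode!r}")
        if self.batch_size < 1:
            raise ConfigError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.max_hops < 1:
            raise ConfigError(f"max_hops must be >= 1, got {self.max_hops}")
        if self.kg_score_override and self.mode == "normal":
            raise ConfigError(
                "kg_score_override is a test/simulate-only hook; refuse to pin "
                "graph scores in normal mode")

    def enabled_channels(self) -> tuple[str, ...]:
        return tuple(c for c in CHANNELS if c not in self.ablate)


def load_config(path: str, **overrides) -> RunConfig:
    """Load a YAML (or JSON) config file; keyword overrides win."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = set(RunConfig.__dataclass_fields__)
    bad = set(data) - known
    if bad:
        raise ConfigError(f"unknown config keys: {sorted(bad)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def with_overrides(cfg: RunConfig, **overrides) -> RunConfig:
    return replace(cfg, **{k: v for k, v in overrides.items() if v is not None})
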