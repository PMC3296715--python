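"""Pipeline configuration: one flat document of overridable thresholds.

Defaults are the published analysis settings (E-value 1e-6, 50-b HSP
separation, 25-kb merge window, 200-b minimum event size, 200-b repeat
adjacency, 10-kb synteny flanks, alpha 0.05, ts/tv 2.0, 20-My recency
cutoff).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .types import ValidationError


@dataclass
class PipelineConfig:
    evalue_threshold: float = 1e-6
    hsp_sep_max_bases: int = 50
    merge_window_bases: int = 25000
    min_event_bases: int = 200
    repeat_adjacency_bases: int = 200
    synteny_flank_bases: int = 10000
    min_unmasked_flank_bases: int = 200
    min_flank_retrievable_bases: int = 100
    significance_alpha: float = 0.05
    ts_tv_ratio: float = 2.0
    recent_branch_age_cutoff_my: float = 20.0
    exclusion_split_label: str = "Drosophila_Sophophora"
    outgroup_age_my: float = 470.0
    random_seed: int = 0

    # seed-and-extend scoring; +2/-3 targets ~60% break-even identity,
    # keeping HSP boundaries tight in A+T-rich sequence while detecting
    # copies beyond 20% divergence (the original search tool's scores
    # are not published; all are configurable)
    match_score: int = 2
    mismatch_score: int = -3
    gap_open: int = -10
    gap_extend: int = -2
    word_size: int = 11
    xdrop: int = 30

    # low-complexity masking (entropy in bits)
    mask_window: int = 21
    mask_locut: float = 1.4
    mask_hicut: float = 1.6

    # branches entering the genus-average rate calculation; empty means
    # "select by recent_branch_age_cutoff_my rule"
    recent_branch_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in (
            "hsp_sep_max_bases",
            "merge_window_bases",
            "min_event_bases",
            "repeat_adjacency_bases",
            "synteny_flank_bases",
            "min_unmasked_flank_bases",
            "recent_branch_age_cutoff_my",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 < self.significance_alpha < 1:
            raise ValidationError("significance_alpha must be in (0, 1)")
        if self.ts_tv_ratio <= 0:
            raise ValidationError("ts_tv_ratio must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
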