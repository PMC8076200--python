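"""Pipeline configuration.

Every numeric criterion of the marker-design protocol lives here: bait
window geometry (30-100 kb windows at ~1-Mb anchors), the minimum number of
alignable panel members, the diagnostic gap threshold (20 bp), PCR product
bounds (100-500 bp at 55 degC annealing), and the agarose-gel resolution
model (a single band-merging threshold in bp).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any


@dataclass(frozen=True)
class PipelineConfig:
    # bait selection
    bait_interval_bp: int = 1_000_000
    bait_min_len: int = 30_000
    bait_max_len: int = 100_000
    max_repeat_fraction: float = 0.3
    repeat_kmer: int = 21
    # ortholog extraction
    min_ortholog_members: int = 6
    anchor_kmer: int = 15
    min_anchors: int = 10
    max_anchor_gap: int = 20_000
    ortholog_pad: int = 2_000
    min_anchor_span_fraction: float = 0.5
    # alignment
    align_match: float = 1.0
    align_mismatch: float = -2.0
    align_gap_open: float = -6.0
    align_gap_extend: float = -0.2
    band_width: int = 500
    # InDel screening
    min_gap_bp: int = 20
    merge_radius_bp: int = 10
    max_markers_per_bait: int = 2
    # primer design
    product_min: int = 100
    product_max: int = 500
    annealing_temp_c: float = 55.0
    primer_len_min: int = 18
    primer_len_max: int = 24
    primer_tm_min_c: float = 55.0
    primer_tm_max_c: float = 65.0
    max_tm_difference_c: float = 3.0
    target_product_bp: int = 300
    # in-silico PCR / gel model
    gel_resolution_bp: int = 20
    epcr_min_product: int = 50
    epcr_max_product: int = 2_000
    epcr_max_mismatch: int = 2
    epcr_three_prime_exact: int = 3
    # analytics
    marker_failure_fraction: float = 0.3
    # randomness (simulation only; the pipeline itself is deterministic)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "bait_interval_bp", "bait_min_len", "bait_max_len",
            "min_ortholog_members", "min_gap_bp", "product_min",
            "product_max", "gel_resolution_bp", "epcr_max_product",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bait_min_len > self.bait_max_len:
            raise ValueError("bait_min_len must be <= bait_max_len")
        if self.product_min >= self.product_max:
            raise ValueError("product_min must be < product_max")
        if not (10 <= self.primer_len_min <= self.primer_len_max <= 36):
            raise ValueError("primer length range must lie within [10, 36]")
        if not 0.0 <= self.max_repeat_fraction <= 1.0:
            raise ValueError("max_repeat_fraction must be in [0, 1]")

    # -- flat key/value config file ------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a flat ``key = value`` file ('#' starts a comment)."""
        known = {f.name: f.type for f in fields(cls)}
        values: dict[str, Any] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = _coerce(val)
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


def _coerce(text: str) -> Any:
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text
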