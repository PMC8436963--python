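"""Run configuration: every tunable of the pipeline with its default.

The defaults reproduce the published method settings exactly: Niblack
factors 0.85 (limbs, trunk, tail) and 0.50 (head), threshold floor 60 and
trunk cap 108 on the 0-255 intensity scale, a 350-px minimum spot size,
and qualifying minima of 4 interior spots for limbs, 6 for trunk and
tail, none for the head.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from .imaging import NIBLACK_K, THRESHOLD_FLOOR, TRUNK_CAP
from .spots import MIN_SPOT_PX, QUALIFY_MIN_INTERIOR

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    niblack_k: Dict[str, float] = field(default_factory=lambda: dict(NIBLACK_K))
    threshold_floor: float = THRESHOLD_FLOOR
    trunk_cap: float = TRUNK_CAP
    min_spot_px: int = MIN_SPOT_PX
    qualify_min_interior: Dict[str, int] = field(
        default_factory=lambda: dict(QUALIFY_MIN_INTERIOR)
    )
    smooth_iterations: int = 2
    connectivity: int = 8  # spot connectivity (background flood uses 4)
    ee_convention: str = "ratio"  # or "eccentricity"
    n_perm: int = 10000
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.ee_convention not in ("ratio", "eccentricity"):
            raise ValueError("ee_convention must be 'ratio' or 'eccentricity'")
        if self.connectivity != 8:
            raise ValueError("only 8-connectivity for spots is supported")
        if self.min_spot_px < 1:
            raise ValueError("min_spot_px must be >= 1")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
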