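"""Training-record types shared between data handling and training."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

Split = Literal["train", "val", "test", "unassigned"]


@dataclass
class SamplePair:
    """One training record: source image(s), target(s), optional masks.

    ``target`` may be empty only for inference-time records. The exclusion
    mask, when present, must resolve to a binary image spatially congruent
    with the target; that is checked when the pair is loaded, not here.
    """

    source: list[Path]
    target: list[Path] = field(default_factory=list)
    exclusion_mask: Path | None = None
    weight_map: Path | None = None
    split: Split = "unassigned"

    def __post_init__(self):
        self.source = [Path(p) for p in self.source]
        self.target = [Path(p) for p in self.target]
        if not self.source:
            raise ValueError("SamplePair.source must be non-empty")
        if self.exclusion_mask is not None:
            self.exclusion_mask = Path(self.exclusion_mask)
        if self.weight_map is not None:
            self.weight_map = Path(self.weight_map)

    @property
    def record_id(self) -> str:
        return self.source[0].stem
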