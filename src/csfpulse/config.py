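"""Pipeline configuration with lossless YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .peakfind import PeakFindParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable parameters of an end-to-end run.

    ``tr`` given here overrides any TR stored in the input NIfTI header.
    """

    tr: float | None = None
    peakfind: PeakFindParams = field(default_factory=PeakFindParams)
    bands_on_smoothed: bool = False       # measure bands on smoothed raw spectrum
    use_power_maps: bool = False          # square magnitudes in band power maps
    map_fraction: float = 0.75            # binarization threshold fraction
    map_sigma: float = 1.6                # Gaussian sigma, voxel units
    map_2d: bool = False                  # slice-wise instead of 3D smoothing
    grouping_tolerance_hz: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.peakfind, dict):
            self.peakfind = PeakFindParams(**self.peakfind)
        if not (0 < self.map_fraction <= 1):
            raise ValueError("map_fraction must be in (0, 1]")
        if self.map_sigma < 0:
            raise ValueError("map_sigma must be >= 0")
        if self.grouping_tolerance_hz <= 0:
            raise ValueError("grouping_tolerance_hz must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(Path(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
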