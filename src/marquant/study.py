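"""Study container: one patient's (or phantom's) image stacks plus annotations."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .geometry import ARTERIES, ContourSet, SliceContours, VoxelGrid


@dataclass
class Study:
    """A CE-SSFP study (ED and/or ES cine stacks) with optional matched LGE.

    Contours are manual endo/epicardial delineations (the algorithm's input,
    not something it computes); ``rv_insertion_deg`` is the anterior RV
    insertion angle that anchors sector 0.  The LGE stack carries its own
    contours and insertion angle.
    """

    grid: VoxelGrid
    images: Mapping[str, np.ndarray]          # timeframe -> (S, R, C)
    contours: ContourSet                      # timeframe -> slice -> SliceContours
    rv_insertion_deg: float
    culprit: str
    lge_grid: VoxelGrid | None = None
    lge_image: np.ndarray | None = None
    lge_contours: Mapping[int, SliceContours] | None = None
    lge_rv_insertion_deg: float | None = None
    territory_table: str | None = None        # optional path overriding the default

    def __post_init__(self) -> None:
        if self.culprit not in ARTERIES:
            raise ValueError(f"culprit must be one of {ARTERIES}, got {self.culprit!r}")
        if not self.images:
            raise ValueError("study has no cine timeframes")
        for tf, img in self.images.items():
            if np.asarray(img).shape != self.grid.shape:
                raise ValueError(f"timeframe {tf}: image shape does not match grid")
            if tf not in self.contours:
                raise ValueError(f"timeframe {tf}: no contours delineated")
        if self.has_lge:
            if self.lge_grid is None or self.lge_contours is None:
                raise ValueError("LGE image requires an LGE grid and contours")
            if np.asarray(self.lge_image).shape != self.lge_grid.shape:
                raise ValueError("LGE image shape does not match LGE grid")
            if self.lge_rv_insertion_deg is None:
                raise ValueError("LGE requires its own RV insertion angle")

    @property
    def has_lge(self) -> bool:
        return self.lge_image is not None

    @property
    def timeframes(self) -> tuple[str, ...]:
        return tuple(self.images.keys())
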