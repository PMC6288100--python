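"""Run configuration: every tunable analysis parameter in one serializable record."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .exceptions import ValidationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of one analysis run.

    Attributes
    ----------
    corner_window_px : int
        Side of each corner background window (px).
    despeckle_radius_px : int
        Median-filter radius; 0 disables speckle filtering (useful on
        noise-free synthetic data).
    min_cell_area_px : int
        Smallest acceptable segmented-cell area.
    donor_floor : float | "auto"
        Minimum background-subtracted donor intensity for a ratio pixel;
        ``"auto"`` uses twice the donor frame's corner-pixel SD, a proxy for
        the noise scale, to keep dim cell-edge pixels from blowing up the
        ratio.
    n_bins : int
        Flow-axis bins (50 in the original protocol).
    n_edge_regions : int
        Bins averaged at each end for the up/down summary (5).
    alpha : float
        Two-tailed significance level of the polarity call.
    t_variant : "welch" | "student"
        Unequal- or pooled-variance t-test.
    weighting : "ratio" | "intensity"
        Per-bin weights: ratio values (default) or raw FRET intensities.
    edges_mode : "per_frame" | "fixed"
        Bin edges from each frame's own mask extent, or frozen from the
        first frame (sensitivity mode for deforming cells).
    segment_channel : "donor" | "fret" | "sum"
        Channel thresholded for segmentation.
    mask_propagation : bool
        Reuse the previous frame's mask when a frame segments to nothing.
    gap_tolerant : bool
        Carry missing frames as NaN columns in the spatio-temporal map.
    """

    corner_window_px: int = 8
    despeckle_radius_px: int = 1
    min_cell_area_px: int = 200
    donor_floor: float | str = "auto"
    n_bins: int = 50
    n_edge_regions: int = 5
    alpha: float = 0.05
    t_variant: str = "welch"
    weighting: str = "ratio"
    edges_mode: str = "per_frame"
    segment_channel: str = "donor"
    mask_propagation: bool = False
    gap_tolerant: bool = False

    def __post_init__(self) -> None:
        if self.t_variant not in ("welch", "student"):
            raise ValidationError(f"unknown t_variant '{self.t_variant}'")
        if self.weighting not in ("ratio", "intensity"):
            raise ValidationError(f"unknown weighting '{self.weighting}'")
        if self.edges_mode not in ("per_frame", "fixed"):
            raise ValidationError(f"unknown edges_mode '{self.edges_mode}'")
        if self.segment_channel not in ("donor", "fret", "sum"):
            raise ValidationError(f"unknown segment_channel '{self.segment_channel}'")
        if isinstance(self.donor_floor, str) and self.donor_floor != "auto":
            raise ValidationError("donor_floor must be a number or 'auto'")
        if self.despeckle_radius_px < 0:
            raise ValidationError("despeckle_radius_px must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
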