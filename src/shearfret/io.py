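"""Image stacks, acquisition metadata, and the file conventions of the pipeline.

Conventions used throughout the package
---------------------------------------
* Images are indexed ``[frame, row, column]`` (row-major, 0-based, origin
  top-left).
* The flow direction is a unit 2-vector ``(d_row, d_col)`` in the same
  row/column basis.  It is acquisition metadata, never hard-coded: a flow
  running from the bottom of the image to the top is ``(-1, 0)``.
* Each acquisition consists of two single-channel multi-page TIFFs — one for
  the donor (ECFP) channel and one for the FRET (acceptor) channel — plus a
  flat key/value sidecar file carrying the metadata below.  Page order is
  chronological.
* Ingestion is value-preserving: pixel values are converted to float64
  without any rescaling, whatever the on-disk bit depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

from .exceptions import ShapeError, ValidationError

__all__ = [
    "AcquisitionMeta",
    "AcquisitionStack",
    "read_stack",
    "write_ratio_stack",
    "read_meta",
    "write_meta",
]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Per-acquisition metadata.

    Parameters
    ----------
    flow_direction
        Unit vector ``(d_row, d_col)`` pointing along the flow (from upstream
        towards downstream).
    stimulus_onset_frame
        0-based index of the first frame acquired with the stimulus applied.
        Must be >= 1 so that at least one pre-stimulus frame exists for
        baseline normalization.
    frame_interval_s
        Seconds between consecutive frames (60 s in the original protocol).
    pixel_size_um
        Physical pixel size; informational only.
    channel_names
        Ordered pair ``(donor, fret)``.
    """

    flow_direction: tuple[float, float]
    stimulus_onset_frame: int
    frame_interval_s: float
    pixel_size_um: float | None = None
    channel_names: tuple[str, str] = ("ECFP", "FRET")
    excitation_nm: float = 420.0
    donor_emission_nm: float = 475.0
    acceptor_emission_nm: float = 535.0

    def __post_init__(self) -> None:
        d = np.asarray(self.flow_direction, dtype=float)
        if d.shape != (2,):
            raise ValidationError("flow_direction must be a 2-vector")
        norm = math.hypot(d[0], d[1])
        if abs(norm - 1.0) > 1e-9:
            raise ValidationError(
                f"flow_direction must be a unit vector (norm={norm!r})"
            )
        if int(self.stimulus_onset_frame) < 1:
            raise ValidationError(
                "stimulus_onset_frame must be >= 1 (need a pre-stimulus baseline)"
            )
        if not self.frame_interval_s > 0:
            raise ValidationError("frame_interval_s must be > 0")
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be > 0")
        object.__setattr__(self, "flow_direction", (float(d[0]), float(d[1])))
        object.__setattr__(self, "stimulus_onset_frame", int(self.stimulus_onset_frame))


@dataclass
class AcquisitionStack:
    """Two-channel time-lapse stack: donor and FRET intensities plus metadata."""

    donor: np.ndarray  # (T, H, W), float64, >= 0
    fret: np.ndarray  # (T, H, W), float64, >= 0
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=np.float64)
        self.fret = np.asarray(self.fret, dtype=np.float64)
        if self.donor.ndim != 3 or self.fret.ndim != 3:
            raise ShapeError("channel stacks must be 3-D (T, H, W)")
        if self.donor.shape != self.fret.shape:
            raise ShapeError(
                f"channel shapes differ: donor {self.donor.shape} vs "
                f"fret {self.fret.shape}"
            )
        if self.donor.shape[0] < 2:
            raise ShapeError("a stack needs at least two frames")
        for name, arr in (("donor", self.donor), ("fret", self.fret)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} channel contains non-finite pixels")
            if arr.min() < 0:
                raise ValidationError(f"{name} channel contains negative pixels")

    @property
    def n_frames(self) -> int:
        return self.donor.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.donor.shape[1:]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.meta.frame_interval_s


def _read_pages(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ShapeError(f"{path}: expected single-channel pages, got shape {arr.shape}")
    return np.asarray(arr, dtype=np.float64)


def read_stack(
    donor_path: str | Path, fret_path: str | Path, meta: AcquisitionMeta
) -> AcquisitionStack:
    """Read the two channel TIFFs of one acquisition into a stack.

    Frames are ordered by page index (chronological order).  Pixel values are
    promoted to float64 but never rescaled; negative pixels are rejected.
    """
    donor = _read_pages(donor_path)
    fret = _read_pages(fret_path)
    if donor.shape != fret.shape:
        raise ShapeError(
            f"donor {donor.shape} and fret {fret.shape} stacks do not match"
        )
    return AcquisitionStack(donor=donor, fret=fret, meta=meta)


def write_ratio_stack(ratio_maps: Sequence, path: str | Path) -> None:
    """Write per-frame ratio maps as a float32 multi-page TIFF.

    Pixels outside each map's valid set are written as NaN.  Accepts
    :class:`~shearfret.ratiometry.RatioMap` objects or plain 2-D arrays.
    """
    if len(ratio_maps) == 0:
        raise ValidationError("no ratio maps to write")
    frames = []
    shape = None
    for m in ratio_maps:
        arr = m.masked_ratio() if hasattr(m, "masked_ratio") else np.asarray(m, dtype=float)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ShapeError("ratio maps have inconsistent shapes")
        frames.append(arr.astype(np.float32))
    tifffile.imwrite(str(path), np.stack(frames, axis=0), photometric="minisblack")


# -- sidecar metadata -------------------------------------------------------

_META_KEYS = (
    "flow_direction_row",
    "flow_direction_col",
    "stimulus_onset_frame",
    "frame_interval_s",
)


def read_meta(path: str | Path) -> tuple[AcquisitionMeta, dict]:
    """Load a flat key/value sidecar file (YAML syntax).

    Returns the parsed :class:`AcquisitionMeta` plus the raw mapping, which may
    carry extra keys such as ``donor_path``/``fret_path``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: sidecar must be a flat key/value mapping")
    for key in _META_KEYS:
        if key not in raw:
            raise ValidationError(f"{path}: missing metadata key '{key}'")
    meta = AcquisitionMeta(
        flow_direction=(float(raw["flow_direction_row"]), float(raw["flow_direction_col"])),
        stimulus_onset_frame=int(raw["stimulus_onset_frame"]),
        frame_interval_s=float(raw["frame_interval_s"]),
        pixel_size_um=(float(raw["pixel_size_um"]) if raw.get("pixel_size_um") else None),
    )
    return meta, raw


def write_meta(
    meta: AcquisitionMeta,
    path: str | Path,
    donor_path: str | None = None,
    fret_path: str | None = None,
) -> None:
    """Write the flat sidecar metadata file next to the channel TIFFs."""
    raw: dict = {
        "flow_direction_row": meta.flow_direction[0],
        "flow_direction_col": meta.flow_direction[1],
        "stimulus_onset_frame": meta.stimulus_onset_frame,
        "frame_interval_s": meta.frame_interval_s,
        "pixel_size_um": meta.pixel_size_um,
    }
    if donor_path is not None:
        raw["donor_path"] = donor_path
    if fret_path is not None:
        raw["fret_path"] = fret_path
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True, default_flow_style=False)
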