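"""Assemble per-frame spatial profiles into a bin x time map and render it.

The normalized spatio-temporal map shows, for each of the 50 flow-axis bins
(downstream to upstream) and each time point, the bin's share of the cell's
ratio signal relative to its own pre-stimulus mean — the "binding degree
distribution" view of the polarity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import AcquisitionMeta
from .polarity import SpatialProfile

__all__ = ["SpatioTemporalMap", "assemble_map", "render_map"]


@dataclass
class SpatioTemporalMap:
    """Normalized percentages on a (bin, time) grid.

    ``values[i, t]`` is bin ``i+1`` at frame ``t``; missing bins or frames are
    NaN, never zero (zero is a meaningful percentage).
    """

    values: np.ndarray  # (n_bins, T)
    times_s: np.ndarray  # (T,)
    bin_axis: np.ndarray  # 1..n_bins, downstream -> upstream
    stimulus_onset_s: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.bin_axis, name="bin"),
            columns=pd.Index(self.times_s, name="time_s"),
        )
        return df


def assemble_map(
    profiles: Sequence[SpatialProfile],
    meta: AcquisitionMeta,
    gap_tolerant: bool = False,
) -> SpatioTemporalMap:
    """Stack normalized per-frame profiles into a single bin x time array.

    Frames must be consecutive; with ``gap_tolerant=True`` a missing frame
    becomes an all-NaN column instead of an error.
    """
    if not profiles:
        raise ValidationError("no profiles to assemble")
    for p in profiles:
        if p.normalized_percentages is None:
            raise ValidationError("profiles must be normalized before assembly")
    n_bins = profiles[0].n_bins
    frames = np.array([p.frame_index for p in profiles])
    first, last = int(frames.min()), int(frames.max())
    expected = np.arange(first, last + 1)
    missing = np.setdiff1d(expected, frames)
    if missing.size and not gap_tolerant:
        raise ValidationError(
            f"gap in frame indices (missing {missing.tolist()}); "
            "set gap_tolerant=True to carry missing columns as NaN"
        )
    values = np.full((n_bins, expected.size), np.nan)
    for p in profiles:
        col = p.frame_index - first
        v = p.normalized_percentages.copy()
        if p.valid is not None:
            v[~p.valid] = np.nan
        values[:, col] = v
    times = expected.astype(float) * meta.frame_interval_s
    return SpatioTemporalMap(
        values=values,
        times_s=times,
        bin_axis=np.arange(1, n_bins + 1),
        stimulus_onset_s=meta.stimulus_onset_frame * meta.frame_interval_s,
    )


def render_map(
    st_map: SpatioTemporalMap,
    out_path: str | Path,
    cmap: str = "viridis",
    dpi: int = 150,
) -> Path:
    """Write a heatmap of the spatio-temporal map with a stimulus-onset marker."""
    fig, ax = plt.subplots(figsize=(7, 4.2))
    t_min = st_map.times_s / 60.0
    mesh = ax.pcolormesh(
        t_min,
        st_map.bin_axis,
        np.ma.masked_invalid(st_map.values),
        cmap=cmap,
        shading="nearest",
    )
    ax.axvline(st_map.stimulus_onset_s / 60.0, color="w", ls="--", lw=1.2)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("flow-axis bin  (1 = downstream → 50 = upstream)")
    fig.colorbar(mesh, ax=ax, label="normalized ratio percentage")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=dpi)
    plt.close(fig)
    return out_path
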