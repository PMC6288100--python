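"""Per-pixel FRET/ECFP ratio maps, whole-cell time series, and spectral ratios.

Ratiometric imaging divides the acceptor (FRET) channel by the donor (ECFP)
channel pixel by pixel, cancelling expression level and optical path length.
The whole-cell mean ratio over time is normalized by its pre-stimulus
baseline within the same cell, so every trace starts at 1 and a stimulus
response reads directly as a fractional change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import AcquisitionMeta
from .preprocess import CellMask

__all__ = [
    "RatioMap",
    "RatioTimeSeries",
    "EmissionSpectrum",
    "compute_ratio_map",
    "whole_cell_series",
    "spectral_fret_ratio",
    "read_spectrum",
]


@dataclass
class RatioMap:
    """Masked per-pixel FRET/donor ratio image of one frame."""

    ratio: np.ndarray  # (H, W) float; meaningful only where valid
    valid: np.ndarray  # (H, W) bool
    frame_index: int = 0
    n_floor_excluded: int = 0  # cell pixels dropped for dim/nonpositive donor
    n_nonpositive_excluded: int = 0  # cell pixels dropped for fret <= 0

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_values(self) -> np.ndarray:
        return self.ratio[self.valid]

    def masked_ratio(self) -> np.ndarray:
        """Ratio image with NaN outside the valid set (export representation)."""
        out = np.full(self.ratio.shape, np.nan, dtype=float)
        out[self.valid] = self.ratio[self.valid]
        return out


@dataclass
class RatioTimeSeries:
    """Whole-cell mean ratio over time with baseline normalization.

    ``normalized_ratio[t] = mean_ratio[t] / baseline`` where the baseline is
    the mean of ``mean_ratio`` over all pre-stimulus frames; frames without
    valid pixels carry NaN and are excluded from the baseline.
    """

    times_s: np.ndarray
    mean_ratio: np.ndarray
    normalized_ratio: np.ndarray
    baseline: float
    n_valid_px: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    stimulus_onset_frame: int = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.times_s)),
                "time_s": self.times_s,
                "mean_ratio": self.mean_ratio,
                "normalized_ratio": self.normalized_ratio,
                "n_valid_px": self.n_valid_px,
            }
        )


@dataclass
class EmissionSpectrum:
    """In-vitro fluorescence emission spectrum (wavelength in nm vs intensity)."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.shape != self.intensity.shape or self.wavelength_nm.ndim != 1:
            raise ValidationError("spectrum needs matching 1-D wavelength/intensity")
        if not np.all(np.diff(self.wavelength_nm) > 0):
            raise ValidationError("wavelengths must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValidationError("intensities must be non-negative")


def compute_ratio_map(
    fret_frame: np.ndarray,
    donor_frame: np.ndarray,
    mask: CellMask | np.ndarray,
    donor_floor: float = 0.0,
    frame_index: int = 0,
) -> RatioMap:
    """Divide FRET by donor over the cell mask, guarding dim donor pixels.

    A cell pixel enters the valid set only if ``donor >= max(donor_floor, tiny)``
    and the resulting ratio is positive and finite; excluded pixels are
    counted, not silently dropped.
    """
    fret = np.asarray(fret_frame, dtype=float)
    donor = np.asarray(donor_frame, dtype=float)
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)
    if fret.shape != donor.shape or fret.shape != m.shape:
        raise ValidationError("frame and mask shapes must agree")
    floor = max(float(donor_floor), np.finfo(float).tiny)
    ok_donor = m & (donor >= floor)
    n_floor = int(m.sum() - ok_donor.sum())
    ratio = np.zeros_like(donor)
    np.divide(fret, donor, out=ratio, where=ok_donor)
    valid = ok_donor & (ratio > 0) & np.isfinite(ratio)
    n_nonpos = int(ok_donor.sum() - valid.sum())
    if not valid.any():
        raise ValidationError(
            f"frame {frame_index}: no valid ratio pixels after donor-floor filtering"
        )
    return RatioMap(
        ratio=ratio,
        valid=valid,
        frame_index=frame_index,
        n_floor_excluded=n_floor,
        n_nonpositive_excluded=n_nonpos,
    )


def whole_cell_series(
    ratio_maps: list[RatioMap], meta: AcquisitionMeta
) -> RatioTimeSeries:
    """Average each frame's valid ratio pixels and normalize by baseline.

    The baseline is the unweighted mean of the per-frame means over all
    frames strictly before ``meta.stimulus_onset_frame``.
    """
    t = len(ratio_maps)
    mean_ratio = np.full(t, np.nan)
    n_valid = np.zeros(t, dtype=int)
    for i, rm in enumerate(ratio_maps):
        vals = rm.valid_values()
        n_valid[i] = vals.size
        if vals.size == 0:
            warnings.warn(f"frame {i}: no valid ratio pixels; excluded from series")
            continue
        mean_ratio[i] = float(vals.mean())
    onset = meta.stimulus_onset_frame
    pre = mean_ratio[:onset]
    pre = pre[np.isfinite(pre)]
    if pre.size == 0:
        raise ValidationError("no usable pre-stimulus frames for the baseline")
    baseline = float(pre.mean())
    if not baseline > 0:
        raise ValidationError("baseline must be positive")
    times = np.arange(t, dtype=float) * meta.frame_interval_s
    return RatioTimeSeries(
        times_s=times,
        mean_ratio=mean_ratio,
        normalized_ratio=mean_ratio / baseline,
        baseline=baseline,
        n_valid_px=n_valid,
        stimulus_onset_frame=onset,
    )


def spectral_fret_ratio(
    spectrum: EmissionSpectrum,
    donor_nm: float = 475.0,
    acceptor_nm: float = 515.0,
) -> float:
    """Donor/acceptor emission ratio from an in-vitro spectrum.

    Intensities at the two wavelengths (default 475 nm / 515 nm) are obtained
    by linear interpolation between the bracketing samples.
    """
    wl, inten = spectrum.wavelength_nm, spectrum.intensity
    for nm in (donor_nm, acceptor_nm):
        if not (wl[0] <= nm <= wl[-1]):
            raise ValidationError(f"{nm} nm outside the measured range "
                                  f"[{wl[0]}, {wl[-1]}] nm")
    i_donor = float(np.interp(donor_nm, wl, inten))
    i_acceptor = float(np.interp(acceptor_nm, wl, inten))
    if i_acceptor <= 0:
        raise ValidationError(f"zero intensity at {acceptor_nm} nm")
    return i_donor / i_acceptor


def read_spectrum(path) -> EmissionSpectrum:
    """Read a two-column (wavelength_nm, intensity) CSV/TSV spectrum."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None,
                     names=["wavelength_nm", "intensity"], skip_blank_lines=True)
    if isinstance(df.iloc[0, 0], str):  # tolerate a header row
        df = df.iloc[1:].astype(float)
    return EmissionSpectrum(
        wavelength_nm=df["wavelength_nm"].to_numpy(float),
        intensity=df["intensity"].to_numpy(float),
    )
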