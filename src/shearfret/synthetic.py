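"""Synthetic two-channel FRET acquisitions with known ground truth.

Forward model
-------------
A single elliptical cell sits on a dark background.  The per-pixel ratio
field is separable in space and time::

    R(x, t) = ratio_baseline * (1 - d * s(t)) * (1 + g * u(x) * s_g(t))

where ``s(t) = 1 - exp(-(t - t0)/tau)`` for frames at or after the stimulus
onset ``t0`` and 0 before, ``d`` is the fractional whole-cell ratio decrease
at plateau (the live-cell experiments show drops of roughly 20-40% of
baseline), ``g`` is the flow-axis gradient amplitude and ``u(x)`` the
normalized flow-axis coordinate inside the cell (-0.5 at the upstream edge,
+0.5 downstream).  By default the gradient develops with the same kinetics
as the decay (``s_g = s``): polarity is a response to flow, so before the
stimulus the cell is spatially uniform.  ``gradient_onset="static"`` bakes
the gradient in from frame 0 instead (such a static gradient cancels under
per-bin baseline normalization).

The donor channel is flat inside the cell (``donor_baseline``, optionally
bleaching exponentially per frame), the FRET channel is ``R * donor``; a
constant background offset is added to both, then optional photon (Poisson)
noise and additive Gaussian read noise.  Intensities are clamped at zero.

Every stochastic draw goes through one seeded generator, so a stack is a
pure function of its ground-truth record.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .io import AcquisitionMeta, AcquisitionStack

__all__ = ["GroundTruth", "generate_stack", "generate_cohort", "DEFAULT_BETWEEN_CELL_SD"]

#: Between-cell spread (SD) of the condition parameters used by
#: :func:`generate_cohort`; the scale matches the few-percent cell-to-cell
#: scatter of normalized responses seen across replicate cells.
DEFAULT_BETWEEN_CELL_SD = {
    "decay_amplitude": 0.05,
    "gradient_slope": 0.05,
    "ratio_baseline": 0.10,
}


@dataclass
class GroundTruth:
    """Generator parameters for one synthetic cell (all units in the fields)."""

    center: tuple[float, float] = (64.0, 64.0)  # (row, col) px
    semi_axes: tuple[float, float] = (40.0, 28.0)  # (a, b) px, a along orientation
    orientation_rad: float = 0.0  # a-axis angle from the column axis
    donor_baseline: float = 500.0  # counts inside the cell
    ratio_baseline: float = 1.2  # fret/donor before stimulation
    background_offset: tuple[float, float] = (100.0, 100.0)  # (donor, fret) counts
    decay_amplitude: float = 0.25  # d: fractional ratio drop at plateau
    decay_tau_s: float = 300.0  # exponential time constant
    gradient_slope: float = 0.0  # g: fractional ratio difference across the cell
    gradient_onset: str = "stimulus"  # "stimulus" (gated by s(t)) or "static"
    bleach_rate: tuple[float, float] = (0.0, 0.0)  # per-frame decay (donor, fret)
    shot_noise: bool = True
    read_noise_sd: float = 5.0  # counts
    stimulus_onset_frame: int = 10
    frame_interval_s: float = 60.0
    flow_direction: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.decay_amplitude < 1.0):
            raise ValidationError("decay_amplitude must be in [0, 1)")
        if abs(self.gradient_slope) >= 2.0:
            raise ValidationError(
                "abs(gradient_slope) must be < 2 to keep the ratio field positive"
            )
        if self.gradient_onset not in ("stimulus", "static"):
            raise ValidationError("gradient_onset must be 'stimulus' or 'static'")
        if self.decay_tau_s <= 0 or self.donor_baseline <= 0 or self.ratio_baseline <= 0:
            raise ValidationError("tau, donor_baseline, ratio_baseline must be > 0")

    # -- derived deterministic quantities ----------------------------------

    def meta(self) -> AcquisitionMeta:
        d = np.asarray(self.flow_direction, dtype=float)
        d = d / math.hypot(d[0], d[1])
        return AcquisitionMeta(
            flow_direction=(float(d[0]), float(d[1])),
            stimulus_onset_frame=self.stimulus_onset_frame,
            frame_interval_s=self.frame_interval_s,
        )

    def cell_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """True ellipse support on the pixel grid."""
        h, w = shape
        rr, cc = np.mgrid[0:h, 0:w].astype(float)
        dr, dc = rr - self.center[0], cc - self.center[1]
        ct, st = math.cos(self.orientation_rad), math.sin(self.orientation_rad)
        a_coord = dc * ct + dr * st
        b_coord = -dc * st + dr * ct
        a, b = self.semi_axes
        return (a_coord / a) ** 2 + (b_coord / b) ** 2 <= 1.0

    def u_field(self, shape: tuple[int, int]) -> np.ndarray:
        """Normalized flow-axis coordinate on the cell: +0.5 downstream edge."""
        mask = self.cell_mask(shape)
        rows, cols = np.nonzero(mask)
        d = np.asarray(self.flow_direction, dtype=float)
        d = d / math.hypot(d[0], d[1])
        p = rows * d[0] + cols * d[1]
        span = p.max() - p.min()
        if span <= 0:
            raise ValidationError("degenerate cell: no extent along the flow axis")
        u = np.zeros(shape, dtype=float)
        u[rows, cols] = (p - p.min()) / span - 0.5
        return u

    def s_curve(self, n_frames: int) -> np.ndarray:
        """Stimulus-response kinetics s(t) per frame (0 before onset)."""
        t = np.arange(n_frames, dtype=float)
        dt = (t - self.stimulus_onset_frame) * self.frame_interval_s
        s = 1.0 - np.exp(-np.maximum(dt, 0.0) / self.decay_tau_s)
        s[t < self.stimulus_onset_frame] = 0.0
        return s

    def ratio_field(self, n_frames: int, shape: tuple[int, int]) -> np.ndarray:
        """Noise-free ratio field R(x, t) on the cell (0 outside), (T, H, W)."""
        mask = self.cell_mask(shape)
        u = self.u_field(shape)
        s = self.s_curve(n_frames)
        s_g = s if self.gradient_onset == "stimulus" else np.ones_like(s)
        decay = 1.0 - self.decay_amplitude * s
        out = np.zeros((n_frames, *shape))
        for t in range(n_frames):
            field = self.ratio_baseline * decay[t] * (1.0 + self.gradient_slope * u * s_g[t])
            out[t] = np.where(mask, field, 0.0)
        return out

    def expected_normalized_series(self, n_frames: int, shape: tuple[int, int]) -> np.ndarray:
        """Closed-form noise-free normalized whole-cell ratio trace.

        The whole-cell mean of per-pixel ratios is
        ``ratio_baseline * (1 - d s(t)) * (1 + g * u_bar * s_g(t))`` with
        ``u_bar`` the mean flow coordinate over cell pixels; dividing by the
        pre-stimulus mean gives the expected normalized trace.
        """
        mask = self.cell_mask(shape)
        u_bar = float(self.u_field(shape)[mask].mean())
        s = self.s_curve(n_frames)
        s_g = s if self.gradient_onset == "stimulus" else np.ones_like(s)
        series = (1.0 - self.decay_amplitude * s) * (1.0 + self.gradient_slope * u_bar * s_g)
        pre = series[: self.stimulus_onset_frame].mean()
        return series / pre

    def expected_bin_traces(
        self, n_frames: int, shape: tuple[int, int], n_bins: int = 50
    ) -> np.ndarray:
        """Closed-form noise-free normalized per-bin traces, shape (n_bins, T).

        Computed by a direct per-pixel loop: each cell pixel is assigned to
        the equal-width flow-axis slab containing its true coordinate (bin 1
        downstream), the ratio-weighted percentage per slab is formed from
        the closed-form field, and each bin trace is divided by its
        pre-stimulus mean.  Independent of the analysis implementation.
        """
        mask = self.cell_mask(shape)
        u = self.u_field(shape)[mask]  # in [-0.5, 0.5], +0.5 downstream
        s = self.s_curve(n_frames)
        s_g = s if self.gradient_onset == "stimulus" else np.ones_like(s)
        traces = np.zeros((n_bins, n_frames))
        for t in range(n_frames):
            w = (1.0 - self.decay_amplitude * s[t]) * (
                1.0 + self.gradient_slope * u * s_g[t]
            )
            sums = np.zeros(n_bins)
            for ui, wi in zip(u, w):
                # bin 1 holds the largest coordinates (downstream)
                b = int(math.floor((0.5 - ui) * n_bins))
                b = min(max(b, 0), n_bins - 1)
                sums[b] += wi
            traces[:, t] = 100.0 * sums / w.sum()
        pre = traces[:, : self.stimulus_onset_frame].mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return traces / pre[:, None]

    # -- (de)serialization --------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruth":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        for key in ("center", "semi_axes", "background_offset", "bleach_rate",
                    "flow_direction"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def generate_stack(
    truth: GroundTruth,
    n_frames: int = 40,
    shape: tuple[int, int] = (128, 128),
    margin_px: int = 16,
) -> tuple[AcquisitionStack, GroundTruth]:
    """Simulate one two-channel acquisition from a ground-truth record.

    The ellipse must leave at least ``margin_px`` of pure background on every
    side so the corner windows never touch the cell.
    """
    h, w = shape
    r0, c0 = truth.center
    r_enclose = max(truth.semi_axes)
    if (
        r0 - r_enclose < margin_px
        or c0 - r_enclose < margin_px
        or r0 + r_enclose > h - margin_px
        or c0 + r_enclose > w - margin_px
    ):
        raise ValidationError(
            f"ellipse (center {truth.center}, max semi-axis {r_enclose}) does not "
            f"leave a {margin_px} px background margin in a {h}x{w} image"
        )
    mask = truth.cell_mask(shape)
    if not mask.any():
        raise ValidationError("cell geometry covers no pixels")
    ratio = truth.ratio_field(n_frames, shape)
    if np.any(ratio[:, mask] <= 0):
        raise ValidationError("parameters produce a nonpositive ratio on the cell")

    frames = np.arange(n_frames, dtype=float)
    bleach_d = np.exp(-truth.bleach_rate[0] * frames)
    bleach_f = np.exp(-truth.bleach_rate[1] * frames)

    donor = np.empty((n_frames, h, w))
    fret = np.empty((n_frames, h, w))
    for t in range(n_frames):
        d_clean = np.where(mask, truth.donor_baseline * bleach_d[t], 0.0)
        f_clean = ratio[t] * truth.donor_baseline * bleach_f[t]
        donor[t] = d_clean + truth.background_offset[0]
        fret[t] = f_clean + truth.background_offset[1]

    rng = np.random.default_rng(truth.seed)
    if truth.shot_noise:
        donor = rng.poisson(donor).astype(float)
        fret = rng.poisson(fret).astype(float)
    if truth.read_noise_sd > 0:
        donor = donor + rng.normal(0.0, truth.read_noise_sd, donor.shape)
        fret = fret + rng.normal(0.0, truth.read_noise_sd, fret.shape)
    donor = np.maximum(donor, 0.0)
    fret = np.maximum(fret, 0.0)

    return AcquisitionStack(donor=donor, fret=fret, meta=truth.meta()), truth


def draw_cohort_truths(
    base_truth: GroundTruth,
    n_cells: int,
    between_cell_sd: dict | None = None,
    master_seed: int = 0,
    vary_geometry: bool = True,
) -> list[GroundTruth]:
    """Draw per-cell ground-truth records for one experimental condition.

    Decay amplitude, gradient slope, and ratio baseline are drawn normally
    around the condition's values with the given between-cell SDs (see
    :data:`DEFAULT_BETWEEN_CELL_SD`; pass 0 to pin a parameter); cell
    geometry is jittered; per-cell noise seeds derive deterministically from
    ``master_seed``, so a cohort is reproducible piecewise.
    """
    if n_cells < 2:
        raise ValidationError("a cohort needs at least 2 cells")
    sd = dict(DEFAULT_BETWEEN_CELL_SD)
    if between_cell_sd is not None:
        sd.update(between_cell_sd)
    ss = np.random.SeedSequence(master_seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    cell_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_cells + 1)[1:]]

    truths = []
    for i in range(n_cells):
        d_i = float(np.clip(
            param_rng.normal(base_truth.decay_amplitude, sd["decay_amplitude"]), 0.0, 0.95
        ))
        g_i = float(np.clip(
            param_rng.normal(base_truth.gradient_slope, sd["gradient_slope"]), -1.9, 1.9
        ))
        rb_i = float(max(
            param_rng.normal(base_truth.ratio_baseline, sd["ratio_baseline"]), 0.1
        ))
        if vary_geometry:
            center = (
                float(base_truth.center[0] + param_rng.uniform(-4, 4)),
                float(base_truth.center[1] + param_rng.uniform(-4, 4)),
            )
            axes = (
                float(base_truth.semi_axes[0] * param_rng.uniform(0.9, 1.1)),
                float(base_truth.semi_axes[1] * param_rng.uniform(0.9, 1.1)),
            )
            theta = float(param_rng.uniform(-0.3, 0.3))
        else:
            center, axes, theta = (
                base_truth.center, base_truth.semi_axes, base_truth.orientation_rad
            )
        truths.append(dataclasses.replace(
            base_truth,
            decay_amplitude=d_i,
            gradient_slope=g_i,
            ratio_baseline=rb_i,
            center=center,
            semi_axes=axes,
            orientation_rad=theta,
            seed=cell_seeds[i],
        ))
    return truths


def generate_cohort(
    base_truth: GroundTruth,
    n_cells: int,
    between_cell_sd: dict | None = None,
    master_seed: int = 0,
    n_frames: int = 40,
    shape: tuple[int, int] = (128, 128),
    vary_geometry: bool = True,
) -> list[tuple[AcquisitionStack, GroundTruth]]:
    """Simulate ``n_cells`` replicate cells of one experimental condition.

    Per-cell parameters come from :func:`draw_cohort_truths`; each cell's
    stack is then generated with its own derived seed.
    """
    truths = draw_cohort_truths(
        base_truth, n_cells, between_cell_sd, master_seed, vary_geometry
    )
    return [generate_stack(t, n_frames=n_frames, shape=shape) for t in truths]
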