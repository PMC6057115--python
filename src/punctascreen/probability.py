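"""Probability-space transforms for immunofluorescence punctum detection.

Array-tomography immunofluorescence channels are dominated by background:
the signal of interest (synaptic puncta) occupies a tiny fraction of the
voxels. The detector therefore models the whole channel as Gaussian noise
and treats signal as an outlier. Three successive transforms turn a raw
intensity volume into a per-voxel probability of belonging to a 3D punctum:

1. :func:`foreground_probability` — per-voxel probability of not being
   background, from a channel-wide Gaussian background model;
2. :func:`blob2d_probability` — probability of belonging to a 2D blob of at
   least the minimum in-plane extent (product over a small window);
3. :func:`span_probability` — probability of belonging to a blob that
   persists across the minimum number of consecutive sections.

Each stage maps a probability volume to a probability volume of the same
shape; values stay in [0, 1] and every added requirement can only lower
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

__all__ = [
    "ImageVolume",
    "BackgroundModel",
    "ProbabilityMap",
    "STAGES",
    "estimate_background",
    "foreground_probability",
    "blob2d_probability",
    "span_probability",
]

#: Valid processing stages for a :class:`ProbabilityMap`.
STAGES = ("foreground", "blob2d", "punctum3d", "synapse")

#: Default acquisition geometry: 100 nm in-plane pixels, 70 nm sections.
DEFAULT_PIXEL_SIZE_NM = 100.0
DEFAULT_SLICE_THICKNESS_NM = 70.0


@dataclass(frozen=True)
class ImageVolume:
    """One antibody channel as a 3D intensity grid plus voxel geometry.

    Parameters
    ----------
    intensities
        Array of shape ``(slices, rows, columns)`` — i.e. (z, y, x) — of
        finite, real-valued intensities. Integer input is converted to
        float64.
    pixel_size_xy
        In-plane pixel size in nanometers (> 0).
    slice_thickness
        Section thickness in nanometers (> 0).
    channel_name
        Free-text channel identifier (e.g. the antibody name).
    """

    intensities: np.ndarray
    pixel_size_xy: float = DEFAULT_PIXEL_SIZE_NM
    slice_thickness: float = DEFAULT_SLICE_THICKNESS_NM
    channel_name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(
                f"intensities must be 3D (z, y, x); got shape {arr.shape}"
            )
        if arr.size == 0:
            raise ValueError("empty input")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if not (self.pixel_size_xy > 0 and self.slice_thickness > 0):
            raise ValueError("voxel sizes must be positive")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of one voxel in cubic micrometers."""
        px_um = self.pixel_size_xy / 1000.0
        dz_um = self.slice_thickness / 1000.0
        return px_um * px_um * dz_um

    @property
    def total_volume_um3(self) -> float:
        """Total imaged volume in cubic micrometers."""
        return self.intensities.size * self.voxel_volume_um3


@dataclass(frozen=True)
class BackgroundModel:
    """Gaussian model of a channel's background noise (mean, SD)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mean) and np.isfinite(self.sd)):
            raise ValueError("background model parameters must be finite")
        if self.sd < 0:
            raise ValueError("background sd must be non-negative")


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-voxel membership probability at one stage of the pipeline.

    ``values`` has the same shape as the source volume; every entry lies in
    [0, 1]. ``stage`` records which requirement the probabilities encode
    (one of :data:`STAGES`).
    """

    values: np.ndarray
    stage: str
    channel_name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError("probability map must be 3D")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def estimate_background(volume: ImageVolume) -> BackgroundModel:
    """Fit the Gaussian background model to a whole channel.

    The entire channel is treated as noise, with genuine signal an outlier
    that barely perturbs the channel-wide statistics. Returns the arithmetic
    mean and the population (divide-by-n) standard deviation of all voxels.

    Raises
    ------
    ValueError
        If the channel has zero variance ("degenerate background"): a
        constant image admits no outlier scoring.
    """
    data = volume.intensities
    if data.size == 0:
        raise ValueError("empty input")
    mean = float(data.mean())
    sd = float(data.std())  # population convention (ddof=0)
    if sd == 0.0:
        raise ValueError("degenerate background: channel has zero variance")
    return BackgroundModel(mean=mean, sd=sd)


def foreground_probability(
    volume: ImageVolume, model: BackgroundModel
) -> ProbabilityMap:
    """Per-voxel probability of belonging to the foreground.

    A voxel's foreground probability is one minus the probability of
    belonging to the background, evaluated as the lower-tail normal CDF of
    its z-score under the background model:

    .. math:: p_\\mathrm{fg}(I) = \\Phi\\left((I - \\mu) / \\sigma\\right)

    This is monotone non-decreasing in intensity and equals 0.5 at the
    background mean.
    """
    if model.sd <= 0:
        raise ValueError("background sd must be positive")
    z = (volume.intensities - model.mean) / model.sd
    return ProbabilityMap(
        values=ndtr(z), stage="foreground", channel_name=volume.channel_name
    )


def _window_product_max(plane_stack: np.ndarray, wy: int, wx: int) -> np.ndarray:
    """Product over every fully-interior wy×wx window, then per-voxel max
    over the windows containing it. Operates slice-wise on (z, y, x)."""
    nz, ny, nx = plane_stack.shape
    py, px = ny - wy + 1, nx - wx + 1
    # product over window offsets, anchored at the window's top-left corner
    prod = np.ones((nz, py, px), dtype=np.float64)
    for dy in range(wy):
        for dx in range(wx):
            prod *= plane_stack[:, dy : dy + py, dx : dx + px]
    # voxel (y, x) is covered by anchor (ay, ax) iff ay+dy == y, ax+dx == x
    out = np.zeros_like(plane_stack)
    for dy in range(wy):
        for dx in range(wx):
            np.maximum(
                out[:, dy : dy + py, dx : dx + px],
                prod,
                out=out[:, dy : dy + py, dx : dx + px],
            )
    return out


def blob2d_probability(
    fg: ProbabilityMap, window_xy: tuple[int, int] = (2, 2)
) -> ProbabilityMap:
    """Probability of belonging to a 2D blob of minimum in-plane extent.

    For each voxel, independently per slice: the maximum, over all windows
    of the given size lying fully inside the slice and containing the voxel,
    of the product of foreground probabilities in that window. The product
    demands the whole minimum blob footprint be foreground-like; the max
    spreads a qualifying window's score to every voxel it covers, so each
    voxel of a blob carries the blob's probability. Border voxels that no
    fully-interior window covers receive 0.

    Parameters
    ----------
    fg
        Foreground-stage probability map.
    window_xy
        Minimum blob extent ``(rows, columns)`` in pixels; default 2×2
        (0.2 × 0.2 μm at 100 nm pixels).
    """
    if fg.stage != "foreground":
        raise ValueError(f"expected foreground-stage map, got {fg.stage!r}")
    wy, wx = int(window_xy[0]), int(window_xy[1])
    nz, ny, nx = fg.shape
    if wy < 1 or wx < 1:
        raise ValueError("window sides must be >= 1")
    if wy > ny or wx > nx:
        raise ValueError(
            f"window {wy}x{wx} larger than slice {ny}x{nx}"
        )
    out = _window_product_max(fg.values, wy, wx)
    return ProbabilityMap(values=out, stage="blob2d", channel_name=fg.channel_name)


def span_probability(blob: ProbabilityMap, span_slices: int) -> ProbabilityMap:
    """Probability of belonging to a blob spanning consecutive sections.

    For each voxel at (z, y, x): the maximum, over all runs of
    ``span_slices`` consecutive slices that contain z, of the product of the
    2D-blob probabilities at (y, x) across the run. Requiring a multi-slice
    span rejects single-section specks (dust, random noise) while
    propagating a qualifying run's score to every slice it covers.
    ``span_slices = 1`` is the identity.
    """
    if blob.stage != "blob2d":
        raise ValueError(f"expected blob2d-stage map, got {blob.stage!r}")
    s = int(span_slices)
    nz = blob.shape[0]
    if s < 1:
        raise ValueError("span_slices must be >= 1")
    if s > nz:
        raise ValueError(f"span {s} exceeds stack depth {nz}")
    vals = blob.values
    nruns = nz - s + 1
    prod = np.ones((nruns,) + vals.shape[1:], dtype=np.float64)
    for k in range(s):
        prod *= vals[k : k + nruns]
    out = np.zeros_like(vals)
    for k in range(s):
        np.maximum(out[k : k + nruns], prod, out=out[k : k + nruns])
    return ProbabilityMap(values=out, stage="punctum3d", channel_name=blob.channel_name)
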