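"""Aspiration-depth extraction from image sequences.

The measurement instrument records the aspiration at 75 f.p.s.; the depth
time series is recovered from the video in three steps: locate the pipette
(wall rows, opening column) in the first frame, track the embryo's leading
edge inside the lumen by normalized cross-correlation template matching
with subpixel (parabolic) peak interpolation, and convert tracked pixel
positions to an :class:`~embryomech.viscoelastic.AspirationTrace` using the
pixel size and frame rate.  Automated tracking removes the bias of manual
depth measurements.

Conventions: 0-based pixel indices, positions at pixel centers, and depth
positive into the pipette regardless of entry side.  Depth zero is defined
by the edge position at the pressure-step onset frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import canny, match_template
from skimage.filters import threshold_otsu

from embryomech.viscoelastic import AspirationTrace, PressureProtocol

__all__ = [
    "ImageSequence",
    "PipetteGeometry",
    "TrackResult",
    "PipetteDetectionError",
    "TrackingError",
    "detect_pipette",
    "track_edge",
    "to_trace",
]


class PipetteDetectionError(RuntimeError):
    """Raised when no plausible pipette geometry is found; the message
    names the detection stage that failed."""


class TrackingError(RuntimeError):
    pass


@dataclass
class ImageSequence:
    """Grayscale raster stack with physical metadata.

    frames: (n, rows, cols), origin top-left, row-major.
    """

    frames: np.ndarray
    pixel_size_m: float = 0.5e-6
    frame_rate_hz: float = 75.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("an image sequence needs >= 2 frames of constant shape")
        if self.pixel_size_m <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("pixel size and frame rate must be positive")


@dataclass
class PipetteGeometry:
    """Pipette wall rows, opening column and lumen radius, in pixels.

    ``wall_rows`` are the lumen-facing rows of the two walls; the lumen is
    strictly between them.
    """

    opening_column: int
    wall_rows: tuple[int, int]
    inner_radius_px: float
    entry_side: str

    def lumen_rows(self, inset: int = 1) -> slice:
        return slice(self.wall_rows[0] + 1 + inset, self.wall_rows[1] - inset)


@dataclass
class TrackResult:
    """Per-frame subpixel edge depth (px, positive into the pipette) and
    matching quality (peak normalized cross-correlation)."""

    depths_px: np.ndarray
    quality: np.ndarray
    flagged: np.ndarray  # frames whose peak fell below threshold


def _wall_bands(mask: np.ndarray, min_run_frac: float) -> list[tuple[int, int]]:
    """Contiguous row bands whose longest horizontal dark run is wall-like."""
    h, w = mask.shape
    min_run = int(min_run_frac * w)
    # longest run of True per row
    padded = np.zeros((h, w + 2), bool)
    padded[:, 1:-1] = mask
    row_ok = np.zeros(h, bool)
    for r in range(h):
        d = np.flatnonzero(np.diff(padded[r].astype(np.int8)))
        if d.size:
            runs = d[1::2] - d[0::2]
            row_ok[r] = runs.max() >= min_run
    bands = []
    r = 0
    while r < h:
        if row_ok[r]:
            r2 = r
            while r2 + 1 < h and row_ok[r2 + 1]:
                r2 += 1
            bands.append((r, r2))
            r = r2 + 1
        else:
            r += 1
    return bands


def detect_pipette(
    frame: np.ndarray,
    min_run_frac: float = 0.25,
    canny_sigma: float = 2.0,
) -> PipetteGeometry:
    """Locate the pipette walls and opening in a single frame.

    Two-stage thresholding (Otsu, then Otsu again among the dark pixels)
    isolates the wall gray level from both background and embryo; rows whose
    longest dark run spans a wall-like fraction of the width form the two
    wall bands.  The opening column is the walls' termination corner,
    refined with Canny edges (Gaussian sigma ``canny_sigma``, Otsu-derived
    hysteresis) inside the wall bands.
    """
    img = np.asarray(frame, float)
    if img.ndim != 2:
        raise ValueError("detect_pipette expects a single 2-D frame")
    t1 = threshold_otsu(img)
    dark = img[img < t1]
    if dark.size < 16 or np.ptp(dark) < 1e-9:
        raise PipetteDetectionError("wall detection failed: no dark structures")
    t2 = threshold_otsu(dark)
    mask = img < t2

    bands = _wall_bands(mask, min_run_frac)
    if len(bands) != 2:
        raise PipetteDetectionError(
            f"wall detection failed: expected 2 wall bands, found {len(bands)}"
        )
    (a0, a1), (b0, b1) = bands
    wall_rows = (a1, b0)  # lumen-facing rows
    gap = b0 - a1
    if gap < 4:
        raise PipetteDetectionError("wall detection failed: lumen gap too small")

    # termination corner of each wall run -> entry side and opening column
    h, w = mask.shape
    ends = []
    sides = []
    for r0, r1 in bands:
        band = mask[r0 : r1 + 1]
        cols = np.flatnonzero(band.any(axis=0))
        if cols.size == 0:
            raise PipetteDetectionError("corner detection failed: empty wall band")
        sides.append("left" if cols[0] <= 2 else "right")
        ends.append(cols[-1] if cols[0] <= 2 else cols[0])
    if sides[0] != sides[1]:
        raise PipetteDetectionError("corner detection failed: walls disagree on entry side")
    entry_side = sides[0]

    # Canny refinement: the strongest vertical edge at the wall tips
    edges = canny(img, sigma=canny_sigma)
    refined = []
    for (r0, r1), end in zip(bands, ends):
        band_edges = edges[r0 : r1 + 1]
        cols = np.flatnonzero(band_edges.any(axis=0))
        if cols.size:
            cand = cols[-1] if entry_side == "left" else cols[0]
            if abs(int(cand) - int(end)) <= 3:
                end = int(cand)
        refined.append(int(end))
    opening = int(round(np.mean(refined)))
    return PipetteGeometry(
        opening_column=opening,
        wall_rows=wall_rows,
        inner_radius_px=gap / 2.0,
        entry_side=entry_side,
    )


def _axis_strip(frame: np.ndarray, geom: PipetteGeometry) -> np.ndarray:
    strip = np.asarray(frame, float)[geom.lumen_rows()]
    return strip if geom.entry_side == "left" else strip[:, ::-1]


def _edge_guess(strip: np.ndarray, opening: int) -> int:
    """Coarse leading-edge column from the lumen intensity profile."""
    prof = strip[:, : opening + 1].mean(axis=0)
    lo, hi = prof.min(), prof.max()
    if hi - lo < 1e-9:
        raise TrackingError("no edge visible inside the lumen")
    dark = prof < (lo + hi) / 2.0
    idx = np.flatnonzero(dark)
    if idx.size == 0:
        raise TrackingError("no edge visible inside the lumen")
    return int(idx[0])  # first dark column = leading edge (tongue grows leftward)


def _parabolic_peak(c: np.ndarray, i: int) -> float:
    if 0 < i < c.size - 1:
        denom = c[i - 1] - 2 * c[i] + c[i + 1]
        if abs(denom) > 1e-12:
            return i + 0.5 * (c[i - 1] - c[i + 1]) / denom
    return float(i)


def track_edge(
    seq: ImageSequence,
    geom: PipetteGeometry,
    template_halfwidth_px: int = 8,
    search_halfwidth_px: int = 50,
    quality_threshold: float = 0.6,
    max_interpolated: int = 3,
) -> TrackResult:
    """Track the aspirated leading edge through the sequence.

    The template is the patch around the frame-0 leading edge restricted to
    the lumen rows.  Each frame is matched by normalized cross-correlation
    over a 1-D window along the pipette axis centered on the previous
    position; the peak is refined by parabolic interpolation and its height
    is the per-frame quality.  Frames below ``quality_threshold`` are
    flagged and linearly interpolated from their neighbours; more than
    ``max_interpolated`` consecutive flagged frames raise
    :class:`TrackingError`.
    """
    n = seq.frames.shape[0]
    # internal axis: columns increase toward the pipette interior's mouth,
    # i.e. the tongue grows toward smaller columns
    opening = geom.opening_column
    if geom.entry_side == "right":
        opening = seq.frames.shape[2] - 1 - geom.opening_column

    strip0 = _axis_strip(seq.frames[0], geom)
    e0 = _edge_guess(strip0, opening)
    hw = template_halfwidth_px
    lo0, hi0 = max(e0 - hw, 0), min(e0 + hw + 1, strip0.shape[1])
    template = strip0[:, lo0:hi0]
    t_center = e0 - lo0  # edge offset within template

    positions = np.full(n, np.nan)
    quality = np.zeros(n)
    prev = float(e0)
    for i in range(n):
        strip = _axis_strip(seq.frames[i], geom)
        lo = int(max(round(prev) - hw - search_halfwidth_px, 0))
        hi = int(min(round(prev) + hw + search_halfwidth_px + 1, strip.shape[1]))
        window = strip[:, lo:hi]
        if window.shape[1] < template.shape[1] + 2:
            raise TrackingError(f"search window fell outside the lumen at frame {i}")
        cc = match_template(window, template).ravel()
        j = int(np.argmax(cc))
        quality[i] = float(cc[j])
        if quality[i] >= quality_threshold:
            positions[i] = lo + _parabolic_peak(cc, j) + t_center
            prev = positions[i]

    flagged = ~np.isfinite(positions)
    if flagged.any():
        runs = _flag_runs(flagged)
        if max(r1 - r0 + 1 for r0, r1 in runs) > max_interpolated:
            raise TrackingError(
                "lost track: more than "
                f"{max_interpolated} consecutive frames below quality "
                f"{quality_threshold}"
            )
        good = np.flatnonzero(~flagged)
        positions[flagged] = np.interp(np.flatnonzero(flagged), good, positions[good])

    depths = e0 - positions  # tongue grows toward smaller columns
    return TrackResult(depths_px=depths, quality=quality, flagged=flagged)


def _flag_runs(flagged: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    i = 0
    n = flagged.size
    while i < n:
        if flagged[i]:
            j = i
            while j + 1 < n and flagged[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def to_trace(
    track: TrackResult,
    seq: ImageSequence,
    protocol: PressureProtocol | None = None,
    onset_frame: int = 0,
) -> AspirationTrace:
    """Convert tracked pixel depths to an aspiration trace in SI units.

    ``onset_frame`` is the last frame before the pressure step (from the
    pressure log or sidecar); its position defines depth zero, and only
    post-onset frames enter the trace, with times zeroed at the onset.
    """
    n = track.depths_px.size
    if not 0 <= onset_frame < n - 1:
        raise ValueError("onset frame must lie inside the sequence")
    depth0 = track.depths_px[onset_frame]
    idx = np.arange(onset_frame + 1, n)
    times = (idx - onset_frame) / seq.frame_rate_hz
    depths = (track.depths_px[idx] - depth0) * seq.pixel_size_m
    pressure = None
    if protocol is not None:
        pressure = np.full(idx.size, protocol.step_pressure_pa)
    return AspirationTrace(times, depths, seq.frame_rate_hz, pressure)
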