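"""Seeded synthetic fixtures emulating the aspiration study's measurements.

Every downstream module is exercised on data produced here: embryo cohorts
with mechanical and cell-cycle features plus blastocyst labels, pressure-step
aspiration traces, grayscale aspiration image sequences, and confocal
z-stacks with a cortical ring of granule puncta.

The cohort geometry mirrors the measured populations: viable zygotes cluster
tightly (log-normal, 15% multiplicative spread by default) around the
species' viable center — human (k1=0.30, η1=0.59, k0=0.12) N·m⁻¹ /
N·s·m⁻¹, mouse (k1=0.17, η1=1.3, k0=0.06) — while non-viable zygotes are
drawn from a dispersed two-component mixture ("too stiff" at 1.8× the
center and "too soft" at 0.55×, 40% spread), with no typical non-viable
phenotype.  The series-dashpot viscosity η0 is drawn from the same
distribution for both classes and therefore carries no class signal by
construction.  Blastocyst labels follow the mechanical class but are
flipped with probability ``label_noise`` so classification is hard but
learnable.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from embryomech.viscoelastic import (
    AspirationTrace,
    ModelKind,
    PressureProtocol,
    ViscoParams,
    creep,
    step_force,
)
from embryomech.tracking import ImageSequence

__all__ = [
    "CohortSpec",
    "EmbryoRecord",
    "VideoScene",
    "ConfocalSpec",
    "sample_cohort",
    "cohort_to_frame",
    "frame_to_records",
    "render_trace",
    "aspiration_motion",
    "render_video",
    "render_confocal",
    "SPECIES_CENTERS",
]

#: per-species viable-cluster centers; mechanics in N·m⁻¹ / N·s·m⁻¹,
#: cell-cycle intervals in hours.  η0 carries no printed value; its default
#: is chosen so the constant-rate tail is visible within a 5-s window.
SPECIES_CENTERS = {
    "human": {
        "k1": 0.30, "eta1": 0.59, "k0": 0.12, "eta0": 5.0,
        "c1": 0.20, "c2": 11.32, "c3": 2.91,
    },
    "mouse": {
        "k1": 0.17, "eta1": 1.3, "k0": 0.06, "eta0": 3.0,
        "c1": 0.20, "c2": 11.32, "c3": 2.91,
    },
}

_MECH = ("k0", "k1", "eta1")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic embryo cohort.

    Default counts follow the measured human cohort (31 viable, 58
    non-viable).  ``viable_spread`` and the mixture spread are multiplicative
    (log-normal) dispersions: 1.15 means "15% spread".
    """

    species: str = "human"
    n_viable: int = 31
    n_nonviable: int = 58
    viable_center: dict | None = None
    viable_spread: float = 1.15
    nonviable_weights: tuple[float, float] = (0.5, 0.5)
    nonviable_stiff_factor: float = 1.8
    nonviable_soft_factor: float = 0.55
    nonviable_spread: float = 1.4
    label_noise: float = 0.1
    cellcycle_center: tuple[float, float, float] | None = None
    cellcycle_viable_cv: float = 0.10
    cellcycle_band: tuple[float, float] = (0.25, 2.5)
    seed: int = 0

    def resolved_center(self) -> dict:
        if self.species not in SPECIES_CENTERS:
            raise ValueError(f"unknown species {self.species!r}")
        center = dict(SPECIES_CENTERS[self.species])
        if self.viable_center:
            center.update(self.viable_center)
        if self.cellcycle_center is not None:
            center["c1"], center["c2"], center["c3"] = self.cellcycle_center
        for name in ("k0", "k1", "eta1", "eta0", "c1", "c2", "c3"):
            if center[name] <= 0:
                raise ValueError(f"center for {name!r} must be positive, got {center[name]}")
        return center

    def __post_init__(self) -> None:
        if self.n_viable < 0 or self.n_nonviable < 0:
            raise ValueError("cohort counts must be non-negative")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must lie in [0, 1]")
        if self.viable_spread < 1.0 or self.nonviable_spread < 1.0:
            raise ValueError("multiplicative spreads must be >= 1")
        self.resolved_center()  # validates centers eagerly


@dataclass
class EmbryoRecord:
    """One embryo's features and labels."""

    embryo_id: str
    species: str
    k0: float
    k1: float
    eta0: float
    eta1: float
    c1: float
    c2: float
    c3: float
    blastocyst: bool
    predicted_viable: bool | None = None

    def visco_params(self) -> ViscoParams:
        return ViscoParams(k0=self.k0, k1=self.k1, eta1=self.eta1, eta0=self.eta0)


def _lognormal(rng, center, spread, size):
    return np.exp(rng.normal(math.log(center), math.log(spread), size))


def sample_cohort(spec: CohortSpec) -> list[EmbryoRecord]:
    """Draw one seeded cohort of embryo records.

    Viable mechanics are tight log-normals around the species center;
    non-viable mechanics come from the stiff/soft mixture; η0 is drawn from
    one shared distribution for both classes.  Viable cell-cycle intervals
    are near their centers; non-viable intervals are spread over a wide
    uniform band.  Blastocyst labels equal the mechanical class flipped with
    probability ``label_noise``.
    """
    rng = np.random.default_rng(spec.seed)
    center = spec.resolved_center()
    records: list[EmbryoRecord] = []

    def mech_viable(n):
        return {m: _lognormal(rng, center[m], spec.viable_spread, n) for m in _MECH}

    def mech_nonviable(n):
        comp = rng.random(n) < spec.nonviable_weights[0]  # True -> stiff
        out = {}
        for m in _MECH:
            stiff = _lognormal(rng, center[m] * spec.nonviable_stiff_factor,
                               spec.nonviable_spread, n)
            soft = _lognormal(rng, center[m] * spec.nonviable_soft_factor,
                              spec.nonviable_spread, n)
            out[m] = np.where(comp, stiff, soft)
        return out

    for viable, n in ((True, spec.n_viable), (False, spec.n_nonviable)):
        mech = mech_viable(n) if viable else mech_nonviable(n)
        eta0 = _lognormal(rng, center["eta0"], spec.viable_spread, n)
        if viable:
            cc = {
                c: np.maximum(
                    rng.normal(center[c], spec.cellcycle_viable_cv * center[c], n), 0.0
                )
                for c in ("c1", "c2", "c3")
            }
        else:
            lo, hi = spec.cellcycle_band
            cc = {c: rng.uniform(lo * center[c], hi * center[c], n)
                  for c in ("c1", "c2", "c3")}
        flips = rng.random(n) < spec.label_noise
        tag = "v" if viable else "nv"
        for i in range(n):
            records.append(
                EmbryoRecord(
                    embryo_id=f"{spec.species[:1]}{tag}{i:03d}",
                    species=spec.species,
                    k0=float(mech["k0"][i]),
                    k1=float(mech["k1"][i]),
                    eta0=float(eta0[i]),
                    eta1=float(mech["eta1"][i]),
                    c1=float(cc["c1"][i]),
                    c2=float(cc["c2"][i]),
                    c3=float(cc["c3"][i]),
                    blastocyst=bool(viable ^ flips[i]),
                )
            )
    return records


_COHORT_COLUMNS = [
    "embryo_id", "species", "k0", "k1", "eta0", "eta1",
    "c1", "c2", "c3", "blastocyst",
]


def cohort_to_frame(records: list[EmbryoRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame in the canonical CSV column order."""
    df = pd.DataFrame([asdict(r) for r in records])
    return df[_COHORT_COLUMNS]


def frame_to_records(df: pd.DataFrame) -> list[EmbryoRecord]:
    return [
        EmbryoRecord(**{k: row[k] for k in _COHORT_COLUMNS})
        for _, row in df.iterrows()
    ]


def render_trace(
    params: ViscoParams,
    protocol: PressureProtocol,
    noise_sd_m: float = 1e-7,
    duration_s: float = 5.0,
    rate_hz: float = 75.0,
    seed: int = 0,
) -> AspirationTrace:
    """Synthetic aspiration trace: modified-Zener creep plus Gaussian noise.

    Depths are the closed-form creep response sampled at ``rate_hz`` from
    the step onset, with i.i.d. zero-mean Gaussian measurement noise of
    standard deviation ``noise_sd_m`` (default 0.1 μm).
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration and rate must be positive")
    if noise_sd_m < 0:
        raise ValueError("noise_sd_m must be non-negative")
    f0 = step_force(protocol)
    n = int(round(duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    x = creep(t, ModelKind.MODIFIED_ZENER, params, f0)
    if noise_sd_m > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise_sd_m, n)
    pressure = np.full(n, protocol.step_pressure_pa)
    return AspirationTrace(t, x, rate_hz, pressure)


def aspiration_motion(
    params: ViscoParams,
    protocol: PressureProtocol,
    n_pre_frames: int = 5,
    duration_s: float = 5.0,
    rate_hz: float = 75.0,
    holding_depth_m: float = 4e-6,
) -> tuple[np.ndarray, int]:
    """Depth-vs-time motion for a rendered aspiration video.

    Returns ``(motion_m, onset_frame)``: ``n_pre_frames`` frames at the
    holding depth (the small tongue drawn in by the holding pressure before
    the step), then the modified-Zener creep response on top of it.
    ``onset_frame`` (the last pre-step frame) is the index
    :func:`embryomech.tracking.to_trace` expects.
    """
    f0 = step_force(protocol)
    n_post = int(round(duration_s * rate_hz))
    t_post = np.arange(1, n_post + 1) / rate_hz
    motion = np.concatenate(
        [np.zeros(n_pre_frames), creep(t_post, ModelKind.MODIFIED_ZENER, params, f0)]
    )
    return motion + holding_depth_m, n_pre_frames - 1


# ---------------------------------------------------------------------------
# aspiration video rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VideoScene:
    """Pixel geometry of a synthetic aspiration scene.

    8-bit grayscale, pipette horizontal.  ``wall_inner_rows`` are the
    lumen-facing rows of the two pipette walls; the lumen occupies the rows
    strictly between them.  For ``entry_side='left'`` the pipette tube spans
    columns [0, opening_column] and the aspirated tongue grows leftward from
    the opening.  Default pixel size 0.5 μm/px.
    """

    shape: tuple[int, int] = (160, 420)
    wall_inner_rows: tuple[int, int] = (55, 105)
    wall_thickness_px: int = 8
    opening_column: int = 300
    entry_side: str = "left"
    embryo_radius_px: float = 80.0
    pixel_size_m: float = 0.5e-6
    frame_rate_hz: float = 75.0
    background_gray: float = 230.0
    wall_gray: float = 30.0
    embryo_gray: float = 110.0

    @property
    def inner_radius_px(self) -> float:
        return (self.wall_inner_rows[1] - self.wall_inner_rows[0]) / 2.0

    def __post_init__(self) -> None:
        h, w = self.shape
        r0, r1 = self.wall_inner_rows
        if not (0 < r0 < r1 < h):
            raise ValueError("wall rows must fit inside the frame")
        if self.embryo_radius_px < self.inner_radius_px:
            raise ValueError(
                "embryo radius smaller than pipette inner radius: "
                "the embryo would pass freely through the pipette"
            )
        if not 0 < self.opening_column < w:
            raise ValueError("opening column outside frame")
        if self.entry_side not in ("left", "right"):
            raise ValueError("entry_side must be 'left' or 'right'")


def render_video(
    motion_m: np.ndarray,
    scene: VideoScene = VideoScene(),
    noise_sd: float = 2.0,
    seed: int = 0,
) -> ImageSequence:
    """Render an aspiration image sequence for a given depth-vs-time motion.

    ``motion_m`` gives the aspiration depth (m, ≥0 into the pipette) at each
    frame time.  Frames show a bright background, dark pipette walls ending
    at the opening, the disk-shaped embryo body sealed against the opening,
    and an aspirated tongue inside the lumen whose anti-aliased leading edge
    sits ``motion`` pixels into the pipette.  Additive Gaussian pixel noise,
    clipped to 8-bit range.
    """
    motion_px = np.asarray(motion_m, float) / scene.pixel_size_m
    if motion_px.ndim != 1 or motion_px.size < 1:
        raise ValueError("motion must be a 1-D per-frame array")
    if np.any(motion_px < -1e-9):
        raise ValueError("aspiration depth must be non-negative")
    h, w = scene.shape
    if np.any(motion_px >= scene.opening_column - 2):
        raise ValueError("motion leaves the frame; enlarge the scene")

    r0, r1 = scene.wall_inner_rows
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]

    static = np.full((h, w), scene.background_gray)
    # embryo body: anti-aliased disk sealed against the opening
    cy = (r0 + r1) / 2.0
    off = math.sqrt(max(scene.embryo_radius_px**2 - scene.inner_radius_px**2, 0.0))
    cx = scene.opening_column + off
    dist = np.hypot(rows - cy, cols - cx)
    cov = np.clip(scene.embryo_radius_px + 0.5 - dist, 0.0, 1.0)
    static = static * (1 - cov) + scene.embryo_gray * cov
    # pipette walls occlude everything beneath them
    wall_rows = ((rows >= r0 - scene.wall_thickness_px + 1) & (rows <= r0)) | (
        (rows >= r1) & (rows <= r1 + scene.wall_thickness_px - 1)
    )
    wall = wall_rows & (cols <= scene.opening_column)
    static[wall] = scene.wall_gray

    lumen = np.zeros((h, w), bool)
    lumen[r0 + 1 : r1, : scene.opening_column + 1] = True

    frames = np.empty((motion_px.size, h, w), np.uint8)
    rng = np.random.default_rng(seed)
    col_axis = np.arange(w, dtype=float)
    for i, d in enumerate(motion_px):
        img = static.copy()
        edge = scene.opening_column - d
        cov_t = np.clip(col_axis + 0.5 - edge, 0.0, 1.0)[None, :]
        tongue = np.where(lumen, cov_t, 0.0)
        img = img * (1 - tongue) + scene.embryo_gray * tongue
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    if scene.entry_side == "right":
        frames = frames[:, :, ::-1].copy()
    return ImageSequence(
        frames=frames,
        pixel_size_m=scene.pixel_size_m,
        frame_rate_hz=scene.frame_rate_hz,
    )


# ---------------------------------------------------------------------------
# confocal z-stack rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfocalSpec:
    """Recipe for a synthetic cortical-granule confocal stack.

    Each slice carries a smooth cortical ring (a flat annulus centered at
    0.95R, slightly wider than the downstream 10%-of-radius scoring band) at
    ``ring_level``, plus ``n_puncta`` Gaussian granule puncta on the
    annulus.  Slice ``k`` is attenuated by exp(−k/attenuation_scale) to
    emulate signal loss at depth.
    """

    shape: tuple[int, int] = (256, 256)
    center: tuple[float, float] = (128.0, 128.0)
    radius_px: float = 60.0
    ring_level: float = 0.6
    ring_halfwidth_frac: float = 0.08  # annulus [0.87R, 1.03R]
    n_puncta: int = 40
    punctum_amplitude: float = 0.6
    punctum_sigma_px: float = 1.5
    background_level: float = 0.03
    interior_level: float = 0.30  # cytoplasm autofluorescence above background
    noise_sd: float = 0.01
    attenuation_scale: float = math.inf
    n_slices: int = 8

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.radius_px <= 0:
            raise ValueError("radius must be positive")
        h, w = self.shape
        cy, cx = self.center
        if not (self.radius_px * 1.05 <= min(cy, cx, h - 1 - cy, w - 1 - cx)):
            raise ValueError("cell (with its cortical ring) must fit inside the frame")


def render_confocal(spec: ConfocalSpec, seed: int = 0) -> np.ndarray:
    """Render a float32 z-stack (slices × rows × cols) of a cortical ring."""
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    cy, cx = spec.center
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    r = np.hypot(rows - cy, cols - cx)
    ring_lo = spec.radius_px * (0.95 - spec.ring_halfwidth_frac)
    ring_hi = spec.radius_px * (0.95 + spec.ring_halfwidth_frac)
    ring = ((r >= ring_lo) & (r <= ring_hi)).astype(float)
    cytoplasm = (r <= ring_hi).astype(float)

    stack = np.empty((spec.n_slices, h, w), np.float32)
    for k in range(spec.n_slices):
        img = (spec.background_level
               + (spec.interior_level - spec.background_level) * cytoplasm
               + spec.ring_level * ring)
        if spec.n_puncta:
            ang = rng.uniform(0, 2 * math.pi, spec.n_puncta)
            rad = rng.normal(0.95 * spec.radius_px, 0.015 * spec.radius_px,
                             spec.n_puncta)
            for a, rr in zip(ang, rad):
                py, px = cy + rr * math.sin(a), cx + rr * math.cos(a)
                img += spec.punctum_amplitude * np.exp(
                    -((rows - py) ** 2 + (cols - px) ** 2)
                    / (2 * spec.punctum_sigma_px**2)
                )
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        att = math.exp(-k / spec.attenuation_scale) if math.isfinite(
            spec.attenuation_scale) else 1.0
        stack[k] = (img * att).astype(np.float32)
    return stack
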