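"""Synthetic swarm sequences with ground truth.

Renders 50-100 dark few-pixel bodies on a white 65:40-aspect arena with
rest/fly Markov switching, random-walk flight, optional attraction drift
and optional vertical excitation while a stimulus is present.  All
randomness flows from one seeded PCG64 stream, so sequences are
reproducible bit-for-bit across runs and platforms.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import asdict, dataclass

import numpy as np

from .session import Session, SessionMeta, make_record

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "GroundTruth",
    "init_state",
    "step_motion",
    "render_frame",
    "simulate_motion",
    "simulate_swarm",
    "ground_truth_session",
    "write_frames",
]


@dataclass(frozen=True)
class SwarmConfig:
    """Motion-model and rendering parameters for the synthetic swarm.

    Arena defaults mirror the 65 cm x 40 cm observation region at
    10 px/cm; body centers are kept ``body_radius`` away from the walls
    (reflecting boundary) so rendered disks are never clipped, and
    ``min_separation`` (0 disables it) keeps bodies apart so that
    detections stay unmerged.
    """

    arena_w: int = 650
    arena_h: int = 400
    n: int = 100
    body_radius: int = 2
    body_intensity_mean: float = 40.0
    body_intensity_sd: float = 10.0
    background: int = 255
    noise_sd: float = 3.0
    p_rest_to_fly: float = 0.1
    p_fly_to_rest: float = 0.2
    sigma: float = 3.0
    kappa: float = 0.0
    presence_sigma_scale_y: float = 1.0
    stimulus_point: tuple[float, float] = (0.0, 200.0)
    presence: tuple[tuple[float, float], ...] = ()
    n_frames: int = 100
    interval: float = 2.0
    seed: int = 0
    min_separation: float = 8.0

    def __post_init__(self) -> None:
        for name in ("p_rest_to_fly", "p_fly_to_rest"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.sigma < 0 or self.kappa < 0:
            raise ValueError("sigma and kappa must be >= 0")
        if min(self.arena_w, self.arena_h) < 4 * self.body_radius:
            raise ValueError("arena dimensions must be >= 4 * body_radius")
        if self.n < 0 or self.n_frames < 1 or self.interval <= 0:
            raise ValueError("need n >= 0, n_frames >= 1, interval > 0")
        for lo, hi in self.presence:
            if hi <= lo:
                raise ValueError(f"presence interval [{lo}, {hi}) is empty")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stimulus_point"] = list(self.stimulus_point)
        d["presence"] = [list(p) for p in self.presence]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SwarmConfig":
        d = dict(d)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stimulus_point" in d:
            d["stimulus_point"] = tuple(d["stimulus_point"])
        if "presence" in d:
            d["presence"] = tuple(tuple(p) for p in d["presence"])
        return cls(**d)


@dataclass
class SwarmState:
    positions: np.ndarray  # (n, 2) float, columns (x, y)
    flying: np.ndarray  # (n,) bool


@dataclass
class GroundTruth:
    """True per-frame positions, flight states and collective means."""

    t: np.ndarray  # (F,)
    positions: np.ndarray  # (F, n, 2)
    flying: np.ndarray  # (F, n) bool

    @property
    def mean_x(self) -> np.ndarray:
        if self.positions.shape[1] == 0:
            return np.full(len(self.t), np.nan)
        return self.positions[:, :, 0].mean(axis=1)

    @property
    def mean_y(self) -> np.ndarray:
        if self.positions.shape[1] == 0:
            return np.full(len(self.t), np.nan)
        return self.positions[:, :, 1].mean(axis=1)

    def to_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame", "t", "individual", "x", "y", "flying"])
            for k in range(len(self.t)):
                for m in range(self.positions.shape[1]):
                    writer.writerow(
                        [
                            k,
                            float(self.t[k]),
                            m,
                            float(self.positions[k, m, 0]),
                            float(self.positions[k, m, 1]),
                            int(self.flying[k, m]),
                        ]
                    )


def _bounds(config: SwarmConfig) -> tuple[float, float, float, float]:
    m = float(config.body_radius)
    return m, config.arena_w - 1 - m, m, config.arena_h - 1 - m


def in_presence(t: float, presence) -> bool:
    return any(lo <= t < hi for lo, hi in presence)


def init_state(config: SwarmConfig, rng: np.random.Generator) -> SwarmState:
    """Place individuals uniformly with pairwise separation, mixed states."""
    xlo, xhi, ylo, yhi = _bounds(config)
    positions = np.empty((config.n, 2))
    for m in range(config.n):
        for _ in range(10_000):
            cand = np.array(
                [rng.uniform(xlo, xhi), rng.uniform(ylo, yhi)]
            )
            if m == 0 or config.min_separation <= 0:
                break
            d = np.hypot(*(positions[:m] - cand).T)
            if d.min() >= config.min_separation:
                break
        else:
            raise RuntimeError("could not place individuals with requested separation")
        positions[m] = cand
    p_total = config.p_rest_to_fly + config.p_fly_to_rest
    p_fly = config.p_rest_to_fly / p_total if p_total > 0 else 0.0
    flying = rng.random(config.n) < p_fly
    return SwarmState(positions, flying)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    if span <= 0:
        return np.full_like(x, (lo + hi) / 2.0)
    y = np.mod(x - lo, 2.0 * span)
    folded = lo + np.minimum(y, 2.0 * span - y)
    return np.where((x >= lo) & (x <= hi), x, folded)


def step_motion(
    state: SwarmState, config: SwarmConfig, rng: np.random.Generator, t: float
) -> SwarmState:
    """Advance one frame: Markov switch, then move the flying individuals.

    Flying individuals take N(0, sigma^2) steps per axis; during stimulus
    presence the vertical step sd is scaled by ``presence_sigma_scale_y``
    and a drift of magnitude ``kappa`` toward ``stimulus_point`` is added.
    Positions reflect off the walls; resting individuals do not move.
    """
    n = config.n
    u = rng.random(n)
    flying = np.where(state.flying, u >= config.p_fly_to_rest, u < config.p_rest_to_fly)

    present = in_presence(t, config.presence)
    steps = rng.normal(0.0, 1.0, (n, 2)) * config.sigma
    if present and config.presence_sigma_scale_y != 1.0:
        steps[:, 1] *= config.presence_sigma_scale_y
    if present and config.kappa > 0:
        delta = np.asarray(config.stimulus_point) - state.positions
        dist = np.hypot(delta[:, 0], delta[:, 1])
        # unit vector toward the stimulus, capped so we never overshoot
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(dist[:, None] > 0, delta / dist[:, None], 0.0)
        steps += unit * np.minimum(config.kappa, dist)[:, None]

    xlo, xhi, ylo, yhi = _bounds(config)
    proposed = state.positions + np.where(flying[:, None], steps, 0.0)
    proposed[:, 0] = _reflect(proposed[:, 0], xlo, xhi)
    proposed[:, 1] = _reflect(proposed[:, 1], ylo, yhi)

    positions = state.positions.copy()
    if config.min_separation > 0:
        # accept moves one at a time; reject any that would crowd a neighbor
        for m in np.flatnonzero(flying):
            others = np.delete(positions, m, axis=0)
            if len(others) == 0:
                positions[m] = proposed[m]
                continue
            d = np.hypot(*(others - proposed[m]).T)
            if d.min() >= config.min_separation:
                positions[m] = proposed[m]
    else:
        positions[flying] = proposed[flying]

    return SwarmState(positions, flying)


def simulate_motion(config: SwarmConfig) -> GroundTruth:
    """Run the motion model alone (no rendering); deterministic in seed."""
    rng_motion, _ = _streams(config.seed)
    t = np.arange(config.n_frames) * config.interval
    positions = np.empty((config.n_frames, config.n, 2))
    flying = np.empty((config.n_frames, config.n), dtype=bool)
    state = init_state(config, rng_motion)
    positions[0], flying[0] = state.positions, state.flying
    for k in range(1, config.n_frames):
        state = step_motion(state, config, rng_motion, float(t[k]))
        positions[k], flying[k] = state.positions, state.flying
    return GroundTruth(t, positions, flying)


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    motion_ss, render_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.Generator(np.random.PCG64(motion_ss)), np.random.Generator(
        np.random.PCG64(render_ss)
    )


def render_frame(
    positions: np.ndarray, config: SwarmConfig, rng: np.random.Generator
) -> np.ndarray:
    """Rasterize one frame: background, filled body disks, pixel noise.

    Disks have no anti-aliasing: a pixel is drawn iff its center lies
    within ``body_radius`` of the body center.  Body intensity is drawn
    per individual from N(mean, sd); noise is additive Gaussian, with the
    final frame clipped to [0, 255].
    """
    h, w = config.arena_h, config.arena_w
    frame = np.full((h, w), float(config.background))
    r = config.body_radius
    intensities = rng.normal(
        config.body_intensity_mean, config.body_intensity_sd, len(positions)
    )
    for (x, y), val in zip(positions, intensities):
        j0 = max(0, math.ceil(x - r))
        j1 = min(w - 1, math.floor(x + r))
        i0 = max(0, math.ceil(y - r))
        i1 = min(h - 1, math.floor(y + r))
        if j1 < j0 or i1 < i0:
            continue
        jj, ii = np.meshgrid(np.arange(j0, j1 + 1), np.arange(i0, i1 + 1))
        mask = (jj - x) ** 2 + (ii - y) ** 2 <= r * r
        patch = frame[i0 : i1 + 1, j0 : j1 + 1]
        patch[mask] = np.clip(val, 0, 255)
    if config.noise_sd > 0:
        frame += rng.normal(0.0, config.noise_sd, frame.shape)
    return np.clip(np.floor(frame + 0.5), 0, 255).astype(np.uint8)


def simulate_swarm(config: SwarmConfig) -> tuple[list[np.ndarray], GroundTruth]:
    """Full synthetic sequence: frames plus aligned ground truth."""
    gt = simulate_motion(config)
    _, rng_render = _streams(config.seed)
    frames = [
        render_frame(gt.positions[k], config, rng_render)
        for k in range(config.n_frames)
    ]
    return frames, gt


def ground_truth_session(gt: GroundTruth, config: SwarmConfig) -> Session:
    """Wrap true per-frame positions as a detection-free session.

    With zero individuals every record is a gap record.
    """
    meta = SessionMeta(
        location="synthetic",
        freq_range=f"seed={config.seed}",
        interval=config.interval,
    )
    records = [
        make_record(float(gt.t[k]), [tuple(p) for p in gt.positions[k]])
        for k in range(len(gt.t))
    ]
    return Session(meta, records)


def write_frames(frames, out_dir: str | os.PathLike, fmt: str = "png") -> list[str]:
    """Write frames as a zero-padded image sequence; returns the paths."""
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for k, frame in enumerate(frames):
        path = os.path.join(out_dir, f"frame_{k:06d}.{fmt}")
        iio.imwrite(path, frame)
        paths.append(path)
    return paths
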