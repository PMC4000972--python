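"""Synthetic surrogate videos of normal vs abnormal patient movement.

Clinical bedside recordings of epileptic patients are private, so the
pipeline is exercised on surrogate clips that reproduce the motion
statistics that distinguish the two classes.  The camera looks down on the
bed, so the patient — rendered as a bright Gaussian-profile blob over a
darker background — rests near the frame centre, and the two classes differ
only in how the blob moves about that resting position:

* **normal** clips move smoothly: the blob follows a slow elliptical path
  around the resting position at constant speed, with small, capped
  heading-rate jitter (regular, comfortable movement);
* **abnormal** clips follow the same path model but make abrupt
  instantaneous direction reversals (heading jumps of at least 90 degrees)
  at a configured rate, and freeze in place for runs of frames (periods of
  no movement) — convulsive movement that stays about the resting position.

With ``jerk_rate = 0`` and ``freeze_prob = 0`` the abnormal model
degenerates exactly to the normal one (same seed, same trajectory).

Nuisance factors seen in real ward footage — slow illumination drift
(lights), pixel noise, extra independently moving persons (distractors) and
per-patient appearance variation (background level, blob brightness/size) —
are opt-in dials.  Every clip is generated from one seeded generator, and a
per-frame trajectory log (position, heading, jerk/freeze/clamp flags) is
produced alongside so tests can verify the motion statistics directly
against the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .video_io import AnnotationRecord, VideoVolume

__all__ = [
    "SynthConfig",
    "SynthClip",
    "generate_normal_clip",
    "generate_abnormal_clip",
    "generate_cohort",
    "iter_cohort",
    "save_cohort",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults give well-separated low-noise clips.

    ``jerk_rate`` is the expected number of abrupt direction reversals per
    100 frames and ``freeze_prob`` the per-frame probability of entering a
    no-motion run of ``freeze_len_frames``; both act on abnormal clips only.
    ``blob_radius`` is in pixels (the rendered blob has a Gaussian profile
    with sigma = radius / 2), speeds are px/frame, intensities in [0, 1].
    The resting position is drawn near the frame centre (``anchor_jitter``
    fraction of the frame) and the normal-motion ellipse spans
    ``orbit_frac`` of the frame half-extent, jittered per clip.
    """

    frame_size: tuple[int, int] = (128, 160)  # (height, width)
    n_frames: int = 250
    frame_rate: float = 25.0
    blob_radius: float = 8.0
    blob_intensity: float = 0.6
    background_intensity: float = 0.25
    speed: float = 2.5
    heading_sd: float = 0.02       # radians/frame jitter on the heading rate
    heading_cap: float = 0.35      # small-angle cap on per-frame heading change
    jerk_rate: float = 12.0        # reversals per 100 frames (abnormal)
    freeze_prob: float = 0.05      # per-frame entry probability (abnormal)
    freeze_len_frames: int = 25
    anchor_jitter: float = 0.04    # resting-position scatter, fraction of frame
    orbit_frac: tuple[float, float] = (0.56, 0.44)  # ellipse span / frame extent
    jerk_amp_decay: float = 0.75   # orbit-amplitude factor applied per reversal
    min_orbit_px: float = 5.0      # convulsion amplitude floor (pixels)
    illum_drift: float = 0.0       # additive sinusoid amplitude
    noise_sd: float = 0.01
    n_distractors: int = 0

    def __post_init__(self) -> None:
        h, w = self.frame_size
        if h < 1 or w < 1 or self.n_frames < 1:
            raise ValueError("frame size and frame count must be >= 1")
        if not (self.frame_rate > 0):
            raise ValueError("frame_rate must be > 0")
        if not (0 <= self.freeze_prob <= 1):
            raise ValueError(f"freeze_prob must be in [0, 1], got {self.freeze_prob}")
        if self.jerk_rate < 0 or self.noise_sd < 0 or self.illum_drift < 0:
            raise ValueError("rates and amplitudes must be non-negative")
        if self.n_distractors < 0 or self.freeze_len_frames < 1:
            raise ValueError("invalid distractor count or freeze length")
        if 2 * self.blob_radius >= min(h, w):
            raise ValueError(
                f"blob of radius {self.blob_radius} does not fit in a "
                f"{h}x{w} frame"
            )
        for name in ("blob_intensity", "background_intensity"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SynthClip:
    """A generated clip with its annotation and per-frame trajectory log."""

    volume: VideoVolume
    annotation: AnnotationRecord
    trajectory: pd.DataFrame


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


_TRAJ_COLS = ["frame", "x", "y", "heading", "jerk", "frozen", "clamped"]


def _simulate_trajectory(
    config: SynthConfig,
    rng: np.random.Generator,
    abnormal: bool,
    anchor: Optional[tuple[float, float]] = None,
) -> pd.DataFrame:
    """Simulate the blob centre per frame; returns the trajectory log.

    Both classes traverse an elliptical path about the resting position
    (``anchor``).  Abnormal clips additionally reverse their direction of
    travel abruptly (the heading jumps by ~180 degrees) at the configured
    rate — each reversal dissipating part of the excursion amplitude, so the
    movement collapses onto small oscillations about the resting position —
    and enter frozen runs.  Normal clips sweep the full ellipse.  Positions
    are clamped to keep the blob inside the frame (the ``clamped`` flag
    marks those frames).
    """
    h, w = config.frame_size
    margin = config.blob_radius + 1.0
    if anchor is None:
        ax = w / 2 + rng.normal(0.0, config.anchor_jitter * w)
        ay = h / 2 + rng.normal(0.0, config.anchor_jitter * h)
    else:
        ax, ay = anchor
    fx, fy = config.orbit_frac
    rx = 0.5 * fx * w * rng.uniform(0.8, 1.2)
    ry = 0.5 * fy * h * rng.uniform(0.8, 1.2)
    rx = min(rx, max(ax - margin, w - margin - ax))
    ry = min(ry, max(ay - margin, h - margin - ay))
    phi = rng.uniform(0.0, 2 * math.pi)
    direction = float(rng.choice((-1.0, 1.0)))

    jerk_p = min(config.jerk_rate / 100.0, 1.0) if abnormal else 0.0
    freeze_p = config.freeze_prob if abnormal else 0.0
    amp = 1.0  # excursion amplitude factor; decays on convulsive reversals
    amp_floor = min(config.min_orbit_px / max(min(rx, ry), 1e-9), 1.0)

    def pos(p, a):
        return ax + a * rx * math.cos(p), ay + a * ry * math.sin(p)

    x, y = pos(phi, amp)
    heading = math.atan2(ry * math.cos(phi) * direction, -rx * math.sin(phi) * direction)
    rows = []
    freeze_left = 0
    for frame in range(config.n_frames):
        jerk = False
        clamped = False
        frozen = freeze_left > 0
        if not frozen and freeze_p > 0 and rng.random() < freeze_p:
            freeze_left = config.freeze_len_frames
            frozen = True
        if frozen:
            freeze_left -= 1
        else:
            if jerk_p > 0 and rng.random() < jerk_p:
                direction = -direction  # abrupt reversal of travel
                amp = max(amp * config.jerk_amp_decay, amp_floor)
                jerk = True
            # angular rate keeping ~constant tangential speed, capped
            radius = amp * (rx + ry) / 2.0
            dphi = min(config.speed / max(radius, 1e-9), math.pi / 2) \
                if config.speed > 0 else 0.0
            step = dphi
            if config.heading_sd > 0 and dphi > 0:
                step += float(np.clip(rng.normal(0.0, config.heading_sd),
                                      -config.heading_cap / 3, config.heading_cap / 3))
            # heading turns fastest at the minor axis, by the axis ratio;
            # capping the phase step there keeps smooth motion under the cap
            ratio = max(rx, ry) / max(min(rx, ry), 1e-9)
            step = min(step, 0.9 * config.heading_cap / ratio)
            phi += direction * max(step, 0.0)
            nx, ny = pos(phi, amp)
            if not (margin <= nx <= w - margin):
                nx = min(max(nx, margin), w - margin)
                clamped = True
            if not (margin <= ny <= h - margin):
                ny = min(max(ny, margin), h - margin)
                clamped = True
            if (nx, ny) != (x, y):
                heading = math.atan2(ny - y, nx - x)
            x, y = nx, ny
        rows.append((frame, x, y, heading, jerk, frozen, clamped))
    return pd.DataFrame(rows, columns=_TRAJ_COLS)


def _render(config: SynthConfig, rng: np.random.Generator,
            trajectories: list[tuple[pd.DataFrame, float, float]]) -> np.ndarray:
    """Render blob trajectories onto the background; returns (h, w, t) data."""
    h, w = config.frame_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    data = np.empty((h, w, config.n_frames))
    phase = rng.uniform(0, 2 * math.pi)
    for t in range(config.n_frames):
        frame = np.full((h, w), config.background_intensity)
        if config.illum_drift > 0:
            frame += config.illum_drift * math.sin(
                2 * math.pi * t / config.n_frames + phase
            )
        for traj, intensity, radius in trajectories:
            sigma = radius / 2.0
            cx, cy = traj.at[t, "x"], traj.at[t, "y"]
            frame += intensity * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2)
            )
        if config.noise_sd > 0:
            frame += rng.normal(0.0, config.noise_sd, size=(h, w))
        data[:, :, t] = np.clip(frame, 0.0, 1.0)
    return data


def _generate_clip(config: SynthConfig, seed: int, abnormal: bool,
                   patient_id: str = "", clip_id: str = "") -> SynthClip:
    rng = np.random.default_rng(seed)
    traj = _simulate_trajectory(config, rng, abnormal)
    layers = [(traj, config.blob_intensity, config.blob_radius)]
    h, w = config.frame_size
    margin = config.blob_radius + 1.0
    for _ in range(config.n_distractors):
        # an extra person moving smoothly about their own spot
        anchor = (rng.uniform(margin, w - margin), rng.uniform(margin, h - margin))
        d_cfg = replace(config, orbit_frac=(0.2, 0.2))
        d_traj = _simulate_trajectory(d_cfg, rng, abnormal=False, anchor=anchor)
        layers.append((d_traj, 0.5 * config.blob_intensity, 0.8 * config.blob_radius))
    data = _render(config, rng, layers)
    label = "abnormal" if abnormal else "normal"
    volume = VideoVolume(data, config.frame_rate, patient_id, clip_id or f"synth_{seed}")
    return SynthClip(
        volume=volume,
        annotation=AnnotationRecord(clip=volume.clip_id, patient_id=patient_id,
                                    label=label),
        trajectory=traj,
    )


def generate_normal_clip(config: SynthConfig, seed: int,
                         with_log: bool = False):
    """Generate a smooth-motion (normal-status) clip; deterministic in seed.

    With ``with_log`` the full :class:`SynthClip` (including the trajectory
    log) is returned instead of just the volume.
    """
    clip = _generate_clip(config, seed, abnormal=False)
    return clip if with_log else clip.volume


def generate_abnormal_clip(config: SynthConfig, seed: int,
                           with_log: bool = False):
    """Generate an abnormal-status clip: abrupt reversals plus frozen runs.

    With ``jerk_rate = 0`` and ``freeze_prob = 0`` the motion model
    degenerates exactly to the normal one for the same seed.
    """
    clip = _generate_clip(config, seed, abnormal=True)
    return clip if with_log else clip.volume


def iter_cohort(
    n_patients: int = 9,
    clips_per_patient: int = 6,
    abnormal_fraction: float = 0.5,
    config: SynthConfig = SynthConfig(),
    seed: int = 0,
):
    """Yield the clips of :func:`generate_cohort` one at a time.

    Identical seeding and output; lets callers process clip volumes
    incrementally instead of holding the whole cohort in memory.
    """
    if n_patients < 1 or clips_per_patient < 2:
        raise ValueError("need n_patients >= 1 and clips_per_patient >= 2")
    if not (0.0 <= abnormal_fraction <= 1.0):
        raise ValueError(f"abnormal_fraction must be in [0, 1], got {abnormal_fraction}")

    master = np.random.default_rng(seed)
    n_abnormal = int(round(abnormal_fraction * clips_per_patient))
    for p in range(n_patients):
        pid = f"patient{p:02d}"
        patient_cfg = replace(
            config,
            background_intensity=float(np.clip(
                config.background_intensity * master.uniform(0.7, 1.3), 0.0, 0.6)),
            blob_intensity=float(np.clip(
                config.blob_intensity * master.uniform(0.85, 1.15), 0.1, 1.0)),
            blob_radius=float(config.blob_radius * master.uniform(0.85, 1.15)),
        )
        flags = np.zeros(clips_per_patient, dtype=bool)
        flags[master.permutation(clips_per_patient)[:n_abnormal]] = True
        for k in range(clips_per_patient):
            clip_seed = int(master.integers(0, 2**31 - 1))
            yield _generate_clip(
                patient_cfg, clip_seed, abnormal=bool(flags[k]),
                patient_id=pid, clip_id=f"{pid}_clip{k:02d}",
            )


def generate_cohort(
    n_patients: int = 9,
    clips_per_patient: int = 6,
    abnormal_fraction: float = 0.5,
    config: SynthConfig = SynthConfig(),
    seed: int = 0,
) -> list[SynthClip]:
    """Generate a labeled multi-patient cohort of surrogate clips.

    Per-patient appearance (background level, blob brightness and size) is
    drawn once per patient, emulating different clothing and lighting; each
    patient receives ``round(abnormal_fraction * clips_per_patient)``
    abnormal clips at seeded random positions.  Deterministic in ``seed``.
    """
    return list(iter_cohort(n_patients, clips_per_patient, abnormal_fraction,
                            config, seed))


def save_cohort(clips: list[SynthClip], outdir) -> None:
    """Write a cohort to disk: PNG frame directories + annotation/trajectory CSVs."""
    import imageio.v2 as imageio

    from .video_io import write_annotations

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for clip in clips:
        clip_dir = outdir / clip.volume.clip_id
        clip_dir.mkdir(exist_ok=True)
        data8 = np.round(clip.volume.data * 255).astype(np.uint8)
        for t in range(clip.volume.n_frames):
            imageio.imwrite(clip_dir / f"frame{t:05d}.png", data8[:, :, t])
        clip.trajectory.to_csv(clip_dir / "trajectory.csv", index=False)
    annotations = [
        replace(c.annotation, clip=str(c.volume.clip_id)) for c in clips
    ]
    write_annotations(annotations, outdir / "annotations.csv")
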