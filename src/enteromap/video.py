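"""Synthetic ex vivo gut-motility videos with analytic ground truth.

An intestinal segment pinned in an organ bath is filmed from above as a
dark tube on a light background.  Its local diameter D(x, t) is modelled
analytically as a baseline minus superposed travelling Gaussian
indentations:

* myogenic ripples — shallow contractions launched at regular intervals
  from random origins, propagating in both directions; they persist
  under neuronal blockade;
* neurogenic waves — deeper contractions, either bidirectional bursts
  separated by quiescent periods (immature circuit) or exclusively
  proximal-to-distal waves (mature circuit).

A ``ttx`` flag emulates tetrodotoxin: neurogenic waves (and quiescent
gating) are removed and the ripple rate optionally rises.  Frames are
rendered from D(x, t) at 3.75 frames/s by default; the ground truth
stores the analytic field and every wave event, so spatiotemporal-map
extraction and event detection can be verified exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "WaveEvent",
    "MotilityTruth",
    "OcclusionError",
    "generate_motility_video",
    "scenario",
    "DEFAULT_FRAME_RATE",
]

DEFAULT_FRAME_RATE = 3.75      # frames/s
DEFAULT_BASELINE = 2000.0      # um tube diameter
DEFAULT_PIXEL_SIZE = 25.0      # um/px for rendered frames


class OcclusionError(ValueError):
    """A wave amplitude at or above the baseline would occlude the tube."""


@dataclass(frozen=True)
class WaveEvent:
    """One travelling contraction in the analytic diameter field."""

    onset_s: float
    origin_um: float
    direction: str               # 'distal', 'proximal' or 'bidirectional'
    velocity_um_s: float
    amplitude_um: float
    sigma_um: float = 400.0      # spatial half-width of the indentation
    kind: str = "ripple"         # 'ripple' or 'neurogenic'


@dataclass
class MotilityTruth:
    """Ground truth for a rendered motility video."""

    diameter_um: np.ndarray      # (n_frames, n_columns) analytic field
    events: list
    baseline_um: float
    ripple_rate_per_min: float
    ttx: bool
    frame_rate: float
    pixel_size: float
    length_um: float
    quiescent_windows: list = field(default_factory=list)


def _wave_field(
    D: np.ndarray,
    xs: np.ndarray,
    ts: np.ndarray,
    ev: WaveEvent,
    length_um: float,
) -> None:
    """Subtract one wave's travelling indentation from D in place."""
    branches = {
        "distal": (ev.velocity_um_s,),
        "proximal": (-ev.velocity_um_s,),
        "bidirectional": (ev.velocity_um_s, -ev.velocity_um_s),
    }[ev.direction]
    for v in branches:
        # Active until the indentation centre leaves the tube by 4 sigma.
        if v > 0:
            t_end = ev.onset_s + (length_um + 4 * ev.sigma_um - ev.origin_um) / v
        else:
            t_end = ev.onset_s + (ev.origin_um + 4 * ev.sigma_um) / (-v)
        sel = (ts >= ev.onset_s) & (ts <= t_end)
        if not sel.any():
            continue
        tt = ts[sel]
        centre = ev.origin_um + v * (tt - ev.onset_s)
        arg = (xs[None, :] - centre[:, None]) / ev.sigma_um
        D[sel] -= ev.amplitude_um * np.exp(-0.5 * arg * arg)


def _regular_onsets(rate_per_min: float, duration_s: float,
                    rng: np.random.Generator, jitter_s: float = 0.5,
                    windows: Optional[Sequence] = None) -> np.ndarray:
    """Near-regular event onsets at a target rate, optionally gated.

    ``windows`` restricts onsets to active intervals [(t0, t1), ...].
    """
    if rate_per_min <= 0:
        return np.empty(0)
    period = 60.0 / rate_per_min
    base = np.arange(period / 2, duration_s, period)
    onsets = base + rng.normal(0.0, jitter_s, size=len(base))
    onsets = onsets[(onsets >= 0) & (onsets < duration_s)]
    if windows is not None:
        keep = np.zeros(len(onsets), dtype=bool)
        for (a, b) in windows:
            keep |= (onsets >= a) & (onsets < b)
        onsets = onsets[keep]
    return np.sort(onsets)


def generate_motility_video(
    length_mm: float = 15.0,
    duration_s: float = 600.0,
    frame_rate: float = DEFAULT_FRAME_RATE,
    baseline_diameter_um: float = DEFAULT_BASELINE,
    ripple_rate_per_min: float = 6.0,
    ripple_amplitude_um: float = 300.0,
    ripple_velocity_um_s: float = 750.0,
    neurogenic: Optional[dict] = None,
    ttx: bool = False,
    ttx_ripple_rate_per_min: Optional[float] = None,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    noise_sd: float = 3.0,
    render: bool = True,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Optional[np.ndarray], MotilityTruth]:
    """Simulate and render a motility recording.

    ``neurogenic`` configures neuronally mediated activity:

    ``{"mode": "bidirectional_bursts", "rate_per_min": r,
       "amplitude_um": a, "velocity_um_s": v,
       "active_s": 35, "quiet_s": 25}``
        bursts of bidirectional contractions separated by quiescent
        periods (gates the *ripples too*: the whole preparation is
        quiet between bursts);
    ``{"mode": "distal_waves", "rate_per_min": r, ...}``
        exclusively proximal-to-distal waves.

    ``ttx=True`` removes all neurogenic structure (waves and quiescent
    gating) and, when ``ttx_ripple_rate_per_min`` is given, raises the
    ripple rate — the tetrodotoxin phenotype.

    Returns ``(frames, truth)``; frames are uint8 (t, rows, cols), dark
    tube on light background, or None when ``render=False`` (analysis
    can then run on the analytic field directly).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    length_um = length_mm * 1000.0
    n_frames = int(round(duration_s * frame_rate))
    n_cols = int(round(length_um / pixel_size))
    ts = np.arange(n_frames) / frame_rate
    xs = (np.arange(n_cols) + 0.5) * pixel_size

    events: list[WaveEvent] = []
    quiescent_windows: list[tuple] = []
    ripple_windows = None

    neuro = None if ttx else neurogenic
    if neuro is not None:
        mode = neuro.get("mode", "distal_waves")
        amp = neuro.get("amplitude_um", 800.0)
        vel = neuro.get("velocity_um_s", 2000.0)
        rate = neuro.get("rate_per_min", 4.0)
        sigma = neuro.get("sigma_um", 600.0)
        if mode == "bidirectional_bursts":
            active = neuro.get("active_s", 35.0)
            quiet = neuro.get("quiet_s", 25.0)
            t = 0.0
            windows = []
            while t < duration_s:
                windows.append((t, min(t + active, duration_s)))
                if t + active < duration_s:
                    quiescent_windows.append(
                        (t + active, min(t + active + quiet, duration_s)))
                t += active + quiet
            ripple_windows = windows
            for onset in _regular_onsets(rate, duration_s, rng,
                                         windows=windows):
                events.append(WaveEvent(
                    onset_s=float(onset),
                    origin_um=float(rng.uniform(0.2, 0.8) * length_um),
                    direction="bidirectional", velocity_um_s=vel,
                    amplitude_um=amp, sigma_um=sigma, kind="neurogenic"))
        elif mode == "distal_waves":
            for onset in _regular_onsets(rate, duration_s, rng):
                events.append(WaveEvent(
                    onset_s=float(onset), origin_um=0.0,
                    direction="distal", velocity_um_s=vel,
                    amplitude_um=amp, sigma_um=sigma, kind="neurogenic"))
        else:
            raise ValueError(f"unknown neurogenic mode {mode!r}")

    rate = ripple_rate_per_min
    if ttx and ttx_ripple_rate_per_min is not None:
        rate = ttx_ripple_rate_per_min
    for onset in _regular_onsets(rate, duration_s, rng,
                                 windows=ripple_windows):
        events.append(WaveEvent(
            onset_s=float(onset),
            origin_um=float(rng.uniform(0.3, 0.7) * length_um),
            direction="bidirectional", velocity_um_s=ripple_velocity_um_s,
            amplitude_um=ripple_amplitude_um, kind="ripple"))

    events.sort(key=lambda e: e.onset_s)
    for ev in events:
        if ev.amplitude_um >= baseline_diameter_um:
            raise OcclusionError(
                f"wave amplitude {ev.amplitude_um} um >= baseline "
                f"{baseline_diameter_um} um")

    D = np.full((n_frames, n_cols), baseline_diameter_um, dtype=float)
    for ev in events:
        _wave_field(D, xs, ts, ev, length_um)
    # Superposed waves may transiently dip below zero; physical floor.
    np.clip(D, 0.0, None, out=D)

    truth = MotilityTruth(
        diameter_um=D.astype(np.float32),
        events=events,
        baseline_um=baseline_diameter_um,
        ripple_rate_per_min=rate,
        ttx=ttx,
        frame_rate=frame_rate,
        pixel_size=pixel_size,
        length_um=length_um,
        quiescent_windows=quiescent_windows,
    )
    if not render:
        return None, truth

    frames = render_frames(D, baseline_diameter_um, pixel_size,
                           noise_sd=noise_sd, rng=rng)
    return frames, truth


def render_frames(
    D: np.ndarray,
    baseline_um: float,
    pixel_size: float,
    bg: float = 200.0,
    fg: float = 50.0,
    noise_sd: float = 3.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render a diameter field as frames: dark tube on light background."""
    if rng is None:
        rng = np.random.default_rng()
    n_frames, n_cols = D.shape
    n_rows = int(np.ceil(1.3 * baseline_um / pixel_size))
    centre = (n_rows - 1) / 2.0
    rows = np.arange(n_rows)[:, None]

    frames = np.empty((n_frames, n_rows, n_cols), dtype=np.uint8)
    for t in range(n_frames):
        hw = D[t] / (2.0 * pixel_size)          # half-width in px
        cover = np.clip(hw[None, :] - np.abs(rows - centre) + 0.5, 0.0, 1.0)
        img = bg - (bg - fg) * cover
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)
    return frames


def scenario(stage: str, ttx: bool = False, duration_s: float = 600.0,
             seed: Optional[int] = None, render: bool = True,
             **kwargs) -> tuple[Optional[np.ndarray], MotilityTruth]:
    """Staged motility phenotypes of the maturing gut.

    ``"14pcw"``
        continuous bidirectional myogenic ripples only (TTX changes
        little beyond rate in some preparations);
    ``"18pcw"``
        bidirectional neurogenic bursts with intervening quiescence;
        TTX ablates the quiescent periods, leaving constant ripples;
    ``"21pcw"``
        exclusively distally propagating contractions with few ripples;
        TTX removes them and raises the myogenic ripple rate.
    """
    presets = {
        "14pcw": dict(ripple_rate_per_min=6.0, neurogenic=None,
                      ttx_ripple_rate_per_min=6.0),
        "18pcw": dict(
            ripple_rate_per_min=6.0,
            neurogenic=dict(mode="bidirectional_bursts", rate_per_min=3.0,
                            amplitude_um=800.0, velocity_um_s=1500.0,
                            active_s=35.0, quiet_s=25.0),
            ttx_ripple_rate_per_min=6.0),
        "21pcw": dict(
            ripple_rate_per_min=1.0,
            neurogenic=dict(mode="distal_waves", rate_per_min=1.5,
                            amplitude_um=800.0, velocity_um_s=2000.0),
            ttx_ripple_rate_per_min=6.0),
    }
    if stage not in presets:
        raise ValueError(f"unknown stage {stage!r}")
    params = dict(presets[stage])
    params.update(kwargs)
    return generate_motility_video(duration_s=duration_s, ttx=ttx,
                                   seed=seed, render=render, **params)
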