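"""Spatiotemporal maps and contraction-event analysis of gut motility.

A spatiotemporal map (STM, a kymograph) holds the local tube diameter
for every longitudinal position and video frame.  Contractions appear
as dark diagonal bands: their slope is the propagation velocity, its
sign the direction (distal = away from the oral end).  Events are
detected as spatiotemporally connected regions of the "contracted"
mask (diameter below the per-column median by a depth threshold) and
classified distal / proximal / bidirectional from the motion of the
region's edges.  Summaries (ripple frequency, quiescent-time fraction,
direction asymmetry, stage label) support baseline-vs-TTX comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks

__all__ = [
    "STM",
    "ContractionEvent",
    "MotilitySummary",
    "ConditionComparison",
    "STMQualityError",
    "compute_stm",
    "detect_contractions",
    "ripple_frequency",
    "classify_pattern",
    "compare_conditions",
]

DEFAULT_DEPTH_THRESHOLD = 100.0   # um below per-column median
DEFAULT_PROMINENCE = 100.0        # um, peak prominence for ripple counting


class STMQualityError(RuntimeError):
    """The video could not be reduced to a usable diameter map."""


@dataclass
class STM:
    """Diameter matrix: rows = time frames, columns = position bins."""

    diameter_um: np.ndarray
    frame_rate: float = 3.75
    bin_um: float = 25.0
    condition: str = "baseline"
    valid: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.diameter_um = np.asarray(self.diameter_um, dtype=float)
        if (self.diameter_um < 0).any():
            raise ValueError("diameters must be >= 0")
        if self.valid is None:
            self.valid = np.ones(self.diameter_um.shape[1], dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.diameter_um.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def length_um(self) -> float:
        return self.diameter_um.shape[1] * self.bin_um

    def reversed_time(self) -> "STM":
        return STM(self.diameter_um[::-1].copy(), self.frame_rate,
                   self.bin_um, self.condition, self.valid.copy(),
                   dict(self.meta))


def compute_stm(
    frames: np.ndarray,
    pixel_size: float,
    frame_rate: float = 3.75,
    threshold: Optional[float] = None,
    condition: str = "baseline",
    max_invalid_frac: float = 0.2,
    chunk: int = 256,
) -> STM:
    """Extract the diameter map from video frames.

    Frames show a dark tube on a light background; per frame and per
    column the diameter is the foreground extent across the tube
    (last minus first dark row, robust to interior holes).  Columns
    with no foreground anywhere are flagged invalid; more than
    ``max_invalid_frac`` invalid columns raises a quality error naming
    them.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be (time, rows, cols)")
    n_t, n_rows, n_cols = frames.shape
    if threshold is None:
        sample = frames[:: max(1, n_t // 16)]
        if np.ptp(sample) == 0:
            raise STMQualityError("frames have no contrast (empty video?)")
        # Midpoint between the dark (tube) and light (background)
        # levels, from robust percentiles.  This cuts the tube edge at
        # half coverage, so the extent is exact to one pixel; a global
        # Otsu would drift with the tube/background area ratio.
        lo, hi = np.percentile(sample, [1.0, 99.0])
        if hi - lo < 10:
            raise STMQualityError("frames have no contrast (empty video?)")
        threshold = float((lo + hi) / 2.0)

    diam = np.zeros((n_t, n_cols), dtype=float)
    any_fg_col = np.zeros(n_cols, dtype=bool)
    for t0 in range(0, n_t, chunk):
        blk = frames[t0:t0 + chunk] < threshold
        has = blk.any(axis=1)                       # (t, col)
        top = blk.argmax(axis=1)
        bottom = n_rows - 1 - blk[:, ::-1, :].argmax(axis=1)
        d = (bottom - top + 1).astype(float)
        d[~has] = 0.0
        diam[t0:t0 + chunk] = d * pixel_size
        any_fg_col |= has.any(axis=0)

    invalid = np.flatnonzero(~any_fg_col)
    if len(invalid) > max_invalid_frac * n_cols:
        raise STMQualityError(
            f"{len(invalid)}/{n_cols} columns contain no tube foreground "
            f"(first few: {invalid[:10].tolist()})")
    return STM(diam, frame_rate=frame_rate, bin_um=pixel_size,
               condition=condition, valid=any_fg_col,
               meta={"threshold": threshold})


@dataclass
class ContractionEvent:
    """A detected contraction wave."""

    onset_s: float
    origin_um: float
    direction: str                 # 'distal', 'proximal', 'bidirectional'
    velocity_um_s: float           # positive magnitude (mean over branches)
    amplitude_um: float
    duration_s: float
    branch_velocities: tuple = ()  # per-branch signed velocities (um/s)


def _contracted_mask(stm: STM, depth_threshold_um: float) -> np.ndarray:
    base = np.median(stm.diameter_um, axis=0)
    mask = (base[None, :] - stm.diameter_um) > depth_threshold_um
    mask[:, ~stm.valid] = False
    return mask


def _first_run(flags: np.ndarray, min_len: int = 3):
    """Slice of the first run of >= min_len consecutive True values."""
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start >= min_len:
                return slice(start, i)
            start = None
    if start is not None and len(flags) - start >= min_len:
        return slice(start, len(flags))
    return None


def _fit_slope(t_s: np.ndarray, pos_um: np.ndarray) -> float:
    if len(t_s) < 2 or np.ptp(t_s) == 0:
        return 0.0
    return float(np.polyfit(t_s, pos_um, 1)[0])


def detect_contractions(
    stm: STM,
    depth_threshold_um: float = DEFAULT_DEPTH_THRESHOLD,
    min_duration_s: float = 1.0,
    min_velocity_um_s: float = 50.0,
    merge_bins: int = 2,
    merge_frames: int = 2,
) -> list:
    """Detect and classify contraction events on an STM.

    The contracted mask (diameter below the per-column median minus the
    depth threshold) is split into 8-connected components in the
    (time, position) plane.  For each component the left and right
    edges of the contracted span are tracked per frame: edges moving
    apart in opposite directions mark one bidirectional event (two
    branches from a common origin); otherwise the direction follows the
    least-squares line through the per-frame position of minimum
    diameter, whose slope is the velocity.
    """
    mask = _contracted_mask(stm, depth_threshold_um)
    if not mask.any():
        return []
    labels, n_comp = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    base = np.median(stm.diameter_um, axis=0)
    dt = 1.0 / stm.frame_rate
    events: list[ContractionEvent] = []

    # ndi.find_objects slice k corresponds to label k + 1.
    for k, sl in enumerate(ndi.find_objects(labels, n_comp)):
        if sl is None:
            continue
        lab = k + 1
        sub = labels[sl] == lab
        t0 = sl[0].start
        n_t = sub.shape[0]
        duration = n_t * dt
        if duration < min_duration_s:
            continue
        ts = (t0 + np.arange(n_t)) * dt
        cols = np.arange(sl[1].start, sl[1].stop)
        left = np.empty(n_t)
        right = np.empty(n_t)
        argmin_pos = np.empty(n_t)
        ok = np.zeros(n_t, dtype=bool)
        d_sub = stm.diameter_um[sl]
        for i in range(n_t):
            row = sub[i]
            if not row.any():
                continue
            ok[i] = True
            idx = np.flatnonzero(row)
            left[i] = (cols[idx[0]] + 0.5) * stm.bin_um
            right[i] = (cols[idx[-1]] + 0.5) * stm.bin_um
            dvals = np.where(row, d_sub[i], np.inf)
            argmin_pos[i] = (cols[np.argmin(dvals)] + 0.5) * stm.bin_um
        ts, left, right, argmin_pos = ts[ok], left[ok], right[ok], argmin_pos[ok]
        if len(ts) < 2:
            continue

        # Once a branch runs off a tube end the clamped edge stops
        # tracking the wave (and, for bidirectional events, the edges
        # of the surviving branch move together afterwards).  Fit edge
        # slopes on the first contiguous run of frames where both edges
        # are interior; fall back to all frames if no such run exists.
        lo = 0.5 * stm.bin_um
        hi = stm.length_um - 1.5 * stm.bin_um
        interior = (left > lo) & (right < hi)
        run = _first_run(interior, min_len=3)
        if run is not None:
            slope_l = _fit_slope(ts[run], left[run])
            slope_r = _fit_slope(ts[run], right[run])
        else:
            slope_l = _fit_slope(ts, left)
            slope_r = _fit_slope(ts, right)
        amplitude = float((base[None, sl[1]] - d_sub)[sub].max())

        if slope_l < -min_velocity_um_s and slope_r > min_velocity_um_s:
            direction = "bidirectional"
            branch = (slope_l, slope_r)
            velocity = float((abs(slope_l) + abs(slope_r)) / 2.0)
            origin = float((left[0] + right[0]) / 2.0)
        else:
            # Trim entry/exit frames where the wave is clipped by the
            # tube ends before fitting the minimum-diameter track.
            m = len(ts)
            trim = m // 10
            s = slice(trim, m - trim) if m - 2 * trim >= 4 else slice(None)
            v = _fit_slope(ts[s], argmin_pos[s])
            direction = "distal" if v >= 0 else "proximal"
            branch = (v,)
            velocity = float(abs(v))
            origin = float(argmin_pos[0])

        events.append(ContractionEvent(
            onset_s=float(ts[0]), origin_um=origin, direction=direction,
            velocity_um_s=velocity, amplitude_um=amplitude,
            duration_s=float(ts[-1] - ts[0] + dt),
            branch_velocities=branch))

    # Merge duplicates whose origins nearly coincide in space and time.
    events.sort(key=lambda e: (e.onset_s, e.origin_um))
    merged: list[ContractionEvent] = []
    for ev in events:
        if merged:
            prev = merged[-1]
            if (abs(ev.onset_s - prev.onset_s) <= merge_frames * dt
                    and abs(ev.origin_um - prev.origin_um)
                    <= merge_bins * stm.bin_um):
                if ev.amplitude_um > prev.amplitude_um:
                    merged[-1] = ev
                continue
        merged.append(ev)
    return merged


def ripple_frequency(
    stm: STM,
    window_s: float = 60.0,
    positions: int = 5,
    prominence_um: float = DEFAULT_PROMINENCE,
) -> float:
    """Contraction minima per minute, averaged over windows and positions.

    Diameter traces at ``positions`` evenly spaced interior columns are
    scanned for local minima with the given prominence; counts are
    taken per full ``window_s`` window and averaged, in events/min.
    """
    if stm.duration_s < window_s:
        raise ValueError(
            f"recording of {stm.duration_s:.1f}s shorter than the "
            f"{window_s:.0f}s counting window")
    n_t, n_cols = stm.diameter_um.shape
    fracs = np.linspace(0.25, 0.75, positions)
    cols = np.unique((fracs * (n_cols - 1)).astype(int))
    cols = [c for c in cols if stm.valid[c]]
    if not cols:
        raise STMQualityError("no valid columns to sample")
    win_frames = int(round(window_s * stm.frame_rate))
    n_win = n_t // win_frames
    counts = []
    for c in cols:
        trace = stm.diameter_um[:, c]
        peaks, _ = find_peaks(-trace, prominence=prominence_um)
        for w in range(n_win):
            lo, hi = w * win_frames, (w + 1) * win_frames
            counts.append(np.count_nonzero((peaks >= lo) & (peaks < hi)))
    return float(np.mean(counts) * (60.0 / window_s))


@dataclass
class MotilitySummary:
    """Stage-level description of one recording."""

    ripple_frequency_per_min: float
    quiescent_fraction: float
    asymmetry: float               # (distal - proximal)/(distal + proximal)
    label: str                     # ripples_only / intermittent_neurogenic /
                                   # distal_propagating
    n_distal: int = 0
    n_proximal: int = 0
    n_bidirectional: int = 0
    low_activity: bool = False
    condition: str = "baseline"


def classify_pattern(
    events: list,
    stm: STM,
    asymmetry_threshold: float = 0.8,
    quiescence_threshold: float = 0.2,
    min_events: int = 3,
    depth_threshold_um: float = DEFAULT_DEPTH_THRESHOLD,
    prominence_um: float = DEFAULT_PROMINENCE,
) -> MotilitySummary:
    """Label a recording by its motility pattern.

    distal_propagating: directional asymmetry above the threshold with
    at least ``min_events`` directional events (the mature, neurogenic
    phenotype).  intermittent_neurogenic: quiescent-time fraction above
    the threshold with bidirectional events present.  Otherwise
    ripples_only (with a low-activity flag when no events at all).
    """
    nd = sum(e.direction == "distal" for e in events)
    np_ = sum(e.direction == "proximal" for e in events)
    nb = sum(e.direction == "bidirectional" for e in events)
    asym = (nd - np_) / (nd + np_) if (nd + np_) else 0.0

    mask = _contracted_mask(stm, depth_threshold_um)
    quiescent = 1.0 - float(mask.any(axis=1).mean())

    freq = (ripple_frequency(stm, prominence_um=prominence_um)
            if stm.duration_s >= 60.0 else 0.0)

    if nd + np_ >= min_events and asym > asymmetry_threshold:
        label = "distal_propagating"
    elif quiescent > quiescence_threshold and nb > 0:
        label = "intermittent_neurogenic"
    else:
        label = "ripples_only"
    return MotilitySummary(
        ripple_frequency_per_min=freq,
        quiescent_fraction=quiescent,
        asymmetry=float(asym),
        label=label,
        n_distal=nd, n_proximal=np_, n_bidirectional=nb,
        low_activity=not events,
        condition=stm.condition,
    )


@dataclass
class ConditionComparison:
    """Paired baseline-vs-treated motility summary."""

    baseline: MotilitySummary
    treated: MotilitySummary
    delta_ripple_frequency: float
    delta_quiescent_fraction: float
    label_transition: tuple


def compare_conditions(baseline: STM, treated: STM,
                       **detect_kwargs) -> ConditionComparison:
    """Compare two recordings of the same segment (e.g. baseline vs TTX)."""
    if baseline.bin_um != treated.bin_um or \
            baseline.frame_rate != treated.frame_rate:
        raise ValueError("baseline and treated STMs must share calibration")
    ev_b = detect_contractions(baseline, **detect_kwargs)
    ev_t = detect_contractions(treated, **detect_kwargs)
    s_b = classify_pattern(ev_b, baseline)
    s_t = classify_pattern(ev_t, treated)
    return ConditionComparison(
        baseline=s_b, treated=s_t,
        delta_ripple_frequency=s_t.ripple_frequency_per_min
        - s_b.ripple_frequency_per_min,
        delta_quiescent_fraction=s_t.quiescent_fraction
        - s_b.quiescent_fraction,
        label_transition=(s_b.label, s_t.label),
    )
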