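"""Synthetic myenteric-plexus point patterns with known ground truth.

Enteric neuron somata in wholemount preparations form, depending on
developmental stage, a near-random array, circumferentially oriented
stripes, or stripes plus "bridging" neurons lying between them at a
different depth in the plexus.  This module generates seeded point
patterns for all three regimes inside a rectangular observation window,
with a hard-core exclusion distance (somata cannot overlap) and full
ground truth for downstream round-trip tests.

Axis convention: x is circumferential, y is longitudinal (oral at y=0).
The window is half-open, [0, W) x [0, H), in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PointPattern",
    "StripeParams",
    "PatternTruth",
    "PackingError",
    "generate_point_pattern",
    "min_pairwise_distance",
]

#: Hard-core exclusion distance in um: somata do not overlap in space.
DEFAULT_D_MIN = 5.0

#: Rejection-sampling cap per point before declaring the packing infeasible.
MAX_ATTEMPTS_PER_POINT = 10_000


class PackingError(RuntimeError):
    """Raised when a hard-core pattern cannot be packed into the window."""


@dataclass(frozen=True)
class StripeParams:
    """Geometry of circumferentially oriented stripe bands.

    Stripes run along the circumferential (x) axis and repeat with
    ``period`` along the longitudinal (y) axis.  A point is "inside" a
    stripe when its longitudinal coordinate falls within a band of
    ``width`` around a band centre.  ``p_in`` is the probability that a
    stripe-regime point is placed inside a band.  ``orientation`` rotates
    the band axis (degrees, 0 = circumferential) for robustness tests.
    """

    period: float = 150.0
    width: float = 40.0
    p_in: float = 0.9
    orientation: float = 0.0
    #: Fraction of points that are "bridging" neurons in grid mode.
    bridging_fraction: float = 0.25
    #: Circumferential spacing/width of the bridge columns in grid mode
    #: (bridging neurons link adjacent stripes at regular circumferential
    #: positions, giving the stripes an overlying grid-like structure).
    bridge_period: float = 150.0
    bridge_width: float = 40.0
    #: Depth (um) assigned to stripe neurons (nearer the circular muscle).
    stripe_depth: float = 0.0
    #: Depth (um) assigned to bridging neurons (nearer the longitudinal muscle).
    bridging_depth: float = 12.0


@dataclass
class PatternTruth:
    """Ground truth for a generated pattern (the acceptance oracle)."""

    mode: str
    seed: Optional[int]
    d_min: float
    stripe_params: Optional[StripeParams] = None
    #: Boolean mask, True where the point lies inside a stripe band.
    in_stripe: Optional[np.ndarray] = None
    #: Boolean mask, True for bridging points (grid mode only).
    is_bridging: Optional[np.ndarray] = None
    #: Per-point subtype membership probabilities, name -> float.
    subtype_probs: dict = field(default_factory=dict)
    #: Per-point subtype draws, name -> bool array.
    subtype_draws: dict = field(default_factory=dict)


@dataclass
class PointPattern:
    """Neuron soma coordinates (um) in a rectangular observation window.

    ``points`` is an (n, 2) float array of (x, y); ``window`` is (W, H).
    ``labels`` maps subtype names to boolean per-point arrays; ``depth``
    is an optional per-point z position in um.
    """

    points: np.ndarray
    window: tuple[float, float]
    labels: dict = field(default_factory=dict)
    depth: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        w, h = self.window
        if len(self.points):
            x, y = self.points[:, 0], self.points[:, 1]
            if (x < 0).any() or (x >= w).any() or (y < 0).any() or (y >= h).any():
                raise ValueError("points must lie inside the half-open window")
        for name, lab in self.labels.items():
            if len(np.asarray(lab)) != len(self.points):
                raise ValueError(f"label {name!r} length != point count")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=float)
            if len(self.depth) != len(self.points):
                raise ValueError("depth length != point count")

    @property
    def n(self) -> int:
        return len(self.points)


def min_pairwise_distance(points: np.ndarray) -> float:
    """Exact minimum pairwise distance (O(n log n) via KD-tree)."""
    from scipy.spatial import cKDTree

    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return np.inf
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return float(d[:, 1].min())


def _band_distance(y: np.ndarray, period: float, width: float) -> np.ndarray:
    """Distance of longitudinal coordinate(s) from the nearest band centre."""
    centres = period / 2.0
    return np.abs((y - centres + period / 2.0) % period - period / 2.0)


def _in_band(x: np.ndarray, y: np.ndarray, sp: StripeParams) -> np.ndarray:
    """Stripe-band membership, honouring the orientation parameter."""
    if sp.orientation:
        th = np.deg2rad(sp.orientation)
        # Rotate so bands are again periodic along the rotated y axis.
        y = -np.sin(th) * x + np.cos(th) * y
    return _band_distance(np.asarray(y), sp.period, sp.width) <= sp.width / 2.0


def _check_feasible(n: int, window: tuple[float, float], d_min: float) -> None:
    w, h = window
    if n < 0:
        raise ValueError("n must be >= 0")
    if d_min < 0:
        raise ValueError("d_min must be >= 0")
    if n * np.pi * (d_min / 2.0) ** 2 >= 0.5 * w * h:
        raise PackingError(
            f"cannot pack {n} points with hard core {d_min} um into "
            f"{w} x {h} um (packing fraction >= 0.5)"
        )


def _dart_throw(
    n: int,
    window: tuple[float, float],
    d_min: float,
    rng: np.random.Generator,
    proposal=None,
) -> np.ndarray:
    """Sequential dart-throwing with rejection under a hard core.

    ``proposal`` draws one candidate (x, y); defaults to uniform on the
    window.  Raises :class:`PackingError` after a bounded number of
    rejections per point rather than silently relaxing d_min.
    """
    w, h = window
    if proposal is None:
        def proposal(r):
            return r.uniform(0.0, w), r.uniform(0.0, h)

    accepted = np.empty((n, 2), dtype=float)
    d2 = d_min * d_min
    for i in range(n):
        for _ in range(MAX_ATTEMPTS_PER_POINT):
            x, y = proposal(rng)
            if i and d_min > 0:
                dx = accepted[:i, 0] - x
                dy = accepted[:i, 1] - y
                if (dx * dx + dy * dy).min() < d2:
                    continue
            accepted[i] = (x, y)
            break
        else:
            raise PackingError(
                f"failed to place point {i + 1}/{n} after "
                f"{MAX_ATTEMPTS_PER_POINT} attempts (d_min={d_min} um)"
            )
    return accepted


def generate_point_pattern(
    mode: str = "csr",
    n: int = 300,
    window: tuple[float, float] = (800.0, 800.0),
    d_min: float = DEFAULT_D_MIN,
    stripe_params: Optional[StripeParams] = None,
    subtype_probs: Optional[dict] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PointPattern, PatternTruth]:
    """Generate a seeded synthetic soma pattern with ground truth.

    Modes
    -----
    ``csr``
        Uniform (complete spatial randomness) with hard-core ``d_min``.
    ``striped``
        Points confined to circumferential bands with probability
        ``stripe_params.p_in``; hard core preserved.
    ``grid``
        Striped, plus a ``bridging_fraction`` of points placed between
        the bands and assigned a deeper z position (nearer the
        longitudinal muscle), stripe points the shallower one.

    ``subtype_probs`` maps marker names (e.g. ``"CalR"``) to membership
    probabilities; independent Bernoulli draws are recorded per point in
    the pattern's labels and in the ground truth.

    Returns the pattern and a :class:`PatternTruth` recording every draw.
    """
    if mode not in ("csr", "striped", "grid"):
        raise ValueError(f"unknown mode {mode!r}; expected csr, striped or grid")
    _check_feasible(n, window, d_min)
    if rng is None:
        rng = np.random.default_rng(seed)
    sp = stripe_params or StripeParams()
    w, h = window

    depth = None
    in_stripe = None
    is_bridging = None

    if mode == "csr":
        pts = _dart_throw(n, window, d_min, rng)
    else:
        # Draw stripe membership first, then sample each point from the
        # corresponding conditional distribution, keeping the hard core
        # against *all* previously accepted points.  In grid mode a
        # fixed fraction of points is forced between the bands
        # ("bridging" neurons); the rest follow p_in as in striped mode.
        target_in = rng.random(n) < sp.p_in
        is_bridging = np.zeros(n, dtype=bool)
        if mode == "grid":
            n_bridge = int(round(sp.bridging_fraction * n))
            bridge_idx = rng.choice(n, size=n_bridge, replace=False)
            is_bridging[bridge_idx] = True
            target_in[is_bridging] = False

        def proposal_factory(want_in: bool, in_bridge_column: bool = False):
            def prop(r):
                for _ in range(MAX_ATTEMPTS_PER_POINT):
                    x, y = r.uniform(0.0, w), r.uniform(0.0, h)
                    if _in_band(np.asarray(x), np.asarray(y), sp) != want_in:
                        continue
                    if in_bridge_column and _band_distance(
                            np.asarray(x), sp.bridge_period,
                            sp.bridge_width) > sp.bridge_width / 2.0:
                        continue
                    return x, y
                raise PackingError("stripe band proposal failed")
            return prop

        pts = np.empty((n, 2), dtype=float)
        d2 = d_min * d_min
        props = {True: proposal_factory(True), False: proposal_factory(False)}
        bridge_prop = proposal_factory(False, in_bridge_column=True)
        for i in range(n):
            prop = bridge_prop if is_bridging[i] else props[bool(target_in[i])]
            for _ in range(MAX_ATTEMPTS_PER_POINT):
                x, y = prop(rng)
                if i and d_min > 0:
                    dx = pts[:i, 0] - x
                    dy = pts[:i, 1] - y
                    if (dx * dx + dy * dy).min() < d2:
                        continue
                pts[i] = (x, y)
                break
            else:
                raise PackingError(
                    f"failed to place striped point {i + 1}/{n} "
                    f"(d_min={d_min} um)"
                )
        in_stripe = _in_band(pts[:, 0], pts[:, 1], sp)

        if mode == "grid":
            # Bridging neurons sit nearer the longitudinal muscle (deeper);
            # stripe neurons nearer the circular muscle.
            depth = np.where(is_bridging, sp.bridging_depth, sp.stripe_depth)
        else:
            is_bridging = None

    labels: dict = {}
    truth = PatternTruth(
        mode=mode,
        seed=seed,
        d_min=d_min,
        stripe_params=sp if mode != "csr" else None,
        in_stripe=in_stripe,
        is_bridging=is_bridging,
    )
    if subtype_probs:
        for name, p in subtype_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"subtype probability for {name!r} not in [0,1]")
            draw = rng.random(n) < p
            labels[name] = draw
            truth.subtype_probs[name] = float(p)
            truth.subtype_draws[name] = draw.copy()

    pattern = PointPattern(
        points=pts,
        window=window,
        labels=labels,
        depth=depth,
        meta={"mode": mode, "seed": seed, "d_min": d_min},
    )
    return pattern, truth
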