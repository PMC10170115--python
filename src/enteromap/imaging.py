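"""Render synthetic fluorescence images from ground-truth geometry.

Two renderers:

* :func:`render_wholemount` draws soma disks of a calibrated area into a
  multi-slice z-stack (one slice per depth plane, 3 um apart by default),
  one channel per marker, emulating HuC/D wholemount stacks of the
  myenteric plexus.
* :func:`render_cross_section` draws the layered gut wall seen in a
  cryosection — mucosa, submucosal plexus, circular muscle, myenteric
  plexus, longitudinal muscle — with scattered nuclei in the myenteric
  band and an optional "apoptotic" channel marking a fraction of somata.

Both return an :class:`ImageStack` plus a ground-truth record so every
measurement operation can be verified round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .points import PointPattern, _dart_throw

__all__ = [
    "ImageStack",
    "RenderTruth",
    "CrossSectionTruth",
    "ResolutionError",
    "GeometryError",
    "render_wholemount",
    "render_cross_section",
    "DEFAULT_SOMA_AREA",
    "DEFAULT_Z_STEP",
]

#: Counting unit for area-based neuron estimates, um^2 per soma.
DEFAULT_SOMA_AREA = 138.0
#: Optical sectioning interval, um.
DEFAULT_Z_STEP = 3.0


class ResolutionError(ValueError):
    """Soma diameter below ~2 px at the requested pixel size."""


class GeometryError(ValueError):
    """Requested bands do not fit the image geometry."""


@dataclass
class ImageStack:
    """Multi-channel intensity volume with physical calibration.

    ``channels`` maps channel name -> (z, y, x) float array of
    non-negative intensities.  All channels share shape and calibration.
    """

    channels: dict
    pixel_size: float
    z_step: float = DEFAULT_Z_STEP
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.z_step <= 0:
            raise ValueError("z_step must be > 0")
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("channel shapes differ")

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    def single(self, name: str) -> "ImageStack":
        """View of one channel as a stack (shared calibration)."""
        return ImageStack(
            {name: self.channels[name]},
            pixel_size=self.pixel_size,
            z_step=self.z_step,
            meta=dict(self.meta),
        )


@dataclass
class RenderTruth:
    """Ground truth of a wholemount render."""

    pattern: PointPattern
    soma_area: float
    soma_radius_um: float
    centroids_px: np.ndarray          # (n, 2) as (row, col), 0-based
    z_index: np.ndarray               # per-soma slice index
    subtype_draws: dict               # marker -> bool array


@dataclass
class CrossSectionTruth:
    """Ground truth of a cross-section render."""

    layer_thicknesses: dict           # layer -> um
    layer_rows: dict                  # layer -> (row_start, row_stop) px
    nucleus_count: int
    nucleus_centers_px: np.ndarray    # (n, 2) (row, col)
    neuron_centers_px: np.ndarray
    apoptotic_mask: np.ndarray        # per-neuron bool


def _paint_disks(img: np.ndarray, centers_px: np.ndarray, radius_px: float,
                 amplitude: float = 1000.0) -> None:
    """Additively paint anti-aliased disks (centers as (row, col))."""
    h, w = img.shape
    r = radius_px
    ir = int(np.ceil(r + 1))
    for cy, cx in centers_px:
        y0, y1 = max(0, int(cy) - ir), min(h, int(cy) + ir + 1)
        x0, x1 = max(0, int(cx) - ir), min(w, int(cx) + ir + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(yy - cy, xx - cx)
        # Linear anti-aliased edge: full inside r-0.5, zero outside r+0.5.
        img[y0:y1, x0:x1] += amplitude * np.clip(r + 0.5 - d, 0.0, 1.0)


def _apply_noise(vol: np.ndarray, rng: np.random.Generator,
                 background: float, gauss_sd: float,
                 poisson_scale: float) -> np.ndarray:
    """Additive Gaussian background + per-pixel Poisson shot noise."""
    out = vol + background
    if poisson_scale > 0:
        out = rng.poisson(np.maximum(out, 0.0) * poisson_scale) / poisson_scale
    out = out + rng.normal(0.0, gauss_sd, size=out.shape)
    return np.maximum(out, 0.0)


def render_wholemount(
    pattern: PointPattern,
    soma_area: float = DEFAULT_SOMA_AREA,
    pixel_size: float = 1.0,
    z_step: float = DEFAULT_Z_STEP,
    reference_channel: str = "HuC/D",
    edge_compensation_um: float = 0.4,
    blur_sigma_um: float = 0.5,
    background: float = 20.0,
    gauss_sd: float = 2.0,
    poisson_scale: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ImageStack, RenderTruth]:
    """Render a point pattern as a multi-channel wholemount z-stack.

    Each soma becomes a disk of ``soma_area`` um^2 in the z-slice nearest
    its depth (depth 0 if the pattern has none), lightly blurred and
    noised.  Each subtype label in the pattern becomes a channel that
    contains exactly the somata whose label is positive; the reference
    channel contains all of them.

    The default field (800 x 800 um at 1 um/px) and the 3 um z interval
    match the acquisition settings the analysis modules assume.

    ``edge_compensation_um`` shrinks the painted radius slightly so that
    the *measured* (blur + global-threshold) foreground area of an
    isolated soma equals ``soma_area``: global thresholds sit below the
    half-maximum of a blurred disk edge and would otherwise dilate every
    soma by a fraction of a pixel.  The compensated radius is what the
    ground truth records.
    """
    from scipy.ndimage import gaussian_filter

    if soma_area <= 0:
        raise ValueError("soma_area must be > 0")
    radius_um = float(np.sqrt(soma_area / np.pi)) - edge_compensation_um
    radius_px = radius_um / pixel_size
    if 2.0 * radius_px < 2.0:
        raise ResolutionError(
            f"soma diameter {2 * radius_um:.2f} um is below 2 px at "
            f"{pixel_size} um/px"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    w_um, h_um = pattern.window
    ny = int(round(h_um / pixel_size))
    nx = int(round(w_um / pixel_size))

    depth = pattern.depth
    if depth is None:
        depth = np.zeros(pattern.n)
    z_index = np.rint(np.asarray(depth) / z_step).astype(int)
    nz = int(z_index.max()) + 1 if pattern.n else 1

    # (row, col) = (y, x) in px; continuous, 0-based pixel-centre coords.
    centroids_px = np.column_stack([
        pattern.points[:, 1] / pixel_size,
        pattern.points[:, 0] / pixel_size,
    ]) if pattern.n else np.empty((0, 2))

    def render_subset(mask: np.ndarray) -> np.ndarray:
        vol = np.zeros((nz, ny, nx), dtype=float)
        for z in range(nz):
            sel = mask & (z_index == z)
            if sel.any():
                _paint_disks(vol[z], centroids_px[sel], radius_px)
        if blur_sigma_um > 0:
            sig = blur_sigma_um / pixel_size
            for z in range(nz):
                vol[z] = gaussian_filter(vol[z], sig, mode="reflect")
        return _apply_noise(vol, rng, background, gauss_sd, poisson_scale)

    all_mask = np.ones(pattern.n, dtype=bool)
    channels = {reference_channel: render_subset(all_mask)}
    draws = {}
    for name, lab in pattern.labels.items():
        lab = np.asarray(lab, dtype=bool)
        channels[name] = render_subset(lab)
        draws[name] = lab.copy()

    stack = ImageStack(
        channels=channels,
        pixel_size=pixel_size,
        z_step=z_step,
        meta={"window_um": pattern.window, "seed": seed,
              "soma_area": soma_area},
    )
    truth = RenderTruth(
        pattern=pattern,
        soma_area=soma_area,
        soma_radius_um=radius_um,
        centroids_px=centroids_px,
        z_index=z_index,
        subtype_draws=draws,
    )
    return stack, truth


#: Wall layers in cross-section, luminal side first.
CROSS_SECTION_LAYERS = ("mucosa", "SMP", "CM", "MP", "LM")

DEFAULT_LAYER_THICKNESS = {
    "mucosa": 150.0,
    "SMP": 40.0,
    "CM": 60.0,
    "MP": 50.0,
    "LM": 40.0,
}


def render_cross_section(
    layer_thicknesses: Optional[dict] = None,
    nucleus_density: float = 5e-4,
    n_neurons: int = 100,
    apoptotic_fraction: float = 0.0,
    pixel_size: float = 0.5,
    width_um: float = 800.0,
    nucleus_radius_um: float = 3.0,
    neuron_radius_um: float = 4.5,
    background: float = 20.0,
    gauss_sd: float = 2.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ImageStack, CrossSectionTruth]:
    """Render a gut-wall cross section as a multi-channel 2D image.

    Horizontal bands (rows) represent, luminal side down the image:
    mucosa, submucosal plexus, circular muscle, myenteric plexus,
    longitudinal muscle.  Channels:

    ``muscle``
        The two smooth-muscle bands (CM then LM) as uniform foreground,
        for thickness transect measurements.
    ``Sox10``
        Nuclei scattered in the MP band at ``nucleus_density`` per um^2
        (count drawn Poisson; the exact draw is in the ground truth).
    ``HuC/D``
        ``n_neurons`` neuron somata in the MP band.
    ``Casp3``
        The apoptotic subset of those somata (Bernoulli
        ``apoptotic_fraction`` per neuron; exact draws recorded).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    th = dict(DEFAULT_LAYER_THICKNESS)
    if layer_thicknesses:
        th.update(layer_thicknesses)
    for k, v in th.items():
        if v <= 0:
            raise GeometryError(f"layer {k!r} thickness must be > 0")
    if nucleus_density < 0:
        raise ValueError("nucleus_density must be >= 0")
    if not 0.0 <= apoptotic_fraction <= 1.0:
        raise ValueError("apoptotic_fraction must be in [0, 1]")

    margin_um = 20.0
    total_um = sum(th[k] for k in CROSS_SECTION_LAYERS) + 2 * margin_um
    ny = int(round(total_um / pixel_size))
    nx = int(round(width_um / pixel_size))

    layer_rows = {}
    row = int(round(margin_um / pixel_size))
    for k in CROSS_SECTION_LAYERS:
        n_rows = int(round(th[k] / pixel_size))
        layer_rows[k] = (row, row + n_rows)
        row += n_rows
    if row > ny:
        raise GeometryError("layer bands exceed image height")

    zeros = lambda: np.zeros((ny, nx), dtype=float)

    muscle = zeros()
    for k in ("CM", "LM"):
        r0, r1 = layer_rows[k]
        muscle[r0:r1, :] = 1000.0

    # Nuclei in the MP band, hard-core so counts are unambiguous.
    mp0, mp1 = layer_rows["MP"]
    mp_h_um = (mp1 - mp0) * pixel_size
    mp_area_um2 = mp_h_um * width_um
    n_nuclei = int(rng.poisson(nucleus_density * mp_area_um2))
    pad = nucleus_radius_um + 1.0
    inner = (width_um - 2 * pad, mp_h_um - 2 * pad)
    nuc_xy = _dart_throw(n_nuclei, inner, 2 * nucleus_radius_um + 1.0, rng)
    nuc_px = np.column_stack([
        mp0 + (nuc_xy[:, 1] + pad) / pixel_size,
        (nuc_xy[:, 0] + pad) / pixel_size,
    ]) if n_nuclei else np.empty((0, 2))
    sox = zeros()
    _paint_disks(sox, nuc_px, nucleus_radius_um / pixel_size)

    pad_n = neuron_radius_um + 1.0
    inner_n = (width_um - 2 * pad_n, mp_h_um - 2 * pad_n)
    neu_xy = _dart_throw(n_neurons, inner_n, 2 * neuron_radius_um + 1.0, rng)
    neu_px = np.column_stack([
        mp0 + (neu_xy[:, 1] + pad_n) / pixel_size,
        (neu_xy[:, 0] + pad_n) / pixel_size,
    ]) if n_neurons else np.empty((0, 2))
    hucd = zeros()
    _paint_disks(hucd, neu_px, neuron_radius_um / pixel_size)

    apop = rng.random(n_neurons) < apoptotic_fraction
    casp = zeros()
    if apop.any():
        _paint_disks(casp, neu_px[apop], neuron_radius_um / pixel_size)

    channels = {}
    for name, img in (("muscle", muscle), ("Sox10", sox),
                      ("HuC/D", hucd), ("Casp3", casp)):
        noisy = _apply_noise(img[None, :, :], rng, background, gauss_sd, 0.0)
        channels[name] = noisy

    stack = ImageStack(channels=channels, pixel_size=pixel_size,
                       z_step=DEFAULT_Z_STEP,
                       meta={"layer_rows": layer_rows, "seed": seed})
    truth = CrossSectionTruth(
        layer_thicknesses=th,
        layer_rows=layer_rows,
        nucleus_count=n_nuclei,
        nucleus_centers_px=nuc_px,
        neuron_centers_px=neu_px,
        apoptotic_mask=apop,
    )
    return stack, truth
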