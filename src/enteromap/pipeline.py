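"""Manifest-driven end-to-end runs.

Two pipelines mirror the two experimental arms:

* wholemount: point pattern (synthetic scenario or image stack) ->
  CIF map -> z-score difference vs hard-core CSR -> subtype fractions,
  aggregated by region and gestational-age bin;
* motility: video (synthetic scenario or frames on disk) -> STM ->
  events -> summary, with paired baseline/TTX comparisons.

Configuration is a flat dataclass with defaults for every stage; the
manifest is a CSV with one row per sample.  All randomness descends
from one master seed (one spawned substream per manifest row), so a
rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cif as cifmod
from . import io as iomod
from . import motility as motmod
from . import points as ptsmod
from . import segment as segmod
from . import video as vidmod
from .imaging import render_wholemount

__all__ = ["RunConfig", "run_wholemount_pipeline", "run_motility_pipeline",
           "age_bin"]

log = logging.getLogger("enteromap")

#: Gestational age groupings used for trendline means (postconceptional
#: weeks).
AGE_BINS = ((13, 15), (18, 20), (21, 23))


def age_bin(age_pcw: float) -> str:
    for lo, hi in AGE_BINS:
        if lo <= age_pcw <= hi:
            return f"{lo}-{hi}PCW"
    return "other"


@dataclass
class RunConfig:
    """Parameters for a pipeline run; every field has a default.

    Unknown keys in a config file are rejected rather than ignored, and
    the config is echoed verbatim into the output directory.
    """

    manifest: Optional[str] = None
    out_dir: Optional[str] = None
    seed: int = 0
    # pattern / CIF stage
    n_points: int = 300
    window_um: tuple = (800.0, 800.0)
    d_min_um: float = 5.0
    cif_L_um: float = 200.0
    cif_bin_um: float = 4.0
    smooth_sd_um: float = 20.0
    n_sim: int = 500
    # imaging stage
    render_images: bool = False
    soma_area_um2: float = 138.0
    pixel_size_um: float = 1.0
    subtype_probs: dict = field(default_factory=dict)
    # motility stage
    frame_rate: float = 3.75
    duration_s: float = 600.0
    depth_threshold_um: float = 100.0
    save_figures: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.window_um, list):
            cfg.window_um = tuple(cfg.window_um)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def echo(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(
            json.dumps(iomod._jsonable(asdict(self)), indent=2))


def _load_manifest(config: RunConfig) -> pd.DataFrame:
    if config.manifest is None:
        raise ValueError("config.manifest is required")
    df = pd.read_csv(config.manifest)
    if df.empty:
        raise ValueError("manifest lists no samples")
    return df


def _row_pattern(row, config: RunConfig, rng: np.random.Generator):
    """Point pattern for one manifest row: from file, image, or scenario."""
    if isinstance(row.get("pattern_file"), str):
        return iomod.load_pattern(row["pattern_file"]), None
    if isinstance(row.get("image_file"), str):
        stack = iomod.load_stack(row["image_file"])
        name = next(iter(stack.channels))
        _, pat = segmod.segment_neurons(stack, channel=name)
        return pat, None
    mode = row.get("mode", "csr")
    pat, truth = ptsmod.generate_point_pattern(
        mode=mode, n=int(row.get("n", config.n_points)),
        window=config.window_um, d_min=config.d_min_um,
        subtype_probs=config.subtype_probs or None, rng=rng)
    if config.render_images:
        stack, _ = render_wholemount(
            pat, soma_area=config.soma_area_um2,
            pixel_size=config.pixel_size_um, rng=rng)
        name = "HuC/D"
        _, pat = segmod.segment_neurons(stack, channel=name)
    return pat, truth


def run_wholemount_pipeline(config: RunConfig) -> pd.DataFrame:
    """Per-sample spatial statistics plus region x age aggregation.

    Returns the per-sample results table; when ``config.out_dir`` is
    set, writes ``wholemount_results.csv``, the aggregate trendline
    table, and (optionally) CIF map figures.  Failures of individual
    samples are logged and skipped; the run fails only if every sample
    fails.
    """
    df = _load_manifest(config)
    streams = np.random.SeedSequence(config.seed).spawn(len(df))
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        config.echo(out_dir)

    rows = []
    errors = []
    for i, (_, row) in enumerate(df.iterrows()):
        rng = np.random.default_rng(streams[i])
        sub_seed = int(streams[i].generate_state(1)[0] % (2 ** 31))
        try:
            pat, _ = _row_pattern(row, config, rng)
            cmap = cifmod.compute_cif(pat, L=config.cif_L_um,
                                      bin_size=config.cif_bin_um,
                                      smooth_sd=config.smooth_sd_um)
            z = cifmod.zscore_difference(
                pat, L=config.cif_L_um, bin_size=config.cif_bin_um,
                smooth_sd=config.smooth_sd_um, d_min=config.d_min_um,
                n_sim=config.n_sim, seed=sub_seed)
            rec = dict(
                sample=row.get("sample", f"sample{i}"),
                region=row.get("region", "NA"),
                age_pcw=row.get("age_pcw", np.nan),
                age_bin=age_bin(float(row.get("age_pcw", np.nan)))
                if pd.notna(row.get("age_pcw", np.nan)) else "other",
                mode=row.get("mode", "data"),
                n_points=pat.n,
                statistic=z.statistic,
                z_data=z.z_data,
                z_diff=z.z_diff,
                band_lo=z.null_band[0],
                band_hi=z.null_band[1],
                seed=sub_seed,
            )
            rows.append(rec)
            if out_dir:
                iomod.save_cifmap(out_dir / f"cif_{rec['sample']}.tif", cmap)
                if config.save_figures:
                    _save_cif_figure(out_dir / f"cif_{rec['sample']}.png",
                                     cmap)
        except Exception as exc:       # per-sample isolation
            log.warning("sample %s failed: %s", row.get("sample", i), exc)
            errors.append((row.get("sample", i), str(exc)))
    if not rows:
        raise RuntimeError(f"all samples failed: {errors}")

    res = pd.DataFrame(rows)
    if out_dir:
        res.to_csv(out_dir / "wholemount_results.csv", index=False)
        agg = (res.groupby(["region", "age_bin"], as_index=False)
               .agg(mean_z_diff=("z_diff", "mean"),
                    n=("z_diff", "size")))
        agg.to_csv(out_dir / "wholemount_trendlines.csv", index=False)
    return res


def _row_stm(row, config: RunConfig, rng: np.random.Generator) -> motmod.STM:
    condition = row.get("condition", "baseline")
    if isinstance(row.get("video_file"), str):
        import tifffile

        frames = tifffile.imread(row["video_file"])
        return motmod.compute_stm(frames,
                                  pixel_size=float(row.get("pixel_size_um",
                                                           25.0)),
                                  frame_rate=config.frame_rate,
                                  condition=condition)
    stage = row.get("stage", "14pcw")
    frames, truth = vidmod.scenario(stage, ttx=condition == "ttx",
                                    duration_s=config.duration_s,
                                    rng=rng)
    return motmod.compute_stm(frames, pixel_size=truth.pixel_size,
                              frame_rate=truth.frame_rate,
                              condition=condition)


def run_motility_pipeline(config: RunConfig) -> pd.DataFrame:
    """Per-recording motility summaries plus paired TTX comparisons.

    Manifest columns: ``sample``, ``condition`` (baseline/ttx/washout),
    and either ``video_file`` or a synthetic ``stage``.  Baseline/ttx
    pairs sharing a sample id are compared; unpaired treated recordings
    are summarised alone with a warning.
    """
    df = _load_manifest(config)
    streams = np.random.SeedSequence(config.seed).spawn(len(df))
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        config.echo(out_dir)

    rows = []
    stms = {}
    for i, (_, row) in enumerate(df.iterrows()):
        rng = np.random.default_rng(streams[i])
        sample = row.get("sample", f"seg{i}")
        condition = row.get("condition", "baseline")
        try:
            stm = _row_stm(row, config, rng)
            events = motmod.detect_contractions(
                stm, depth_threshold_um=config.depth_threshold_um)
            summ = motmod.classify_pattern(events, stm)
            stms[(sample, condition)] = stm
            rows.append(dict(
                sample=sample, condition=condition,
                stage=row.get("stage", "data"),
                label=summ.label,
                ripple_frequency_per_min=summ.ripple_frequency_per_min,
                quiescent_fraction=summ.quiescent_fraction,
                asymmetry=summ.asymmetry,
                n_events=len(events),
            ))
            if out_dir:
                iomod.save_stm(out_dir / f"stm_{sample}_{condition}.tif", stm)
                iomod.save_events(
                    out_dir / f"events_{sample}_{condition}.csv", events)
        except Exception as exc:
            log.warning("recording %s/%s failed: %s", sample, condition, exc)
    if not rows:
        raise RuntimeError("all recordings failed")
    res = pd.DataFrame(rows)

    comps = []
    for (sample, condition), stm in stms.items():
        if condition != "ttx":
            continue
        if (sample, "baseline") not in stms:
            log.warning("treated recording %s has no baseline pair", sample)
            continue
        c = motmod.compare_conditions(stms[(sample, "baseline")], stm)
        comps.append(dict(
            sample=sample,
            baseline_label=c.baseline.label,
            ttx_label=c.treated.label,
            delta_ripple_frequency=c.delta_ripple_frequency,
            delta_quiescent_fraction=c.delta_quiescent_fraction,
        ))
    comp = pd.DataFrame(comps)
    if out_dir:
        res.to_csv(out_dir / "motility_results.csv", index=False)
        if len(comp):
            comp.to_csv(out_dir / "motility_comparisons.csv", index=False)
    res.attrs["comparisons"] = comp
    return res


def _save_cif_figure(path, cmap) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    extent = (-cmap.L, cmap.L, -cmap.L, cmap.L)
    im = ax.imshow(cmap.smoothed, origin="lower", extent=extent,
                   cmap="viridis")
    ax.set_xlabel("circumferential lag (um)")
    ax.set_ylabel("longitudinal lag (um)")
    fig.colorbar(im, ax=ax, label="neighbour intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
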