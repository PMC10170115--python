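# enteromap

Quantitative analysis of enteric nervous system (ENS) organization and
ex vivo gastrointestinal motility, with a synthetic ground-truth data
generator so that every stage can be verified end to end without any
tissue data.

During mid-gestation the myenteric plexus (MP) — the ENS layer between
the circular and longitudinal muscle that drives gut motility —
reorganizes from a random array of neurons into circumferentially
oriented stripes with an overlying grid of "bridging" neurons, while
motility matures from myogenic ripples to neurally driven, distally
propagating contractions.  `enteromap` implements the image- and
video-analysis used to quantify both processes:

* **Spatial statistics.**  From soma coordinates (x = circumferential,
  y = longitudinal, in µm) the conditional intensity function (CIF) is
  the map of neighbour counts at every 2D lag (Δx, Δy) ∈ [−L, L]²,
  translation-edge-corrected and smoothed with a 20 µm Gaussian.
  Departure from randomness is scored as

      z_diff = z(data) − mean z(null),   z(s) = (T(s) − μ̂) / σ̂,

  where T is a monotone transform of the coefficient of variation of
  the smoothed CIF and μ̂, σ̂ come from a Monte Carlo null of hard-core
  CSR patterns (minimum separation 5 µm, matched n and window, 500
  samples by default).  Null z-scores are computed leave-one-out; their
  2.5–97.5 percentile band is the "random value range".  A stripe-period
  estimator reads the dominant longitudinal frequency off the CIF.
* **Image measurements.**  Soma segmentation (blur → Otsu → watershed),
  area-based neuron counting (total HuC/D area ÷ 138 µm² per soma),
  subtype colocalization and fractions (CalR, nNOS, Caspase-3 with a
  polygon ROI), depth projection (µm of the brightest z-slice, 3 µm
  steps), muscle-layer thickness on cross-section transects, and
  nuclear (Sox10) density in a ~100,000 µm² ROI.
* **Motility.**  Spatiotemporal maps (STM: tube diameter vs position
  and time, from videos at 3.75 frames/s), contraction-event detection
  and classification (distal / proximal / bidirectional, velocity from
  a least-squares ridge fit), ripple frequency (events/min), stage
  labels (`ripples_only`, `intermittent_neurogenic`,
  `distal_propagating`) and baseline-vs-TTX comparisons.
* **Synthetic data.**  Seeded generators for point patterns (CSR /
  striped / grid with hard core), wholemount z-stacks, layered
  cross-sections, and motility videos with an analytic diameter field —
  each returning the full ground truth used by the tests.

## Worked example

```python
from enteromap.cif import zscore_difference
from enteromap.points import generate_point_pattern

for mode in ("csr", "striped", "grid"):
    pattern, truth = generate_point_pattern(mode, n=300,
                                            window=(800.0, 800.0),
                                            d_min=5.0, seed=1)
    r = zscore_difference(pattern, n_sim=100, seed=2)
    print(mode, round(r.z_diff, 2), [round(b, 2) for b in r.null_band])
```

prints

```
csr      -0.87  [-2.24, 1.98]
striped  10.09  [-2.24, 1.98]
grid      8.20  [-2.24, 1.98]
```

The random pattern scores inside the random band (indistinguishable
from CSR); striped and grid tissue score far above its upper edge —
the organization is non-random and clustered.  The `examples/`
directory has one short script per capability (pattern scoring,
segmentation round trip, subtype fractions, STM and event detection,
TTX comparison), each printing the numbers it computes.

A thin CLI wraps the same library calls:

```
enteromap simulate video --stage 21pcw --out video.tif
enteromap motility video.tif --pixel-size 25
```

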