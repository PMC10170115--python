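"""Compare baseline motility with neuronal blockade (TTX).

An immature-circuit recording (bidirectional bursts separated by
quiescent periods) is paired with its TTX counterpart: blocking
neurons ablates the quiescent gating, leaving continuous myogenic
ripples.
"""

from enteromap.motility import compare_conditions, compute_stm
from enteromap.video import scenario

base_frames, base_truth = scenario("18pcw", duration_s=300, seed=31)
ttx_frames, ttx_truth = scenario("18pcw", ttx=True, duration_s=300, seed=31)

baseline = compute_stm(base_frames, pixel_size=base_truth.pixel_size)
treated = compute_stm(ttx_frames, pixel_size=ttx_truth.pixel_size,
                      condition="ttx")
comp = compare_conditions(baseline, treated)

print(f"baseline: {comp.baseline.label}  "
      f"quiescent={comp.baseline.quiescent_fraction:.2f}  "
      f"ripples/min={comp.baseline.ripple_frequency_per_min:.1f}")
print(f"TTX:      {comp.treated.label}  "
      f"quiescent={comp.treated.quiescent_fraction:.2f}  "
      f"ripples/min={comp.treated.ripple_frequency_per_min:.1f}")
print(f"delta quiescent fraction: {comp.delta_quiescent_fraction:+.2f}")

# The quiescent fraction collapsing toward zero under TTX shows the
# pauses were neuronally imposed; the surviving ripples are myogenic.
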