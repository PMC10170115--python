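"""Estimate the fraction of neurons expressing a subtype marker.

The generator labels each soma calretinin-positive with probability
0.4; the estimator colocalizes the subtype channel with the pan-
neuronal channel and divides by the area-based total neuron count.
"""

from enteromap.imaging import render_wholemount
from enteromap.points import generate_point_pattern
from enteromap.segment import subtype_fraction

pattern, truth = generate_point_pattern("csr", n=200, seed=11,
                                        subtype_probs={"CalR": 0.4})
stack, _ = render_wholemount(pattern, seed=11)
res = subtype_fraction(stack, stack, reference_channel="HuC/D",
                       subtype_channel="CalR")

print(f"true positives:     {truth.subtype_draws['CalR'].sum()} / 200")
print(f"double-positive:    {res.double_positive}")
print(f"estimated neurons:  {res.estimated_total:.1f}")
print(f"estimated fraction: {res.fraction:.3f}  (true draw "
      f"{truth.subtype_draws['CalR'].mean():.3f})")
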