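"""Variant allele frequencies and the clonal fraction.

Simulates read support for 500 somatic variants in a tumor whose true
clonal fraction is 0.9, then recovers that fraction by counting variants
with VAF >= 0.25.
"""

import immunosift as ims

variants, truth = ims.generate_variant_table(
    n_variants=500, clonal_fraction_target=0.9, depth=100, seed=1
)
summary = ims.clonal_fraction(variants, threshold=0.25)

print(f"variants:          {summary.n_variants}")
print(f"clonal (VAF>=0.25): {summary.n_clonal}")
print(f"clonal fraction:   {summary.clonal_fraction:.3f}  (planted: {truth.true_clonal_fraction})")
print()
print("A clonal fraction near 1 means the sample is genetically homogeneous:")
print("almost every mutation is carried by (essentially) every tumor cell.")
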