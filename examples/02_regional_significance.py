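"""Regional mean/difference maps and pointwise significance mapping.

For the long-term-wear group, paired Wilcoxon signed-rank tests run at
every map cell (post vs pre), with Benjamini-Hochberg FDR control across
the map.  The rejected cells concentrate in the mid-periphery and the
nasal/temporal hotspots, while the centre stays quiet.
"""

import numpy as np

import tearmap as tm

cohort, _ = tm.generate_cohort(tm.default_params(seed=0), "OD")

pre = tm.group_mean_map(cohort, "G3", "pre")
post = tm.group_mean_map(cohort, "G3", "post")
diff = tm.difference_map(post, pre)
r = pre.grid.ring_radii
central = r <= 1.0
periph = (r >= 3.5) & (r <= 4.5)
print("G3 mean change (post - pre), tear-quality units:")
print(f"  central disc  (r <= 1 mm):   {np.nanmean(diff.values[central]):+.4f}")
print(f"  periphery (3.5-4.5 mm):      {np.nanmean(diff.values[periph]):+.4f}")

sig = tm.pointwise_signed_rank_map(cohort, "G3", alpha=0.05)
print("fraction of cells with significant change (BH at 0.05):")
print(f"  whole map:     {sig.rejected_fraction():.2f}")
print(f"  central 1 mm:  {sig.rejected_fraction(0.0, 1.0):.2f}")
print(f"  3.5-4.5 mm:    {sig.rejected_fraction(3.5, 4.5):.2f}")

# A positive peripheral change with near-zero central change, significant
# only outside the centre, is the hallmark regional pattern of lens wear.
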