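"""Voxel-based morphometry on two phantom groups.

Segments gray matter for ten healthy (NC) and ten late-stage (AD) phantoms,
contrasts the GM probability maps with a voxel-wise two-sample GLM, and
reports where the statistic peaks relative to the planted atrophy region.
"""

import numpy as np

from neurofuse import (
    PhantomSpec,
    generate_subject,
    glm_tmap,
    gm_mask,
    segment_tissues,
    skull_strip,
    zscore_normalize,
)

spec = PhantomSpec(seed=0, n_per_class=10)
gm_maps = {"NC": [], "AD": []}
region = None
for name, cls in (("NC", 0), ("AD", 3)):
    for k in range(10):
        pair = generate_subject(spec, cls, k)
        stripped, mask = skull_strip(pair.mri)
        tissues = segment_tissues(zscore_normalize(stripped, mask), mask, seed=0)
        gm_maps[name].append(tissues.gm)
        region = pair.ground_truth["atrophy_mask"]

stat = glm_tmap(gm_maps["NC"], gm_maps["AD"])
peak = tuple(int(v) for v in
             np.unravel_index(np.argmax(np.abs(stat.t_values)), stat.t_values.shape))
print(f"df = {stat.df}, peak |t| = {np.abs(stat.t_values).max():.2f} at voxel {peak}")
print(f"peak inside planted atrophy region: {bool(region[peak])}")
print(f"mean |t| inside region: {np.abs(stat.t_values)[region].mean():.2f}, "
      f"outside: {np.abs(stat.t_values)[~region].mean():.2f}")
# The strongest group difference in gray-matter density localizes to the
# planted 'hippocampus' blob, the effect VBM is meant to expose.
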