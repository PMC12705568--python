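"""The three mask-coding fusion variants on one co-registered pair.

Shows that hard masking zeroes extra-GM functional signal, soft fusion
modulates it continuously, and the structural channel is never touched.
"""

import numpy as np

from neurofuse import (
    PhantomSpec,
    generate_subject,
    gm_mask,
    mask_code_fuse,
    segment_tissues,
    simple_concat,
    skull_strip,
    soft_fuse,
    zscore_normalize,
)

pair = generate_subject(PhantomSpec(seed=0), "MCI", 0)
stripped, mask = skull_strip(pair.mri)
mri = zscore_normalize(stripped, mask)
pet = zscore_normalize(pair.pet.with_data(pair.pet.data * mask.data), mask)
tissues = segment_tissues(mri, mask, seed=0)
gmask = gm_mask(tissues, 0.5)

concat = simple_concat(mri, pet)
hard = mask_code_fuse(mri, pet, gmask)
soft = soft_fuse(mri, pet, tissues.gm, alpha=1.0)

for name, fused in (("concat", concat), ("mask_hard", hard), ("mask_soft", soft)):
    frac = np.count_nonzero(fused.pet) / mask.n_voxels
    print(f"{name:10s} | PET energy {np.abs(fused.pet).sum():8.1f} | "
          f"nonzero PET fraction of brain {frac:.2f} | "
          f"MRI channel untouched: {np.array_equal(fused.mri, mri.data)}")
# Hard masking keeps functional signal only inside the binary GM mask; soft
# fusion shades it by GM probability; the anatomical channel is identical in
# all three variants.
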