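"""Reading and writing Visium-style directories.

Writes a synthetic slide out as a minimal spaceranger-like directory
(MTX triplet + tissue positions CSV + slide PNG) and reads it back,
demonstrating the I/O round trip a real 10x dataset would follow.
"""

import tempfile
from pathlib import Path

import numpy as np

import sducl

ds = sducl.generate(sducl.SyntheticSpec(grid_shape=(6, 10), n_genes=80,
                                        n_markers_per_domain=8, seed=1))

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "slide"
    sducl.write_fixture_visium(ds, out)
    print("wrote:", sorted(p.name for p in out.iterdir()))

    back = sducl.read_visium(out)
    order = [back.spot_ids.index(b) for b in ds.spot_ids]
    print("counts round-trip exact:",
          bool(np.array_equal(back.counts[order], ds.counts)))
    print(f"read {back.n_spots} spots, image {back.image.shape}")

    patches = sducl.crop_patches(back, patch_px=12)
    print("patch stack:", patches.shape)
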