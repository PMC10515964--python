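"""Reconstruct a sparse 2-D section series into template space.

A phantom's gene-expression channel is sliced every 2 voxels, 20 % of the
sections are dropped and each is jittered in-plane by up to 4 px — the
shape of real chromogenic section data.  The seven-step chain inverts,
stacks and spline-infills the sections, corrects each against a linearly
aligned reference, registers the template to the corrected stack and pulls
the sample through the inverse.  Printed: the voxel-wise correlation of the
mapped volume with the phantom's true expression (how much of the spatial
pattern survived sectioning and mapping), per gene.
"""

import numpy as np

from devatlas.ish import run_chain
from devatlas.synthetic import PhantomSpec, make_ish_series, make_phantom

phantom = make_phantom(PhantomSpec(shape=(64, 64, 48), n_random=10, seed=4))
series, truth = make_ish_series(phantom.expression, dz=2, drop_fraction=0.2,
                                jitter_px=4, genes=("geneA",), seed=7)
print(f"sections: {len(series.slices)} kept of {series.n_nominal} nominal")

out = run_chain(series, phantom.image, size=64)

corr = np.corrcoef(out["mapped"].data.ravel(),
                   phantom.expression.data.ravel())[0, 1]
print(f"mapped-to-truth expression correlation: {corr:.3f}")
for gene, vol in out["per_gene"].items():
    g = np.corrcoef(vol.data.ravel(), phantom.expression.data.ravel())[0, 1]
    print(f"  {gene}: correlation {g:.3f}")
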