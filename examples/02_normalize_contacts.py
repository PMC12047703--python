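"""Balance a contact matrix three ways and compare row-sum flatness.

Hi-C counts carry per-bin visibility biases; balancing removes them.
SQRTVC is a one-shot correction, ICE iterates to equal visibility, and
KR solves for an exactly doubly stochastic rescaling. The printed
row-sum coefficient of variation shows how flat each method leaves the
matrix.
"""

import numpy as np

from chromgae import SynthConfig, generate, ice, kr, sqrtvc

_, truth = generate(SynthConfig(n_segments=60, n_chroms=1, seed=3))
mat = truth.chromosomes["chr1"].contact_matrix()
M = mat.values


def row_cv(m):
    r = m.sum(axis=1)
    r = r[r > 0]
    return r.std() / r.mean()


print(f"bins: {mat.n_bins}, raw row-sum CV: {row_cv(M):.3f}")
for name, out in (
    ("SQRTVC", sqrtvc(M)),
    ("ICE", np.asarray(ice(M, tol=1e-8))),
    ("KR", np.asarray(kr(M))),
):
    print(f"{name:>6}: row-sum CV {row_cv(out):.2e}")
print(
    "\nICE and KR drive the coefficient of variation to ~0 (equal\n"
    "visibility); SQRTVC only attenuates it, by design."
)
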