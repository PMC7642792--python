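"""Moving-box local resolution on a two-compartment phantom.

The inner sphere carries signal to Fourier shell 14, the outer shell only
to shell 6.  The local map (11^3 boxes, sigma_g = 2) separates the two
compartments; estimates are diffused by about two window widths around
each band limit — the price of localizing in both spaces at once.
"""

import numpy as np
from scipy import ndimage

import mfscres as m

n = 64
k_in, k_out = 14, 6
ax = np.arange(n)
z, y, x = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
c = n // 2
r = np.sqrt((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2)
inner = r <= 0.17 * n
outer = (r > 0.24 * n) & (r <= 0.40 * n)
kb = m.shell_index_grid(n)


def bandlimit(d, k1):
    f = np.fft.fftn(d)
    f[kb > k1] = 0
    return np.fft.ifftn(f).real


def compartment(seed, k1, weight):
    s = bandlimit(np.random.default_rng(seed).normal(size=(n,) * 3), k1)
    for _ in range(10):              # nearly band-limited AND compact
        s = bandlimit(s * weight, k1)
    return s / s.std()


signal = (compartment(1, k_in, ndimage.gaussian_filter(inner.astype(float), 2))
          + compartment(2, k_out, ndimage.gaussian_filter(outer.astype(float), 2)))
noise = 0.8 * signal.std()
u = m.Volume(signal + np.random.default_rng(50).normal(scale=noise, size=(n,) * 3))
v = m.Volume(signal + np.random.default_rng(51).normal(scale=noise, size=(n,) * 3))

lmap = m.local_resolution_map(u, v, m.Mask((inner | outer).astype(float)),
                              box_side=11, stride=4, sigma_g=2.0)
k_eff = np.where(lmap.data > 0, n / np.maximum(lmap.data, 1e-9), 0.0)
for name, sel in (("inner (band limit k=14)", inner),
                  ("outer (band limit k=6)", outer)):
    core = ndimage.binary_erosion(sel, iterations=5) & (lmap.data > 0)
    print(f"{name}: median local resolution shell = {np.median(k_eff[core]):.0f}")
# Higher shell = finer detail: the inner compartment resolves finer
# structure than the outer one, as built.
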