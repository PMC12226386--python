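"""Forward-model a photon arrival-time histogram and invert it.

Builds a noisy TPSF for known tissue optics (mua = 0.015/mm,
musp = 1.2/mm at a 30 mm source-detector separation), then fits the
IRF-convolved diffusion model to recover the coefficients. The printed
relative errors show what a 10^6-photon measurement can resolve.
"""

import numpy as np

from nirtrs.inversion import fit_tpsf
from nirtrs.optics import (
    TPSF, OpticalProperties, ProbeGeometry, TimeGrid,
    convolve_irf, gaussian_irf, reflectance, sample_counts,
)

grid = TimeGrid()                      # 4096 bins x 10 ps
geometry = ProbeGeometry(rho=30.0)     # 3 cm probe, n = 1.4
truth = OpticalProperties(mua=0.015, musp=1.2, wavelength=763)

irf = gaussian_irf(grid)               # 150 ps FWHM instrument response
expected = convolve_irf(reflectance(geometry, truth, grid), irf)
counts = sample_counts(expected, total_photons=1_000_000, seed=42)
tpsf = TPSF(grid=grid, counts=counts,
            irf_counts=np.round(irf * 1e6).astype(np.int64),
            wavelength=763, geometry=geometry)

result = fit_tpsf(tpsf)
print(f"true   mua = {truth.mua:.4f} /mm   musp = {truth.musp:.3f} /mm")
print(f"fitted mua = {result.props.mua:.4f} /mm   "
      f"musp = {result.props.musp:.3f} /mm  "
      f"(converged={result.converged}, {result.n_bins_used} bins)")
print(f"relative error: mua {abs(result.props.mua/truth.mua-1):.2%}, "
      f"musp {abs(result.props.musp/truth.musp-1):.2%}")
print("Sub-percent errors mean shot noise, not the model, limits accuracy "
      "at this photon budget.")
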