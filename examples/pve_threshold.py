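"""Closed-form PVE mixture and the global threshold.

Builds the partial-volume distribution for a boundary pixel that is part
CSF, part white/grey matter, and prints the threshold T_PVE it implies.
"""

import ventpve as vp
from ventpve.types import GaussianParams

csf = GaussianParams(mu=10.0, sigma=4.0)   # cerebrospinal fluid, HU
wgm = GaussianParams(mu=40.0, sigma=5.0)   # white + grey matter, HU

for alpha in (0.5, 0.6):
    model = vp.PVEModel.from_components(csf, wgm, alpha)
    print(
        f"alpha={alpha}: PVE mean mu_g={model.pve.mu:.1f} HU, "
        f"sigma_g={model.pve.sigma:.2f} HU -> threshold T_PVE={model.t_pve:.1f} HU"
    )

# T_PVE is the most probable intensity of a pixel mixing the two tissues at
# fraction alpha; pixels at or below it are classed as CSF.

print()
print(f"rectangle-fit tail share: {vp.rectangle_fit_tail_share():.1f}%")
print(f"FWHM background share:    {vp.fwhm_background_share():.1f}%")
# The first is the one-sided Gaussian tail beyond the equal-area-rectangle
# cutoff sqrt(pi/2); the second is the background share a full-width-at-
# half-maximum cutoff admits under the same linear mixing model.
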