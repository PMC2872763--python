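"""Recovering a rater's implicit mixing cutoff from ground truth.

A phantom is rendered whose one-pixel ventricle border mixes CSF and
background at exactly alpha = 0.6 -- emulating an expert whose marked
boundary sits at their implicit cutoff.  The cutoff is then recovered
blindly: fit the histogram mixture, find the ground-truth boundary mean,
and invert the PVE mean equation.
"""

import ventpve as vp

spec = vp.PhantomSpec(border_alpha_model=0.6, seed=42)
out = vp.generate_phantom(spec)
print(f"phantom: {spec.shape[0]}x{spec.shape[1]}, {out.n_border_pixels} border pixels")

gt = out.gt_at_alpha(0.6)  # the mask this rater would draw

fit = vp.fit_gmm_em(vp.build_histogram(out.slice), n_components=3, seed=42)
tissues = vp.identify_tissue_components(fit)
print(f"fitted CSF  N({tissues.csf.mu:.2f}, {tissues.csf.sigma:.2f}) HU  (true 10, 4)")
print(f"fitted WGM  N({tissues.wgm.mu:.2f}, {tissues.wgm.sigma:.2f}) HU  (true 38, 5)")

boundary_mean = vp.gt_boundary_intensity_mean(out.slice, gt)
alpha0 = vp.estimate_alpha0(boundary_mean, tissues.csf, tissues.wgm)
print(f"GT boundary mean intensity: {boundary_mean:.2f} HU")
print(f"recovered alpha0 = {alpha0:.3f}  (generative cutoff 0.6)")
# alpha0 close to 0.6 means the method reads the rater's implicit
# partial-volume cutoff back out of nothing but the marked mask.
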