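"""Compute the five vegetation indices from one set of band reflectances.

A healthy vegetated pixel: low visible reflectance, high NIR. Each index
transforms the same four bands with a different background adjustment.
"""

from marshphen.indices import VI_NAMES, compute_vi

bands = dict(blue=0.04, green=0.07, red=0.05, nir=0.45)

for vi in VI_NAMES:
    print(f"{vi:6s} {compute_vi(**bands, vi_name=vi):.4f}")

# NDVI/GNDVI are normalized ratios in [-1, 1]; SAVI/WAVI damp soil and
# water background with the L = 0.5 adjustment; EVI amplifies the blue
# band 7.5-fold, which is exactly why omitted clouds destabilize it.
print("\nEVI with the 7.0 blue-coefficient variant:",
      round(compute_vi(**bands, vi_name="EVI", evi_blue_coef=7.0), 4))
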