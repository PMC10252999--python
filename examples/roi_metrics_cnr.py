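"""Measure attenuation, noise and CNR on a single vessel phantom.

Generates a 3.5 mm vessel cross-section reconstructed with a moderately
soft kernel (PSF sigma 0.48 mm, 37.9 HU noise), places a lumen ROI and a
pericoronary-fat ROI, and reports the contrast-to-noise ratio
CNR = (HU_lumen - HU_fat) / SD_lumen.
"""

from vesseliq import (
    CircularROI,
    KernelSpec,
    PhantomSpec,
    cnr,
    generate_vessel_image,
    roi_mean_sd,
)

kernel = KernelSpec("Br", 36, psf_sigma=0.482, noise_sd=37.9,
                    attenuation_bias=40.0)
spec = PhantomSpec(vessel_diameter=3.5, kernel=kernel, seed=42)
image = generate_vessel_image(spec)

lumen = roi_mean_sd(image, CircularROI("lumen", (9.6, 9.6), radius=0.9))
fat = roi_mean_sd(image, CircularROI("fat", (4.0, 4.0), radius=2.5))
result = cnr(lumen, fat)

print(f"lumen: mean {lumen.mean_hu:6.1f} HU, SD {lumen.sd_hu:5.1f} HU "
      f"({lumen.n_pixels} px)")
print(f"fat:   mean {fat.mean_hu:6.1f} HU, SD {fat.sd_hu:5.1f} HU "
      f"({fat.n_pixels} px)")
print(f"CNR = {result.cnr:.1f}")
print("The lumen mean lands somewhat below the 840 HU plateau (800 HU")
print("contrast + 40 HU kernel offset) because the soft kernel's blur mixes")
print("edge values into the ROI; the fat-ROI SD estimates image noise; and")
print("CNR ~20 is typical of a soft kernel at the lowest sharpness level.")
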