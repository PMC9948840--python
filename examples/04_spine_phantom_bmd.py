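"""Two-material decomposition: bone mineral density in a spine-phantom scene.

Renders the synthetic spine phantom (spongiosa at 50/100/200 mg/cm^3
hydroxyapatite in water) with 10 HU Gaussian noise, measures each VOI, and
recovers BMD by the hydroxyapatite/water decomposition.
"""

from deqct import (
    BeamCalibration,
    HYDROXYAPATITE,
    MaterialSpec,
    basis_attenuation,
    builtin_scene,
    decompose,
    voi_stats,
)
from deqct.synthetic import render_scene

beam = BeamCalibration(80, 130, n=3.2, alpha_low=0.8975, alpha_high=0.9492)
scene = builtin_scene("esp3", noise_sd_hu=(10.0, 10.0), seed=11, region_size=40)
render = render_scene(scene, beam)

ha = basis_attenuation(HYDROXYAPATITE, beam)
water = basis_attenuation(MaterialSpec.from_formula("water", "H2O", 1.0), beam)

print("vertebra  nominal BMD   measured BMD   error")
for voi, nominal in zip(voi_stats(render.pair, render.mask), (50.0, 100.0, 200.0)):
    res = decompose(voi, [ha, water])
    err = res.bmd_mg_cm3 - nominal
    print(
        f"   {voi.label}       {nominal:6.0f} mg/cm3  {res.bmd_mg_cm3:7.1f} mg/cm3 "
        f"{err:+6.1f}"
    )
print()
print("With 40^3-voxel VOIs the 10 HU voxel noise averages down to a few")
print("hundredths of an HU, so recovered BMD sits within ~1 mg/cm3 of nominal.")
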