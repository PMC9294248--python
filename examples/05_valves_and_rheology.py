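"""Valve setup and blood rheology for one regurgitant case.

Maps an MR grade to a regurgitation fraction, sizes the regurgitant
orifice, evaluates the porous-baffle pressure drop across a closing valve,
and samples the Carreau–Yasuda viscosity over the physiological shear range.
"""

import numpy as np

from lvshapeflow import (
    BafflePorosity,
    ValveSpec,
    apparent_viscosity,
    baffle_pressure_drop,
    mr_to_regurg_fraction,
    size_regurg_orifice,
)

grade, sv, systole = 2.5, 70.0, 0.288
frac = mr_to_regurg_fraction(grade)
area = size_regurg_orifice(sv, frac, systole, target_jet_velocity=4.0)
mv = ValveSpec("mitral", regurg_area=area)

print(f"MR grade {grade}  ->  regurgitation fraction {100 * frac:.0f}% of SV")
print(f"regurgitant volume       : {sv * frac:.1f} ml per beat")
print(f"regurgitant orifice area : {area:.2f} cm² (4 m/s jet)")
print(f"mitral valve             : {mv.opened_area} cm² open, "
      f"{1e3 * mv.opening_duration:.0f}/{1e3 * mv.closing_duration:.0f} ms ramps")

por = BafflePorosity(alpha=1.0, beta=0.0, rho=1050.0)
for v in (0.5, 1.0, 2.0):
    print(f"baffle drop at v_n = {v:.1f} m/s : {baffle_pressure_drop(v, por):8.0f} Pa")

print("\nshear rate (1/s)   viscosity (Pa·s)")
for g in (0.0, 0.1, 1.0, 10.0, 100.0, 1000.0):
    print(f"{g:12.1f}     {apparent_viscosity(g):10.4f}")
print("blood thins from 0.16 Pa·s at rest toward 0.0035 Pa·s at high shear.")
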