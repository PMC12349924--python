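"""Derive the SI interpretation of the reduced units.

The model measures length in sigma (bead size), time in tau and energy
in eps.  Comparing the model membrane with a real one — 5 nm vs 5 sigma
thickness, 5 um^2/s vs 1e-2 sigma^2/tau lipid diffusion, 310 K at a
simulated 1.1 eps/kB — pins all three units.
"""

from nanospin import convert, derive_unit_system
from nanospin.units import si_interpretation_table

units = derive_unit_system(
    membrane_thickness_physical=5e-9,   # m
    membrane_thickness_model=5.0,       # sigma
    D_physical=5e-12,                   # m^2/s  (5 um^2/s)
    D_model=1e-2,                       # sigma^2/tau
    T_physical=310.0,                   # K
    T_model=1.1,                        # eps/kB
)

print("derived unit system:")
for name, value, unit in si_interpretation_table(units):
    print(f"  1 {name:<15} = {value:.6g} {unit}")

tension = convert(26.4, "pressure_2d", "reduced_to_si", units)
print(f"\na stretching modulus of 26.4 eps/sigma^2 is {tension * 1e3:.1f} mN/m")
# Expected output: sigma = 1 nm, tau = 2 ns, eps = 3.89e-21 J, so
# 1 eps/sigma^2 = 3.89 mN/m and 26.4 eps/sigma^2 ~ 103 mN/m — the range
# measured for fluid lipid membranes.
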