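"""Unit constants and conversions.

Internally everything is SI (m, m3, s, Pa, kg). Clinical parameters are
usually quoted in litres and cmH2O; convert at the interface.
"""

CMH2O_PER_PA = 1.0 / 98.0665
PA_PER_CMH2O = 98.0665

L_PER_M3 = 1000.0
M3_PER_L = 1.0e-3

#: acceleration due to gravity, m s^-2 (acts along -z)
GRAVITY = 9.81

#: Boltzmann constant, J K^-1
K_BOLTZMANN = 1.380649e-23

#: body temperature, K
BODY_TEMPERATURE = 310.15

#: dynamic viscosity of air at body temperature, Pa s
AIR_VISCOSITY = 1.9e-5

#: mean free path of air molecules at body conditions, m
AIR_MEAN_FREE_PATH = 68e-9

#: diffusivity of N2 in O2 at 37 C, m2 s^-1
D_N2_IN_O2 = 2.3e-5


def elastance_cmh2o_per_l_to_si(e: float) -> float:
    """cmH2O/l -> Pa/m3."""
    return e * PA_PER_CMH2O / M3_PER_L


def elastance_si_to_cmh2o_per_l(e: float) -> float:
    """Pa/m3 -> cmH2O/l."""
    return e * CMH2O_PER_PA * M3_PER_L
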