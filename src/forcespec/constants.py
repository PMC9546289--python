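"""Physical constants and unit conventions.

The repository-wide unit system is nm, pN, s, K. Young's moduli are quoted in
kPa (1 kPa = 1e-3 pN/nm^2) and mechanical work in fJ (1 fJ = 1e6 pN*nm); the
conversions happen only at reporting boundaries.
"""

#: Boltzmann constant in pN*nm/K.
KB_PN_NM_PER_K = 0.0138065

#: kPa expressed in pN/nm^2.
KPA_TO_PN_PER_NM2 = 1e-3

#: pN*nm expressed in fJ.
PN_NM_TO_FJ = 1e-6


def kbt(temperature_K: float) -> float:
    """Thermal energy k_B*T in pN*nm at the given temperature in kelvin."""
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K}")
    return KB_PN_NM_PER_K * temperature_K
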