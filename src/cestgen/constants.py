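"""Physical constants and unit helpers.

All internal angular frequencies are rad/s; chemical shifts and saturation
offsets are expressed in ppm relative to the water resonance (positive =
downfield) and converted with ``gamma * B0 * 1e-6``.
"""

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H = 267.5221874e6

#: Water proton concentration in mM (2 * 55.5 M), used to convert a solute
#: concentration and exchangeable-proton count into a proton volume fraction.
WATER_PROTON_MM = 110_000.0

#: Static fields (T) for which scenario presets are defined.
SUPPORTED_B0 = (3.0, 4.7, 7.0, 9.4, 11.7)


def ppm_to_rad(ppm, b0_t, gamma=GAMMA_H):
    """Convert an offset in ppm to rad/s at field ``b0_t``."""
    return ppm * 1e-6 * gamma * b0_t


def ut_to_rad(b1_ut, gamma=GAMMA_H):
    """Convert a B1 amplitude in microtesla to a nutation rate omega_1 (rad/s)."""
    return b1_ut * 1e-6 * gamma
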