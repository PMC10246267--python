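"""Physical constants and unit conventions.

Units used throughout the package: mV, ms, uA, mM.  Temperature is kept in
kelvin; the default corresponds to the 11.5 degC bath used for all synthetic
recordings.
"""

# CODATA 2018
R_GAS = 8.31446261815324       # J / (mol K)
FARADAY = 96485.33212          # C / mol
E0 = 1.602176634e-19           # C, elementary charge

T_DEFAULT = 284.65             # K  (11.5 degC)


def thermal_voltage_mV(temperature: float = T_DEFAULT) -> float:
    """RT/F in millivolts (~24.53 mV at 11.5 degC)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return 1000.0 * R_GAS * temperature / FARADAY
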