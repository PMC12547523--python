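"""Physical constants (CODATA 2018 exact values where defined)."""

#: Universal gas constant, J mol^-1 K^-1
R = 8.314462618

#: Boltzmann constant, J K^-1
KB = 1.380649e-23

#: Planck constant, J s
PLANCK = 6.62607015e-34

#: Celsius -> Kelvin offset
T0_CELSIUS = 273.15
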