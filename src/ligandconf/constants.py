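"""Physical constants in the unit system used throughout: kcal/mol, K, s, Hz.

All energies are kcal/mol and all first-order rates are 1/s, matching the
conventions of variable-temperature NMR kinetics.
"""

#: Gas constant, kcal/(mol K).
R_KCAL = 1.9872e-3

#: Boltzmann constant over Planck constant, 1/(s K); kB*T/h is the Eyring
#: attempt frequency (~6.25e12 /s at 300 K).
KB_OVER_H = 1.380649e-23 / 6.62607015e-34

#: ln(2), for half-life <-> rate conversions t_half = ln(2)/k.
import math

LN2 = math.log(2.0)
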