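"""Physical constants and unit conventions.

Energies are kcal/mol, lengths Å (or dimensionless toy coordinates),
time ps, temperature kelvin, mass amu.
"""

#: Boltzmann constant, kcal/(mol K)
KB = 0.0019872041

#: Conversion (kcal/mol)/Å / amu -> Å/ps^2, i.e. 1 kcal/mol = 418.4 amu Å^2/ps^2
FORCE_TO_ACC = 418.4
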