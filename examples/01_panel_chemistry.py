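"""Analyte panel chemistry: molecular weights and fluorine mass fractions.

The registry holds the targeted PFAS panel (formula, chemical class,
perfluorinated-carbon count, internal-standard assignment).  Fluorine mass
fractions are what convert a targeted concentration (ng analyte/g tissue)
into a fluorine equivalent (ng F/g) for the organofluorine mass balance.
"""

from liverpfas import default_panel, fluorine_mass_fraction, molecular_weight

panel = default_panel()
print(f"panel: {len(panel)} analytes across {len(panel.classes())} chemical classes\n")

print(f"{'analyte':<14} {'class':<18} {'MW g/mol':>9} {'F fraction':>11}")
for name in ["PFBA", "PFOA", "L-PFOS", "8:2 FTS", "FOSA", "9Cl-PF3ONS", "PFECHS"]:
    a = panel.get(name)
    print(f"{name:<14} {a.chem_class:<18} {molecular_weight(a):>9.2f} {fluorine_mass_fraction(a):>11.4f}")

print(
    "\nThe fluorine fraction is (F count x 18.998)/MW: e.g. PFOA carries ~69% "
    "of its mass as fluorine, so 1 ng/g PFOA contributes ~0.69 ng F/g to the "
    "extractable organofluorine budget."
)
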