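"""Chemical constants for DEHP and its four measured urinary metabolites.

Molecular weights are formula masses computed from IUPAC 2021 standard atomic
weights (C 12.011, H 1.008, O 15.999), in g/mol:

    DEHP   di(2-ethylhexyl) phthalate            C24H38O4
    MEHP   mono(2-ethylhexyl) phthalate          C16H22O4
    MEHHP  mono(2-ethyl-5-hydroxyhexyl) phthalate C16H22O5
    MEOHP  mono(2-ethyl-5-oxohexyl) phthalate    C16H20O5
    MECPP  mono(2-ethyl-5-carboxypentyl) phthalate C16H20O6
"""

_C, _H, _O = 12.011, 1.008, 15.999


def formula_mass(c: int, h: int, o: int) -> float:
    """Formula mass in g/mol of a C/H/O compound."""
    return c * _C + h * _H + o * _O


MW_DEHP = formula_mass(24, 38, 4)

METABOLITES = ("MEHP", "MEHHP", "MEOHP", "MECPP")

MW_METABOLITE = {
    "MEHP": formula_mass(16, 22, 4),
    "MEHHP": formula_mass(16, 22, 5),
    "MEOHP": formula_mass(16, 20, 5),
    "MECPP": formula_mass(16, 20, 6),
}
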