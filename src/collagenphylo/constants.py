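"""Physical constants for peptide mass calculation.

Monoisotopic residue masses (Da) for the 20 standard amino acids, plus the
masses of water, a proton, and the two collagen-relevant modifications:
hydroxylation (O addition, e.g. proline -> hydroxyproline) and deamidation
(N/Q -> D/E, +0.984016 Da).
"""

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Monoisotopic residue (i.e. dehydrated) masses, Da.
RESIDUE_MASS = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

WATER_MASS = 18.010565
PROTON_MASS = 1.007276
HYDROXYLATION_MASS = 15.994915
DEAMIDATION_MASS = 0.984016

#: Unknown residue used throughout the alignment machinery.
UNKNOWN = "X"
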