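{
  "comment": "Average residue masses (Da) and Bjellqvist-style pKa values as used by the common ExPASy/ProtParam-family calculators.",
  "water_mass": 18.01524,
  "average_residue_mass": {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    "X": 110.0
  },
  "pka_positive": {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
  "pka_negative": {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
}
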