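"""Monoisotopic masses (IUPAC/CODATA) used for MRM transition arithmetic.

All values in Da. Kept in one place so every m/z in the package derives
from the same constants.
"""

MASS_H = 1.00782503207
MASS_C = 12.0
MASS_O = 15.9949146196
MASS_P = 30.97376163

MASS_PROTON = 1.007276466879
MASS_ELECTRON = 0.000548579909
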