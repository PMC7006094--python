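"""Grantham (1974) amino-acid substitution distances.

Physicochemical dissimilarity between amino-acid pairs, combining
composition, polarity and molecular volume. Symmetric, zero on the diagonal,
positive off-diagonal; the range runs from 5 (Leu-Ile) to 215 (Cys-Trp).
Used as a severity feature for missense substitutions.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

#: residue order of the published table
_ORDER = "SRLPTAVGIFYCHQNKDEMW"

# upper triangle, row i against columns i+1.. in _ORDER
_UPPER = """
110 145 74 58 99 124 56 142 155 144 112 89 68 46 121 65 80 135 177
102 103 71 112 96 125 97 97 77 180 29 43 86 26 96 54 91 101
98 92 96 32 138 5 22 36 198 99 113 153 107 172 138 15 61
38 27 68 42 95 114 110 169 77 76 91 103 108 93 87 147
58 69 59 89 103 92 149 47 42 65 78 85 65 81 128
64 60 94 113 112 195 86 91 111 106 126 107 84 148
109 29 50 55 192 84 96 133 97 152 121 21 88
135 153 147 159 98 87 80 127 94 98 127 184
21 33 198 94 109 149 102 168 134 10 61
22 205 100 116 158 102 177 140 28 40
194 83 99 143 85 160 122 36 37
174 154 139 202 154 170 196 215
24 68 32 81 40 87 115
46 53 61 29 101 130
94 23 42 142 174
101 56 95 110
45 160 181
126 152
67
""".split("\n")

GRANTHAM: Dict[Tuple[str, str], float] = {}
for _i, _row in enumerate(r for r in _UPPER if r.strip()):
    for _j, _value in enumerate(_row.split()):
        a, b = _ORDER[_i], _ORDER[_i + 1 + _j]
        GRANTHAM[(a, b)] = GRANTHAM[(b, a)] = float(_value)
for _a in _ORDER:
    GRANTHAM[(_a, _a)] = 0.0


def grantham(ref_aa: str, alt_aa: str) -> Optional[float]:
    """Distance between two standard amino acids (one-letter codes).

    Returns None (feature missing) for stop codons or non-standard codes.
    """
    key = (ref_aa.upper(), alt_aa.upper())
    return GRANTHAM.get(key)
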