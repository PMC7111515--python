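"""A default 27-state epigenetic state model for the synthetic generator.

Each state is a recurring combination of eight epigenetic features (nuclease
accessibility, four activating histone marks, two repressive marks, CTCF).
The table gives every state a short label, mean signal emissions per feature,
an accessibility flag (does the state correspond to nuclease-open chromatin),
and ground-truth regression coefficients for the promoter and distal-cCRE
contexts of the expression model.  Signs follow the usual biology: promoter-
and enhancer-like states push expression up, Polycomb and heterochromatin
push it down, and the quiescent state 0 is the reference with both
coefficients fixed at 0.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

FEATURES: Tuple[str, ...] = (
    "atac", "h3k4me3", "h3k4me1", "h3k27ac", "h3k36me3", "h3k27me3", "h3k9me3", "ctcf",
)

# label, accessible, (atac, k4me3, k4me1, k27ac, k36me3, k27me3, k9me3, ctcf), beta_prom, beta_ccre
_TABLE: List[Tuple[str, bool, Tuple[float, ...], float, float]] = [
    ("Q",    False, (0, 0, 0, 0, 0, 0, 0, 0),  0.0,  0.0),   # 0 quiescent
    ("T",    False, (0, 0, 0, 0, 6, 0, 0, 0),  0.3,  0.3),   # 1 transcribed
    ("Ts",   False, (0, 0, 0, 0, 9, 0, 0, 0),  0.5,  0.5),   # 2 strongly transcribed
    ("PcG",  False, (0, 0, 0, 0, 0, 7, 0, 0), -2.0, -2.0),   # 3 Polycomb repressed
    ("H",    False, (0, 0, 0, 0, 0, 0, 7, 0), -1.5, -1.5),   # 4 heterochromatin
    ("HT",   False, (0, 0, 0, 0, 5, 0, 5, 0), -0.8, -0.8),   # 5 het + transcribed
    ("PcW",  False, (0, 0, 0, 0, 0, 3, 0, 0), -1.0, -1.2),   # 6 weak Polycomb
    ("C",    False, (0, 0, 0, 0, 0, 0, 0, 7),  0.2, -0.8),   # 7 CTCF only
    ("E",    False, (0, 0, 5, 0, 0, 0, 0, 0),  0.8,  1.2),   # 8 enhancer-like
    ("EN",   True,  (5, 0, 6, 0, 0, 0, 0, 0),  0.6,  4.5),   # 9 poised enhancer, open
    ("PA",   True,  (7, 8, 0, 7, 0, 0, 0, 0),  4.0,  5.0),   # 10 active promoter, open
    ("P",    False, (0, 6, 0, 0, 0, 0, 0, 0),  3.0,  1.5),   # 11 promoter-like
    ("EA",   True,  (6, 0, 6, 7, 0, 0, 0, 0),  1.8,  6.0),   # 12 active enhancer, open
    ("CN",   True,  (6, 0, 0, 0, 0, 0, 0, 7),  0.4, -4.5),   # 13 CTCF + open
    ("EAT",  False, (0, 0, 5, 5, 5, 0, 0, 0),  1.2,  2.4),   # 14 active enhancer in gene body
    ("PN",   True,  (6, 7, 0, 0, 0, 0, 0, 0),  3.4,  4.8),   # 15 open promoter, no K27ac
    ("B",    False, (0, 5, 0, 0, 0, 5, 0, 0),  0.5, -0.3),   # 16 bivalent promoter
    ("EC",   False, (0, 0, 5, 0, 0, 0, 0, 5),  0.6,  1.4),   # 17 enhancer + CTCF
    ("PAT",  True,  (6, 8, 0, 6, 5, 0, 0, 0),  3.8,  5.2),   # 18 active promoter, transcribed
    ("TE",   False, (0, 0, 4, 0, 6, 0, 0, 0),  0.9,  1.1),   # 19 transcribed enhancer
    ("EW",   False, (0, 0, 3, 0, 0, 0, 0, 0),  0.4,  0.6),   # 20 weak enhancer
    ("PAC",  True,  (7, 8, 0, 7, 0, 0, 0, 6),  3.9,  5.4),   # 21 active promoter + CTCF
    ("HW",   False, (0, 0, 0, 0, 0, 0, 4, 0), -1.0, -1.0),   # 22 weak heterochromatin
    ("PcT",  False, (0, 0, 0, 0, 4, 5, 0, 0), -1.2, -1.4),   # 23 Polycomb + transcribed
    ("PAE",  True,  (7, 7, 5, 7, 0, 0, 0, 0),  3.6,  5.8),   # 24 promoter/enhancer mixed, open
    ("BN",   True,  (5, 5, 0, 0, 0, 5, 0, 0),  0.3, -4.0),   # 25 open bivalent
    ("ECT",  False, (0, 0, 4, 0, 4, 0, 0, 4),  0.7,  1.0),   # 26 enhancer + CTCF, transcribed
]

N_STATES = len(_TABLE)
STATE_LABELS: Tuple[str, ...] = tuple(row[0] for row in _TABLE)
ACCESSIBLE_STATES = frozenset(i for i, row in enumerate(_TABLE) if row[1])
EMISSION_MEANS = np.array([row[2] for row in _TABLE], dtype=float)
BETA_PROMOTER = np.array([row[3] for row in _TABLE], dtype=float)
BETA_CCRE = np.array([row[4] for row in _TABLE], dtype=float)
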