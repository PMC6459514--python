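"""Published per-variant count data for the built-in cohort fixtures.

These are the printed zygosity counts from the source study's validation
set (49 Sanger-positive cases plus their compound findings), healthy
controls (n=50), and patient cohort (n=171 with compound-het pairs).
The fixture generators in :mod:`ligatyper.synth` expand them into
per-sample genotype truth sets.
"""

from __future__ import annotations

# --- validation set: 49 positive cases, (het, hom) per variant ------------
# MT-RNR1 c.1555A>G carriers are homoplasmic (counted under hom).
VALIDATION_COUNTS: dict[str, tuple[int, int]] = {
    "c.139G>T": (2, 0),
    "c.176_191del16": (1, 0),
    "c.235delC": (10, 6),
    "c.299_300delAT": (2, 0),
    "c.571T>G": (1, 0),
    "IVS7-2A>G": (3, 3),
    "c.1174A>T": (1, 0),
    "c.1229C>T": (2, 0),
    "c.2168A>G": (3, 0),
    "c.1555A>G": (0, 11),
    "c.580G>A": (1, 0),
    "c.812G>A": (1, 0),
    "c.650G>T": (1, 0),
    "c.505G>A": (1, 0),
}

# --- validation set compound findings: (primary, added second, n) ----------
# The second variant is layered onto a sample already carrying the first
# as its primary finding; cross-gene rows are dual-gene findings.
VALIDATION_PAIRS: list[tuple[str, str, int]] = [
    ("IVS7-2A>G", "c.2168A>G", 1),
    ("c.235delC", "c.299_300delAT", 2),
    ("c.235delC", "c.1555A>G", 1),
    ("c.235delC", "IVS7-2A>G", 1),
    ("c.580G>A", "c.1555A>G", 1),
    ("c.571T>G", "c.1174A>T", 1),
    ("c.1229C>T", "c.2168A>G", 2),
]

# --- controls: 50 samples, heterozygous carrier counts ---------------------
CONTROL_COUNTS: dict[str, int] = {
    "c.176_191del16": 1,
    "c.235delC": 1,
    "c.299_300delAT": 1,
    "IVS7-2A>G": 2,
}
CONTROL_N = 50

# --- patient cohort: 171 samples, (hom, het) per variant -------------------
COHORT_COUNTS: dict[str, tuple[int, int]] = {
    "c.176_191del16": (0, 1),
    "c.235delC": (12, 4),
    "c.299_300delAT": (2, 9),
    "c.571T>G": (0, 2),
    "c.538C>T": (0, 1),
    "c.580G>A": (0, 6),
    "IVS7-2A>G": (2, 4),
    "c.1229C>T": (0, 4),
    "IVS15+5G>A": (0, 1),
    "c.2168A>G": (0, 3),
    "c.1494C>T": (1, 0),
    "c.1555A>G": (5, 0),
}
COHORT_PAIRS: list[tuple[str, str, int]] = [
    ("IVS7-2A>G", "c.1229C>T", 1),
    ("IVS7-2A>G", "c.2168A>G", 1),
    ("c.235delC", "c.176_191del16", 1),
    ("c.235delC", "c.299_300delAT", 6),
]
COHORT_N = 171
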