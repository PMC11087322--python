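"""Independent oracles used by the test suite.

Everything here is deliberately scalar / brute-force and shares no code
with the package: per-pixel math-module CIELAB conversion, exhaustive
pixel tallies, and a hand-typed codon table.
"""

import math

import numpy as np

# --- scalar sRGB -> CIELAB, written from the standard formulas ------------

_M = (
    (0.4124564, 0.3575761, 0.1804375),
    (0.2126729, 0.7151522, 0.0721750),
    (0.0193339, 0.1191920, 0.9503041),
)
_WHITE = (95.047, 100.000, 108.883)


def _decode(u):
    u = u / 255.0
    return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4


def _f(t):
    d = 6.0 / 29.0
    return t ** (1.0 / 3.0) if t > d**3 else t / (3 * d * d) + 4.0 / 29.0


def scalar_srgb_to_lab(r, g, b):
    """One 8-bit sRGB triplet -> (L*, a*, b*), pure-math implementation."""
    lin = (_decode(r), _decode(g), _decode(b))
    xyz = [100.0 * sum(m * v for m, v in zip(row, lin)) for row in _M]
    fx, fy, fz = (_f(c / w) for c, w in zip(xyz, _WHITE))
    return 116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)


# --- brute-force pixel geometry -------------------------------------------

def disk_pixel_count(cx, cy, radius, width, height):
    """Pixels whose centers lie within `radius` of (cx, cy), by enumeration."""
    n = 0
    for y in range(height):
        for x in range(width):
            if (x - cx) ** 2 + (y - cy) ** 2 <= radius**2:
                n += 1
    return n


def disk_mask(cx, cy, radius, width, height):
    out = np.zeros((height, width), dtype=bool)
    for y in range(height):
        for x in range(width):
            if (x - cx) ** 2 + (y - cy) ** 2 <= radius**2:
                out[y, x] = True
    return out


def count_in_circle_brute(mask, cx, cy, radius):
    h, w = mask.shape
    n = 0
    for y in range(h):
        for x in range(w):
            if mask[y, x] and (x - cx) ** 2 + (y - cy) ** 2 <= radius**2:
                n += 1
    return n


# --- hand-typed standard genetic code (NCBI table 1) ----------------------

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


def translate_brute(dna):
    return "".join(CODON_TABLE[dna[i : i + 3]] for i in range(0, len(dna), 3))
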