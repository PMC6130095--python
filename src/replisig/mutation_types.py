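"""Canonical mutation-type spaces and trinucleotide index tables.

Somatic single-nucleotide variants are classified by the pyrimidine of the
mutated Watson-Crick base pair and its immediate 5'/3' context, giving 96
contextual substitution types (6 pyrimidine substitutions x 16 flanking-base
combinations).  Adding the replication template strand of the pyrimidine
(leading vs lagging) doubles the space to 192 strand-resolved types.

Orderings follow the COSMIC convention: substitution groups C>A, C>G, C>T,
T>A, T>C, T>G; within a group the 5' base varies first, then the 3' base,
both alphabetically.  The 192-type space puts the whole leading block
(indices 0-95) before the lagging block (96-191).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_TO_INT = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_INT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TEMPLATES = ("leading", "lagging")

N_TYPES_96 = 96
N_TYPES_192 = 192
N_TRINUC_32 = 32
N_TRINUC_64 = 64

# substitution index from (ref_int, alt_int), pyrimidine ref only; -1 invalid
_SUB_INDEX = -np.ones((4, 4), dtype=np.int8)
_SUB_INDEX[1, 0] = 0  # C>A
_SUB_INDEX[1, 2] = 1  # C>G
_SUB_INDEX[1, 3] = 2  # C>T
_SUB_INDEX[3, 0] = 3  # T>A
_SUB_INDEX[3, 1] = 4  # T>C
_SUB_INDEX[3, 2] = 5  # T>G


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def type96_index(sub: int, five: int, three: int) -> int:
    """Canonical 0-95 index from substitution group and flanking base ints."""
    return sub * 16 + five * 4 + three


def type96_label(idx: int) -> str:
    sub, rest = divmod(idx, 16)
    five, three = divmod(rest, 4)
    return f"{BASES[five]}[{SUBSTITUTIONS[sub]}]{BASES[three]}"


def type192_index(idx96: int, template: str) -> int:
    return idx96 + (0 if template == "leading" else 96)


def type192_unpack(idx192: int) -> tuple[int, str]:
    return idx192 % 96, TEMPLATES[idx192 // 96]


def type192_label(idx192: int) -> str:
    idx96, template = type192_unpack(idx192)
    return f"{type96_label(idx96)}_{template}"


TYPE96_LABELS = tuple(type96_label(i) for i in range(N_TYPES_96))
TYPE192_LABELS = tuple(type192_label(i) for i in range(N_TYPES_192))

#: pyrimidine-centric trinucleotide (32-space) of each 96-type:
#: center C for groups 0-2, center T for groups 3-5.
TYPE96_TO_TRINUC32 = np.array(
    [(0 if i // 16 < 3 else 16) + (i % 16) for i in range(N_TYPES_96)],
    dtype=np.int64,
)

TRINUC32_LABELS = tuple(
    f"{BASES[(i % 16) // 4]}{'C' if i < 16 else 'T'}{BASES[i % 4]}"
    for i in range(N_TRINUC_32)
)


def encode_bases(seq: str) -> np.ndarray:
    """Uppercase DNA string -> int8 array (A=0,C=1,G=2,T=3, other=-1)."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_TO_INT.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def trinuc64_codes(encoded: np.ndarray) -> np.ndarray:
    """Plus-strand 3-mer code (16*a + 4*b + c) centered on every position.

    Positions whose window touches a sequence end or a non-ACGT base get -1.
    """
    out = np.full(encoded.shape[0], -1, dtype=np.int64)
    if encoded.shape[0] < 3:
        return out
    a, b, c = encoded[:-2], encoded[1:-1], encoded[2:]
    valid = (a >= 0) & (b >= 0) & (c >= 0)
    codes = 16 * a.astype(np.int64) + 4 * b + c
    out[1:-1] = np.where(valid, codes, -1)
    return out


def _build_trinuc64_maps() -> tuple[np.ndarray, np.ndarray]:
    """Per 64-code: pyrimidine-centric 32-index and whether the plus-strand
    center base is itself the pyrimidine (else the reverse complement is
    used)."""
    to32 = np.zeros(N_TRINUC_64, dtype=np.int64)
    center_is_pyr = np.zeros(N_TRINUC_64, dtype=bool)
    for code in range(N_TRINUC_64):
        a, rest = divmod(code, 16)
        b, c = divmod(rest, 4)
        if b in (1, 3):  # C or T
            to32[code] = (0 if b == 1 else 16) + a * 4 + c
            center_is_pyr[code] = True
        else:  # G or A: reverse complement
            ra, rb, rc = 3 - c, 3 - b, 3 - a
            to32[code] = (0 if rb == 1 else 16) + ra * 4 + rc
    return to32, center_is_pyr


TRINUC64_TO_PYR32, TRINUC64_CENTER_IS_PYR = _build_trinuc64_maps()

#: 64-code of the pyrimidine-centric representative of each 32-trinuc
TRINUC32_TO_CODE64 = np.array(
    [16 * BASE_TO_INT[t[0]] + 4 * BASE_TO_INT[t[1]] + BASE_TO_INT[t[2]]
     for t in TRINUC32_LABELS],
    dtype=np.int64,
)


def classify_arrays(
    ref: np.ndarray, alt: np.ndarray, ctx5: np.ndarray, ctx3: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 96-type classification from integer-encoded plus-strand
    bases.

    Returns (type96, pyr_on_plus); type96 is -1 where ref/alt do not form a
    valid SNV or the context is invalid.  Purine references are reverse
    complemented together with their context.
    """
    ref = ref.astype(np.int64)
    alt = alt.astype(np.int64)
    ctx5 = ctx5.astype(np.int64)
    ctx3 = ctx3.astype(np.int64)
    valid = (
        (ref >= 0) & (alt >= 0) & (ctx5 >= 0) & (ctx3 >= 0) & (ref != alt)
    )
    pyr_on_plus = (ref == 1) | (ref == 3)
    comp = COMPLEMENT_INT.astype(np.int64)
    r = np.where(pyr_on_plus, ref, comp[np.clip(ref, 0, 3)])
    a = np.where(pyr_on_plus, alt, comp[np.clip(alt, 0, 3)])
    f = np.where(pyr_on_plus, ctx5, comp[np.clip(ctx3, 0, 3)])
    t = np.where(pyr_on_plus, ctx3, comp[np.clip(ctx5, 0, 3)])
    sub = _SUB_INDEX[np.clip(r, 0, 3), np.clip(a, 0, 3)].astype(np.int64)
    out = np.where(valid & (sub >= 0), sub * 16 + f * 4 + t, -1)
    return out, pyr_on_plus
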