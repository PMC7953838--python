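"""Low-level DNA utilities shared across the pipeline.

Sequences travel in two representations: plain Python strings (IO boundaries)
and numpy uint8 code arrays with A=0, C=1, G=2, T=3 and 4 for anything else
(internal compute). All internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

# byte -> 2-bit code, 4 marks non-ACGT (N, separators, ...)
CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    CODE_LUT[ord(_b)] = _i
    CODE_LUT[ord(_b.lower())] = _i

DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 codes (non-ACGT -> 4)."""
    return CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return DECODE_LUT[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def random_codes(rng: np.random.Generator, length: int, gc_content: float = 0.5) -> np.ndarray:
    """Random sequence codes with the requested GC fraction (C and G equiprobable)."""
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    return rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.uint8)


def mutate_codes(
    rng: np.random.Generator, codes: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """Substitute bases at ``positions`` uniformly among the three other bases.

    Returns a new array; the input is left untouched.
    """
    out = codes.copy()
    if len(positions):
        shift = rng.integers(1, 4, size=len(positions)).astype(np.uint8)
        out[positions] = (out[positions] + shift) % 4
    return out


# --- ORF-like gene sequences -------------------------------------------------

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in _STOP_CODONS and a + b + c != "ATG"
]


def random_orf(rng: np.random.Generator, length: int = 900) -> str:
    """Random single-exon ORF: ATG + stop-free codons + TAA, ``length`` bp total."""
    if length % 3 != 0 or length < 9:
        raise ValueError("ORF length must be a multiple of 3 and >= 9")
    n_inner = length // 3 - 2
    inner = rng.choice(len(_SENSE_CODONS), size=n_inner)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in inner) + "TAA"


_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    _CODON_TABLE.update(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        _CODON_TABLE[stop] = "*"


def translate(seq: str) -> str:
    """Translate frame 1 with the standard code; trailing stop stripped."""
    if not _CODON_TABLE:
        _build_codon_table()
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aas.append(_CODON_TABLE.get(seq[i : i + 3], "X"))
    prot = "".join(aas)
    return prot[:-1] if prot.endswith("*") else prot


_AA_TO_CODONS: dict[str, list[str]] = {}


def reverse_translate(rng: np.random.Generator, protein: str) -> str:
    """Back-translate a protein with uniformly random synonymous codons + TAA stop."""
    if not _CODON_TABLE:
        _build_codon_table()
    if not _AA_TO_CODONS:
        for codon, aa in _CODON_TABLE.items():
            _AA_TO_CODONS.setdefault(aa, []).append(codon)
    codons = []
    for aa in protein:
        choices = _AA_TO_CODONS[aa]
        codons.append(choices[rng.integers(len(choices))])
    return "".join(codons) + "TAA"


def random_protein(rng: np.random.Generator, length: int) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    idx = rng.integers(0, len(aas), size=length)
    return "".join(aas[i] for i in idx)
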