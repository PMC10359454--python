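"""Low-level sequence utilities shared across the package.

Sequences are handled in two representations: Python strings for IO and
small fixtures, and numpy ``uint8`` code matrices (A=0, C=1, G=2, T=3) for
bulk per-position work on hundreds of thousands of molecules.
"""

from __future__ import annotations

from itertools import product

import numpy as np

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3

#: All 256 NNCGNN contexts in lexicographic order.
ALL_NNCGNN: tuple[str, ...] = tuple(
    f"{n1}{n2}CG{n3}{n4}" for n1, n2, n3, n4 in product(BASES, repeat=4)
)
NNCGNN_INDEX: dict[str, int] = {ctx: i for i, ctx in enumerate(ALL_NNCGNN)}

# byte value -> code; 255 marks anything that is not ACGT (N, gaps, ...)
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_DEC = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as a uint8 code array (non-ACGT -> 255)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_many(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) code matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    joined = "".join(seqs)
    mat = _ENC[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    return mat.reshape(len(seqs), -1)


def decode(codes: np.ndarray) -> str:
    """Decode a 1-D code array back to a string (255 -> N)."""
    out = np.where(codes < 4, _DEC[np.minimum(codes, 3)], ord("N")).astype(np.uint8)
    return out.tobytes().decode("ascii")


def decode_rows(mat: np.ndarray) -> list[str]:
    out = np.where(mat < 4, _DEC[np.minimum(mat, 3)], ord("N")).astype(np.uint8)
    flat = out.tobytes().decode("ascii")
    n, width = mat.shape
    return [flat[i * width : (i + 1) * width] for i in range(n)]


def complement_codes(mat: np.ndarray) -> np.ndarray:
    """Complement of a code matrix (A<->T, C<->G); 255 stays 255."""
    return np.where(mat < 4, 3 - mat, mat).astype(np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence string."""
    return "".join(_COMP.get(b, "N") for b in reversed(seq.upper()))


def context_index_from_codes(flank_codes: np.ndarray) -> np.ndarray:
    """Map (n, 4) code arrays of the NN..NN flank bases to 0..255 indices.

    Columns are the bases at positions -2, -1, +1, +2 around the CpG.
    Rows containing a non-ACGT code map to -1.
    """
    ok = (flank_codes < 4).all(axis=1)
    vals = flank_codes.astype(np.int64)
    idx = ((vals[:, 0] * 4 + vals[:, 1]) * 4 + vals[:, 2]) * 4 + vals[:, 3]
    return np.where(ok, idx, -1)


def nncgnn_of(seq: str, cpg_pos: int) -> str:
    """NNCGNN 6-mer of ``seq`` around the CpG whose C sits at ``cpg_pos``."""
    ctx = seq[cpg_pos - 2 : cpg_pos + 4]
    if len(ctx) != 6 or ctx[2:4] != "CG":
        raise ValueError(f"no CpG at position {cpg_pos} of {seq!r}")
    return ctx
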