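"""DNA alphabet helpers shared across the package.

The scoring models operate on the strict four-letter alphabet A/C/G/T.
Inputs are canonicalized once at the boundary: lowercase is accepted,
'U' is treated as 'T' (RNA-style input), and anything else — including
IUPAC ambiguity codes — is rejected.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """A sequence contains characters outside the A/C/G/T alphabet."""


def canonical_seq(seq: str, *, length: int | None = None) -> str:
    """Uppercase, map U->T, and validate a DNA string.

    Parameters
    ----------
    seq : str
        Raw sequence.
    length : int, optional
        If given, the canonicalized sequence must have exactly this length.

    Raises
    ------
    AlphabetError
        On characters outside {A, C, G, T, U} (case-insensitive).
    ValueError
        On a length mismatch.
    """
    s = str(seq).strip().upper().replace("U", "T")
    bad = set(s) - set(BASES)
    if bad:
        raise AlphabetError(
            f"sequence {seq!r} contains characters outside ACGT: {sorted(bad)}"
        )
    if length is not None and len(s) != length:
        raise ValueError(f"expected a {length}-mer, got {len(s)} bases: {seq!r}")
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA string."""
    return canonical_seq(seq).translate(_COMPLEMENT)[::-1]


def seq_to_indices(seq: str) -> np.ndarray:
    """Map a canonical DNA string to row indices into an ACGT-ordered matrix."""
    return np.fromiter((BASE_INDEX[b] for b in seq), dtype=np.intp, count=len(seq))
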