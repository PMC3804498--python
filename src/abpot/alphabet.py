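"""The 20-letter amino-acid alphabet and integer encoding used throughout.

Framework alignments here are gapless by construction, so the alphabet is
exactly the 20 canonical residues — no gap symbol, no ambiguity codes
(X/B/Z/J/U/O are rejected at the I/O boundary).
"""

from __future__ import annotations

import numpy as np

#: Canonical residue order (alphabetical by one-letter code). All probability
#: and energy tables are indexed in this order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

N_AA: int = len(AMINO_ACIDS)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Lookup table from byte value to code; -1 marks a non-canonical letter.
_BYTE_TO_CODE = np.full(256, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _BYTE_TO_CODE[ord(_aa)] = _i


def encode(sequence: str) -> np.ndarray:
    """Encode a residue string to an int8 code array.

    Raises
    ------
    ValueError
        If any character is not one of the 20 canonical residues. The
        message reports the 1-based position of the first offender.
    """
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _BYTE_TO_CODE[raw]
    bad = np.nonzero(codes < 0)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"non-canonical residue {sequence[pos]!r} at position {pos + 1}"
        )
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return "".join(AMINO_ACIDS[int(c)] for c in codes)
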