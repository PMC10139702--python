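"""Amino-acid alphabet and integer encoding.

Residues are indexed in the classic PAML/Dayhoff order, which is also the
row order of the shipped empirical model files. Gap ('-') and ambiguity
('X') are encoded as :data:`MISSING` and treated as missing data throughout
(never as a 21st state).
"""

from __future__ import annotations

import numpy as np

#: One-letter residue codes in PAML matrix order.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

N_STATES = 20

#: Sentinel integer code for gap / unknown residues.
MISSING = -1

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Indices of the residues sorted alphabetically by one-letter code;
#: used for deterministic tie-breaking of posterior modes.
ALPHABETICAL_INDICES = tuple(sorted(range(N_STATES), key=lambda i: AA_ORDER[i]))

_MISSING_CHARS = frozenset("-X")


def encode(seq: str) -> np.ndarray:
    """Encode a residue string into integer codes (``MISSING`` for '-'/'X').

    Raises
    ------
    ValueError
        If the sequence contains a symbol outside the 20 one-letter codes,
        '-' and 'X' (case-insensitive).
    """
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        if ch in _MISSING_CHARS:
            out[i] = MISSING
        else:
            try:
                out[i] = AA_INDEX[ch]
            except KeyError:
                raise ValueError(
                    f"unknown residue symbol {ch!r} at column {i + 1}"
                ) from None
    return out


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; ``MISSING`` renders as '-'."""
    return "".join("-" if c == MISSING else AA_ORDER[c] for c in codes)
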