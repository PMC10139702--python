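"""Aligned protein sequences, encoded for the likelihood engine."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabet import MISSING, N_STATES, decode, encode

__all__ = ["AlignmentError", "ProteinAlignment"]


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, bad symbols, duplicates)."""


@dataclass
class ProteinAlignment:
    """Fixed-length amino-acid alignment.

    ``codes`` is an (n_sequences, length) int8 matrix over residue indices
    0..19 with :data:`~convscan.alphabet.MISSING` for '-' and 'X'.
    """

    names: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.names):
            raise AlignmentError("codes matrix does not match sequence names")
        if self.length < 1:
            raise AlignmentError("alignment must have at least one column")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("duplicate sequence names")
        self._index = {name: i for i, name in enumerate(self.names)}

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    def row(self, name: str) -> np.ndarray:
        try:
            return self.codes[self._index[name]]
        except KeyError:
            raise AlignmentError(f"sequence {name!r} not in alignment") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def sequence(self, name: str) -> str:
        return decode(self.row(name))

    def residue_counts(self) -> np.ndarray:
        """Counts of each of the 20 residues over the whole alignment."""
        flat = self.codes[self.codes != MISSING]
        return np.bincount(flat.astype(np.int64), minlength=N_STATES).astype(float)

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "ProteinAlignment":
        names = list(sequences)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        rows = []
        for name in names:
            try:
                rows.append(encode(sequences[name]))
            except ValueError as exc:
                raise AlignmentError(f"sequence {name!r}: {exc}") from exc
        return cls(names=names, codes=np.vstack(rows))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProteinAlignment":
        path = Path(path)
        try:
            records = list(SeqIO.parse(str(path), "fasta"))
        except (OSError, ValueError) as exc:
            raise AlignmentError(f"{path}: cannot read FASTA: {exc}") from exc
        if not records:
            raise AlignmentError(f"{path}: no FASTA records found")
        seqs: dict[str, str] = {}
        for rec in records:
            if rec.id in seqs:
                raise AlignmentError(f"{path}: duplicate record {rec.id!r}")
            seqs[rec.id] = str(rec.seq)
        try:
            return cls.from_sequences(seqs)
        except AlignmentError as exc:
            raise AlignmentError(f"{path}: {exc}") from exc

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in self.names:
                fh.write(f">{name}\n{self.sequence(name)}\n")
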