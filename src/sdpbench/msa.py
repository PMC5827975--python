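"""Core containers for aligned protein families.

The package works on pre-aligned families: every sequence is a string over the
20 standard amino-acid letters plus ``-`` for a gap, and all sequences in one
family have equal length.  Columns are indexed 0-based internally; user-facing
tables are 1-based (stated in their headers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP

#: integer code used for the gap character in encoded alignments
GAP_CODE = -1

_CODE_LUT = np.full(128, -2, dtype=np.int8)
for _i, _a in enumerate(AMINO_ACIDS):
    _CODE_LUT[ord(_a)] = _i
_CODE_LUT[ord(GAP)] = GAP_CODE


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, bad symbols, dup ids)."""


@dataclass(frozen=True)
class TimedSequence:
    """One homolog: identifier, aligned residue string, publication year.

    ``publication_date`` is an integer calendar year (snapshots are taken on a
    grid of years); ``None`` marks a sequence that has not been dated yet.
    """

    seq_id: str
    residues: str
    publication_date: int | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlignmentError(f"empty residue string for {self.seq_id!r}")


class Alignment:
    """An in-memory MSA: ordered sequence ids plus an (N, L) character matrix."""

    def __init__(self, ids: Sequence[str], chars: np.ndarray):
        chars = np.asarray(chars, dtype="U1")
        if chars.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        if len(ids) != chars.shape[0]:
            raise AlignmentError("number of ids does not match matrix rows")
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if list(ids).count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dup}")
        self.ids: list[str] = list(ids)
        self.chars: np.ndarray = chars
        self._codes: np.ndarray | None = None

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        ids, seqs = [], []
        for sid, seq in records:
            ids.append(sid)
            seqs.append(seq.upper())
        if not ids:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            bad = next(i for i, s in zip(ids, seqs) if len(s) != len(seqs[0]))
            raise AlignmentError(f"ragged alignment (offending record: {bad!r})")
        chars = np.array([list(s) for s in seqs], dtype="U1")
        aln = cls(ids, chars)
        aln.validate()
        return aln

    @classmethod
    def from_timed(cls, seqs: Sequence[TimedSequence]) -> "Alignment":
        return cls.from_records((s.seq_id, s.residues) for s in seqs)

    # -- basic properties --------------------------------------------------
    @property
    def n_sequences(self) -> int:
        return self.chars.shape[0]

    @property
    def n_columns(self) -> int:
        return self.chars.shape[1]

    def validate(self) -> None:
        codepoints = self.chars.view(np.uint32).reshape(self.chars.shape)
        bad = (codepoints >= 128) | (_CODE_LUT[np.minimum(codepoints, 127)] == -2)
        if bad.any():
            i = int(np.argwhere(bad)[0, 0])
            sym = self.chars[bad][0]
            raise AlignmentError(
                f"illegal symbol {sym!r} in record {self.ids[i]!r} "
                f"(allowed: {ALPHABET})"
            )

    def encoded(self) -> np.ndarray:
        """(N, L) int8 matrix: 0..19 for amino acids, -1 for gaps."""
        if self._codes is None:
            cp = self.chars.view(np.uint32).reshape(self.chars.shape)
            self._codes = _CODE_LUT[cp]
        return self._codes

    # -- accessors ---------------------------------------------------------
    def sequence(self, i: int) -> str:
        return "".join(self.chars[i])

    def column(self, p: int) -> str:
        return "".join(self.chars[:, p])

    def take(self, indices: Sequence[int]) -> "Alignment":
        idx = list(indices)
        return Alignment([self.ids[i] for i in idx], self.chars[idx])

    def __len__(self) -> int:
        return self.n_sequences

    def __iter__(self) -> Iterator[tuple[str, str]]:
        for i, sid in enumerate(self.ids):
            yield sid, self.sequence(i)

    def __repr__(self) -> str:
        return f"Alignment(n_sequences={self.n_sequences}, n_columns={self.n_columns})"
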