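"""Triangular base-pairing matrix for a window subsequence.

The matrix of a sequence ``s[0..n-1]`` has column ``j`` representing ``s[j]``
and row ``i`` representing ``s[n-1-i]``.  A cell ``(i, j)`` is positive iff
``s[j]`` and ``s[n-1-i]`` can pair; positive values record the length of the
contiguous paired run ending at the cell along its diagonal, so long exact
stems appear as runs of increasing integers on a diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .errors import InvalidAlphabetError, InvalidInputError

NUCLEOTIDES = "ACGU"

#: Allowed pairs: Watson-Crick plus the G-U wobble.  The wobble is required
#: so that the "percentage of GU pairing" feature can be non-zero.
COMPLEMENTARY_PAIRS = frozenset(
    {frozenset("AU"), frozenset("GC"), frozenset("GU")}
)

_INDEX = {b: k for k, b in enumerate(NUCLEOTIDES)}

_COMP_TABLE = np.zeros((4, 4), dtype=bool)
for _a, _b in [("A", "U"), ("G", "C"), ("G", "U")]:
    _COMP_TABLE[_INDEX[_a], _INDEX[_b]] = True
    _COMP_TABLE[_INDEX[_b], _INDEX[_a]] = True

#: Default minimum number of unpaired nucleotides in a terminal loop
#: (steric minimum for RNA).
MIN_LOOP = 3


def is_complementary(a: str, b: str) -> bool:
    """True iff nucleotides *a* and *b* can pair (Watson-Crick or G-U wobble).

    Symmetric in its arguments.  Raises :class:`InvalidAlphabetError` for
    characters outside ``{A, C, G, U}``.
    """
    if a not in _INDEX or b not in _INDEX:
        raise InvalidAlphabetError(
            f"non-nucleotide input: {a!r}, {b!r} (expected one of A, C, G, U)"
        )
    return bool(_COMP_TABLE[_INDEX[a], _INDEX[b]])


def normalize_residues(raw: str, *, record_id: str = "<anonymous>") -> str:
    """Uppercase, map T to U, and validate the alphabet.

    IUPAC ambiguity codes (and anything else outside ACGU) are rejected with
    an error naming the offending record and 0-based position.
    """
    residues = raw.upper().replace("T", "U")
    for pos, ch in enumerate(residues):
        if ch not in _INDEX:
            raise InvalidAlphabetError(
                f"record {record_id!r}: invalid character {ch!r} at position "
                f"{pos} (IUPAC ambiguity codes are not supported)"
            )
    return residues


@dataclass(frozen=True)
class RNASequence:
    """A normalized RNA sequence over {A, C, G, U}.

    ``origin`` optionally records provenance as
    ``(source sequence id, 0-based start offset, strand)``.
    """

    id: str
    residues: str
    origin: Optional[Tuple[str, int, str]] = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise InvalidInputError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues):
            if ch not in _INDEX:
                raise InvalidAlphabetError(
                    f"record {self.id!r}: invalid character {ch!r} at "
                    f"position {pos}"
                )

    @classmethod
    def from_string(
        cls,
        raw: str,
        id: str = "<anonymous>",
        origin: Optional[Tuple[str, int, str]] = None,
    ) -> "RNASequence":
        """Build a sequence from raw text, normalizing case and T->U."""
        if len(raw) < 1:
            raise InvalidInputError(f"record {id!r}: empty sequence")
        return cls(id=id, residues=normalize_residues(raw, record_id=id), origin=origin)

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, start: int, end: int, id: Optional[str] = None) -> "RNASequence":
        """0-based half-open slice carrying provenance in ``origin``."""
        if not (0 <= start < end <= len(self.residues)):
            raise InvalidInputError(
                f"slice [{start}, {end}) out of bounds for length {len(self)}"
            )
        return RNASequence(
            id=id if id is not None else f"{self.id}:{start}-{end}",
            residues=self.residues[start:end],
            origin=(self.id, start, "+"),
        )


def encode(residues: str) -> np.ndarray:
    """Encode residues as integer codes A=0, C=1, G=2, U=3."""
    return np.frombuffer(
        residues.encode("ascii").translate(_ENCODE_TABLE), dtype=np.uint8
    ).astype(np.int64)


_ENCODE_TABLE = bytes.maketrans(b"ACGU", bytes([0, 1, 2, 3]))


@dataclass
class PairingMatrix:
    """The run-length base-pairing matrix of one window subsequence."""

    seq: RNASequence
    cells: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.seq)

    def cell(self, i: int, j: int) -> int:
        """Run-length value at row *i*, column *j*."""
        return int(self.cells[i, j])

    def pair_positions(self, i: int, j: int) -> Tuple[int, int]:
        """Sequence positions compared at cell ``(i, j)``: ``(j, n-1-i)``."""
        return j, self.n - 1 - i

    def usable(self, min_loop: int = MIN_LOOP) -> np.ndarray:
        """Mask of positive cells whose pair leaves >= *min_loop* nt between
        the partners (a base cannot pair with itself or across a too-short
        terminal loop): requires ``i + j <= n - 2 - min_loop``."""
        n = self.n
        i = np.arange(n)[:, None]
        j = np.arange(n)[None, :]
        return (self.cells > 0) & (i + j <= n - 2 - min_loop)


def build_pairing_matrix(seq: RNASequence) -> PairingMatrix:
    """Construct the triangular base-pairing matrix for *seq*.

    ``cell(i, j)`` is 0 if ``s[j]`` and ``s[n-1-i]`` cannot pair, and
    ``cell(i-1, j-1) + 1`` otherwise (out-of-range neighbors count as 0),
    recording the length of the paired run ending at the cell.
    """
    n = len(seq)
    if n < 1:
        raise InvalidInputError("empty sequence")
    enc = encode(seq.residues)
    # comp[i, j] <-> s[n-1-i] pairs s[j]
    comp = _COMP_TABLE[enc[::-1][:, None], enc[None, :]]
    cells = np.zeros((n, n), dtype=np.int32)
    cells[0] = comp[0]
    for i in range(1, n):
        cells[i, 0] = comp[i, 0]
        cells[i, 1:] = (cells[i - 1, :-1] + 1) * comp[i, 1:]
    return PairingMatrix(seq=seq, cells=cells)
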