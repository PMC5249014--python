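"""Three-stage incremental hairpin construction over the pairing matrix.

Stage 1 extracts *exact stems* (maximal runs of positive cells on a matrix
diagonal).  Stage 2 extends an exact stem along its own diagonal into a
*non-exact stem* by absorbing neighboring runs across small symmetric
internal loops.  Stage 3 anchors the non-exact stem and explores nearby
diagonals to admit bulges and asymmetric internal loops, producing a
complete hairpin candidate with a dot-bracket structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import InconsistentInputError, InvalidInputError, MirnacleError
from .pairing_matrix import MIN_LOOP, PairingMatrix, _COMP_TABLE, encode


@dataclass(frozen=True)
class SearchConfig:
    """Parameters steering the structural search.

    ``loop_penalty`` is the per-unpaired-nt cost subtracted from the pairs
    gained when scoring a stage-3 extension step; ``max_shift`` bounds both
    the per-side gap and the diagonal shift ``|gap5 - gap3|`` of a step.
    """

    min_exact_stem: int = 4
    min_loop: int = MIN_LOOP
    max_shift: int = 10
    loop_penalty: float = 0.3
    min_size: int = 50
    max_size: int = 150

    def __post_init__(self) -> None:
        if self.min_exact_stem < 1:
            raise InvalidInputError("min_exact_stem must be >= 1")
        if self.min_size > self.max_size:
            raise InvalidInputError("min_size must be <= max_size")


@dataclass(frozen=True)
class ExactStem:
    """A maximal uninterrupted run of base pairs on one matrix diagonal.

    The run starts at cell ``(i, j)`` and spans ``length`` cells; in window
    coordinates the 5' arm is ``[j, j+length)`` and the 3' arm is
    ``[n-i-length, n-i)``, pairing position ``j+t`` with ``n-1-i-t``.
    """

    n: int  # window length the coordinates refer to
    i: int
    j: int
    length: int

    @property
    def diagonal(self) -> int:
        return self.i - self.j

    @property
    def arm5(self) -> Tuple[int, int]:
        return self.j, self.j + self.length

    @property
    def arm3(self) -> Tuple[int, int]:
        return self.n - self.i - self.length, self.n - self.i

    def pairs(self) -> List[Tuple[int, int]]:
        """Base pairs (p5, p3), outermost first."""
        return [
            (self.j + t, self.n - 1 - self.i - t) for t in range(self.length)
        ]


@dataclass(frozen=True)
class NonExactStem:
    """Exact stems on one diagonal bridged by small symmetric internal loops.

    ``loops[k]`` is the per-side size of the symmetric loop between
    ``stems[k]`` and ``stems[k+1]``; every loop is strictly smaller than both
    flanking stem lengths.
    """

    stems: Tuple[ExactStem, ...]
    loops: Tuple[int, ...]
    seed: ExactStem

    def __post_init__(self) -> None:
        if len(self.loops) != len(self.stems) - 1:
            raise InvalidInputError("loop list must bridge consecutive stems")
        diag = {s.diagonal for s in self.stems}
        if len(diag) != 1:
            raise InvalidInputError("non-exact stem spans several diagonals")

    @property
    def diagonal(self) -> int:
        return self.seed.diagonal

    @property
    def total_pairs(self) -> int:
        return sum(s.length for s in self.stems)

    @property
    def region(self) -> Tuple[int, int]:
        """Window interval spanned from the outermost 5' base to the
        outermost 3' base (half-open)."""
        outer = self.stems[0]
        return outer.arm5[0], outer.arm3[1]

    @property
    def span5(self) -> Tuple[int, int]:
        return self.stems[0].arm5[0], self.stems[-1].arm5[1]

    @property
    def span3(self) -> Tuple[int, int]:
        return self.stems[-1].arm3[0], self.stems[0].arm3[1]

    def pairs(self) -> List[Tuple[int, int]]:
        out: List[Tuple[int, int]] = []
        for s in self.stems:
            out.extend(s.pairs())
        return out


@dataclass(frozen=True)
class StructureElement:
    """One element of a hairpin decomposition, walking base -> terminal loop.

    kinds: ``stem`` (size = bp), ``sym_loop``/``asym_loop`` (left/right =
    unpaired nt on the 5'/3' arm), ``bulge_left``/``bulge_right`` (unpaired
    nt on the 5'/3' arm only), ``terminal_loop``.
    """

    kind: str
    size: int
    left: int = 0
    right: int = 0


@dataclass(frozen=True)
class HairpinCandidate:
    """A complete hairpin: nested pair chain, structure and decomposition."""

    start: int  # window coordinates, half-open
    end: int
    pair_chain: Tuple[Tuple[int, int], ...]  # outermost -> innermost
    structure: str
    elements: Tuple[StructureElement, ...]
    seed: ExactStem
    window_offset: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pair_chain)

    @property
    def terminal_loop_size(self) -> int:
        a, b = self.pair_chain[-1]
        return b - a - 1

    def source_interval(self) -> Tuple[int, int]:
        """Interval in source-sequence coordinates."""
        return self.start + self.window_offset, self.end + self.window_offset


# ---------------------------------------------------------------------------
# Stage 1: exact stems


def _usable_run_lengths(matrix: PairingMatrix, min_loop: int) -> np.ndarray:
    """Run lengths restricted to the usable triangle (see
    :meth:`PairingMatrix.usable`).  Cached on the matrix object since stage-2
    extension re-reads it once per seed stem."""
    cache = getattr(matrix, "_rl_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(matrix, "_rl_cache", cache)
    if min_loop in cache:
        return cache[min_loop]
    usable = matrix.usable(min_loop)
    n = matrix.n
    rl = np.zeros((n, n), dtype=np.int32)
    rl[0] = usable[0]
    for i in range(1, n):
        rl[i, 0] = usable[i, 0]
        rl[i, 1:] = (rl[i - 1, :-1] + 1) * usable[i, 1:]
    cache[min_loop] = rl
    return rl


def find_exact_stems(
    matrix: PairingMatrix, min_len: int, min_loop: int = MIN_LOOP
) -> List[ExactStem]:
    """Every maximal diagonal run of pairable cells with length >= *min_len*.

    Runs are confined to the triangle where the 5' arm strictly precedes the
    3' arm with >= *min_loop* nt in between.  Sorted by (diagonal, start).
    """
    if min_len < 1:
        raise InvalidInputError("min_len must be >= 1")
    rl = _usable_run_lengths(matrix, min_loop)
    n = matrix.n
    # a run ends at (i, j) when the next diagonal cell is out of range or 0
    ends = rl >= min_len
    ends[:-1, :-1] &= rl[1:, 1:] == 0
    stems = []
    for i, j in zip(*np.nonzero(ends)):
        length = int(rl[i, j])
        stems.append(
            ExactStem(n=n, i=int(i) - length + 1, j=int(j) - length + 1, length=length)
        )
    stems.sort(key=lambda s: (s.diagonal, s.i))
    return stems


def _diagonal_runs(
    matrix: PairingMatrix, diagonal: int, min_loop: int
) -> List[ExactStem]:
    """All maximal usable runs (any length >= 1) on one diagonal, ordered
    from the hairpin base toward the terminal loop (increasing j)."""
    rl = _usable_run_lengths(matrix, min_loop)
    n = matrix.n
    runs: List[ExactStem] = []
    # cells on diagonal d: (i, j) = (d + t, t) for valid t
    t0 = max(0, -diagonal)
    t1 = min(n, n - diagonal)
    for t in range(t0, t1):
        i, j = diagonal + t, t
        v = int(rl[i, j])
        if v > 0 and (t + 1 >= t1 or rl[i + 1, j + 1] == 0):
            runs.append(ExactStem(n=n, i=i - v + 1, j=j - v + 1, length=v))
    return runs


# ---------------------------------------------------------------------------
# Stage 2: non-exact stems


def extend_to_non_exact_stem(
    matrix: PairingMatrix,
    seed: ExactStem,
    min_len: Optional[int] = None,
    min_loop: int = MIN_LOOP,
) -> NonExactStem:
    """Greedily absorb neighboring runs on the seed's diagonal.

    A neighboring maximal run of length L2 separated from the structure's
    flanking stem (length L1) by a zero-gap of g cells is absorbed iff
    ``g < min(L1, L2)`` — the symmetric-loop rule.  Extension proceeds in
    both directions until no absorbable run remains.
    """
    if seed.n != matrix.n:
        raise InconsistentInputError("seed was not built from this matrix")
    runs = _diagonal_runs(matrix, seed.diagonal, min_loop)
    try:
        idx = next(
            k for k, r in enumerate(runs) if r.i == seed.i and r.length == seed.length
        )
    except StopIteration:
        raise InconsistentInputError(
            "seed stem not found on its diagonal; matrix/seed mismatch"
        ) from None

    lo = hi = idx

    def gap(a: ExactStem, b: ExactStem) -> int:
        # zero cells between run a and run b on the shared diagonal
        return b.j - (a.j + a.length)

    changed = True
    while changed:
        changed = False
        if hi + 1 < len(runs):
            g = gap(runs[hi], runs[hi + 1])
            if g < min(runs[hi].length, runs[hi + 1].length):
                hi += 1
                changed = True
        if lo - 1 >= 0:
            g = gap(runs[lo - 1], runs[lo])
            if g < min(runs[lo - 1].length, runs[lo].length):
                lo -= 1
                changed = True

    stems = tuple(runs[lo : hi + 1])
    loops = tuple(gap(a, b) for a, b in zip(stems, stems[1:]))
    return NonExactStem(stems=stems, loops=loops, seed=seed)


# ---------------------------------------------------------------------------
# Stage 3: complete hairpins


def _comp_lookup(matrix: PairingMatrix) -> List[List[bool]]:
    """Pairwise complementarity of window positions as plain nested lists
    (cached; scalar numpy indexing is too slow for the stage-3 inner loop)."""
    comp = getattr(matrix, "_comp_cache", None)
    if comp is None:
        enc = encode(matrix.seq.residues)
        comp = _COMP_TABLE[enc[:, None], enc[None, :]].tolist()
        object.__setattr__(matrix, "_comp_cache", comp)
    return comp


def _best_step(
    comp: List[List[bool]],
    a: int,
    b: int,
    inward: bool,
    n: int,
    config: SearchConfig,
) -> Optional[Tuple[float, int, int, int]]:
    """Best extension step from the chain end pair (a, b).

    Tries every (gap5, gap3) with per-side gaps and |gap5-gap3| bounded by
    ``max_shift``, extends a maximal exact run from the first new pair, and
    scores it as (pairs gained - loop_penalty * unpaired nt introduced).
    Returns ``(score, gap5, gap3, run_len)`` for the best admissible step
    with positive score, or None.  Ties are broken by smaller total gap,
    then smaller |shift|, then 5'-most (smaller gap5).
    """
    best: Optional[Tuple[float, int, int, int]] = None
    best_key: Optional[Tuple[float, int, int, int]] = None
    max_gap = config.max_shift
    for g5 in range(max_gap + 1):
        for g3 in range(max_gap + 1):
            if abs(g5 - g3) > config.max_shift:
                continue
            if inward:
                a2, b2 = a + 1 + g5, b - 1 - g3
                if b2 - a2 - 1 < config.min_loop:
                    continue
            else:
                a2, b2 = a - 1 - g5, b + 1 + g3
                if a2 < 0 or b2 >= n:
                    continue
            if not comp[a2][b2]:
                continue
            run = 1
            if inward:
                while (
                    b2 - run - (a2 + run) - 1 >= config.min_loop
                    and comp[a2 + run][b2 - run]
                ):
                    run += 1
            else:
                while (
                    a2 - run >= 0
                    and b2 + run < n
                    and comp[a2 - run][b2 + run]
                ):
                    run += 1
            score = run - config.loop_penalty * (g5 + g3)
            if score <= 0:
                continue
            key = (-score, g5 + g3, abs(g5 - g3), g5)
            if best_key is None or key < best_key:
                best_key = key
                best = (score, g5, g3, run)
    return best


def build_hairpin(
    matrix: PairingMatrix,
    nes: NonExactStem,
    config: Optional[SearchConfig] = None,
) -> HairpinCandidate:
    """Grow a complete hairpin from a non-exact stem.

    The non-exact stem's pairs are anchored.  The chain is then extended
    deterministically in both directions — inward toward the terminal loop
    and outward toward the hairpin opening — by repeatedly taking the
    best-scoring admissible step (see :func:`_best_step`), which may
    introduce bulges and asymmetric internal loops on shifted diagonals.
    When no extension is possible the result degenerates to the non-exact
    stem closed by its terminal loop.
    """
    config = config or SearchConfig()
    if nes.seed.n != matrix.n:
        raise InconsistentInputError("non-exact stem was not built from this matrix")
    n = matrix.n
    comp = _comp_lookup(matrix)

    chain: List[Tuple[int, int]] = nes.pairs()

    # inward: toward the terminal loop
    while True:
        a, b = chain[-1]
        step = _best_step(comp, a, b, inward=True, n=n, config=config)
        if step is None:
            break
        _, g5, g3, run = step
        a2, b2 = a + 1 + g5, b - 1 - g3
        chain.extend((a2 + t, b2 - t) for t in range(run))

    # outward: toward the hairpin opening
    while True:
        a, b = chain[0]
        step = _best_step(comp, a, b, inward=False, n=n, config=config)
        if step is None:
            break
        _, g5, g3, run = step
        a2, b2 = a - 1 - g5, b + 1 + g3
        head = [(a2 - t, b2 + t) for t in range(run)]
        chain[:0] = reversed(head)

    start, end = chain[0][0], chain[0][1] + 1
    structure = _chain_to_dot_bracket(chain, start, end)
    elements = decompose_elements(chain)
    return HairpinCandidate(
        start=start,
        end=end,
        pair_chain=tuple(chain),
        structure=structure,
        elements=elements,
        seed=nes.seed,
    )


def decompose_elements(
    chain: Sequence[Tuple[int, int]]
) -> Tuple[StructureElement, ...]:
    """Decompose a nested pair chain into stems, loops and bulges.

    Bulges are tagged by the arm they sit on: the 5' arm lies left of the
    terminal loop in sequence order, the 3' arm right of it.
    """
    elements: List[StructureElement] = []
    stem_len = 1
    for (a1, b1), (a2, b2) in zip(chain, chain[1:]):
        d5 = a2 - a1 - 1
        d3 = b1 - b2 - 1
        if d5 == 0 and d3 == 0:
            stem_len += 1
            continue
        elements.append(StructureElement("stem", stem_len))
        stem_len = 1
        if d5 > 0 and d3 > 0:
            kind = "sym_loop" if d5 == d3 else "asym_loop"
            elements.append(StructureElement(kind, max(d5, d3), left=d5, right=d3))
        elif d5 > 0:
            elements.append(StructureElement("bulge_left", d5, left=d5))
        else:
            elements.append(StructureElement("bulge_right", d3, right=d3))
    elements.append(StructureElement("stem", stem_len))
    a, b = chain[-1]
    elements.append(StructureElement("terminal_loop", b - a - 1))
    return tuple(elements)


def _chain_to_dot_bracket(
    chain: Sequence[Tuple[int, int]], start: int, end: int
) -> str:
    chars = ["."] * (end - start)
    for a, b in chain:
        chars[a - start] = "("
        chars[b - start] = ")"
    return "".join(chars)


def to_dot_bracket(cand: HairpinCandidate) -> str:
    """Dot-bracket string of a candidate, validated for consistency."""
    s = cand.structure
    if len(s) != cand.end - cand.start:
        raise MirnacleError("structure length does not match candidate interval")
    if s.count("(") != s.count(")") or s.count("(") != cand.n_pairs:
        raise MirnacleError("inconsistent pairing in candidate structure")
    return s


def parse_dot_bracket(structure: str) -> List[Tuple[int, int]]:
    """Parse a dot-bracket string into a sorted list of 0-based pairs."""
    stack: List[int] = []
    pairs: List[Tuple[int, int]] = []
    for k, ch in enumerate(structure):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise InvalidInputError(f"unbalanced ')' at position {k}")
            pairs.append((stack.pop(), k))
        elif ch != ".":
            raise InvalidInputError(f"invalid structure character {ch!r}")
    if stack:
        raise InvalidInputError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def filter_by_size(cand: HairpinCandidate, min_size: int, max_size: int) -> bool:
    """True iff the candidate length is within [min_size, max_size] (inclusive)."""
    if min_size > max_size:
        raise InvalidInputError("min_size must be <= max_size")
    return min_size <= cand.end - cand.start <= max_size


def validate_structure(cand: HairpinCandidate) -> None:
    """Assert the candidate's pairs are nested, non-crossing and mutually
    consistent with its dot-bracket string."""
    chain = cand.pair_chain
    seen: set = set()
    for a, b in chain:
        if a >= b:
            raise MirnacleError(f"pair ({a}, {b}) not ordered")
        if a in seen or b in seen:
            raise MirnacleError(f"position re-used in pair ({a}, {b})")
        seen.update((a, b))
    for (a1, b1), (a2, b2) in zip(chain, chain[1:]):
        if not (a1 < a2 < b2 < b1):
            raise MirnacleError(
                f"pairs ({a1},{b1}) and ({a2},{b2}) are not nested"
            )
    if parse_dot_bracket(cand.structure) != sorted(
        (a - cand.start, b - cand.start) for a, b in chain
    ):
        raise MirnacleError("dot-bracket disagrees with pair chain")
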