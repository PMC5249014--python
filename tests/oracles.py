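"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's incremental algorithms: the matrix
oracle recomputes every cell by walking the paired run back from the cell
itself, and the hairpin oracle exhaustively enumerates admissible nested
structures instead of extending greedily.
"""

from __future__ import annotations

import functools
from typing import List, Sequence, Tuple

from mirnacle.hairpin_search import SearchConfig
from mirnacle.pairing_matrix import is_complementary


def brute_force_matrix_cell(residues: str, i: int, j: int) -> int:
    """Run length ending at (i, j), straight from the definition: the number
    of consecutive offsets u = 0, 1, ... for which ``s[j-u]`` pairs
    ``s[n-1-(i-u)]``."""
    n = len(residues)
    run = 0
    while (
        i - run >= 0
        and j - run >= 0
        and is_complementary(residues[j - run], residues[n - 1 - (i - run)])
    ):
        run += 1
    return run


def brute_force_matrix(residues: str):
    import numpy as np

    n = len(residues)
    return np.array(
        [
            [brute_force_matrix_cell(residues, i, j) for j in range(n)]
            for i in range(n)
        ]
    )


def brute_force_exact_stems(
    residues: str, min_len: int, min_loop: int = 3
) -> List[Tuple[int, int, int]]:
    """Maximal paired runs (arm5_start, arm3_end, length) by direct
    enumeration of every candidate pairing, without the matrix."""
    n = len(residues)
    found = set()
    for a in range(n):  # 5' start
        for b in range(a + min_loop + 1, n):  # 3' end pairs position a
            # extend a run starting at pair (a, b)
            if a > 0 and b + 1 < n and is_complementary(residues[a - 1], residues[b + 1]):
                continue  # not maximal: extendable outward
            run = 0
            while (
                a + run < b - run
                and (b - run) - (a + run) - 1 >= min_loop
                and is_complementary(residues[a + run], residues[b - run])
            ):
                run += 1
            if run >= min_len:
                found.add((a, b + 1, run))
    return sorted(found)


def max_pairs_exhaustive(
    residues: str,
    anchor: Sequence[Tuple[int, int]],
    config: SearchConfig,
) -> int:
    """Maximum pair count over all nested structures that contain the anchor
    chain and respect the search's admissibility rules: per-side gaps and
    |gap5 - gap3| bounded by ``max_shift``, terminal loop >= ``min_loop``,
    and every added run scoring positive (run length >
    loop_penalty * unpaired nt introduced).

    Unlike the greedy search this explores every admissible run prefix at
    every step, so it is a true optimum for the same constraint set.
    """
    n = len(residues)

    def comp(a: int, b: int) -> bool:
        return is_complementary(residues[a], residues[b])

    @functools.lru_cache(maxsize=None)
    def best_inward(a: int, b: int) -> int:
        best = 0
        for g5 in range(config.max_shift + 1):
            for g3 in range(config.max_shift + 1):
                if abs(g5 - g3) > config.max_shift:
                    continue
                a2, b2 = a + 1 + g5, b - 1 - g3
                if b2 - a2 - 1 < config.min_loop or not comp(a2, b2):
                    continue
                max_run = 1
                while (
                    (b2 - max_run) - (a2 + max_run) - 1 >= config.min_loop
                    and comp(a2 + max_run, b2 - max_run)
                ):
                    max_run += 1
                for run in range(1, max_run + 1):
                    if run - config.loop_penalty * (g5 + g3) <= 0:
                        continue
                    gain = run + best_inward(a2 + run - 1, b2 - run + 1)
                    best = max(best, gain)
        return best

    @functools.lru_cache(maxsize=None)
    def best_outward(a: int, b: int) -> int:
        best = 0
        for g5 in range(config.max_shift + 1):
            for g3 in range(config.max_shift + 1):
                if abs(g5 - g3) > config.max_shift:
                    continue
                a2, b2 = a - 1 - g5, b + 1 + g3
                if a2 < 0 or b2 >= n or not comp(a2, b2):
                    continue
                max_run = 1
                while (
                    a2 - max_run >= 0
                    and b2 + max_run < n
                    and comp(a2 - max_run, b2 + max_run)
                ):
                    max_run += 1
                for run in range(1, max_run + 1):
                    if run - config.loop_penalty * (g5 + g3) <= 0:
                        continue
                    gain = run + best_outward(a2 - run + 1, b2 + run - 1)
                    best = max(best, gain)
        return best

    inner_a, inner_b = anchor[-1]
    outer_a, outer_b = anchor[0]
    return len(anchor) + best_inward(inner_a, inner_b) + best_outward(outer_a, outer_b)
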