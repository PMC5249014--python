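"""Stage-wise feature vectors for exact stems, non-exact stems and hairpins.

Stage 1 has 29 features, stage 2 the same block plus 6 loop/pairing summaries
(35), and stage 3 adds 13 structural/energy summaries plus the 32 triplet
features (80).  Percentage features are on a 0-100 scale; energies are in
kcal/mol.  Any ratio with a zero denominator is emitted as 0 (with a logged
warning) so degenerate candidates still yield finite vectors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Protocol, Sequence, Tuple

import numpy as np

from .errors import (
    EnergyBackendError,
    InconsistentInputError,
    InsufficientLengthError,
)
from .hairpin_search import ExactStem, HairpinCandidate, NonExactStem
from .pairing_matrix import NUCLEOTIDES, RNASequence, encode

logger = logging.getLogger(__name__)

DINUCLEOTIDES: Tuple[str, ...] = tuple(
    a + b for a, b in itertools.product(NUCLEOTIDES, repeat=2)
)

#: 8 paired/unpaired patterns of three consecutive positions x 4 middle
#: nucleotides; '(' marks a paired position, '.' an unpaired one.
TRIPLET_PATTERNS: Tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("(.", repeat=3)
)
TRIPLETS: Tuple[str, ...] = tuple(
    f"{mid}{pat}" for mid in NUCLEOTIDES for pat in TRIPLET_PATTERNS
)

STAGE1_NAMES: Tuple[str, ...] = (
    ("size", "delta_g")
    + tuple(f"pct_{b}" for b in NUCLEOTIDES)
    + tuple(f"max_run_{b}" for b in NUCLEOTIDES)
    + ("pct_gu_pairing",)
    + tuple(f"dinuc_{d}" for d in DINUCLEOTIDES)
    + ("pct_ga_minus_cu", "pct_g_minus_c")
)

STAGE2_NAMES: Tuple[str, ...] = STAGE1_NAMES + (
    "pct_base_pairing",
    "n_exact_stems",
    "avg_palindrome_size",
    "n_sym_loops",
    "avg_sym_loop_size",
    "max_sym_loop_size",
)

STAGE3_NAMES: Tuple[str, ...] = (
    STAGE2_NAMES
    + (
        "avg_exact_stem_size",
        "terminal_loop_size",
        "pct_gc_pairing",
        "adjusted_mfe",
        "pct_nes_coverage",
        "max_bulge_side_diff",
        "max_bulge_left",
        "max_bulge_right",
        "bulge_count_diff",
        "n_consecutive_bulges",
        "n_consecutive_bulges_same_side",
        "mfe1",
        "mfe2",
    )
    + tuple(f"triplet_{t}" for t in TRIPLETS)
)

STAGE_NAMES: Dict[int, Tuple[str, ...]] = {
    1: STAGE1_NAMES,
    2: STAGE2_NAMES,
    3: STAGE3_NAMES,
}

assert len(STAGE1_NAMES) == 29
assert len(STAGE2_NAMES) == 35
assert len(STAGE3_NAMES) == 80


@dataclass(frozen=True)
class FeatureVector:
    """Stage-tagged ordered (name, value) pairs."""

    stage: int
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.stage not in STAGE_NAMES:
            raise InconsistentInputError(f"unknown stage {self.stage}")
        if len(self.values) != len(STAGE_NAMES[self.stage]):
            raise InconsistentInputError(
                f"stage {self.stage} expects {len(STAGE_NAMES[self.stage])} "
                f"values, got {len(self.values)}"
            )

    @property
    def names(self) -> Tuple[str, ...]:
        return STAGE_NAMES[self.stage]

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[self.names.index(name)]


class EnergyBackend(Protocol):
    """Contract for the thermodynamic backend.

    ``duplex_energy`` scores the hybridization of two arms (the stage-1
    deltaG); ``fold_mfe`` returns the minimum free energy of a sequence's
    optimal secondary structure.  Both are <= 0 whenever at least one base
    pair is possible.
    """

    def duplex_energy(self, arm5: str, arm3: str) -> float: ...

    def fold_mfe(self, sequence: str) -> float: ...


_PAIR_WEIGHT = {frozenset("GC"): 2.0, frozenset("AU"): 1.0, frozenset("GU"): 0.5}


def _pair_weight(a: str, b: str) -> float:
    return _PAIR_WEIGHT.get(frozenset((a, b)), 0.0)


class StackingEnergyModel:
    """Dependency-free stacking-count approximation of the energy backend.

    Scores -2 kcal/mol per GC-involving pair, -1 per AU and -0.5 per GU.
    ``fold_mfe`` maximizes the total weighted pairing of a single nested
    stem-loop structure (no multibranch) by dynamic programming with a
    3-nt minimum hairpin loop.  An adapter wrapping an external
    thermodynamic folder can be substituted under the same contract.
    """

    min_loop = 3

    def duplex_energy(self, arm5: str, arm3: str) -> float:
        try:
            total = 0.0
            for a, b in zip(arm5, reversed(arm3)):
                total -= _pair_weight(a, b)
            return total
        except TypeError as exc:  # non-string input
            raise EnergyBackendError("duplex_energy failed") from exc

    def fold_mfe(self, sequence: str) -> float:
        return _fold_mfe_cached(sequence, self.min_loop)


@lru_cache(maxsize=4096)
def _fold_mfe_cached(sequence: str, min_loop: int) -> float:
    n = len(sequence)
    if n < min_loop + 2:
        return 0.0
    enc = encode(sequence)
    w = np.array(
        [[_pair_weight(a, b) for b in NUCLEOTIDES] for a in NUCLEOTIDES]
    )
    pairw = w[enc[:, None], enc[None, :]]
    W = np.zeros((n, n))
    for span in range(min_loop + 1, n):
        i = np.arange(0, n - span)
        j = i + span
        best = np.maximum(W[i + 1, j], W[i, j - 1])
        inner = W[i + 1, j - 1] + pairw[i, j]
        np.maximum(best, np.where(pairw[i, j] > 0, inner, 0.0), out=best)
        W[i, j] = best
    return -float(W[0, n - 1])


# ---------------------------------------------------------------------------
# Profiles


def dinucleotide_profile(seq: RNASequence) -> Tuple[float, ...]:
    """Percentage of each of the 16 ordered dinucleotides; sums to 100."""
    n = len(seq)
    if n < 2:
        raise InsufficientLengthError(
            f"dinucleotide profile needs n >= 2, got {n}"
        )
    counts = {d: 0 for d in DINUCLEOTIDES}
    for k in range(n - 1):
        counts[seq.residues[k : k + 2]] += 1
    return tuple(100.0 * counts[d] / (n - 1) for d in DINUCLEOTIDES)


def triplet_profile(seq: RNASequence, structure: str) -> Tuple[float, ...]:
    """Percentage of each of the 32 (middle nucleotide x 3-position
    paired/unpaired pattern) triplets; sums to 100.

    A closing bracket counts as paired, so ')' maps to '('.
    """
    n = len(seq)
    if len(structure) != n:
        raise InconsistentInputError(
            f"structure length {len(structure)} != sequence length {n}"
        )
    if n < 3:
        raise InsufficientLengthError(f"triplet profile needs n >= 3, got {n}")
    paired = structure.replace(")", "(")
    counts = {t: 0 for t in TRIPLETS}
    for k in range(n - 2):
        key = seq.residues[k + 1] + paired[k : k + 3]
        counts[key] += 1
    return tuple(100.0 * counts[t] / (n - 2) for t in TRIPLETS)


# ---------------------------------------------------------------------------
# Shared composition block (the stage-1 features)


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator computing %s; emitting 0", what)
        return 0.0
    return num / den


def _max_run(residues: str, base: str) -> int:
    best = cur = 0
    for ch in residues:
        cur = cur + 1 if ch == base else 0
        best = max(best, cur)
    return best


def _pct_gu(seq: RNASequence, pairs: Sequence[Tuple[int, int]]) -> float:
    if not pairs:
        return 0.0
    gu = sum(
        1
        for a, b in pairs
        if frozenset((seq.residues[a], seq.residues[b])) == frozenset("GU")
    )
    return 100.0 * gu / len(pairs)


def _composition_block(
    residues: str,
    size: float,
    delta_g: float,
    pct_gu: float,
) -> List[float]:
    n = len(residues)
    counts = {b: residues.count(b) for b in NUCLEOTIDES}
    block = [float(size), float(delta_g)]
    block += [100.0 * counts[b] / n for b in NUCLEOTIDES]
    block += [float(_max_run(residues, b)) for b in NUCLEOTIDES]
    block.append(pct_gu)
    comp_seq = RNASequence(id="_block", residues=residues)
    if n >= 2:
        block += list(dinucleotide_profile(comp_seq))
    else:
        block += [0.0] * 16
    ga = counts["G"] + counts["A"]
    cu = counts["C"] + counts["U"]
    block.append(100.0 * (ga - cu) / n)
    block.append(100.0 * (counts["G"] - counts["C"]) / n)
    return block


def stage1_features(
    stem: ExactStem, seq: RNASequence, energy: EnergyBackend
) -> FeatureVector:
    """29 features computed over the stem's two arms concatenated."""
    if stem.arm3[1] > len(seq):
        raise InconsistentInputError("stem arms do not lie within the sequence")
    a5s, a5e = stem.arm5
    a3s, a3e = stem.arm3
    arm5 = seq.residues[a5s:a5e]
    arm3 = seq.residues[a3s:a3e]
    try:
        dg = energy.duplex_energy(arm5, arm3)
    except EnergyBackendError:
        raise
    except Exception as exc:
        raise EnergyBackendError("duplex_energy backend failed") from exc
    block = _composition_block(
        arm5 + arm3, stem.length, dg, _pct_gu(seq, stem.pairs())
    )
    return FeatureVector(stage=1, values=tuple(block))


def stage2_features(
    nes: NonExactStem, seq: RNASequence, energy: EnergyBackend
) -> FeatureVector:
    """35 features; the stage-1 block is recomputed over the spanned region."""
    start, end = nes.region
    if end > len(seq):
        raise InconsistentInputError("non-exact stem exceeds the sequence")
    region = seq.residues[start:end]
    s5s, s5e = nes.span5
    s3s, s3e = nes.span3
    try:
        dg = energy.duplex_energy(seq.residues[s5s:s5e], seq.residues[s3s:s3e])
    except EnergyBackendError:
        raise
    except Exception as exc:
        raise EnergyBackendError("duplex_energy backend failed") from exc
    pairs = nes.pairs()
    block = _composition_block(region, nes.total_pairs, dg, _pct_gu(seq, pairs))
    block += _loop_block(
        region_len=end - start,
        n_pairs=nes.total_pairs,
        stem_sizes=[s.length for s in nes.stems],
        sym_loops=list(nes.loops),
    )
    return FeatureVector(stage=2, values=tuple(block))


def _loop_block(
    region_len: int,
    n_pairs: int,
    stem_sizes: Sequence[int],
    sym_loops: Sequence[int],
) -> List[float]:
    pct_pairing = _safe_ratio(100.0 * 2 * n_pairs, region_len, "pct_base_pairing")
    avg_palindrome = float(np.mean(stem_sizes)) if stem_sizes else 0.0
    n_loops = len(sym_loops)
    avg_loop = float(np.mean(sym_loops)) if sym_loops else 0.0
    max_loop = float(max(sym_loops)) if sym_loops else 0.0
    return [pct_pairing, float(len(stem_sizes)), avg_palindrome, float(n_loops), avg_loop, max_loop]


def _nes_coverage(cand: HairpinCandidate) -> float:
    """Percentage of candidate nucleotides inside non-exact-stem regions
    (maximal same-diagonal runs of stems bridged by symmetric loops)."""
    covered = 0
    segment = 0  # nt covered by the current same-diagonal segment
    pending_loop = 0
    for el in cand.elements:
        if el.kind == "stem":
            segment += 2 * el.size + pending_loop
            pending_loop = 0
        elif el.kind == "sym_loop":
            pending_loop = 2 * el.size
        elif el.kind == "terminal_loop":
            break
        else:  # bulge or asymmetric loop ends the segment
            covered += segment
            segment = 0
            pending_loop = 0
    covered += segment
    return _safe_ratio(100.0 * covered, cand.end - cand.start, "pct_nes_coverage")


def stage3_features(
    cand: HairpinCandidate, seq: RNASequence, energy: EnergyBackend
) -> FeatureVector:
    """80 features over the full hairpin candidate."""
    if not cand.structure or len(cand.structure) != cand.end - cand.start:
        raise InconsistentInputError("candidate is missing a valid structure")
    start, end = cand.start, cand.end
    region = seq.residues[start:end]
    length = end - start
    pairs = list(cand.pair_chain)
    inner_a, inner_b = cand.pair_chain[-1]
    arm5 = seq.residues[start : inner_a + 1]
    arm3 = seq.residues[inner_b:end]
    try:
        dg = energy.duplex_energy(arm5, arm3)
        mfe = energy.fold_mfe(region)
    except EnergyBackendError:
        raise
    except Exception as exc:
        raise EnergyBackendError("energy backend failed") from exc

    block = _composition_block(region, len(pairs), dg, _pct_gu(seq, pairs))

    stems = [el for el in cand.elements if el.kind == "stem"]
    sym_loops = [el.size for el in cand.elements if el.kind == "sym_loop"]
    stem_sizes = [el.size for el in stems]
    block += _loop_block(length, len(pairs), stem_sizes, sym_loops)

    gc_pairs = sum(
        1
        for a, b in pairs
        if frozenset((seq.residues[a], seq.residues[b])) == frozenset("GC")
    )
    pct_gc_pairing = _safe_ratio(100.0 * gc_pairs, len(pairs), "pct_gc_pairing")

    adjusted_mfe = 100.0 * mfe / length
    gc_content = 100.0 * (region.count("G") + region.count("C")) / length
    mfe1 = _safe_ratio(adjusted_mfe, gc_content, "mfe1")
    mfe2 = _safe_ratio(adjusted_mfe, float(len(stems)), "mfe2")

    bulges = [el for el in cand.elements if el.kind.startswith("bulge")]
    loops_and_bulges = [
        el
        for el in cand.elements
        if el.kind in ("sym_loop", "asym_loop", "bulge_left", "bulge_right")
    ]
    max_side_diff = max(
        (abs(el.left - el.right) for el in loops_and_bulges), default=0
    )
    max_left = max((el.size for el in bulges if el.kind == "bulge_left"), default=0)
    max_right = max((el.size for el in bulges if el.kind == "bulge_right"), default=0)
    n_left = sum(1 for el in bulges if el.kind == "bulge_left")
    n_right = sum(1 for el in bulges if el.kind == "bulge_right")

    # consecutive bulges: successive loop-type elements (separated only by a
    # stem) that are both bulges; the same-side variant additionally requires
    # an identical arm.
    loop_seq = [el for el in cand.elements if el.kind != "stem"][:-1]
    consec = sum(
        1
        for e1, e2 in zip(loop_seq, loop_seq[1:])
        if e1.kind.startswith("bulge") and e2.kind.startswith("bulge")
    )
    consec_same = sum(
        1
        for e1, e2 in zip(loop_seq, loop_seq[1:])
        if e1.kind.startswith("bulge") and e1.kind == e2.kind
    )

    block += [
        float(np.mean(stem_sizes)) if stem_sizes else 0.0,
        float(cand.terminal_loop_size),
        pct_gc_pairing,
        adjusted_mfe,
        _nes_coverage(cand),
        float(max_side_diff),
        float(max_left),
        float(max_right),
        float(n_left - n_right),
        float(consec),
        float(consec_same),
        mfe1,
        mfe2,
    ]
    region_seq = RNASequence(id="_cand", residues=region)
    block += list(triplet_profile(region_seq, cand.structure))
    return FeatureVector(stage=3, values=tuple(block))
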