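"""Synthetic stem-loops, background sequences and hairpin-implanted genomes.

All randomness flows through explicit seeds (one ``numpy`` generator per
call); no global state.  These generators stand in for curated positive and
negative corpora so training, scanning and evaluation are testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .errors import InvalidSpecError, PlacementError
from .io import Interval
from .pairing_matrix import NUCLEOTIDES, RNASequence

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def reverse_complement(residues: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(residues))


@dataclass(frozen=True)
class HairpinSpec:
    """Controls for one synthetic stem-loop.

    ``bulge_sizes`` inserts that many unpaired nt into alternating arms;
    ``gu_fraction`` converts that fraction of stem pairs into G-U wobbles
    (where the arm base allows it); ``mutation_rate`` independently flips
    each final position to a random different base.
    """

    stem: int = 25
    loop: int = 8
    bulge_sizes: Tuple[int, ...] = ()
    gu_fraction: float = 0.0
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stem < 1 or self.loop < 1:
            raise InvalidSpecError("stem and loop must be >= 1")
        if not 0.0 <= self.gu_fraction <= 1.0:
            raise InvalidSpecError("gu_fraction must be in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise InvalidSpecError("mutation_rate must be in [0, 1]")
        if sum(self.bulge_sizes) >= self.stem:
            raise InvalidSpecError("total bulge size must be < stem length")

    @property
    def length(self) -> int:
        return 2 * self.stem + self.loop + sum(self.bulge_sizes)


def _random_residues(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(NUCLEOTIDES), size=length, p=p))


def generate_hairpin(spec: HairpinSpec) -> RNASequence:
    """arm5 + loop + reverse-complement(arm5), with wobbles, bulges and
    mutations applied per spec.  Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    arm5 = list(_random_residues(rng, spec.stem))
    arm3 = list(reverse_complement("".join(arm5)))  # arm3[k] pairs arm5[stem-1-k]
    if spec.gu_fraction > 0:
        eligible = [k for k, b in enumerate(arm5) if b in "GU"]
        n_wobble = int(round(spec.gu_fraction * spec.stem))
        for k in rng.permutation(eligible)[:n_wobble]:
            arm3[spec.stem - 1 - k] = "U" if arm5[k] == "G" else "G"
    for b_idx, size in enumerate(spec.bulge_sizes):
        arm = arm5 if b_idx % 2 == 0 else arm3
        pos = int(rng.integers(1, len(arm)))
        arm[pos:pos] = list(_random_residues(rng, size))
    loop = _random_residues(rng, spec.loop)
    residues = "".join(arm5) + loop + "".join(arm3)
    if spec.mutation_rate > 0:
        out = []
        for b in residues:
            if rng.uniform() < spec.mutation_rate:
                out.append(rng.choice([c for c in NUCLEOTIDES if c != b]))
            else:
                out.append(b)
        residues = "".join(out)
    return RNASequence(id=f"hairpin_s{spec.stem}_l{spec.loop}_seed{spec.seed}", residues=residues)


def generate_negative(length: int, gc: float = 0.5, seed: int = 0) -> RNASequence:
    """i.i.d. background sequence at the requested GC fraction."""
    if length < 1:
        raise InvalidSpecError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise InvalidSpecError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return RNASequence(
        id=f"negative_len{length}_seed{seed}",
        residues=_random_residues(rng, length, gc),
    )


def dinucleotide_shuffle(seq: RNASequence, seed: int = 0) -> RNASequence:
    """Shuffle preserving the exact dinucleotide counts (random Euler path
    through the dinucleotide multigraph, Altschul-Erikson style)."""
    rng = np.random.default_rng(seed)
    s = seq.residues
    if len(s) < 3:
        return RNASequence(id=f"{seq.id}_shuf", residues=s)
    for _attempt in range(100):
        edges = {b: [] for b in set(s)}
        for a, b in zip(s, s[1:]):
            edges[a].append(b)
        for a in edges:
            rng.shuffle(edges[a])
        # walk the Euler path from the original start vertex
        out = [s[0]]
        stack = [s[0]]
        path: List[str] = []
        counters = {a: 0 for a in edges}
        # Hierholzer's algorithm
        while stack:
            v = stack[-1]
            if counters[v] < len(edges[v]):
                stack.append(edges[v][counters[v]])
                counters[v] += 1
            else:
                path.append(stack.pop())
        if len(path) == len(s):
            return RNASequence(id=f"{seq.id}_shuf", residues="".join(reversed(path)))
    # multigraph had no usable Euler path ordering; fall back to the input
    return RNASequence(id=f"{seq.id}_shuf", residues=s)


@dataclass
class SyntheticGenome:
    """A background sequence with implanted hairpins and truth intervals."""

    sequence: RNASequence
    truth: List[Interval] = field(default_factory=list)
    seed: int = 0


def implant(
    genome_length: int,
    specs: Sequence[HairpinSpec],
    seed: int = 0,
    gc: float = 0.5,
    min_gap: int = 50,
) -> SyntheticGenome:
    """Place the specified hairpins at random non-overlapping positions
    (>= *min_gap* nt apart and from the ends) in an i.i.d. background.

    Truth intervals are returned BED-style (0-based half-open).
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    hairpins = [generate_hairpin(spec) for spec in specs]
    total = sum(len(h) for h in hairpins) + min_gap * (len(hairpins) + 1)
    if total > genome_length:
        raise PlacementError(
            f"{len(specs)} hairpins need >= {total} nt, genome is {genome_length}"
        )
    placements: List[Tuple[int, int]] = []
    for h in hairpins:
        placed = False
        for _try in range(1000):
            start = int(rng.integers(min_gap, genome_length - len(h) - min_gap + 1))
            end = start + len(h)
            if all(
                start >= e + min_gap or end + min_gap <= s
                for s, e in placements
            ):
                placements.append((start, end))
                placed = True
                break
        if not placed:
            raise PlacementError("could not place all hairpins; genome too crowded")
    background = list(_random_residues(rng, genome_length, gc))
    truth = []
    order = sorted(range(len(hairpins)), key=lambda k: placements[k][0])
    for k in order:
        start, end = placements[k]
        background[start:end] = list(hairpins[k].residues)
        truth.append(
            Interval(
                chrom=f"synthetic_genome_seed{seed}",
                start=start,
                end=end,
                name=hairpins[k].id,
            )
        )
    return SyntheticGenome(
        sequence=RNASequence(
            id=f"synthetic_genome_seed{seed}", residues="".join(background)
        ),
        truth=truth,
        seed=seed,
    )


def training_sequences(
    n_positives: int,
    n_negatives: int,
    seed: int = 0,
    min_size: int = 50,
    max_size: int = 150,
) -> Tuple[List[RNASequence], List[RNASequence]]:
    """Convenience corpus: hairpin positives sized within [min_size,
    max_size]; negatives half dinucleotide-shuffled positives, half i.i.d.
    background of matching lengths."""
    rng = np.random.default_rng(seed)
    positives = []
    for k in range(n_positives):
        loop = int(rng.integers(4, 10))
        max_stem = (max_size - loop) // 2
        min_stem = max(10, (min_size - loop) // 2 + 1)
        stem = int(rng.integers(min_stem, max_stem + 1))
        bulges: Tuple[int, ...] = ()
        if rng.uniform() < 0.5:
            bulges = tuple(
                int(rng.integers(1, 4)) for _ in range(int(rng.integers(1, 3)))
            )
        spec = HairpinSpec(
            stem=stem,
            loop=loop,
            bulge_sizes=bulges,
            gu_fraction=float(rng.uniform(0, 0.2)),
            mutation_rate=float(rng.uniform(0, 0.05)),
            seed=int(rng.integers(0, 2**31)),
        )
        positives.append(generate_hairpin(spec))
    negatives = []
    for k in range(n_negatives):
        if k % 2 == 0 and positives:
            src = positives[k % len(positives)]
            negatives.append(
                dinucleotide_shuffle(src, seed=int(rng.integers(0, 2**31)))
            )
        else:
            length = int(rng.integers(min_size, max_size + 1))
            negatives.append(
                generate_negative(length, gc=0.5, seed=int(rng.integers(0, 2**31)))
            )
    return positives, negatives
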