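"""Sliding-window genome scanning, prediction merging and evaluation.

A window of ``window`` nt slides ``step`` nt at a time along the input; each
window's pairing matrix is searched for exact stems, which are gated by the
stage-1 model, extended to non-exact stems (stage-2 gate), grown into
hairpins (stage-3 gate) and size-filtered.  Overlapping duplicates from
neighboring windows are merged.  Evaluation against known hairpins uses the
center-distance criterion: a prediction is true when its center lies within
10% of the known hairpin's size from the known center.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidInputError
from .features import (
    EnergyBackend,
    StackingEnergyModel,
    stage1_features,
    stage2_features,
    stage3_features,
)
from .hairpin_search import (
    HairpinCandidate,
    SearchConfig,
    build_hairpin,
    extend_to_non_exact_stem,
    filter_by_size,
    find_exact_stems,
)
from .io import Interval
from .pairing_matrix import MIN_LOOP, RNASequence, build_pairing_matrix

if TYPE_CHECKING:  # pragma: no cover
    from .cascade import CascadeModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    """Scanner parameters (defaults follow the tool's standard settings:
    stem >= 4 bp, 150-nt window, 10-nt step, 50-150 nt predictions,
    thresholds (0.3, 0.3, 0.7))."""

    window: int = 150
    step: int = 10
    min_exact_stem: int = 4
    min_size: int = 50
    max_size: int = 150
    thresholds: Tuple[float, float, float] = (0.3, 0.3, 0.7)
    min_loop: int = MIN_LOOP
    max_shift: int = 10
    loop_penalty: float = 0.3
    scan_reverse: bool = False

    def __post_init__(self) -> None:
        if self.window < self.max_size:
            raise InvalidInputError("window must be >= max_size")
        if self.step < 1:
            raise InvalidInputError("step must be >= 1")
        for t in self.thresholds:
            if not 0.0 <= t <= 1.0:
                raise InvalidInputError("thresholds must be in [0, 1]")

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            min_exact_stem=self.min_exact_stem,
            min_loop=self.min_loop,
            max_shift=self.max_shift,
            loop_penalty=self.loop_penalty,
            min_size=self.min_size,
            max_size=self.max_size,
        )


@dataclass(frozen=True)
class Prediction:
    """One predicted hairpin in source-sequence coordinates (0-based
    half-open)."""

    sequence_id: str
    start: int
    end: int
    probability: float
    structure: str
    strand: str = "+"
    window_start: int = 0

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    def to_interval(self, name: str = ".") -> Interval:
        return Interval(
            chrom=self.sequence_id,
            start=self.start,
            end=self.end,
            name=name,
            score=self.probability,
            strand=self.strand,
        )


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    sn: float
    sl: float
    gm: float
    matches: List[Tuple[Prediction, Interval]] = field(default_factory=list)


def window_offsets(n: int, window: int, step: int) -> List[int]:
    """Window start offsets: 0, step, 2*step, ... plus a final window
    anchored at ``n - window`` so the sequence tail is always covered."""
    if n <= window:
        return [0]
    last = n - window
    offsets = list(range(0, last + 1, step))
    if offsets[-1] != last:
        offsets.append(last)
    return offsets


def scan_sequence(
    seq: RNASequence,
    model: "CascadeModel",
    config: Optional[ScanConfig] = None,
    energy: Optional[EnergyBackend] = None,
) -> List[Prediction]:
    """Run the three-stage cascade over every window of *seq* and merge the
    surviving predictions.  Deterministic for fixed inputs."""
    config = config or ScanConfig()
    energy = energy or StackingEnergyModel()
    if len(seq) < config.min_size:
        logger.warning(
            "sequence %s shorter than min_size (%d < %d); nothing to scan",
            seq.id,
            len(seq),
            config.min_size,
        )
        return []
    search = config.search_config()
    t1, t2, t3 = config.thresholds
    predictions: List[Prediction] = []
    seen: set = set()
    for offset in window_offsets(len(seq), config.window, config.step):
        wseq = seq.subsequence(offset, min(offset + config.window, len(seq)))
        matrix = build_pairing_matrix(wseq)
        stems = find_exact_stems(matrix, config.min_exact_stem, config.min_loop)
        if not stems:
            continue
        fvs1 = np.array(
            [stage1_features(s, wseq, energy).as_array() for s in stems]
        )
        p1 = model.models[1].predict_proba(fvs1)
        passed = [s for s, p in zip(stems, p1) if p >= t1]
        if not passed:
            continue

        nes_map: Dict[Tuple[int, Tuple[int, int]], object] = {}
        for s in passed:
            nes = extend_to_non_exact_stem(matrix, s, min_loop=config.min_loop)
            nes_map.setdefault((nes.diagonal, nes.region), nes)
        nes_list = list(nes_map.values())
        fvs2 = np.array(
            [stage2_features(nes, wseq, energy).as_array() for nes in nes_list]
        )
        p2 = model.models[2].predict_proba(fvs2)
        nes_passed = [nes for nes, p in zip(nes_list, p2) if p >= t2]
        if not nes_passed:
            continue

        hp_map: Dict[Tuple[int, int, str], HairpinCandidate] = {}
        for nes in nes_passed:
            hp = build_hairpin(matrix, nes, search)
            if not filter_by_size(hp, config.min_size, config.max_size):
                continue
            hp_map.setdefault((hp.start, hp.end, hp.structure), hp)
        if not hp_map:
            continue
        hps = list(hp_map.values())
        fvs3 = np.array(
            [stage3_features(hp, wseq, energy).as_array() for hp in hps]
        )
        p3 = model.models[3].predict_proba(fvs3)
        for hp, p in zip(hps, p3):
            if p < t3:
                continue
            key = (hp.start + offset, hp.end + offset, hp.structure)
            if key in seen:
                continue
            seen.add(key)
            predictions.append(
                Prediction(
                    sequence_id=seq.id,
                    start=hp.start + offset,
                    end=hp.end + offset,
                    probability=float(p),
                    structure=hp.structure,
                    window_start=offset,
                )
            )
    return merge_predictions(predictions)


def _reciprocal_overlap(a: Prediction, b: Prediction) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start), inter / (b.end - b.start))


def merge_predictions(preds: Sequence[Prediction]) -> List[Prediction]:
    """Collapse duplicate detections of the same hairpin from overlapping
    windows: predictions overlapping >= 50% reciprocally are grouped around
    their maximum-probability member, which represents the group.

    Implemented as non-maximum suppression (highest probability first) so
    that chains of pairwise overlaps cannot collapse distinct loci into one
    group.  Output sorted by start.
    """
    if not preds:
        return []
    order = sorted(preds, key=lambda p: (-p.probability, p.start, p.end))
    kept: List[Prediction] = []
    for p in order:
        if all(_reciprocal_overlap(p, q) < 0.5 for q in kept):
            kept.append(p)
    return sorted(kept, key=lambda p: (p.start, p.end))


def compute_metrics(tp: int, fn: int, fp: int) -> Tuple[float, float, float]:
    """Sensitivity, selectivity and their geometric mean, as percentages.

    SN = 100*TP/(TP+FN); SL = 100*TP/(TP+FP); GM = sqrt(SN*SL).  A zero
    denominator yields 0 for the affected metric, with a warning.
    """
    if tp < 0 or fn < 0 or fp < 0:
        raise InvalidInputError("counts must be non-negative")
    if tp + fn == 0:
        logger.warning("TP+FN == 0; sensitivity set to 0")
        sn = 0.0
    else:
        sn = 100.0 * tp / (tp + fn)
    if tp + fp == 0:
        logger.warning("TP+FP == 0; selectivity set to 0")
        sl = 0.0
    else:
        sl = 100.0 * tp / (tp + fp)
    return sn, sl, geometric_mean(sn, sl)


def geometric_mean(sn: float, sl: float) -> float:
    """GM = sqrt(SN * SL)."""
    return math.sqrt(sn * sl)


def match_predictions(
    preds: Sequence[Prediction], known: Sequence[Interval]
) -> EvaluationResult:
    """Greedy one-to-one matching by smallest center distance.

    A prediction is a true positive when the distance from its center to the
    center of a known hairpin is <= 10% of the known hairpin's size; each
    known hairpin (and each prediction) is matched at most once.
    """
    candidates = []
    for pi, p in enumerate(preds):
        for ki, k in enumerate(known):
            if k.chrom != p.sequence_id:
                continue
            dist = abs(p.center - k.center)
            if dist <= 0.1 * len(k):
                candidates.append((dist, pi, ki))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_p: set = set()
    used_k: set = set()
    matches: List[Tuple[Prediction, Interval]] = []
    for dist, pi, ki in candidates:
        if pi in used_p or ki in used_k:
            continue
        used_p.add(pi)
        used_k.add(ki)
        matches.append((preds[pi], known[ki]))
    tp = len(matches)
    fp = len(preds) - tp
    fn = len(known) - tp
    sn, sl, gm = compute_metrics(tp, fn, fp)
    return EvaluationResult(tp=tp, fp=fp, fn=fn, sn=sn, sl=sl, gm=gm, matches=matches)
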