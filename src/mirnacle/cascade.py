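"""Stage-wise training sets, SMOTE rebalancing and the three-model cascade.

Each structural stage (exact stem, non-exact stem, hairpin) has its own
training set and its own random-forest model.  Minority classes are
rebalanced to parity with SMOTE before training; at prediction time a
candidate passes a stage when its positive-class probability is greater
than or equal to the stage threshold.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from . import io as mio
from .errors import (
    CVConfigurationError,
    InconsistentInputError,
    InsufficientMinorityError,
    InvalidInputError,
    TrainingDataError,
)
from .features import (
    STAGE_NAMES,
    EnergyBackend,
    FeatureVector,
    StackingEnergyModel,
    stage1_features,
    stage2_features,
    stage3_features,
)
from .hairpin_search import (
    SearchConfig,
    build_hairpin,
    extend_to_non_exact_stem,
    find_exact_stems,
)
from .pairing_matrix import RNASequence, build_pairing_matrix
from .scanner import compute_metrics

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE = "positive", "negative"


@dataclass(frozen=True)
class LabeledExample:
    vector: FeatureVector
    label: str
    source_id: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise InvalidInputError(f"unknown label {self.label!r}")


@dataclass
class StageTrainingSet:
    stage: int
    examples: List[LabeledExample] = field(default_factory=list)

    def add(self, example: LabeledExample) -> None:
        if example.vector.stage != self.stage:
            raise InconsistentInputError(
                f"stage-{example.vector.stage} vector added to a "
                f"stage-{self.stage} training set"
            )
        self.examples.append(example)

    @property
    def class_counts(self) -> Dict[str, int]:
        counts = {POSITIVE: 0, NEGATIVE: 0}
        for ex in self.examples:
            counts[ex.label] += 1
        return counts

    def arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        X = np.array([ex.vector.as_array() for ex in self.examples])
        y = np.array([1 if ex.label == POSITIVE else 0 for ex in self.examples])
        return X, y

    def to_arff(self, path) -> None:
        X, _ = self.arrays()
        mio.write_arff(
            path,
            relation=f"stage{self.stage}",
            attribute_names=STAGE_NAMES[self.stage],
            rows=X.tolist(),
            labels=[ex.label for ex in self.examples],
        )

    @classmethod
    def from_arff(cls, path, stage: Optional[int] = None) -> "StageTrainingSet":
        relation, names, rows, labels = mio.read_arff(path)
        if stage is None:
            by_len = {len(v): k for k, v in STAGE_NAMES.items()}
            if len(names) not in by_len:
                raise InvalidInputError(
                    f"cannot infer stage from {len(names)} attributes"
                )
            stage = by_len[len(names)]
        ts = cls(stage=stage)
        for row, label in zip(rows, labels):
            ts.add(
                LabeledExample(
                    vector=FeatureVector(stage=stage, values=tuple(row)),
                    label=label,
                    source_id=relation,
                )
            )
        return ts


# ---------------------------------------------------------------------------
# SMOTE


def _smote_arrays(
    X_min: np.ndarray,
    k: int,
    n_synthetic: int,
    rng: np.random.Generator,
    scale_min: np.ndarray,
    scale_range: np.ndarray,
) -> np.ndarray:
    """Synthetic minority points x + u * (x_nn - x) in the original feature
    space, with neighbors found under min-max scaling."""
    if len(X_min) < 2:
        raise InsufficientMinorityError(
            f"SMOTE needs >= 2 minority examples, got {len(X_min)}"
        )
    if n_synthetic == 0:
        return np.empty((0, X_min.shape[1]))
    k_eff = min(k, len(X_min) - 1)
    Xs = (X_min - scale_min) / scale_range
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xs)
    _, idx = nn.kneighbors(Xs)  # first neighbor is the point itself
    base = rng.integers(0, len(X_min), size=n_synthetic)
    pick = rng.integers(1, k_eff + 1, size=n_synthetic)
    u = rng.uniform(0.0, 1.0, size=n_synthetic)
    neighbors = idx[base, pick]
    return X_min[base] + u[:, None] * (X_min[neighbors] - X_min[base])


def smote_oversample(
    minority: Sequence[FeatureVector],
    k: int,
    target: int,
    seed: int,
) -> List[FeatureVector]:
    """SMOTE: interpolate each synthetic point between a minority example and
    one of its k nearest neighbors (Euclidean on min-max-scaled features).

    Returns ``target - len(minority)`` synthetic vectors; deterministic for a
    fixed seed.
    """
    if len(minority) < 2:
        raise InsufficientMinorityError(
            f"SMOTE needs >= 2 minority examples, got {len(minority)}"
        )
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if target < len(minority):
        raise InvalidInputError("target must be >= the minority size")
    stage = minority[0].stage
    X = np.array([fv.as_array() for fv in minority])
    lo, rng_span = _minmax_bounds(X)
    synth = _smote_arrays(
        X, k, target - len(minority), np.random.default_rng(seed), lo, rng_span
    )
    return [FeatureVector(stage=stage, values=tuple(row)) for row in synth]


def _minmax_bounds(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    return lo, span


# ---------------------------------------------------------------------------
# Stage models


@dataclass
class StageModel:
    """A trained per-stage classifier emitting P(positive)."""

    stage: int
    forest: RandomForestClassifier
    scale_min: np.ndarray
    scale_range: np.ndarray
    seed: int
    smote_k: int
    n_trees: int

    @property
    def feature_names(self) -> Tuple[str, ...]:
        return STAGE_NAMES[self.stage]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(positive) for each row of X (original feature space)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise InconsistentInputError(
                f"stage-{self.stage} model expects {len(self.feature_names)} "
                f"features, got {X.shape[1]}"
            )
        Xs = (X - self.scale_min) / self.scale_range
        proba = self.forest.predict_proba(Xs)
        pos_col = list(self.forest.classes_).index(1)
        return proba[:, pos_col]


def train_stage_model(
    ts: StageTrainingSet,
    smote_k: int = 5,
    n_trees: int = 100,
    seed: int = 0,
) -> StageModel:
    """SMOTE the minority class to parity, then train a random forest."""
    counts = ts.class_counts
    if counts[POSITIVE] == 0 or counts[NEGATIVE] == 0:
        raise TrainingDataError(
            f"stage {ts.stage}: need both classes, got {counts}"
        )
    X, y = ts.arrays()
    lo, span = _minmax_bounds(X)
    Xs = (X - lo) / span
    n_pos, n_neg = counts[POSITIVE], counts[NEGATIVE]
    rng = np.random.default_rng(seed)
    if n_pos != n_neg:
        minority_label = 1 if n_pos < n_neg else 0
        X_min = Xs[y == minority_label]
        n_synth = abs(n_neg - n_pos)
        if len(X_min) >= 2:
            zeros = np.zeros(X.shape[1])
            ones = np.ones(X.shape[1])
            synth = _smote_arrays(X_min, smote_k, n_synth, rng, zeros, ones)
            Xs = np.vstack([Xs, synth])
            y = np.concatenate([y, np.full(n_synth, minority_label)])
        else:
            raise InsufficientMinorityError(
                f"stage {ts.stage}: minority class has {len(X_min)} examples"
            )
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(Xs, y)
    return StageModel(
        stage=ts.stage,
        forest=forest,
        scale_min=lo,
        scale_range=span,
        seed=seed,
        smote_k=smote_k,
        n_trees=n_trees,
    )


def classify_stage(
    model: StageModel, fv: FeatureVector, threshold: float
) -> Tuple[float, bool]:
    """Probability of the positive class and the inclusive threshold gate."""
    if fv.stage != model.stage:
        raise InconsistentInputError(
            f"stage-{fv.stage} vector given to a stage-{model.stage} model"
        )
    if not 0.0 <= threshold <= 1.0:
        raise InvalidInputError("threshold must be in [0, 1]")
    p = float(model.predict_proba(fv.as_array()[None, :])[0])
    return p, p >= threshold


@dataclass
class CascadeModel:
    """Three stage models plus their probability thresholds."""

    models: Dict[int, StageModel]
    thresholds: Tuple[float, float, float] = (0.3, 0.3, 0.7)

    def __post_init__(self) -> None:
        if set(self.models) != {1, 2, 3}:
            raise InvalidInputError("cascade requires models for stages 1, 2, 3")
        for t in self.thresholds:
            if not 0.0 <= t <= 1.0:
                raise InvalidInputError("thresholds must be in [0, 1]")

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"thresholds": list(self.thresholds), "stages": {}}
        for stage, model in self.models.items():
            with open(directory / f"stage{stage}.pkl", "wb") as fh:
                pickle.dump(model, fh)
            meta["stages"][str(stage)] = {
                "seed": model.seed,
                "smote_k": model.smote_k,
                "n_trees": model.n_trees,
                "feature_names": list(model.feature_names),
                "scale_min": model.scale_min.tolist(),
                "scale_range": model.scale_range.tolist(),
            }
        with open(directory / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, directory) -> "CascadeModel":
        directory = Path(directory)
        with open(directory / "metadata.json") as fh:
            meta = json.load(fh)
        models = {}
        for stage in (1, 2, 3):
            with open(directory / f"stage{stage}.pkl", "rb") as fh:
                models[stage] = pickle.load(fh)
        return cls(models=models, thresholds=tuple(meta["thresholds"]))


# ---------------------------------------------------------------------------
# Training-set construction


def _best_candidates(seq: RNASequence, config: SearchConfig):
    """Highest-scoring exact stem, non-exact stem and hairpin of a sequence
    (most paired bases, ties broken 5'-most), or None per stage."""
    matrix = build_pairing_matrix(seq)
    stems = find_exact_stems(matrix, config.min_exact_stem, config.min_loop)
    if not stems:
        return None, None, None
    best_stem = max(stems, key=lambda s: (s.length, -s.arm5[0]))
    nes_list = [
        extend_to_non_exact_stem(matrix, s, min_loop=config.min_loop)
        for s in stems
    ]
    best_nes = max(nes_list, key=lambda x: (x.total_pairs, -x.region[0]))
    seen = set()
    hairpins = []
    for nes in nes_list:
        key = (nes.diagonal, nes.region)
        if key in seen:
            continue
        seen.add(key)
        hairpins.append(build_hairpin(matrix, nes, config))
    best_hp = max(hairpins, key=lambda h: (h.n_pairs, -h.start))
    return best_stem, best_nes, best_hp


def build_stage_training_sets(
    positives: Sequence[RNASequence],
    negatives: Sequence[RNASequence],
    config: Optional[SearchConfig] = None,
    energy: Optional[EnergyBackend] = None,
) -> Tuple[StageTrainingSet, StageTrainingSet, StageTrainingSet]:
    """Run every example sequence through the ungated structural pipeline and
    keep its single best candidate per stage as one labeled example.

    Sequences yielding no candidate at some stage are skipped for that stage
    with a warning; an empty class in any resulting set raises
    :class:`TrainingDataError`.
    """
    if not positives or not negatives:
        raise InvalidInputError("positive and negative lists must be non-empty")
    config = config or SearchConfig()
    energy = energy or StackingEnergyModel()
    sets = (
        StageTrainingSet(stage=1),
        StageTrainingSet(stage=2),
        StageTrainingSet(stage=3),
    )
    for label, seqs in ((POSITIVE, positives), (NEGATIVE, negatives)):
        for seq in seqs:
            stem, nes, hp = _best_candidates(seq, config)
            if stem is None:
                logger.warning(
                    "sequence %s produced no exact stem; skipped", seq.id
                )
                continue
            sets[0].add(
                LabeledExample(stage1_features(stem, seq, energy), label, seq.id)
            )
            sets[1].add(
                LabeledExample(stage2_features(nes, seq, energy), label, seq.id)
            )
            sets[2].add(
                LabeledExample(stage3_features(hp, seq, energy), label, seq.id)
            )
    for ts in sets:
        counts = ts.class_counts
        if counts[POSITIVE] == 0 or counts[NEGATIVE] == 0:
            raise TrainingDataError(
                f"stage {ts.stage}: a class ended up empty ({counts})"
            )
    return sets


def train_cascade(
    positives: Sequence[RNASequence],
    negatives: Sequence[RNASequence],
    config: Optional[SearchConfig] = None,
    thresholds: Tuple[float, float, float] = (0.3, 0.3, 0.7),
    smote_k: int = 5,
    n_trees: int = 100,
    seed: int = 0,
    energy: Optional[EnergyBackend] = None,
) -> CascadeModel:
    """Convenience wrapper: build stage training sets and train all models."""
    sets = build_stage_training_sets(positives, negatives, config, energy)
    models = {
        ts.stage: train_stage_model(ts, smote_k=smote_k, n_trees=n_trees, seed=seed)
        for ts in sets
    }
    return CascadeModel(models=models, thresholds=thresholds)


# ---------------------------------------------------------------------------
# Cross-validation


def cross_validate(
    ts: StageTrainingSet,
    folds: int = 10,
    seed: int = 0,
    smote_k: int = 5,
    n_trees: int = 100,
    decision_threshold: float = 0.5,
) -> Tuple[float, float, float]:
    """Stratified k-fold CV with SMOTE applied inside training folds only.

    Confusion counts are pooled over folds; returns (SN, SL, GM) as
    percentages.
    """
    if folds < 2:
        raise CVConfigurationError("folds must be >= 2")
    counts = ts.class_counts
    if min(counts.values()) < folds:
        raise CVConfigurationError(
            f"each class needs >= {folds} members for {folds}-fold CV, "
            f"got {counts}"
        )
    X, y = ts.arrays()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = fp = fn = 0
    for fold_idx, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        sub = StageTrainingSet(stage=ts.stage)
        for i in train_idx:
            sub.add(ts.examples[i])
        model = train_stage_model(
            sub, smote_k=smote_k, n_trees=n_trees, seed=seed + fold_idx
        )
        p = model.predict_proba(X[test_idx])
        pred = p >= decision_threshold
        truth = y[test_idx] == 1
        tp += int(np.sum(pred & truth))
        fp += int(np.sum(pred & ~truth))
        fn += int(np.sum(~pred & truth))
    return compute_metrics(tp, fn, fp)
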