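"""Training-set assembly and the class-weighted logistic-regression classifier.

The labeled-set recipe mirrors the construction the detector was designed
around: positives are independently validated editing sites (a consensus set
plus a smaller extra-validated set); negatives are drawn from per-criterion
hard-filter-failing pools, aligner-discordant sites, known SNPs and
unvalidated calls.  With the canonical pool sizes (7x150 + 300 + 1200 + 375)
the negative set has 2925 members and, with 1475 positives, the full set has
4400 examples at roughly a 1:2 positive:negative mix.

The classifier is logistic regression with a positive-class weight of 2.0.
Hyperparameters (L1 vs L2 penalty and the regularization strength) are chosen
by five-fold cross-validated grid search maximizing F0.5, the
precision-weighted F-measure; feature standardization is fitted inside each
fold.  The final model is refit on all examples with the winning settings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import fbeta_score, make_scorer
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import CapacityError, DegenerateDataError, FeatureOrderError
from .features import FEATURE_NAMES

MODEL_FORMAT_VERSION = 1

__all__ = ["LabeledExample", "PoolSizes", "HyperParameterGrid", "Model",
           "assemble_training_set", "f_beta", "train_classifier",
           "split_train_test"]


@dataclass
class LabeledExample:
    """A site with its feature vector, label and sampling provenance."""

    site: object                      # CandidateSite or any hashable site id
    label: int                        # 1 positive, 0 negative
    provenance: str
    features: Optional[np.ndarray] = None

    POSITIVE_TAGS = ("consensus-validated", "two-method-validated")
    NEGATIVE_TAGS = ("filter-fail", "aligner-discordant", "snp", "unvalidated")


def _site_key(site: object):
    key = getattr(site, "key", None)
    return key if key is not None else site


@dataclass
class PoolSizes:
    """How many negatives to draw from each pool (defaults: canonical sizes)."""

    filter_fail: Tuple[int, ...] = (150,) * 7
    aligner_discordant: int = 300
    snp: int = 1200
    unvalidated: int = 375

    @property
    def total(self) -> int:
        return sum(self.filter_fail) + self.aligner_discordant + self.snp \
            + self.unvalidated


def _sample(pool: Sequence, n: int, rng: np.random.Generator, name: str) -> List:
    if n > len(pool):
        raise CapacityError(
            f"pool {name!r} holds {len(pool)} sites; {n} requested"
        )
    if n == len(pool):
        return list(pool)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def assemble_training_set(
    consensus_positives: Sequence,
    extra_validated: Sequence,
    filter_fail_pools: Sequence[Sequence],
    aligner_discordant: Sequence,
    snp_sites: Sequence,
    unvalidated: Sequence,
    per_pool_n: Optional[PoolSizes] = None,
    seed: int = 0,
) -> List[LabeledExample]:
    """Assemble labeled examples following the canonical recipe.

    All positives are kept; negatives are sampled per pool with a fixed seed.
    A site appearing in several pools keeps its first-listed provenance.
    """
    sizes = per_pool_n or PoolSizes()
    if len(sizes.filter_fail) != len(filter_fail_pools):
        raise ValueError(
            f"{len(filter_fail_pools)} filter-fail pools but "
            f"{len(sizes.filter_fail)} requested counts"
        )
    rng = np.random.default_rng(int(seed))
    examples: List[LabeledExample] = []
    seen = set()

    def _extend(sites: Sequence, label: int, provenance: str) -> None:
        for site in sites:
            key = _site_key(site)
            if key in seen:
                continue
            seen.add(key)
            examples.append(LabeledExample(site, label, provenance))

    _extend(consensus_positives, 1, "consensus-validated")
    _extend(extra_validated, 1, "two-method-validated")
    for i, (pool, n) in enumerate(zip(filter_fail_pools, sizes.filter_fail)):
        _extend(_sample(pool, n, rng, f"filter-fail[{i}]"), 0, "filter-fail")
    _extend(_sample(aligner_discordant, sizes.aligner_discordant, rng,
                    "aligner-discordant"), 0, "aligner-discordant")
    _extend(_sample(snp_sites, sizes.snp, rng, "snp"), 0, "snp")
    _extend(_sample(unvalidated, sizes.unvalidated, rng, "unvalidated"),
            0, "unvalidated")
    return examples


def f_beta(precision: float, recall: float, beta: float = 0.5) -> float:
    """F-beta = (1 + b^2) P R / (b^2 P + R); defined as 0 when P = R = 0."""
    if not 0.0 <= precision <= 1.0 or not 0.0 <= recall <= 1.0:
        raise ValueError("precision and recall must lie in [0, 1]")
    if beta <= 0:
        raise ValueError("beta must be positive")
    denom = beta * beta * precision + recall
    if denom == 0.0:
        return 0.0
    return (1.0 + beta * beta) * precision * recall / denom


@dataclass
class HyperParameterGrid:
    penalties: Tuple[str, ...] = ("l1", "l2")
    strengths: Tuple[float, ...] = tuple(np.logspace(-3, 3, 7))
    positive_weight: float = 2.0
    folds: int = 5
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not self.penalties or not self.strengths:
            raise ValueError("grid must be non-empty")
        if self.folds < 2:
            raise ValueError("fold count must be >= 2")


@dataclass
class Model:
    """A trained linear-logistic classifier with its standardization.

    ``score = sigmoid(((x - center) / scale) . weights + intercept)``, on
    feature vectors in the exact order of ``feature_names``.
    """

    feature_names: Tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    weights: np.ndarray
    intercept: float
    penalty: str
    C: float
    positive_weight: float
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.feature_names)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.center) == len(self.scale) == len(self.weights) == n):
            raise ValueError("weight/scaling lengths must match feature count")

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return ((X - self.center) / self.scale) @ self.weights + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.decision(X)
        return 1.0 / (1.0 + np.exp(-z))

    def to_dict(self) -> Dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "feature_names": list(self.feature_names),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "weights": self.weights.tolist(),
            "intercept": float(self.intercept),
            "penalty": self.penalty,
            "C": float(self.C),
            "positive_weight": float(self.positive_weight),
            "metadata": self.metadata,
        }

    def save(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")
        return path

    @classmethod
    def from_dict(cls, doc: Dict) -> "Model":
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format {doc.get('format_version')!r}"
            )
        return cls(
            feature_names=tuple(doc["feature_names"]),
            center=np.array(doc["center"]),
            scale=np.array(doc["scale"]),
            weights=np.array(doc["weights"]),
            intercept=float(doc["intercept"]),
            penalty=doc["penalty"],
            C=float(doc["C"]),
            positive_weight=float(doc["positive_weight"]),
            metadata=doc.get("metadata", {}),
        )

    @classmethod
    def load(cls, path: str) -> "Model":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _example_matrix(
    examples: Sequence[LabeledExample],
) -> Tuple[np.ndarray, np.ndarray]:
    X = np.vstack([np.asarray(e.features, dtype=float) for e in examples])
    y = np.array([e.label for e in examples], dtype=int)
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        i, j = bad[0]
        name = FEATURE_NAMES[j] if X.shape[1] == len(FEATURE_NAMES) else f"#{j}"
        raise DegenerateDataError(
            f"non-finite feature {name} at example "
            f"{_site_key(examples[int(i)].site)}"
        )
    return X, y


def train_classifier(
    examples: Sequence[LabeledExample],
    grid: Optional[HyperParameterGrid] = None,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> Model:
    """Fit the class-weighted LR classifier with CV + grid search.

    Standardization is fitted on the training folds only during cross
    validation; the grid point with the highest mean cross-validated F0.5 is
    refit on all examples.  Deterministic for fixed inputs and seed.
    """
    grid = grid or HyperParameterGrid()
    X, y = _example_matrix(examples)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DegenerateDataError("training requires both classes")
    if counts.min() < grid.folds:
        raise DegenerateDataError(
            f"minority class has {counts.min()} examples; "
            f"{grid.folds}-fold CV impossible"
        )
    names = tuple(feature_names) if feature_names is not None else (
        FEATURE_NAMES if X.shape[1] == len(FEATURE_NAMES)
        else tuple(f"f{i}" for i in range(X.shape[1]))
    )
    if len(names) != X.shape[1]:
        raise FeatureOrderError(
            f"{len(names)} feature names for {X.shape[1]}-dimensional vectors"
        )

    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(
            solver="liblinear",
            class_weight={0: 1.0, 1: grid.positive_weight},
            max_iter=2000,
            random_state=int(seed) % (2**31),
        )),
    ])
    scorer = make_scorer(fbeta_score, beta=grid.beta, zero_division=0)
    # l1_ratio 1.0 <-> L1, 0.0 <-> L2 (sklearn >= 1.8 parameterization)
    ratio_of = {"l1": 1.0, "l2": 0.0}
    search = GridSearchCV(
        pipe,
        param_grid={"clf__l1_ratio": [ratio_of[p] for p in grid.penalties],
                    "clf__C": list(grid.strengths)},
        scoring=scorer,
        cv=StratifiedKFold(n_splits=grid.folds, shuffle=True,
                           random_state=int(seed) % (2**31)),
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    best = search.best_estimator_
    scaler: StandardScaler = best.named_steps["scale"]
    clf: LogisticRegression = best.named_steps["clf"]
    return Model(
        feature_names=names,
        center=scaler.mean_,
        scale=scaler.scale_,
        weights=clf.coef_[0],
        intercept=float(clf.intercept_[0]),
        penalty="l1" if search.best_params_["clf__l1_ratio"] == 1.0 else "l2",
        C=float(search.best_params_["clf__C"]),
        positive_weight=grid.positive_weight,
        metadata={
            "seed": int(seed),
            "folds": grid.folds,
            "n_examples": int(len(examples)),
            "n_positive": int(counts[classes == 1][0]),
            "cv_f05": float(search.best_score_),
            "grid_penalties": list(grid.penalties),
            "grid_strengths": [float(c) for c in grid.strengths],
        },
    )


def split_train_test(
    examples: Sequence[LabeledExample],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> Tuple[List[LabeledExample], List[LabeledExample]]:
    """Label-stratified train/test split (default 80/20)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    labels = [e.label for e in examples]
    try:
        train, test = train_test_split(
            list(examples), test_size=test_fraction,
            stratify=labels, random_state=int(seed) % (2**31),
        )
    except ValueError as exc:
        raise CapacityError(f"cannot stratify split: {exc}") from exc
    return train, test
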