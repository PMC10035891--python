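"""Single-feature Gaussian naive-Bayes case/control classification.

Class balancing (down/up sampling), repeated stratified k-fold
cross-validation, out-of-sample transfer between datasets, rank-based AUC
and binomial significance of the achieved accuracy. The case class is the
positive class throughout. No preprocessing beyond balancing and no
hyperparameter tuning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FeatureSet",
    "GaussianNB1D",
    "balance",
    "repeated_kfold",
    "out_of_sample",
    "auc_rank",
    "binomial_significance",
    "PerfReport",
]

POSITIVE = "case"
NEGATIVE = "control"


@dataclass
class FeatureSet:
    """One feature value per subject with a class label."""

    features: np.ndarray
    labels: np.ndarray  # strings "control" / "case"
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float).ravel()
        self.labels = np.asarray(self.labels)
        if self.features.shape != self.labels.shape:
            raise ValueError("features and labels must have equal length")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        bad = set(np.unique(self.labels)) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")

    def class_counts(self) -> dict[str, int]:
        return {
            c: int(np.sum(self.labels == c)) for c in (NEGATIVE, POSITIVE)
        }

    def subset(self, idx: np.ndarray) -> "FeatureSet":
        return FeatureSet(self.features[idx], self.labels[idx], self.dataset_id)


class GaussianNB1D:
    """Closed-form Gaussian naive Bayes for a single feature.

    Per-class Gaussian likelihoods (sample variance) with class priors
    estimated from the training labels.
    """

    def __init__(self) -> None:
        self.params_: dict[str, tuple[float, float, float]] = {}

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "GaussianNB1D":
        features = np.asarray(features, dtype=float).ravel()
        labels = np.asarray(labels)
        classes = np.unique(labels)
        if len(classes) < 2:
            raise ValueError("both classes required for training")
        self.params_ = {}
        for c in classes:
            vals = features[labels == c]
            if vals.size < 2:
                raise ValueError(f"class {c!r} needs >= 2 training samples")
            var = float(np.var(vals, ddof=1))
            if var == 0:
                raise ValueError(f"class {c!r} has zero feature variance")
            self.params_[str(c)] = (
                float(np.mean(vals)),
                var,
                vals.size / features.size,
            )
        return self

    def posterior(self, features: np.ndarray) -> np.ndarray:
        """P(case | x) for each test feature."""
        if not self.params_:
            raise RuntimeError("fit before predicting")
        x = np.asarray(features, dtype=float).ravel()
        like = {}
        for c, (mu, var, prior) in self.params_.items():
            like[c] = prior * sps.norm.pdf(x, loc=mu, scale=np.sqrt(var))
        total = like[POSITIVE] + like[NEGATIVE]
        # both likelihoods can underflow far from the data; fall back to prior
        post = np.where(
            total > 0, like[POSITIVE] / np.where(total > 0, total, 1.0),
            self.params_[POSITIVE][2],
        )
        return post

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.where(self.posterior(features) >= 0.5, POSITIVE, NEGATIVE)


def balance(
    fset: FeatureSet,
    mode: str = "down",
    seed: int | np.random.Generator | None = 0,
    n_per_class: int | None = None,
) -> FeatureSet:
    """Equalize class counts by seeded down- or up-sampling.

    ``mode="down"`` removes random majority-class subjects; ``"up"``
    resamples the minority class with replacement. ``n_per_class`` forces
    a specific per-class count (used for cross-dataset testing); it must
    not exceed the available count under down-sampling.
    """
    if mode not in ("down", "up"):
        raise ValueError(f"mode must be 'down' or 'up', got {mode!r}")
    rng = np.random.default_rng(seed)
    counts = fset.class_counts()
    if n_per_class is None:
        target = min(counts.values()) if mode == "down" else max(counts.values())
    else:
        target = n_per_class
    keep: list[np.ndarray] = []
    for c in (NEGATIVE, POSITIVE):
        idx = np.flatnonzero(fset.labels == c)
        if idx.size == target:
            keep.append(idx)
        elif idx.size > target:
            keep.append(rng.choice(idx, size=target, replace=False))
        else:
            if mode == "down" or n_per_class is not None:
                raise ValueError(
                    f"cannot draw {target} subjects from class {c!r} "
                    f"with only {idx.size} available"
                )
            extra = rng.choice(idx, size=target - idx.size, replace=True)
            keep.append(np.concatenate([idx, extra]))
    order = np.sort(np.concatenate(keep))
    return fset.subset(order)


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) formulation, ties mid-ranked."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == POSITIVE
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    ranks = sps.rankdata(scores)
    return float(
        (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def binomial_significance(
    n_correct: int, n_total: int, chance: float = 0.5
) -> float:
    """Upper-tail binomial p: P(X >= n_correct), X ~ Bin(n_total, chance)."""
    if not 0 <= n_correct <= n_total:
        raise ValueError("need 0 <= n_correct <= n_total")
    return float(sps.binom.sf(n_correct - 1, n_total, chance))


@dataclass
class PerfReport:
    """Classifier performance with case as the positive class."""

    auc: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    p_value: float
    n_per_class: dict[str, int] = field(default_factory=dict)
    sampling: str = "down"
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "p_value": self.p_value,
            "n_per_class": self.n_per_class,
            "sampling": self.sampling,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _rates(
    predictions: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, int]:
    pos = labels == POSITIVE
    sens = float(np.mean(predictions[pos] == POSITIVE)) if pos.any() else 0.0
    spec = float(np.mean(predictions[~pos] == NEGATIVE)) if (~pos).any() else 0.0
    n_correct = int(np.sum(predictions == labels))
    return sens, spec, (sens + spec) / 2.0, n_correct


def repeated_kfold(
    fset: FeatureSet,
    k: int = 10,
    reps: int = 20,
    sampling: str = "down",
    seed: int = 0,
) -> PerfReport:
    """Repeated stratified k-fold cross-validation on a balanced sample.

    Per repetition, held-out posterior scores and predictions are pooled
    over the k folds and scored; metrics are then averaged across
    repetitions. The binomial p-value uses the mean pooled correct count.
    """
    rng = np.random.default_rng(seed)
    balanced = balance(fset, mode=sampling, seed=rng)
    n = balanced.features.size
    if n < k:
        raise ValueError(f"{n} samples for {k} folds")
    y_int = (balanced.labels == POSITIVE).astype(int)

    aucs, baccs, senss, specs, corrects = [], [], [], [], []
    for rep in range(reps):
        splitter = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        scores = np.empty(n)
        preds = np.empty(n, dtype=object)
        for train_idx, test_idx in splitter.split(balanced.features[:, None], y_int):
            model = GaussianNB1D().fit(
                balanced.features[train_idx], balanced.labels[train_idx]
            )
            scores[test_idx] = model.posterior(balanced.features[test_idx])
            preds[test_idx] = model.predict(balanced.features[test_idx])
        sens, spec, bacc, n_correct = _rates(preds, balanced.labels)
        aucs.append(auc_rank(scores, balanced.labels))
        baccs.append(bacc)
        senss.append(sens)
        specs.append(spec)
        corrects.append(n_correct)
    mean_correct = int(round(float(np.mean(corrects))))
    return PerfReport(
        auc=float(np.mean(aucs)),
        balanced_accuracy=float(np.mean(baccs)),
        sensitivity=float(np.mean(senss)),
        specificity=float(np.mean(specs)),
        p_value=binomial_significance(mean_correct, n),
        n_per_class=balanced.class_counts(),
        sampling=sampling,
        seed=seed,
    )


def out_of_sample(
    train_set: FeatureSet,
    test_set: FeatureSet,
    n_balance: int = 53,
    sampling: str = "down",
    seed: int = 0,
) -> PerfReport:
    """Train on one balanced dataset, evaluate once on another.

    Both datasets are down-sampled to ``n_balance`` subjects per class so
    the two cohorts are comparable.
    """
    rng = np.random.default_rng(seed)
    train_b = balance(train_set, mode=sampling, seed=rng, n_per_class=n_balance)
    test_b = balance(test_set, mode=sampling, seed=rng, n_per_class=n_balance)
    model = GaussianNB1D().fit(train_b.features, train_b.labels)
    scores = model.posterior(test_b.features)
    preds = model.predict(test_b.features)
    sens, spec, bacc, n_correct = _rates(preds, test_b.labels)
    return PerfReport(
        auc=auc_rank(scores, test_b.labels),
        balanced_accuracy=bacc,
        sensitivity=sens,
        specificity=spec,
        p_value=binomial_significance(n_correct, test_b.features.size),
        n_per_class=test_b.class_counts(),
        sampling=sampling,
        seed=seed,
    )
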