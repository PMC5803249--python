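"""Low/high-energy conformation classification.

In Metropolis Monte Carlo over conformations, most random moves land in
high-energy regions that will be rejected anyway; a small, fast
classifier that recognizes low-energy conformations lets the sampler
skip the expensive energy-model evaluation for the rest.  The
classifier is a five-member ensemble of small logistic networks trained
on the same Fourier angle features as the regressor, with a threshold
energy (default 46 kcal/mol ≈ 2 eV) separating "low" from "high".  Each
member casts a binary vote; the ensemble probability is the mean of the
five votes, hence confined to {0, 0.2, 0.4, 0.6, 0.8, 1.0}, and a
conformation is called low when the probability exceeds 0.5 (five
voters, so no ties).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier

from .features import FeatureEncoding, encode_batch
from .regression import (
    MemberNetwork,
    NetworkSpec,
    SplitFractions,
    TrainingConfig,
    _standardize_fit,
    split_dataset,
)

__all__ = [
    "DEFAULT_CLASSIFIER_SPECS",
    "DEFAULT_THRESHOLD_KCAL_MOL",
    "ClassifierEnsemble",
    "ConfusionMatrix",
    "train_classifier_ensemble",
    "classify",
    "confusion_metrics",
]

#: The five classification-network architectures of the reference protocol.
DEFAULT_CLASSIFIER_SPECS = ((30,), (40,), (50,), (5, 5), (10, 3))

#: Default low/high threshold: 46 kcal/mol (2 eV).
DEFAULT_THRESHOLD_KCAL_MOL = 46.0


@dataclass
class ConfusionMatrix:
    """TP/FP/FN/TN counts; positive class = low-energy conformation."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, predicted_low, actual_low) -> "ConfusionMatrix":
        p = np.asarray(predicted_low, bool)
        a = np.asarray(actual_low, bool)
        return cls(
            tp=int(np.sum(p & a)), fp=int(np.sum(p & ~a)),
            fn=int(np.sum(~p & a)), tn=int(np.sum(~p & ~a)),
        )


def confusion_metrics(cm: ConfusionMatrix) -> dict:
    """Sensitivity TP/P, specificity TN/N, accuracy, F1 = 2TP/(2TP+FP+FN).

    Each metric is None (undefined) when its denominator is zero, never
    silently 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    p = cm.tp + cm.fn
    n = cm.tn + cm.fp
    return {
        "sensitivity": cm.tp / p if p > 0 else None,
        "specificity": cm.tn / n if n > 0 else None,
        "accuracy": (cm.tp + cm.tn) / cm.total,
        "f1": 2 * cm.tp / (2 * cm.tp + cm.fp + cm.fn)
        if (2 * cm.tp + cm.fp + cm.fn) > 0 else None,
    }


@dataclass
class ClassifierEnsemble:
    """Vote-averaging ensemble of logistic-output member networks."""

    members: list
    encoding: FeatureEncoding
    n_dihedrals: int
    threshold_energy: float
    x_mean: np.ndarray
    x_std: np.ndarray
    metadata: dict = field(default_factory=dict)

    def _features(self, angles_deg) -> np.ndarray:
        a = np.atleast_2d(np.asarray(angles_deg, float))
        if a.shape[1] != self.n_dihedrals:
            raise ValueError(
                f"configuration has {a.shape[1]} angles, model has {self.n_dihedrals}"
            )
        X = encode_batch(a, self.encoding)
        return (X - self.x_mean) / self.x_std

    def member_votes(self, angles_deg) -> np.ndarray:
        """(n_members, n_samples) binary low-energy votes."""
        Xs = self._features(angles_deg)
        return np.stack([(m.forward(Xs) > 0.5).astype(float)
                         for m in self.members])

    def probability_batch(self, angles_deg) -> np.ndarray:
        """Mean of member votes — a lattice of multiples of 1/n_members."""
        return self.member_votes(angles_deg).mean(axis=0)

    def classify_batch(self, angles_deg):
        prob = self.probability_batch(angles_deg)
        return prob, prob > 0.5

    def classify(self, angles_deg):
        prob, low = self.classify_batch(np.atleast_2d(angles_deg))
        return float(prob[0]), bool(low[0])

    def to_dict(self) -> dict:
        return {
            "kind": "classifier_ensemble",
            "members": [m.to_dict() for m in self.members],
            "encoding": self.encoding.to_dict(),
            "n_dihedrals": self.n_dihedrals,
            "threshold_energy": self.threshold_energy,
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierEnsemble":
        return cls(
            [MemberNetwork.from_dict(m) for m in d["members"]],
            FeatureEncoding.from_dict(d["encoding"]),
            int(d["n_dihedrals"]),
            float(d["threshold_energy"]),
            np.array(d["x_mean"]), np.array(d["x_std"]),
            d.get("metadata", {}),
        )

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ClassifierEnsemble":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_classifier_ensemble(angles_deg: np.ndarray, energies: np.ndarray,
                              threshold_energy: float = DEFAULT_THRESHOLD_KCAL_MOL,
                              specs=None, fractions: SplitFractions | None = None,
                              config: TrainingConfig | None = None,
                              encoding: FeatureEncoding | None = None,
                              base_seed: int = 0) -> ClassifierEnsemble:
    """Train the low/high-energy vote ensemble.

    Labels: 1 (positive, "low") where energy < ``threshold_energy``.
    Same features, split protocol and optimizer settings as the
    regression ensemble.  Aborts, reporting the class counts, if the
    thresholded dataset is single-class.
    """
    angles_deg = np.atleast_2d(np.asarray(angles_deg, float))
    energies = np.asarray(energies, float)
    labels = (energies < threshold_energy).astype(int)
    n_low, n_high = int(labels.sum()), int((1 - labels).sum())
    if n_low == 0 or n_high == 0:
        raise ValueError(
            f"single-class dataset at threshold {threshold_energy} kcal/mol: "
            f"{n_low} low / {n_high} high"
        )
    f = fractions or SplitFractions()
    cfg = config or TrainingConfig()
    enc = encoding or FeatureEncoding()
    if specs is None:
        specs = [NetworkSpec(s, base_seed + i)
                 for i, s in enumerate(DEFAULT_CLASSIFIER_SPECS)]
    else:
        specs = [s if isinstance(s, NetworkSpec) else NetworkSpec(tuple(s), base_seed + i)
                 for i, s in enumerate(specs)]

    n = angles_deg.shape[0]
    idx_train, idx_val, idx_test = split_dataset(n, f, seed=base_seed)
    X = encode_batch(angles_deg, enc)
    x_mean, x_std = _standardize_fit(X[idx_train])
    Xs = (X - x_mean) / x_std
    fit_idx = np.concatenate([idx_train, idx_val])
    val_fraction = f.validation / (f.train + f.validation)

    members, meta_members = [], []
    for mi, spec in enumerate(specs):
        clf = MLPClassifier(
            hidden_layer_sizes=spec.hidden_layer_sizes,
            activation="logistic",
            solver="adam",
            alpha=cfg.l2_penalty,
            batch_size=min(cfg.batch_size, len(fit_idx)),
            learning_rate_init=cfg.learning_rate,
            max_iter=cfg.max_epochs,
            early_stopping=True,
            validation_fraction=val_fraction,
            n_iter_no_change=cfg.patience,
            tol=cfg.tol,
            random_state=spec.seed,
        )
        clf.fit(Xs[fit_idx], labels[fit_idx])
        if not np.isfinite(clf.loss_):
            raise RuntimeError(
                f"member {mi} ({spec.hidden_layer_sizes}): non-finite training loss"
            )
        # binary MLPClassifier ends in a single logistic unit whose output
        # is P(class 1 = low)
        members.append(MemberNetwork.from_sklearn(clf, output_activation="logistic"))
        meta_members.append({
            "hidden_layer_sizes": list(spec.hidden_layer_sizes),
            "seed": spec.seed,
            "stopped_epoch": int(clf.n_iter_),
            "best_validation_score": float(clf.best_validation_score_),
        })

    return ClassifierEnsemble(
        members=members, encoding=enc, n_dihedrals=angles_deg.shape[1],
        threshold_energy=float(threshold_energy),
        x_mean=x_mean, x_std=x_std,
        metadata={
            "n_samples": n,
            "class_counts": {"low": n_low, "high": n_high},
            "split_sizes": [len(idx_train), len(idx_val), len(idx_test)],
            "test_indices": idx_test.tolist(),
            "base_seed": base_seed,
            "members": meta_members,
        },
    )


def classify(ensemble: ClassifierEnsemble, angles_deg):
    """(probability, is_low) of one configuration under the vote ensemble."""
    return ensemble.classify(angles_deg)
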