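"""Correlated dihedral energy regression: ensembles of logistic MLPs.

The correlated potential is a model-averaged ensemble of five
feed-forward networks with logistic (sigmoid) hidden units

    h_j^i(x_j^i) = 1 / (1 + exp(-x_j^i)),   x^i = b^{i-1} + ω^{i-1} h^{i-1},

a linear output unit, Fourier-encoded angle features, and the training
protocol: Adam, minibatch 200, L2 regularization, early stopping on a
13% validation split, 72/13/15 train/validation/test fractions.
Training is delegated to scikit-learn's MLPRegressor; prediction runs
through this module's own explicit matrix-vector forward pass over the
extracted weights, so a trained model is a plain, self-describing
archive of arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPRegressor

from .features import FeatureEncoding, encode_batch

__all__ = [
    "NetworkSpec",
    "SplitFractions",
    "TrainingConfig",
    "MemberNetwork",
    "EnergyNetworkEnsemble",
    "DEFAULT_REGRESSOR_SPECS",
    "split_dataset",
    "train_ensemble",
    "predict_energy",
    "evaluate_model",
    "regression_metrics",
    "KCAL_PER_EV",
]

#: 1 eV in kcal/mol, used only at reporting boundaries.
KCAL_PER_EV = 23.0605


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of one ensemble member."""

    hidden_layer_sizes: tuple
    seed: int = 0

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.hidden_layer_sizes)
        if not 1 <= len(sizes) <= 3:
            raise ValueError("1 to 3 hidden layers supported")
        if any(s < 1 for s in sizes):
            raise ValueError("hidden layer sizes must be positive")
        object.__setattr__(self, "hidden_layer_sizes", sizes)


#: The five prediction-network architectures of the reference protocol.
DEFAULT_REGRESSOR_SPECS = (
    (30, 10), (100, 10), (110, 7), (60, 30, 10), (50, 20, 8),
)


@dataclass(frozen=True)
class SplitFractions:
    """Train/validation/test fractions; defaults 0.72/0.13/0.15."""

    train: float = 0.72
    validation: float = 0.13
    test: float = 0.15

    def __post_init__(self):
        if min(self.train, self.validation, self.test) < 0:
            raise ValueError("fractions must be nonnegative")
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer hyperparameters shared by all ensemble members."""

    learning_rate: float = 1e-3
    l2_penalty: float = 1e-4
    batch_size: int = 200
    patience: int = 10          # early-stopping epochs without improvement
    tol: float = 1e-4           # relative improvement threshold
    max_epochs: int = 400


def split_dataset(n_samples: int, fractions: SplitFractions | None = None,
                  seed: int = 0):
    """Shuffle indices 0..n−1 into disjoint, exhaustive train/val/test sets.

    Validation and test sizes are floor-rounded from their fractions; the
    remainder goes to training (150 000 samples → 108 000/19 500/22 500).
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples to split")
    f = fractions or SplitFractions()
    n_val = int(np.floor(n_samples * f.validation))
    n_test = int(np.floor(n_samples * f.test))
    n_train = n_samples - n_val - n_test
    perm = np.random.default_rng(seed).permutation(n_samples)
    return (perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:])


def _logistic(x):
    # clip keeps exp() in range; exact for |x| < 500 where logistic is
    # already 0 or 1 to double precision
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))


@dataclass
class MemberNetwork:
    """Plain-array feed-forward network: logistic hidden layers + output.

    ``weights[i]`` has shape (fan_in, fan_out); forward pass is the
    layer-by-layer affine map followed by the logistic activation on
    hidden layers and ``output_activation`` ('identity' or 'logistic')
    on the last layer.
    """

    weights: list
    biases: list
    output_activation: str = "identity"

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = np.atleast_2d(np.asarray(X, float))
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last:
                h = _logistic(h)
            elif self.output_activation == "logistic":
                h = _logistic(h)
        return h[:, 0] if h.shape[1] == 1 else h

    def to_dict(self) -> dict:
        return {
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "output_activation": self.output_activation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MemberNetwork":
        return cls(
            [np.array(w) for w in d["weights"]],
            [np.array(b) for b in d["biases"]],
            d["output_activation"],
        )

    @classmethod
    def from_sklearn(cls, model, output_activation: str = "identity"):
        return cls([np.array(w) for w in model.coefs_],
                   [np.array(b) for b in model.intercepts_],
                   output_activation)


@dataclass
class EnergyNetworkEnsemble:
    """Model-averaged ensemble of member networks with shared scalers.

    Prediction is the arithmetic mean of the member outputs, de-scaled to
    kcal/mol.  Feature and target standardization statistics come from
    the training split only.
    """

    members: list
    encoding: FeatureEncoding
    n_dihedrals: int
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    metadata: dict = field(default_factory=dict)

    def _features(self, angles_deg) -> np.ndarray:
        a = np.atleast_2d(np.asarray(angles_deg, float))
        if a.shape[1] != self.n_dihedrals:
            raise ValueError(
                f"configuration has {a.shape[1]} angles, model has {self.n_dihedrals}"
            )
        X = encode_batch(a, self.encoding)
        return (X - self.x_mean) / self.x_std

    def member_predictions(self, angles_deg) -> np.ndarray:
        """(n_members, n_samples) member outputs in kcal/mol."""
        Xs = self._features(angles_deg)
        return np.stack([m.forward(Xs) * self.y_std + self.y_mean
                         for m in self.members])

    def predict_batch(self, angles_deg) -> np.ndarray:
        return self.member_predictions(angles_deg).mean(axis=0)

    evaluate_batch = predict_batch  # energy-model protocol

    def predict(self, angles_deg) -> float:
        return float(self.predict_batch(np.atleast_2d(angles_deg))[0])

    def to_dict(self) -> dict:
        return {
            "kind": "energy_network_ensemble",
            "members": [m.to_dict() for m in self.members],
            "encoding": self.encoding.to_dict(),
            "n_dihedrals": self.n_dihedrals,
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyNetworkEnsemble":
        return cls(
            [MemberNetwork.from_dict(m) for m in d["members"]],
            FeatureEncoding.from_dict(d["encoding"]),
            int(d["n_dihedrals"]),
            np.array(d["x_mean"]), np.array(d["x_std"]),
            float(d["y_mean"]), float(d["y_std"]),
            d.get("metadata", {}),
        )

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "EnergyNetworkEnsemble":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _standardize_fit(X_train):
    mean = X_train.mean(axis=0)
    std = X_train.std(axis=0)
    std[std < 1e-12] = 1.0  # constant features carry no information
    return mean, std


def train_ensemble(angles_deg: np.ndarray, energies: np.ndarray,
                   specs=None, fractions: SplitFractions | None = None,
                   config: TrainingConfig | None = None,
                   encoding: FeatureEncoding | None = None,
                   base_seed: int = 0,
                   allow_constant_target: bool = False) -> EnergyNetworkEnsemble:
    """Train the model-averaged regression ensemble.

    Every member sees the same 72/13/15 split (derived from
    ``base_seed``); members differ only by architecture and by their own
    initialization seed ``base_seed + member index``.  Each is trained
    with Adam (minibatch 200), L2 penalty, and early stopping monitored
    on the validation fraction; the best-validation-epoch weights are
    retained.  Returns the ensemble with training metadata (split sizes,
    per-member stopped epoch and validation loss) and the test indices
    recorded for downstream evaluation.
    """
    angles_deg = np.atleast_2d(np.asarray(angles_deg, float))
    energies = np.asarray(energies, float)
    if angles_deg.shape[0] != energies.shape[0]:
        raise ValueError("angles and energies length mismatch")
    if angles_deg.shape[0] < 50:
        raise ValueError("need at least 50 samples")
    if not np.all(np.isfinite(energies)):
        raise ValueError("non-finite energies in dataset")
    f = fractions or SplitFractions()
    cfg = config or TrainingConfig()
    enc = encoding or FeatureEncoding()
    n_d = angles_deg.shape[1]
    if specs is None:
        specs = [NetworkSpec(s, base_seed + i)
                 for i, s in enumerate(DEFAULT_REGRESSOR_SPECS)]
    else:
        specs = [s if isinstance(s, NetworkSpec) else NetworkSpec(tuple(s), base_seed + i)
                 for i, s in enumerate(specs)]

    n = angles_deg.shape[0]
    idx_train, idx_val, idx_test = split_dataset(n, f, seed=base_seed)
    assert not (set(idx_train) & set(idx_val) or set(idx_train) & set(idx_test)
                or set(idx_val) & set(idx_test)), "split leakage"

    X = encode_batch(angles_deg, enc)
    x_mean, x_std = _standardize_fit(X[idx_train])
    y_mean = float(energies[idx_train].mean())
    y_std = float(energies[idx_train].std())
    degenerate_target = y_std < 1e-12
    if degenerate_target:
        if not allow_constant_target:
            raise ValueError("degenerate (constant) target variance")
        y_std = 1.0
    Xs = (X - x_mean) / x_std
    ys = (energies - y_mean) / y_std

    fit_idx = np.concatenate([idx_train, idx_val])
    # sklearn's early stopping holds out validation_fraction of the data
    # passed to fit; feeding train∪validation with 13/85 reproduces the
    # 72/13 proportions of the protocol
    val_fraction = f.validation / (f.train + f.validation)

    members, meta_members = [], []
    for mi, spec in enumerate(specs):
        reg = MLPRegressor(
            hidden_layer_sizes=spec.hidden_layer_sizes,
            activation="logistic",
            solver="adam",
            alpha=cfg.l2_penalty,
            batch_size=min(cfg.batch_size, len(fit_idx)),
            learning_rate_init=cfg.learning_rate,
            max_iter=cfg.max_epochs,
            # validation R^2 is undefined on a constant target, so early
            # stopping is only meaningful for a non-degenerate dataset
            early_stopping=not degenerate_target,
            validation_fraction=val_fraction,
            n_iter_no_change=cfg.patience,
            tol=cfg.tol,
            random_state=spec.seed,
        )
        reg.fit(Xs[fit_idx], ys[fit_idx])
        if not np.isfinite(reg.loss_):
            raise RuntimeError(
                f"member {mi} ({spec.hidden_layer_sizes}): non-finite training loss"
            )
        members.append(MemberNetwork.from_sklearn(reg))
        meta_members.append({
            "hidden_layer_sizes": list(spec.hidden_layer_sizes),
            "seed": spec.seed,
            "stopped_epoch": int(reg.n_iter_),
            "best_validation_score": float(reg.best_validation_score_)
            if not degenerate_target else None,
            "final_loss": float(reg.loss_),
        })

    ens = EnergyNetworkEnsemble(
        members=members, encoding=enc, n_dihedrals=n_d,
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
        metadata={
            "n_samples": n,
            "split_sizes": [len(idx_train), len(idx_val), len(idx_test)],
            "test_indices": idx_test.tolist(),
            "base_seed": base_seed,
            "members": meta_members,
        },
    )
    return ens


def predict_energy(ensemble: EnergyNetworkEnsemble, angles_deg) -> float:
    """Ensemble energy (kcal/mol) of one configuration: mean of member outputs."""
    return ensemble.predict(angles_deg)


def regression_metrics(predictions: np.ndarray, references: np.ndarray,
                       n_dihedrals: int, cutoff: float | None = None,
                       bin_width: float = 2.0) -> dict:
    """Accuracy metrics of predicted vs reference conformer energies.

    MAE is reported per dihedral angle (mean |Δ| / n_d) in kcal/mol and
    meV (1 eV = 23.0605 kcal/mol).  Pearson r is the standard product-
    moment coefficient, reported as None when either series has zero
    variance.  With ``cutoff`` set, the MAE is additionally recomputed on
    the subset of reference energies below the cutoff (the low-energy
    regime relevant at simulation temperatures).  Histograms of both
    energy series (shared bins of ``bin_width`` kcal/mol) support
    distribution-shift comparison.
    """
    pred = np.asarray(predictions, float)
    ref = np.asarray(references, float)
    if pred.shape != ref.shape or pred.size == 0:
        raise ValueError("predictions and references must be equal-length, nonempty")
    abs_err = np.abs(pred - ref)
    mae = float(abs_err.mean())
    mae_per_d = mae / n_dihedrals
    if pred.std() < 1e-15 or ref.std() < 1e-15:
        r = None
    else:
        r = float(np.corrcoef(pred, ref)[0, 1])
    lo = min(pred.min(), ref.min())
    hi = max(pred.max(), ref.max())
    edges = np.arange(np.floor(lo / bin_width) * bin_width,
                      hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    out = {
        "n": int(pred.size),
        "mae_kcal_mol": mae,
        "mae_per_dihedral_kcal_mol": mae_per_d,
        "mae_per_dihedral_mev": mae_per_d * 1000.0 / KCAL_PER_EV,
        "pearson_r": r,
        "histogram": {
            "bin_edges": edges.tolist(),
            "reference": np.histogram(ref, edges)[0].tolist(),
            "predicted": np.histogram(pred, edges)[0].tolist(),
        },
    }
    if cutoff is not None:
        mask = ref < cutoff
        if mask.any():
            sub = float(abs_err[mask].mean())
            out["cutoff_kcal_mol"] = float(cutoff)
            out["n_below_cutoff"] = int(mask.sum())
            out["mae_per_dihedral_below_cutoff_kcal_mol"] = sub / n_dihedrals
        else:
            out["cutoff_kcal_mol"] = float(cutoff)
            out["n_below_cutoff"] = 0
    return out


def evaluate_model(model, angles_deg: np.ndarray, energies: np.ndarray,
                   n_dihedrals: int | None = None, cutoff: float | None = None,
                   bin_width: float = 2.0) -> dict:
    """Evaluate any energy model exposing ``evaluate_batch`` on a test set."""
    angles_deg = np.atleast_2d(np.asarray(angles_deg, float))
    if angles_deg.shape[0] == 0:
        raise ValueError("empty test set")
    n_d = n_dihedrals or angles_deg.shape[1]
    pred = model.evaluate_batch(angles_deg)
    return regression_metrics(pred, energies, n_d, cutoff=cutoff, bin_width=bin_width)
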