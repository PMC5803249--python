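"""End-to-end benchmark harness.

Runs the full comparison a desk-scale study needs: generate a dataset
from a synthetic correlated PES, split it 72/13/15, scan-parameterize
the uncorrelated force field (Fourier and tabulated), train the
five-network regression ensemble and the classification ensemble, and
evaluate everything on the identical held-out test split.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from .classification import (
    ConfusionMatrix,
    confusion_metrics,
    train_classifier_ensemble,
)
from .fourier_ff import scan_parameterize
from .regression import (
    SplitFractions,
    TrainingConfig,
    evaluate_model,
    split_dataset,
    train_ensemble,
)
from .synthetic import SyntheticPES, default_coupling_pairs, generate_dataset, make_pes

__all__ = ["BenchmarkConfig", "BenchmarkReport", "run_benchmark", "StageError"]


class StageError(RuntimeError):
    """A benchmark stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class BenchmarkConfig:
    """Declarative description of one benchmark run."""

    n_dihedrals: int = 5
    n_samples: int = 20_000
    coupling_style: str = "hub"
    coupling_strength: float = 1.0
    amplitude_scale: float = 1.0
    seed: int = 0
    n_scan_samples: int = 72
    scan_mode: str = "tabulated"
    classifier_threshold: float = 46.0
    train_classifier: bool = True
    fractions: SplitFractions = field(default_factory=SplitFractions)
    training: TrainingConfig = field(default_factory=TrainingConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        d = dict(d)
        if "fractions" in d:
            d["fractions"] = SplitFractions(**d["fractions"])
        if "training" in d:
            d["training"] = TrainingConfig(**d["training"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ValueError(f"invalid benchmark config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "n_dihedrals": self.n_dihedrals,
            "n_samples": self.n_samples,
            "coupling_style": self.coupling_style,
            "coupling_strength": self.coupling_strength,
            "amplitude_scale": self.amplitude_scale,
            "seed": self.seed,
            "n_scan_samples": self.n_scan_samples,
            "scan_mode": self.scan_mode,
            "classifier_threshold": self.classifier_threshold,
            "train_classifier": self.train_classifier,
            "fractions": vars(self.fractions),
            "training": vars(self.training),
        }


@dataclass
class BenchmarkReport:
    """Metrics of every model on the shared test split, plus provenance."""

    config: dict
    dataset: dict
    uncorrelated: dict
    ann: dict
    classifier: dict | None
    regime: str
    runtime_s: float

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "dataset": self.dataset,
            "uncorrelated": self.uncorrelated,
            "ann": self.ann,
            "classifier": self.classifier,
            "regime": self.regime,
            "runtime_s": self.runtime_s,
        }

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def run_benchmark(config: BenchmarkConfig | dict | None = None,
                  pes: SyntheticPES | None = None):
    """Run the full pipeline; returns (BenchmarkReport, artifacts dict).

    ``artifacts`` holds the in-memory objects (pes, dataset, models,
    test indices) for callers that want more than the report.
    """
    if config is None:
        config = BenchmarkConfig()
    elif isinstance(config, dict):
        config = BenchmarkConfig.from_dict(config)
    t0 = time.time()

    stage = "generate"
    try:
        if pes is None:
            pairs = default_coupling_pairs(config.n_dihedrals, config.coupling_style) \
                if config.coupling_strength != 0 else None
            pes = make_pes(
                config.n_dihedrals, pairs, config.coupling_strength,
                seed=config.seed, amplitude_scale=config.amplitude_scale,
            )
        angles, energies = generate_dataset(pes, config.n_samples, seed=config.seed + 1)

        stage = "split"
        idx_train, idx_val, idx_test = split_dataset(
            config.n_samples, config.fractions, seed=config.seed
        )

        stage = "fit-ff"
        ff = scan_parameterize(
            pes.evaluate, config.n_dihedrals, config.n_scan_samples,
            mode=config.scan_mode,
        )

        stage = "train"
        ensemble = train_ensemble(
            angles, energies, fractions=config.fractions,
            config=config.training, base_seed=config.seed,
        )
        # train_ensemble derives the same split from the same seed; the
        # report's guarantee is a single shared test set
        assert ensemble.metadata["test_indices"] == idx_test.tolist()

        stage = "train-classifier"
        classifier = None
        classifier_metrics = None
        if config.train_classifier:
            labels_low = energies < config.classifier_threshold
            if labels_low.all() or not labels_low.any():
                classifier_metrics = {
                    "skipped": "single-class at threshold "
                               f"{config.classifier_threshold} kcal/mol"
                }
            else:
                classifier = train_classifier_ensemble(
                    angles, energies, config.classifier_threshold,
                    fractions=config.fractions, config=config.training,
                    base_seed=config.seed,
                )
                prob, is_low = classifier.classify_batch(angles[idx_test])
                cm = ConfusionMatrix.from_predictions(
                    is_low, labels_low[idx_test]
                )
                classifier_metrics = {
                    "threshold_kcal_mol": config.classifier_threshold,
                    "confusion": vars(cm).copy(),
                    "metrics": confusion_metrics(cm),
                }

        stage = "evaluate"
        test_angles = angles[idx_test]
        test_energies = energies[idx_test]
        cutoff = 11.5 if config.amplitude_scale <= 2 else None
        unc = evaluate_model(ff, test_angles, test_energies,
                             config.n_dihedrals, cutoff=cutoff)
        ann = evaluate_model(ensemble, test_angles, test_energies,
                             config.n_dihedrals, cutoff=cutoff)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    regime = "separable" if config.coupling_strength == 0 else "coupled"
    report = BenchmarkReport(
        config=config.to_dict(),
        dataset={
            "n_samples": config.n_samples,
            "n_dihedrals": config.n_dihedrals,
            "split_sizes": [len(idx_train), len(idx_val), len(idx_test)],
            "seed": config.seed,
            "energy_min": float(energies.min()),
            "energy_max": float(energies.max()),
        },
        uncorrelated=unc,
        ann=ann,
        classifier=classifier_metrics,
        regime=regime,
        runtime_s=time.time() - t0,
    )
    artifacts = {
        "pes": pes,
        "angles": angles,
        "energies": energies,
        "ff": ff,
        "ensemble": ensemble,
        "classifier": classifier,
        "test_indices": idx_test,
    }
    return report, artifacts


def save_plots(report: BenchmarkReport, artifacts: dict, outdir) -> list:
    """Optional figures: predicted-vs-reference scatter per model and the
    test-split energy histogram.  Metrics never depend on these."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    idx = artifacts["test_indices"]
    angles = artifacts["angles"][idx]
    ref = artifacts["energies"][idx]
    written = []
    for name, model in (("uncorrelated", artifacts["ff"]),
                        ("ann", artifacts["ensemble"])):
        pred = model.evaluate_batch(angles)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(ref, pred, ".", ms=2, alpha=0.4)
        lims = [min(ref.min(), pred.min()), max(ref.max(), pred.max())]
        ax.plot(lims, lims, "k-", lw=0.8)
        ax.set_xlabel("reference energy (kcal/mol)")
        ax.set_ylabel(f"{name} model energy (kcal/mol)")
        r = report.to_dict()[name]["pearson_r"]
        ax.set_title(f"{name}: r = {r:.3f}" if r is not None else name)
        path = outdir / f"scatter_{name}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    # each model reports its own bin edges (pred/ref ranges differ)
    for label, hist, key in (
        ("reference", report.ann["histogram"], "reference"),
        ("ann", report.ann["histogram"], "predicted"),
        ("uncorrelated", report.uncorrelated["histogram"], "predicted"),
    ):
        edges = np.asarray(hist["bin_edges"])
        centers = 0.5 * (edges[:-1] + edges[1:])
        ax.step(centers, hist[key], where="mid", label=label)
    ax.set_xlabel("conformer energy (kcal/mol)")
    ax.set_ylabel("count")
    ax.legend()
    path = outdir / "energy_histogram.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)
    return written
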