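import numpy as np
import pytest
from sklearn.neural_network import MLPRegressor

from torsionnet.features import FeatureEncoding, encode_batch
from torsionnet.fourier_ff import scan_parameterize
from torsionnet.regression import (
    EnergyNetworkEnsemble,
    MemberNetwork,
    NetworkSpec,
    SplitFractions,
    TrainingConfig,
    evaluate_model,
    predict_energy,
    regression_metrics,
    split_dataset,
    train_ensemble,
)
from torsionnet.synthetic import generate_dataset, make_pes


# -- splitting ----------------------------------------------------------------


def test_split_sizes_at_paper_scale():
    tr, va, te = split_dataset(150_000, seed=0)
    assert (len(tr), len(va), len(te)) == (108_000, 19_500, 22_500)


def test_split_sizes_small():
    tr, va, te = split_dataset(100, seed=0)
    assert (len(tr), len(va), len(te)) == (72, 13, 15)


def test_split_disjoint_exhaustive_deterministic():
    a = split_dataset(1000, seed=42)
    b = split_dataset(1000, seed=42)
    c = split_dataset(1000, seed=43)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)
    union = np.concatenate(a)
    assert len(union) == 1000 and len(set(union)) == 1000
    assert any(not np.array_equal(x, y) for x, y in zip(a, c))


def test_bad_fractions_rejected():
    with pytest.raises(ValueError):
        SplitFractions(0.7, 0.2, 0.2)


# -- forward pass -------------------------------------------------------------


def _manual_forward(weights, biases, x, output="identity"):
    """Layer-by-layer arithmetic with explicit loops (oracle)."""
    h = list(x)
    for layer, (w, b) in enumerate(zip(weights, biases)):
        out = []
        for j in range(w.shape[1]):
            s = b[j]
            for i in range(w.shape[0]):
                s += w[i, j] * h[i]
            if layer < len(weights) - 1 or output == "logistic":
                s = 1.0 / (1.0 + np.exp(-s))
            out.append(s)
        h = out
    return h[0]


def test_forward_pass_matches_manual_arithmetic():
    rng = np.random.default_rng(20)
    weights = [rng.normal(size=(5, 4)), rng.normal(size=(4, 3)), rng.normal(size=(3, 1))]
    biases = [rng.normal(size=4), rng.normal(size=3), rng.normal(size=1)]
    net = MemberNetwork(weights, biases)
    for _ in range(20):
        x = rng.normal(size=5)
        assert net.forward(x[None, :])[0] == pytest.approx(
            _manual_forward(weights, biases, x), abs=1e-10
        )


def test_forward_pass_matches_sklearn_oracle():
    rng = np.random.default_rng(21)
    X = rng.normal(size=(200, 6))
    y = X @ rng.normal(size=6) + rng.normal(size=200) * 0.1
    reg = MLPRegressor(hidden_layer_sizes=(7, 3), activation="logistic",
                       solver="adam", max_iter=50, random_state=0)
    reg.fit(X, y)
    net = MemberNetwork.from_sklearn(reg)
    Xt = rng.normal(size=(50, 6))
    np.testing.assert_allclose(net.forward(Xt), reg.predict(Xt), atol=1e-10)


def test_zero_weight_logistic_unit():
    # one hidden logistic unit, all weights/biases zero: activation 0.5,
    # propagated through a known output layer
    net = MemberNetwork([np.zeros((3, 1)), np.array([[2.0]])],
                        [np.zeros(1), np.array([1.0])])
    assert net.forward(np.zeros((1, 3)))[0] == pytest.approx(2.0 * 0.5 + 1.0)


# -- ensemble mechanics -------------------------------------------------------


def _toy_ensemble(n_members, seed=0):
    rng = np.random.default_rng(seed)
    enc = FeatureEncoding()
    dim = enc.feature_dim(2)
    members = [
        MemberNetwork([rng.normal(size=(dim, 4)), rng.normal(size=(4, 1))],
                      [rng.normal(size=4), rng.normal(size=1)])
        for _ in range(n_members)
    ]
    return EnergyNetworkEnsemble(
        members=members, encoding=enc, n_dihedrals=2,
        x_mean=np.zeros(dim), x_std=np.ones(dim), y_mean=1.0, y_std=2.0,
    )


def test_single_member_prediction_is_member_output():
    ens = _toy_ensemble(1)
    angles = np.array([[30.0, 200.0]])
    assert ens.predict_batch(angles)[0] == ens.member_predictions(angles)[0, 0]


def test_prediction_is_arithmetic_mean_of_members():
    ens = _toy_ensemble(5)
    angles = np.array([[130.0, 20.0], [5.0, 355.0]])
    mean = ens.member_predictions(angles).mean(axis=0)
    np.testing.assert_allclose(ens.predict_batch(angles), mean, atol=1e-12)
    assert predict_energy(ens, angles[0]) == pytest.approx(mean[0], abs=1e-12)


def test_dimension_mismatch_raises():
    ens = _toy_ensemble(2)
    with pytest.raises(ValueError):
        ens.predict([1.0, 2.0, 3.0])


def test_ensemble_serialization_round_trip(tmp_path):
    ens = _toy_ensemble(3)
    path = tmp_path / "ens.json"
    ens.save(path)
    back = EnergyNetworkEnsemble.load(path)
    angles = np.random.default_rng(1).uniform(0, 360, size=(10, 2))
    np.testing.assert_allclose(back.predict_batch(angles),
                               ens.predict_batch(angles), atol=1e-12)


# -- training -----------------------------------------------------------------

FAST = TrainingConfig(max_epochs=200)


def test_degenerate_target_guard_and_override():
    rng = np.random.default_rng(22)
    angles = rng.uniform(0, 360, size=(200, 2))
    const = np.full(200, 7.5)
    with pytest.raises(ValueError, match="degenerate"):
        train_ensemble(angles, const, specs=[(4,)], config=FAST)
    cfg = TrainingConfig(max_epochs=600, batch_size=10, tol=1e-8)
    ens = train_ensemble(angles, const, specs=[(4,)], config=cfg,
                         allow_constant_target=True)
    assert ens.predict(angles[0]) == pytest.approx(7.5, abs=1e-2)


def test_nonfinite_energies_rejected():
    rng = np.random.default_rng(23)
    angles = rng.uniform(0, 360, size=(100, 2))
    e = rng.normal(size=100)
    e[3] = np.nan
    with pytest.raises(ValueError):
        train_ensemble(angles, e)


def test_ensemble_learns_separable_pes(separable_pes):
    """Five-network ensemble on a smooth separable 3-torsion surface:
    held-out MAE well under 0.1 kcal/mol (pilot-run regression bound)."""
    angles, energies = generate_dataset(separable_pes, 5000, seed=12)
    ens = train_ensemble(angles, energies, base_seed=11)
    idx = np.array(ens.metadata["test_indices"])
    m = evaluate_model(ens, angles[idx], energies[idx], 3)
    assert m["mae_kcal_mol"] <= 0.1
    # training bookkeeping: shared split, early stopping recorded
    assert m["n"] == len(idx)
    for member in ens.metadata["members"]:
        assert member["stopped_epoch"] >= 1
        assert np.isfinite(member["best_validation_score"])


def test_ensemble_beats_uncorrelated_scan_on_coupled_pes(coupled_pes, coupled_dataset):
    """Head-to-head on the identical test split of a coupled surface: the
    ensemble's MAE is at least 2x below the scan-parameterized model's."""
    angles, energies = coupled_dataset
    ens = train_ensemble(angles, energies, base_seed=13)
    ff = scan_parameterize(coupled_pes.evaluate, 3, 72, mode="tabulated")
    idx = np.array(ens.metadata["test_indices"])
    ann = evaluate_model(ens, angles[idx], energies[idx], 3)
    unc = evaluate_model(ff, angles[idx], energies[idx], 3)
    assert ann["mae_kcal_mol"] < unc["mae_kcal_mol"] / 2
    assert ann["pearson_r"] > unc["pearson_r"]


# -- metrics ------------------------------------------------------------------


def test_metrics_identity_and_antisymmetry():
    rng = np.random.default_rng(24)
    ref = rng.normal(size=100)
    m = regression_metrics(ref, ref, n_dihedrals=4)
    assert m["mae_kcal_mol"] == 0.0
    assert m["pearson_r"] == pytest.approx(1.0)
    zero_mean = ref - ref.mean()
    m2 = regression_metrics(-zero_mean, zero_mean, n_dihedrals=4)
    assert m2["pearson_r"] == pytest.approx(-1.0)


def test_metrics_hand_computed_five_points():
    pred = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
    ref = np.array([1.5, 2.0, 3.0, 5.0, 6.5])
    # |err| = .5, 0, 1, .5, .5 -> mean 0.5; n_d = 2 -> 0.25 per dihedral
    m = regression_metrics(pred, ref, n_dihedrals=2)
    assert m["mae_kcal_mol"] == pytest.approx(0.5)
    assert m["mae_per_dihedral_kcal_mol"] == pytest.approx(0.25)
    assert m["mae_per_dihedral_mev"] == pytest.approx(0.25 * 1000 / 23.0605)
    # spreadsheet-style Pearson on the same 5 points
    px, py = pred - pred.mean(), ref - ref.mean()
    r_hand = (px * py).sum() / np.sqrt((px**2).sum() * (py**2).sum())
    assert m["pearson_r"] == pytest.approx(r_hand, abs=1e-12)


def test_metrics_zero_variance_pearson_undefined():
    m = regression_metrics(np.ones(10), np.arange(10.0), n_dihedrals=1)
    assert m["pearson_r"] is None


def test_metrics_energy_cutoff_subset():
    pred = np.array([0.0, 1.0, 10.0, 30.0])
    ref = np.array([1.0, 2.0, 12.0, 20.0])
    m = regression_metrics(pred, ref, n_dihedrals=1, cutoff=11.5)
    assert m["n_below_cutoff"] == 2
    assert m["mae_per_dihedral_below_cutoff_kcal_mol"] == pytest.approx(1.0)


def test_evaluate_model_rejects_empty_test_set(separable_pes):
    with pytest.raises(ValueError):
        evaluate_model(separable_pes, np.empty((0, 3)), np.empty(0))
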