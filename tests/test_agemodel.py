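"""PLS1 age model: NIPALS correctness, prediction contracts, bias correction,
accuracy metrics and bootstrap weight stability."""

import numpy as np
import pandas as pd
import pytest

from cogage import (
    SimulationConfig,
    accuracy,
    apply_bias_correction,
    bootstrap_stability,
    fit_age_model,
    fit_bias_correction,
    generate_cohort,
    load_model,
    predict_age,
    save_model,
)
from cogage.agemodel import BiasCorrection, FittingError


def _toy_sessions(rng, n=60, predictors=("a", "b", "c")):
    age = rng.uniform(55, 97, size=n)
    data = {"participant_id": [f"T{i}" for i in range(n)], "age_at_session": age}
    for j, p in enumerate(predictors):
        data[p] = (j + 1) * age + rng.normal(0, 5, size=n)
    return pd.DataFrame(data)


def test_first_weight_proportional_to_cross_covariance():
    """One NIPALS component: w1 ∝ Xᵀy on centered data (hand oracle)."""
    X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [4.0, 4.0]])
    y = np.array([60.0, 62.0, 70.0, 75.0])
    df = pd.DataFrame({"p1": X[:, 0], "p2": X[:, 1], "age_at_session": y})
    model = fit_age_model(df, n_components=1, predictors=["p1", "p2"])
    # oracle: covariance of z-scored predictors with centered age, normalized
    Xz = (X - X.mean(0)) / X.std(0, ddof=1)
    w_oracle = Xz.T @ (y - y.mean())
    w_oracle /= np.linalg.norm(w_oracle)
    np.testing.assert_allclose(np.abs(model.weights[:, 0]), np.abs(w_oracle), atol=1e-12)


def test_predictions_match_cross_decomposition_oracle(rng):
    """PLS1 predictions agree with an independent cross-decomposition
    implementation to 1e-6 on a fixed matrix."""
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    preds = [f"x{i}" for i in range(8)]
    df = _toy_sessions(rng, n=50, predictors=preds)
    for k in (1, 3, 5):
        model = fit_age_model(df, n_components=k, predictors=preds)
        ours = predict_age(model, df)
        X = df[preds].to_numpy()
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        y = df["age_at_session"].to_numpy()
        ref = sklearn.PLSRegression(n_components=k, scale=False).fit(Xz, y - y.mean())
        theirs = ref.predict(Xz).ravel() + y.mean()
        np.testing.assert_allclose(ours, theirs, atol=1e-6)


def test_oracle_agreement_on_default_cohort(default_cohort):
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    train = default_cohort.sessions_for("train")
    model = fit_age_model(train)
    X = train[model.predictors].to_numpy()
    Xz = (X - model.x_mean) / model.x_sd
    y = train["age_at_session"].to_numpy()
    ref = sklearn.PLSRegression(n_components=5, scale=False).fit(Xz, y - y.mean())
    np.testing.assert_allclose(
        predict_age(model, train), ref.predict(Xz).ravel() + y.mean(), atol=1e-6
    )


def test_noise_free_cohort_recovered_exactly():
    cfg = SimulationConfig(
        n_train=60, n_test=60, noise_sd=0.0, ability_sd=0.0, practice_effect=0.0,
        sa_fraction=0.0, sessions_lambda=0.3, sessions_lambda_train=0.3, seed=2,
    )
    cohort = generate_cohort(cfg)
    train = cohort.sessions_for("train")
    model = fit_age_model(train)
    acc = accuracy(predict_age(model, train), train["age_at_session"].to_numpy())
    assert acc.r2 > 0.9999
    assert acc.mae < 0.05


def test_training_r2_monotone_in_components(rng):
    preds = [f"x{i}" for i in range(6)]
    df = _toy_sessions(rng, n=80, predictors=preds)
    r2 = []
    for k in range(1, 7):
        m = fit_age_model(df, n_components=k, predictors=preds)
        r2.append(accuracy(predict_age(m, df), df["age_at_session"].to_numpy()).r2)
    assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))


def test_prediction_is_pure_and_name_aligned(small_cohort):
    train = small_cohort.sessions_for("train")
    model = fit_age_model(train)
    test = small_cohort.sessions_for("test")
    base = predict_age(model, test)
    # duplicating a row changes nothing for the original rows
    doubled = pd.concat([test, test.iloc[[0]]], ignore_index=True)
    np.testing.assert_array_equal(predict_age(model, doubled)[: len(test)], base)
    # permuting predictor column order is irrelevant (alignment by name)
    shuffled = test[list(test.columns[::-1])]
    np.testing.assert_array_equal(predict_age(model, shuffled), base)


def test_missing_predictor_column_rejected(small_cohort):
    train = small_cohort.sessions_for("train")
    model = fit_age_model(train)
    with pytest.raises(FittingError, match="tmt_b"):
        predict_age(model, train.drop(columns=["tmt_b"]))


def test_zero_variance_predictor_named(rng):
    df = _toy_sessions(rng, n=30, predictors=["good"])
    df["flat"] = 1.0
    with pytest.raises(FittingError, match="flat"):
        fit_age_model(df, n_components=1, predictors=["good", "flat"])


def test_too_few_rows_rejected(rng):
    df = _toy_sessions(rng, n=4, predictors=["a", "b"])
    with pytest.raises(FittingError):
        fit_age_model(df, n_components=5, predictors=["a", "b"])


def test_generalization_gap_shrinks_with_training_size():
    """Test R² trails training R² on average, less so for larger cohorts."""
    def mean_gap(n_train, seeds):
        gaps = []
        for seed in seeds:
            cfg = SimulationConfig(n_train=n_train, n_test=120, seed=seed,
                                   sessions_lambda=1.0, sessions_lambda_train=1.0)
            cohort = generate_cohort(cfg)
            train = cohort.sessions_for("train")
            test = cohort.sessions_for("test")
            m = fit_age_model(train)
            tr = accuracy(predict_age(m, train), train["age_at_session"].to_numpy()).r2
            te = accuracy(predict_age(m, test), test["age_at_session"].to_numpy()).r2
            gaps.append(tr - te)
        return np.mean(gaps)

    small = mean_gap(40, range(8))
    large = mean_gap(400, range(8))
    assert small > 0          # overfitting dominates at tiny n
    assert large < small      # and shrinks as the training cohort grows


# --- bias correction ---------------------------------------------------------

def test_zero_correction_is_identity():
    pred = np.array([70.0, 75.0, 80.0])
    age = np.array([68.0, 76.0, 81.0])
    res = apply_bias_correction(BiasCorrection(alpha=0.0, beta=0.0), pred, age)
    np.testing.assert_array_equal(res.predicted_age_corrected, pred)
    np.testing.assert_array_equal(res.cag_corrected, pred - age)


def test_planted_linear_bias_removed_exactly():
    age = np.linspace(55, 97, 40)
    cag = -0.5 * age + 40.0          # exactly linear bias, no noise
    pred = age + cag
    corr = fit_bias_correction(cag, age)
    assert corr.alpha == pytest.approx(-0.5, abs=1e-10)
    assert corr.beta == pytest.approx(40.0, abs=1e-8)
    res = apply_bias_correction(corr, pred, age)
    np.testing.assert_allclose(res.cag_corrected, 0.0, atol=1e-8)


def test_corrected_cag_orthogonal_to_age_on_fitting_set(rng):
    age = rng.uniform(55, 97, size=200)
    pred = age + rng.normal(0, 5, size=200) - 0.3 * (age - 75)
    corr = fit_bias_correction(pred - age, age)
    res = apply_bias_correction(corr, pred, age)
    slope = np.polyfit(age, res.cag_corrected, 1)[0]
    assert abs(slope) < 1e-8


def test_bias_fit_rejects_degenerate_age():
    with pytest.raises(FittingError):
        fit_bias_correction(np.zeros(5), np.full(5, 70.0))


# --- accuracy ----------------------------------------------------------------

def test_accuracy_cases():
    age = np.array([70.0, 80.0, 90.0])
    perfect = accuracy(age, age)
    assert (perfect.r, perfect.r2, perfect.mae) == (1.0, 1.0, 0.0)
    null = accuracy(np.full(3, 80.0), age)
    assert null.r2 == pytest.approx(0.0)
    hand = accuracy(np.array([72.0, 78.0, 92.0]), age)
    assert hand.mae == pytest.approx(2.0)
    with pytest.raises(FittingError):
        accuracy(np.array([1.0, 2.0]), np.array([70.0, 70.0]))


# --- bootstrap stability -----------------------------------------------------

def _signal_noise_sessions(seed, n=120):
    r = np.random.default_rng(seed)
    age = r.uniform(55, 97, size=n)
    return pd.DataFrame(
        {
            "participant_id": [f"S{i}" for i in range(n)],
            "age_at_session": age,
            "signal": -0.5 * age + r.normal(0, 3, size=n),
            "signal2": -0.3 * age + r.normal(0, 3, size=n),
            "pure_noise": r.normal(0, 1, size=n),
        }
    )


def test_signal_z_exceeds_noise_z():
    df = _signal_noise_sessions(seed=0)
    stab = bootstrap_stability(df, n_components=2, B=200, seed=1,
                               predictors=["signal", "signal2", "pure_noise"])
    z = np.abs(stab.z[:, 0])
    assert z[0] > z[2]


def test_bootstrap_deterministic():
    df = _signal_noise_sessions(seed=3)
    kwargs = dict(n_components=2, B=50, seed=9,
                  predictors=["signal", "signal2", "pure_noise"])
    a = bootstrap_stability(df, **kwargs)
    b = bootstrap_stability(df, **kwargs)
    np.testing.assert_array_equal(a.z, b.z)
    assert a.n_samples == b.n_samples


def test_degenerate_resamples_skipped_and_counted():
    df = _signal_noise_sessions(seed=4, n=25)
    # a predictor whose variance hinges on a single row: resamples missing it
    # are degenerate and must be skipped, not silently averaged
    df["fragile"] = 0.0
    df.loc[0, "fragile"] = 1.0
    stab = bootstrap_stability(df, n_components=1, B=60, seed=2,
                               predictors=["signal", "fragile"])
    assert stab.n_skipped > 0
    assert stab.n_samples + stab.n_skipped == 60


def test_bootstrap_rejects_tiny_b(small_cohort):
    with pytest.raises(FittingError):
        bootstrap_stability(small_cohort.sessions_for("train"), B=1)


def test_model_json_roundtrip(tmp_path, small_cohort):
    train = small_cohort.sessions_for("train")
    model = fit_age_model(train)
    bias = fit_bias_correction(
        predict_age(model, train) - train["age_at_session"].to_numpy(),
        train["age_at_session"].to_numpy(),
    )
    path = tmp_path / "model.json"
    save_model(model, path, bias=bias, provenance={"seed": 7})
    loaded, loaded_bias = load_model(path)
    np.testing.assert_array_equal(loaded.coef, model.coef)
    np.testing.assert_array_equal(
        predict_age(loaded, train), predict_age(model, train)
    )
    assert loaded_bias == bias
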