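"""Random-forest gain model: supervision, training, prediction, K_P."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from rqcontrol import TwinParams, required_agitation, steady_state_rq
from rqcontrol.config import GainModelConfig
from rqcontrol.gain_model import (
    GainModel,
    build_training_set,
    derive_kp,
    predict_agitation,
    train,
)
from rqcontrol.io import FermLog, SCHEMA_COLUMNS
from rqcontrol.twin import inlet_blend


def synthetic_steady_log(params, n_rpm, rq, n_rows=20):
    """A hand-built log sitting at one steady state throughout."""
    rows = []
    blend = inlet_blend(params.F_air, 0.0, params)
    for i in range(n_rows):
        t = 0.5 + i / 6.0
        row = {c: 0.0 for c in SCHEMA_COLUMNS}
        row.update(
            t=t, N=n_rpm, V=params.V0, X=params.X0, S=0.0,
            feed_rate=0.025, qS_true=params.mu_set / params.Y_XS_ox,
            F_air=params.F_air, F_O2=0.0,
            y_O2_in=blend.y_O2_in, y_CO2_in=blend.y_CO2_in,
            RQ_meas=rq, RQ_ctrl=rq, OUR_meas=0.04, CER_meas=0.04 * rq,
            cum_fed=10.0, action_rule="NONE",
        )
        rows.append(row)
    return FermLog(pd.DataFrame(rows), meta={"mu_set": params.mu_set})


# ------------------------------------------------------------- supervision

def test_training_targets_fixed_point_at_setpoint(params):
    """A log already holding RQ=1.4 gets its own agitation as the target."""
    blend = inlet_blend(params.F_air, 0.0, params)
    n_hold = required_agitation(1.4, params.X0, params.mu_set / params.Y_XS_ox,
                                params, V=params.V0, blend=blend)
    log = synthetic_steady_log(params, n_hold, 1.4)
    X, y = build_training_set([log], params)
    assert np.allclose(y, n_hold, atol=1e-9)
    assert (X["N"] == n_hold).all()


def test_training_target_exceeds_current_agitation_when_rq_high(params):
    blend = inlet_blend(params.F_air, 0.0, params)
    n_hold = required_agitation(1.4, params.X0, params.mu_set / params.Y_XS_ox,
                                params, V=params.V0, blend=blend)
    log = synthetic_steady_log(params, n_hold - 50.0, 1.5)
    X, y = build_training_set([log], params)
    assert (y > X["N"].to_numpy()).all()


def test_inversion_matches_bisection_on_steady_twin(params):
    """Closed-form required agitation vs a brentq oracle, to 0.5 rpm."""
    blend = inlet_blend(params.F_air, 0.0, params)
    for x_bio, qs, v in ((25.0, 0.20, 2.0), (60.0, 0.23, 2.8), (85.0, 0.24, 3.5)):
        n_closed = required_agitation(1.4, x_bio, qs, params, V=v, blend=blend)
        n_oracle = brentq(
            lambda n: steady_state_rq(n, x_bio, qs, params, V=v, blend=blend) - 1.4,
            200.0, 4000.0, xtol=1e-6,
        )
        assert abs(n_closed - n_oracle) < 0.5


def test_empty_corpus_rejected(params):
    with pytest.raises(ValueError):
        build_training_set([], params)


# ---------------------------------------------------------------- training

def test_forest_is_deterministic_given_seed(training_set):
    X, y = training_set
    grid = X.iloc[::40]
    a = train(X, y, n_trees=20, seed=9)
    b = train(X, y, n_trees=20, seed=9)
    assert np.array_equal(a.forest.predict(grid.to_numpy()),
                          b.forest.predict(grid.to_numpy()))


def test_single_tree_forest_equals_its_tree(training_set):
    X, y = training_set
    model = train(X, y, n_trees=1, seed=2)
    grid = X.iloc[::17].to_numpy()
    assert np.allclose(model.forest.predict(grid),
                       model.forest.estimators_[0].predict(grid))


def test_prediction_is_mean_of_tree_predictions(gain_model, training_set):
    X, _ = training_set
    grid = X.iloc[::23]
    per_tree = np.stack([t.predict(grid.to_numpy())
                         for t in gain_model.forest.estimators_])
    mean = per_tree.mean(axis=0)
    ens = gain_model.forest.predict(grid.to_numpy())
    assert np.allclose(ens, mean, rtol=1e-10)
    assert np.all(ens <= per_tree.max(axis=0) + 1e-9)
    assert np.all(ens >= per_tree.min(axis=0) - 1e-9)


def test_held_out_accuracy_of_required_agitation(training_set):
    """Out-of-bag style split: error well under 5% of the target range."""
    X, y = training_set
    rng = np.random.default_rng(4)
    idx = rng.permutation(len(X))
    cut = int(0.75 * len(X))
    tr, te = idx[:cut], idx[cut:]
    model = train(X.iloc[tr], y[tr], n_trees=100, seed=4)
    pred = model.forest.predict(X.iloc[te].to_numpy())
    rmse = float(np.sqrt(np.mean((pred - y[te]) ** 2)))
    assert rmse < 0.05 * (y.max() - y.min())
    assert np.median(np.abs(pred - y[te]) / y[te]) < 0.05


def test_too_small_training_set_rejected():
    X = pd.DataFrame({"f": np.arange(10, dtype=float)})
    with pytest.raises(ValueError):
        train(X, np.arange(10, dtype=float))


# -------------------------------------------------------------- prediction

def test_feature_schema_is_enforced(gain_model):
    good = {f: 1.0 for f in gain_model.features}
    predict_agitation(gain_model, good)  # does not raise
    bad = dict(good)
    del bad["RQ"]
    with pytest.raises(KeyError):
        predict_agitation(gain_model, bad)
    with pytest.raises(ValueError):
        predict_agitation(gain_model, [1.0, 2.0])


def test_model_round_trips_through_persistence(gain_model, tmp_path):
    path = tmp_path / "gain.joblib"
    gain_model.save(str(path))
    loaded = GainModel.load(str(path))
    x = {f: 1.0 for f in gain_model.features}
    assert predict_agitation(loaded, x) == predict_agitation(gain_model, x)
    assert loaded.features == gain_model.features


# ------------------------------------------------------------------- K_P

def test_derive_kp_reproduces_predicted_correction(training_set):
    X, y = training_set
    model = train(X, y, n_trees=30, seed=6)
    x = X.iloc[100].to_dict()
    n_pred = predict_agitation(model, x)
    current = n_pred - 25.0
    got_pred, kp = derive_kp(model, x, current_N=current, rq=1.45, set_point=1.4)
    assert got_pred == pytest.approx(n_pred)
    # epsilon * K_P equals the predicted correction when signs agree
    assert 0.05 * kp == pytest.approx(25.0)


def test_derive_kp_zero_error_is_undefined(gain_model):
    x = {f: 1.0 for f in gain_model.features}
    with pytest.raises(ZeroDivisionError):
        derive_kp(gain_model, x, current_N=600.0, rq=1.4, set_point=1.4)
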