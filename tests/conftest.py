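import numpy as np
import pytest

from wheelload.kinematics import build_feature_frame
from wheelload.simulator import RigConfig, StyleConfig, simulate_trial


@pytest.fixture(scope="session")
def rig():
    return RigConfig()


@pytest.fixture(scope="session")
def trial_style2(rig):
    """A short noisy style-2 trial (moderate trunk motion at 1.2 m/s)."""
    return simulate_trial(rig, StyleConfig.preset(2, duration=20.0, seed=7))


@pytest.fixture(scope="session")
def trial_style2_clean(rig):
    """Same conditions without sensor noise."""
    return simulate_trial(
        rig,
        StyleConfig.preset(2, duration=20.0, seed=7,
                           noise_sd_accel=0.0, noise_sd_gyro=0.0),
    )


@pytest.fixture(scope="session")
def frame_style2(rig, trial_style2):
    return build_feature_frame(trial_style2.trunk, trial_style2.wheel,
                               rig.rear_wheel_diameter, load=trial_style2.load)


@pytest.fixture(scope="session")
def end_to_end():
    """Full pipeline over 3 seeded cohorts: simulate, train, compare methods.

    Twelve virtual participants, trunk-motion styles 2-3, 30-s trials; the
    last three participants are held out as unseen test subjects. The
    final-architecture LSTM (reduced width) and a linear baseline are
    trained per seed; every held-out trial is scored as model-based vs
    drag-test-based rolling resistance against the gold standard.
    """
    from wheelload.calibration import (RollingCoefficients,
                                       drag_based_rolling_resistance)
    from wheelload.dataset import split_sessions
    from wheelload.model import FrontLoadModel, ModelSpec
    from wheelload.resistance import (compare_methods, constant_trace,
                                      instantaneous_rolling_resistance)
    from wheelload.simulator import make_cohort

    out = {"trials": [], "test_reports": [], "lstm_val_mae": [],
           "linear_val_mae": []}
    for seed in (0, 1, 2):
        ds = make_cohort(n_participants=12, styles=(2, 3), duration=30.0,
                         seed=seed)
        holdout = ds.participants[-3:]
        ds = split_sessions(ds, holdout_participants=holdout,
                            train_fraction=0.8, seed=seed)
        spec = ModelSpec(
            model_type="lstm",
            hyperparameters={"units": 24, "epochs": 40, "patience": 8,
                             "train_stride": 3},
            seed=seed,
        )
        res = FrontLoadModel(ds, spec).fit()
        lin = FrontLoadModel(ds, ModelSpec(model_type="linear",
                                           seed=seed)).fit()
        out["lstm_val_mae"].append(res.validation_report.mae)
        out["linear_val_mae"].append(lin.validation_report.mae)
        test_sessions = ds.subset("test").sessions
        out["test_reports"].append(res.evaluate_sessions(test_sessions))
        for s in test_sessions:
            m = s.meta
            coeffs = RollingCoefficients(cf=m["cf_true"], cr=m["cr_true"])
            t, pred = res.predict(s.frame)
            w = spec.window
            gold = instantaneous_rolling_resistance(
                s.frame.outcome[w - 1:], m["fn_total"], coeffs, t=t,
                source="gold")
            model_tr = instantaneous_rolling_resistance(
                pred, m["fn_total"], coeffs, t=t, source="model")
            drag_val = drag_based_rolling_resistance(
                coeffs, m["rel_front_static"] / 100.0 * m["fn_total"],
                m["fn_total"])
            comp = compare_methods(gold, model_tr, constant_trace(drag_val, t))
            out["trials"].append({
                "comparison": comp,
                "mean_dynamic_rel": float(np.mean(s.frame.outcome)),
                "static_rel": m["rel_front_static"],
            })
    return out
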