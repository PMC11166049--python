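"""Predicting relative front-wheel load from kinematic features.

The mapping from the trunk/wheelchair predictors to the relative
front-wheel load (percent of total weight on the front wheels) is learned
on session-level training data. Five estimator families share one
interface: ordinary linear regression, random-forest regression, a
multilayer perceptron, and LSTM / GRU recurrent networks that consume a
sliding window of past samples. The final configuration is a single-layer
LSTM with 50 units, learning rate 0.01, batch size 128, dropout 0.1 and a
20-sample window.

Usage follows the model/results idiom::

    spec = ModelSpec(model_type="lstm")
    res = FrontLoadModel(dataset, spec).fit()
    pred_t, pred = res.predict(frame)
    print(res.summary())

Fit metrics are oriented as mean(observed - predicted) for the signed
error; see :mod:`wheelload.resistance` for the opposite orientation used
in method comparisons.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from ._recurrent import RecurrentRegressor
from .dataset import SessionDataset
from .kinematics import PREDICTORS, FeatureFrame

__all__ = [
    "Standardizer",
    "ModelSpec",
    "EvalReport",
    "FrontLoadModel",
    "FrontLoadResults",
    "make_windows",
    "evaluate",
    "exhaustive_feature_selection",
    "noise_robustness_check",
    "relative_load_to_kg",
]

FINAL_HYPERPARAMETERS = {
    "hidden_layers": 1,
    "units": 50,
    "learning_rate": 0.01,
    "batch_size": 128,
    "dropout": 0.1,
    "window": 20,
    "epochs": 200,
    "patience": 20,
    "train_stride": 1,
}
#: the most predictive subset found by exhaustive selection
DEFAULT_FEATURES = ("v_wc", "a_wc", "a_tr_perp")


@dataclass
class Standardizer:
    """Per-feature z-scoring, fitted on training data only."""

    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sd + self.mean

    def to_dict(self) -> dict:
        return {"mean": np.asarray(self.mean).tolist(),
                "sd": np.asarray(self.sd).tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(mean=np.asarray(d["mean"], dtype=float),
                   sd=np.asarray(d["sd"], dtype=float))


@dataclass
class ModelSpec:
    """Estimator family, feature subset and hyperparameters."""

    model_type: str = "lstm"   # linear | random_forest | feedforward | lstm | gru
    feature_subset: tuple = DEFAULT_FEATURES
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_type not in ("linear", "random_forest", "feedforward",
                                   "lstm", "gru"):
            raise ValueError(f"unknown model type {self.model_type!r}")
        unknown = set(self.feature_subset) - set(PREDICTORS)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")
        hp = dict(FINAL_HYPERPARAMETERS)
        if self.model_type not in ("lstm", "gru"):
            hp["window"] = 1
        hp.update(self.hyperparameters)
        if hp["window"] < 1:
            raise ValueError("window must be >= 1")
        self.hyperparameters = hp

    @property
    def window(self) -> int:
        return int(self.hyperparameters["window"])


@dataclass
class EvalReport:
    """Signed/absolute/squared error summary, me = mean(observed - predicted)."""

    me: float
    mae: float
    rmse: float

    def as_dict(self) -> dict:
        return {"me": self.me, "mae": self.mae, "rmse": self.rmse}


def evaluate(predicted, observed) -> EvalReport:
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise ValueError("predicted and observed must be equal-length, non-empty")
    err = observed - predicted
    return EvalReport(me=float(np.mean(err)),
                      mae=float(np.mean(np.abs(err))),
                      rmse=float(np.sqrt(np.mean(err**2))))


def make_windows(frame: FeatureFrame, window: int, features=None,
                 stride: int = 1):
    """Sliding windows (stride-aware) with the outcome at each window's end.

    Returns (X, y, t) where X has shape (n_windows, window, n_features),
    and y/t are the outcome and timestamp at the last sample of each
    window. Without an outcome channel, y is None.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(frame) < window:
        raise ValueError(f"frame of {len(frame)} samples shorter than "
                         f"window {window}")
    feats = frame.features(features or PREDICTORS)
    n = len(frame)
    idx_last = np.arange(window - 1, n, stride)
    offsets = np.arange(-(window - 1), 1)
    X = feats[idx_last[:, None] + offsets[None, :]]
    t = frame.t[idx_last]
    y = frame.outcome[idx_last] if frame.has_outcome else None
    return X, y, t


def _gather_windows(sessions, features, window, stride=1):
    Xs, ys = [], []
    for s in sessions:
        X, y, _ = make_windows(s.frame, window, features, stride)
        Xs.append(X)
        ys.append(y)
    if not Xs:
        raise ValueError("no sessions in split")
    return np.concatenate(Xs), np.concatenate(ys)


class FrontLoadModel:
    """Load-distribution model over a split :class:`SessionDataset`.

    The standardizer (features and outcome) is fitted on the training
    split only; the validation split steers early stopping and model
    choice but never the standardization or the parameter fit itself.
    """

    def __init__(self, dataset: SessionDataset, spec: ModelSpec):
        self.dataset = dataset
        self.spec = spec
        self.train_sessions = dataset.subset("train").sessions
        self.val_sessions = dataset.subset("validation").sessions
        if not self.train_sessions:
            raise ValueError("dataset has no training sessions")
        for s in self.train_sessions + self.val_sessions:
            if not s.frame.has_outcome:
                raise ValueError(f"session {s.key} lacks the outcome channel")

    def fit(self, noise_sd: float = 0.0) -> "FrontLoadResults":
        spec = self.spec
        hp = spec.hyperparameters
        feats = spec.feature_subset
        window = spec.window
        stride = int(hp.get("train_stride", 1))

        Xtr, ytr = _gather_windows(self.train_sessions, feats, window, stride)
        x_std = Standardizer().fit(Xtr.reshape(-1, len(feats)))
        y_std = Standardizer().fit(ytr[:, None])
        Xtr_z = x_std.transform(Xtr.reshape(-1, len(feats))).reshape(Xtr.shape)
        ytr_z = y_std.transform(ytr[:, None])[:, 0]

        if not np.isfinite(Xtr_z).all() or not np.isfinite(ytr_z).all():
            raise ValueError("non-finite values in training inputs")

        if self.val_sessions:
            Xv, yv = _gather_windows(self.val_sessions, feats, window)
            Xv_z = x_std.transform(Xv.reshape(-1, len(feats))).reshape(Xv.shape)
            yv_z = y_std.transform(yv[:, None])[:, 0]
        else:
            Xv_z = yv_z = None

        est = self._fit_backend(spec, Xtr_z, ytr_z, Xv_z, yv_z, noise_sd)
        res = FrontLoadResults(model=self, estimator=est, x_std=x_std,
                               y_std=y_std, noise_sd=noise_sd)
        res.train_report = res.evaluate_sessions(self.train_sessions)
        if self.val_sessions:
            res.validation_report = res.evaluate_sessions(self.val_sessions)
        return res

    def _fit_backend(self, spec, Xtr, ytr, Xv, yv, noise_sd):
        hp = spec.hyperparameters
        rng_seed = spec.seed
        if spec.model_type in ("lstm", "gru"):
            est = RecurrentRegressor(
                n_features=len(spec.feature_subset),
                cell=spec.model_type,
                units=int(hp["units"]),
                learning_rate=float(hp["learning_rate"]),
                batch_size=int(hp["batch_size"]),
                dropout=float(hp["dropout"]),
                epochs=int(hp["epochs"]),
                patience=int(hp["patience"]),
                noise_sd=noise_sd,
                seed=rng_seed,
            )
            est.fit(Xtr, ytr, Xv, yv)
            return est
        # flat backends see the flattened window
        Xf = Xtr.reshape(len(Xtr), -1)
        if noise_sd > 0:
            rng = np.random.default_rng(rng_seed + 1)
            Xf = Xf + rng.normal(0.0, noise_sd, size=Xf.shape)
        if spec.model_type == "linear":
            from sklearn.linear_model import LinearRegression
            return LinearRegression().fit(Xf, ytr)
        if spec.model_type == "random_forest":
            from sklearn.ensemble import RandomForestRegressor
            return RandomForestRegressor(
                n_estimators=int(hp.get("n_estimators", 100)),
                max_depth=hp.get("max_depth"),
                random_state=rng_seed, n_jobs=1,
            ).fit(Xf, ytr)
        from sklearn.neural_network import MLPRegressor
        return MLPRegressor(
            hidden_layer_sizes=(int(hp["units"]),) * int(hp["hidden_layers"]),
            learning_rate_init=float(hp["learning_rate"]),
            batch_size=min(int(hp["batch_size"]), len(Xf)),
            max_iter=int(hp["epochs"]),
            random_state=rng_seed,
        ).fit(Xf, ytr)


@dataclass
class FrontLoadResults:
    """Fitted predictor with its standardizers and fit diagnostics."""

    model: FrontLoadModel
    estimator: object
    x_std: Standardizer
    y_std: Standardizer
    noise_sd: float = 0.0
    train_report: EvalReport | None = None
    validation_report: EvalReport | None = None

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    def predict(self, frame: FeatureFrame):
        """(timestamps, predicted rel_front in percent, clipped to [0, 100]).

        Predictions start at the end of the first full window, so the
        output is window-1 samples shorter than the frame.
        """
        spec = self.spec
        missing = [c for c in spec.feature_subset if c not in frame.data.columns]
        if missing:
            raise ValueError(f"frame missing model features {missing}")
        X, _, t = make_windows(frame, spec.window, spec.feature_subset)
        nf = len(spec.feature_subset)
        Xz = self.x_std.transform(X.reshape(-1, nf)).reshape(X.shape)
        if isinstance(self.estimator, RecurrentRegressor):
            yz = self.estimator.predict(Xz)
        else:
            yz = self.estimator.predict(Xz.reshape(len(Xz), -1))
        y = self.y_std.inverse_transform(np.asarray(yz)[:, None])[:, 0]
        return t, np.clip(y, 0.0, 100.0)

    def evaluate_sessions(self, sessions) -> EvalReport:
        preds, obs = [], []
        for s in sessions:
            t, y = self.predict(s.frame)
            preds.append(y)
            obs.append(s.frame.outcome[self.spec.window - 1:])
        return evaluate(np.concatenate(preds), np.concatenate(obs))

    def summary(self) -> str:
        spec = self.spec
        lines = [
            "Front-wheel load model",
            "----------------------",
            f"model type      {spec.model_type}",
            f"features        {', '.join(spec.feature_subset)}",
            f"window          {spec.window} samples",
            f"train sessions  {len(self.model.train_sessions)}",
            f"val sessions    {len(self.model.val_sessions)}",
        ]
        for name, rep in (("train", self.train_report),
                          ("validation", self.validation_report)):
            if rep is not None:
                lines.append(
                    f"{name:<10} ME {rep.me:6.2f}  MAE {rep.mae:5.2f}  "
                    f"RMSE {rep.rmse:5.2f}  (% front load)"
                )
        return "\n".join(lines)

    def plot_prediction(self, frame: FeatureFrame, ax=None):
        """Observed vs predicted relative front load over time."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        t, y = self.predict(frame)
        if frame.has_outcome:
            ax.plot(frame.t, frame.outcome, "k-", lw=1, label="observed")
        ax.plot(t, y, "-", color="purple", lw=1, label="predicted")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("front-wheel load (%)")
        ax.legend(loc="upper right", fontsize=8)
        return ax

    # ---- persistence ------------------------------------------------
    def save(self, directory) -> None:
        """Write weights + standardizers + spec to a model directory."""
        import os
        import yaml
        os.makedirs(directory, exist_ok=True)
        if not isinstance(self.estimator, RecurrentRegressor):
            raise NotImplementedError(
                "only recurrent models support directory persistence"
            )
        weights = self.estimator.get_weights()
        np.savez(os.path.join(directory, "weights.npz"), **weights)
        with open(os.path.join(directory, "standardizer.json"), "w") as fh:
            json.dump({"x": self.x_std.to_dict(), "y": self.y_std.to_dict()}, fh)
        with open(os.path.join(directory, "spec.yaml"), "w") as fh:
            yaml.safe_dump(
                {"model_type": self.spec.model_type,
                 "feature_subset": list(self.spec.feature_subset),
                 "hyperparameters": self.spec.hyperparameters,
                 "seed": self.spec.seed},
                fh,
            )

    @classmethod
    def load(cls, directory) -> "FrontLoadResults":
        import os
        import yaml
        with open(os.path.join(directory, "spec.yaml")) as fh:
            d = yaml.safe_load(fh)
        spec = ModelSpec(model_type=d["model_type"],
                         feature_subset=tuple(d["feature_subset"]),
                         hyperparameters=d["hyperparameters"],
                         seed=d["seed"])
        est = RecurrentRegressor(
            n_features=len(spec.feature_subset), cell=spec.model_type,
            units=int(spec.hyperparameters["units"]), seed=spec.seed,
        )
        with np.load(os.path.join(directory, "weights.npz")) as npz:
            est.set_weights({k: npz[k] for k in npz.files})
        with open(os.path.join(directory, "standardizer.json")) as fh:
            sd = json.load(fh)
        dummy_model = object.__new__(FrontLoadModel)
        dummy_model.spec = spec
        dummy_model.train_sessions = []
        dummy_model.val_sessions = []
        dummy_model.dataset = SessionDataset([])
        return cls(model=dummy_model, estimator=est,
                   x_std=Standardizer.from_dict(sd["x"]),
                   y_std=Standardizer.from_dict(sd["y"]))


def exhaustive_feature_selection(train: SessionDataset | list, n_folds: int = 7,
                                 seed: int = 0, n_estimators: int = 30,
                                 max_depth: int | None = None,
                                 max_samples_per_session: int | None = None):
    """Score every non-empty predictor subset by grouped cross-validation.

    A random-forest regressor is scored with ``n_folds``-fold
    cross-validation whose folds partition *sessions* (never samples of
    one session across folds). Returns a list of
    ``(subset, mean_mae, sd_mae)`` sorted by mean MAE ascending.
    """
    from sklearn.ensemble import RandomForestRegressor

    sessions = list(train.sessions if isinstance(train, SessionDataset) else train)
    if len(sessions) < n_folds:
        raise ValueError(f"need >= {n_folds} sessions for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    Xs, ys, groups = [], [], []
    for gi, s in enumerate(sessions):
        X = s.frame.features(PREDICTORS)
        y = s.frame.outcome
        if max_samples_per_session and len(X) > max_samples_per_session:
            idx = rng.choice(len(X), max_samples_per_session, replace=False)
            idx.sort()
            X, y = X[idx], y[idx]
        Xs.append(X)
        ys.append(y)
        groups.append(np.full(len(X), gi))
    X_all = np.concatenate(Xs)
    y_all = np.concatenate(ys)
    groups = np.concatenate(groups)

    order = rng.permutation(len(sessions))
    fold_of_session = np.empty(len(sessions), dtype=int)
    for rank, si in enumerate(order):
        fold_of_session[si] = rank % n_folds
    fold = fold_of_session[groups]

    name_to_col = {n: i for i, n in enumerate(PREDICTORS)}
    results = []
    for k in range(1, len(PREDICTORS) + 1):
        for subset in itertools.combinations(PREDICTORS, k):
            cols = [name_to_col[n] for n in subset]
            fold_mae = []
            for f in range(n_folds):
                tr = fold != f
                te = ~tr
                rf = RandomForestRegressor(
                    n_estimators=n_estimators, max_depth=max_depth,
                    random_state=seed, n_jobs=1,
                )
                rf.fit(X_all[np.ix_(tr, cols)], y_all[tr])
                pred = rf.predict(X_all[np.ix_(te, cols)])
                fold_mae.append(np.mean(np.abs(y_all[te] - pred)))
            results.append((subset, float(np.mean(fold_mae)),
                            float(np.std(fold_mae))))
    results.sort(key=lambda r: r[1])
    return results


def best_subset_of_size(results, k: int):
    """Best-scoring subset of exactly k features from selection results."""
    for subset, mae, sd in results:
        if len(subset) == k:
            return subset, mae, sd
    raise ValueError(f"no subset of size {k} in results")


def noise_robustness_check(spec: ModelSpec, dataset: SessionDataset,
                           test_sessions, noise_sd: float = 0.2):
    """Overfitting diagnostic: fit with and without input-noise injection.

    Trains ``spec`` twice — as-is, and with zero-mean Gaussian noise of the
    given sd injected on the standardized inputs during training — and
    evaluates both on the test sessions. A large gap between the two test
    MAEs indicates the fit is driven by white noise, i.e. overfitting.
    """
    base = FrontLoadModel(dataset, spec).fit(noise_sd=0.0)
    noisy = FrontLoadModel(dataset, spec).fit(noise_sd=noise_sd)
    return (base.evaluate_sessions(test_sessions),
            noisy.evaluate_sessions(test_sessions))


def relative_load_to_kg(error_percent: float, total_mass_kg: float) -> float:
    """Convert a relative-load error in percent to kilograms.

    A load-share error of p percent of the total weight corresponds to
    p/100 * total mass in kilograms (e.g. 3.8 % of 68 kg is about 2.6 kg).
    """
    return error_percent / 100.0 * total_mass_kg
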