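"""Random-forest gain scheduling for the adaptive-proportional controller.

A 100-tree random-forest regressor learns the agitation speed required to
hold the respiratory quotient at its set-point, as a function of nine
process features (fed-batch time, current agitation, measured RQ, OUR,
CER, feed rate, cumulative glucose fed, inlet O2 fraction, total
biomass).  The training corpus is generated by closed-loop twin runs of
the simpler strategies (manual-heuristic and Boolean-logic) at several
programmed growth rates; the supervision target is the twin's
ground-truth inversion of the kLa/OTR map — a simulation-only shortcut
standing in for the operator-action labels a real plant would provide.

At control time the forest's prediction is converted into a proportional
gain K_P = (N_predicted - N_current) / (RQ - set-point), so the
adaptive-proportional law delta_rpm = epsilon * K_P reproduces exactly
the predicted correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .config import GainModelConfig, TwinParams, with_mu
from .twin import inlet_blend, required_agitation

__all__ = [
    "GainModel",
    "build_training_set",
    "train",
    "predict_agitation",
    "derive_kp",
    "generate_training_corpus",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


@dataclass
class GainModel:
    """Trained forest plus its feature schema and training metadata."""

    forest: RandomForestRegressor
    features: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.forest.estimators_)

    def feature_array(self, x: dict | Sequence[float]) -> np.ndarray:
        if isinstance(x, dict):
            missing = [f for f in self.features if f not in x]
            if missing:
                raise KeyError(f"feature vector missing {missing}")
            vals = [float(x[f]) for f in self.features]
        else:
            vals = [float(v) for v in x]
            if len(vals) != len(self.features):
                raise ValueError(
                    f"expected {len(self.features)} features, got {len(vals)}"
                )
        arr = np.asarray(vals, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature vector contains non-finite values")
        return arr.reshape(1, -1)

    def save(self, path: str) -> None:
        joblib.dump(
            {
                "schema_version": SCHEMA_VERSION,
                "features": self.features,
                "metadata": self.metadata,
                "forest": self.forest,
            },
            path,
        )

    @classmethod
    def load(cls, path: str) -> "GainModel":
        blob = joblib.load(path)
        if blob.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"gain-model schema {blob.get('schema_version')} != {SCHEMA_VERSION}"
            )
        return cls(
            forest=blob["forest"],
            features=tuple(blob["features"]),
            metadata=blob["metadata"],
        )


def build_training_set(
    logs: Sequence,
    params: TwinParams,
    config: GainModelConfig | None = None,
    set_point: float = 1.4,
) -> tuple[pd.DataFrame, np.ndarray]:
    """One training row per control instant across a corpus of logs.

    The target of each row is the agitation speed that would hold RQ at
    ``set_point`` given the row's true metabolic state (closed-form
    steady-state inversion).  Rows with undefined RQ, or taken while
    residual glucose accumulates, are dropped.
    """
    config = config or GainModelConfig()
    if not logs:
        raise ValueError("training corpus is empty")
    feats, targets = [], []
    interval = config.row_interval_min / 60.0
    for log in logs:
        df = log.df
        mu = log.meta.get("mu_set", params.mu_set)
        p = with_mu(params, mu)
        next_row = config.min_time_h
        for row in df.itertuples():
            if row.t < next_row - 1e-9:
                continue
            next_row = row.t + interval
            if not math.isfinite(row.RQ_meas) or row.S > 0.5 or row.qS_true <= 0:
                continue
            blend = inlet_blend(row.F_air, row.F_O2, p)
            try:
                target = required_agitation(
                    set_point, row.X, row.qS_true, p, V=row.V, blend=blend
                )
            except ValueError:
                continue  # set-point unreachable within the O2 supply
            smoothed = row.RQ_ctrl if math.isfinite(row.RQ_ctrl) else row.RQ_meas
            feats.append(
                {
                    "t": row.t,
                    "N": row.N,
                    "RQ": smoothed,
                    "OUR": row.OUR_meas,
                    "CER": row.CER_meas,
                    "feed_rate": row.feed_rate,
                    "cum_glucose_fed": row.cum_fed,
                    "y_O2_in": row.y_O2_in,
                    "total_biomass": row.X * row.V,
                }
            )
            targets.append(target)
    if not feats:
        raise ValueError("no usable training rows in corpus")
    features = pd.DataFrame(feats)[list(config.features)]
    return features, np.asarray(targets)


def train(
    features: pd.DataFrame,
    targets: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
    config: GainModelConfig | None = None,
) -> GainModel:
    """Fit the bootstrap forest (per-split feature subsampling, seeded)."""
    config = config or GainModelConfig()
    if len(features) < 50:
        raise ValueError(f"need >= 50 training rows, got {len(features)}")
    targets = np.asarray(targets, dtype=float)
    if np.ptp(targets) == 0:
        warnings.warn("degenerate (constant) training targets", stacklevel=2)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        min_samples_leaf=config.min_samples_leaf,
        max_features=config.max_features,
        bootstrap=True,
        random_state=seed,
    )
    forest.fit(features.to_numpy(), targets)
    return GainModel(
        forest=forest,
        features=tuple(features.columns),
        metadata={
            "n_trees": n_trees,
            "seed": seed,
            "n_rows": len(features),
            "target": "required agitation (rpm)",
        },
    )


def predict_agitation(model: GainModel, x: dict | Sequence[float]) -> float:
    """Forest prediction: arithmetic mean of the per-tree predictions."""
    return float(model.forest.predict(model.feature_array(x))[0])


def derive_kp(
    model: GainModel,
    x: dict | Sequence[float],
    current_N: float,
    rq: float,
    set_point: float,
    kp_range: tuple[float, float] = (0.0, 600.0),
) -> tuple[float, float]:
    """Non-negative gain whose magnitude is set by the predicted correction.

    K_P = |N_predicted - N_current| / |epsilon|, clamped to ``kp_range``,
    so that when the model's correction agrees in sign with the error the
    proportional law epsilon*K_P reproduces it exactly, and when the model
    is extrapolating (prediction on the wrong side of the error — e.g.
    process states never seen in training) the controller still moves in
    the direction of the error with the model-implied step size.  K_P is
    never negative, so the sign of delta_rpm always follows epsilon, and
    clamping can shrink but never flip the move.  The default upper clamp
    brackets the plant's own steady-state sensitivity |dN/dRQ| (roughly
    0.55*N over the operating range), preventing noise-amplified jumps
    when epsilon is small.

    Returns ``(predicted_N, K_P)``.
    """
    eps = rq - set_point
    if eps == 0:
        raise ZeroDivisionError("K_P undefined at zero error")
    n_pred = predict_agitation(model, x)
    kp = abs(n_pred - current_N) / abs(eps)
    kp = min(max(kp, kp_range[0]), kp_range[1])
    return n_pred, kp


def generate_training_corpus(
    params: TwinParams,
    config: GainModelConfig | None = None,
    seed: int = 0,
    horizon_h: float = 20.0,
) -> list:
    """Closed-loop twin runs emulating the historical fermentation corpus.

    Runs every configured strategy at every configured growth rate (one
    replicate each), without inlet-gas disturbances — mirroring a record
    of plain hypoxic fed-batches at several mu values.
    """
    from .config import ControllerConfig
    from .controllers import make_controller
    from .twin import simulate

    config = config or GainModelConfig()
    logs = []
    run = 0
    for mu in config.corpus_mu_values:
        for strategy in config.corpus_strategies:
            controller = make_controller(ControllerConfig(type=strategy))
            logs.append(
                simulate(
                    controller,
                    with_mu(params, mu),
                    horizon_h=horizon_h,
                    seed=seed * 1009 + run,
                )
            )
            run += 1
    return logs
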