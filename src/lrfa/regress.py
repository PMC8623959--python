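"""SVR torque prediction, fold construction and evaluation metrics.

The regression stage fits an epsilon-insensitive support vector regression
with an RBF kernel on the normalized selected variables. Hyperparameters
(epsilon, C, gamma) are tuned by exhaustive search over power-of-two grids,
scored by mean R-squared over an internal three-fold split of the training
rows. Validation uses torque-stratified three-fold assignments in which the
minimum- and maximum-torque measurements always land in the training fold,
so validation never extrapolates, plus the conventional single-variable
baseline: a logarithmic fit of dominant peak frequency against torque.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .features import OBJECTIVE_COLUMN

__all__ = [
    "SVRConfig",
    "TrainedModel",
    "EvaluationReport",
    "assign_folds",
    "train_svr",
    "predict",
    "evaluate",
    "fit_log_baseline",
    "predict_from_log_baseline",
    "loocv",
    "save_model",
    "load_model",
]


def _pow2(lo: int, hi: int, step: int) -> tuple[float, ...]:
    return tuple(2.0**b for b in range(lo, hi + 1, step))


@dataclass(frozen=True)
class SVRConfig:
    """Hyperparameter search settings.

    Default grids are powers of two: epsilon 2^-20..2^9, C 2^-10..2^10,
    gamma 2^-15..2^9, stepping ``grid_step_exponent`` in the exponent.
    Explicit ``*_grid`` values override the exponent ranges.
    """

    grid_step_exponent: int = 1
    epsilon_grid: tuple[float, ...] | None = None
    C_grid: tuple[float, ...] | None = None
    gamma_grid: tuple[float, ...] | None = None
    cv_folds_for_tuning: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step_exponent < 1:
            raise ValueError("grid_step_exponent must be >= 1")
        if self.cv_folds_for_tuning < 2:
            raise ValueError("cv_folds_for_tuning must be >= 2")
        for name in ("epsilon_grid", "C_grid", "gamma_grid"):
            g = getattr(self, name)
            if g is not None and (len(g) == 0 or any(v <= 0 for v in g)):
                raise ValueError(f"{name} must be positive and non-empty")

    @property
    def epsilons(self) -> tuple[float, ...]:
        return self.epsilon_grid or _pow2(-20, 9, self.grid_step_exponent)

    @property
    def Cs(self) -> tuple[float, ...]:
        return self.C_grid or _pow2(-10, 10, self.grid_step_exponent)

    @property
    def gammas(self) -> tuple[float, ...]:
        return self.gamma_grid or _pow2(-15, 9, self.grid_step_exponent)


def assign_folds(torques: np.ndarray | list[float]) -> np.ndarray:
    """Torque-stratified three-fold assignment (fold indices 1..3).

    The minimum- and maximum-torque measurements go to fold 1, so models
    trained on fold 1 never have to extrapolate. The remaining measurements,
    sorted by torque (ties kept in input order), are dealt out in
    consecutive triplets, one to each fold, which spreads every torque
    regime evenly across folds.
    """
    torques = np.asarray(torques, dtype=float)
    n = len(torques)
    if n < 5:
        raise ValueError("need at least 5 measurements for three folds")
    folds = np.zeros(n, dtype=int)
    i_min = int(np.argmin(torques))
    i_max = int(np.argmax(torques))
    if i_min == i_max:
        raise ValueError("all torques equal; folds would be arbitrary")
    folds[i_min] = 1
    folds[i_max] = 1
    rest = [i for i in range(n) if i not in (i_min, i_max)]
    rest.sort(key=lambda i: torques[i])  # stable: torque ties keep input order
    for pos, i in enumerate(rest):
        folds[i] = pos % 3 + 1
    return folds


@dataclass
class TrainedModel:
    """Fitted SVR plus everything needed to reproduce its predictions.

    The prediction path is: z-score the selected variables with the stored
    training statistics, evaluate the RBF kernel expansion against the
    stored support vectors, then map the normalized output back to Nm.
    """

    selected_variables: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    objective_mean: float
    objective_sd: float
    epsilon: float
    C: float
    gamma: float
    support_vectors: np.ndarray
    dual_coefs: np.ndarray
    intercept: float
    training_r2: float
    training_torque_range: tuple[float, float]
    tuning_r2: float = float("nan")
    feature_mins: np.ndarray | None = None
    feature_maxs: np.ndarray | None = None

    def _predict_normalized(self, Xn: np.ndarray) -> np.ndarray:
        K = rbf_kernel(Xn, self.support_vectors, gamma=self.gamma)
        return K @ self.dual_coefs + self.intercept


def _norm_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    degenerate = sds == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} selected variable(s) constant on the "
            "training rows; they contribute nothing to the kernel",
            RuntimeWarning,
            stacklevel=3,
        )
        sds = np.where(degenerate, 1.0, sds)
    return means, sds


def _cv_r2(
    X: np.ndarray, y: np.ndarray, eps: float, C: float, gamma: float, splits
) -> float:
    scores = []
    for tr, va in splits:
        svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=eps)
        svr.fit(X[tr], y[tr])
        pred = svr.predict(X[va])
        sst = float(np.sum((y[va] - y[va].mean()) ** 2))
        if sst == 0.0:
            continue
        scores.append(1.0 - float(np.sum((y[va] - pred) ** 2)) / sst)
    return float(np.mean(scores)) if scores else -np.inf


def train_svr(
    table: pd.DataFrame, variables: list[str], cfg: SVRConfig
) -> TrainedModel:
    """Grid-search and fit the SVR torque predictor on a feature table.

    Every (epsilon, C, gamma) triple on the power-of-two grids is scored by
    mean R-squared over a seeded internal 3-fold split of the training rows;
    the best triple (first in grid order on ties) is refit on all rows.
    Normalization statistics come from the training rows only.
    """
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"table lacks selected variables: {missing}")
    n = len(table)
    single = len(cfg.epsilons) == len(cfg.Cs) == len(cfg.gammas) == 1
    if n < cfg.cv_folds_for_tuning and not single:
        raise ValueError(
            f"need at least {cfg.cv_folds_for_tuning} rows to tune, got {n}"
        )
    if n < 2:
        raise ValueError("need at least 2 training rows")
    X = table[list(variables)].to_numpy(dtype=float)
    y = table[OBJECTIVE_COLUMN].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("objective has zero variance on the training rows")

    means, sds = _norm_stats(X)
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=1))
    Xn = (X - means) / sds
    yn = (y - y_mean) / y_sd

    best = (-np.inf, None)
    if single:
        best = (float("nan"), (cfg.epsilons[0], cfg.Cs[0], cfg.gammas[0]))
    else:
        kf = KFold(
            n_splits=cfg.cv_folds_for_tuning, shuffle=True, random_state=cfg.rng_seed
        )
        splits = list(kf.split(Xn))
        for eps in cfg.epsilons:
            for C in cfg.Cs:
                for gamma in cfg.gammas:
                    score = _cv_r2(Xn, yn, eps, C, gamma, splits)
                    if score > best[0]:
                        best = (score, (eps, C, gamma))
        if best[1] is None:
            raise ValueError("hyperparameter tuning failed on every grid point")
    tuning_r2, (eps, C, gamma) = best

    svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=eps)
    svr.fit(Xn, yn)
    pred_n = svr.predict(Xn)
    sst = float(np.sum((yn - yn.mean()) ** 2))
    training_r2 = 1.0 - float(np.sum((yn - pred_n) ** 2)) / sst
    return TrainedModel(
        selected_variables=list(variables),
        feature_means=means,
        feature_sds=sds,
        objective_mean=y_mean,
        objective_sd=y_sd,
        epsilon=float(eps),
        C=float(C),
        gamma=float(gamma),
        support_vectors=svr.support_vectors_.copy(),
        dual_coefs=svr.dual_coef_.ravel().copy(),
        intercept=float(svr.intercept_[0]),
        training_r2=training_r2,
        training_torque_range=(float(y.min()), float(y.max())),
        tuning_r2=float(tuning_r2),
        feature_mins=X.min(axis=0),
        feature_maxs=X.max(axis=0),
    )


def predict(model: TrainedModel, rows: pd.DataFrame) -> np.ndarray:
    """Predicted peak torque (Nm) for each row of a feature table.

    Rows whose features fall outside the training feature range are
    predicted anyway but flagged with a warning: accuracy degrades sharply
    under extrapolation.
    """
    missing = [v for v in model.selected_variables if v not in rows.columns]
    if missing:
        raise ValueError(f"rows lack selected variables: {missing}")
    X = rows[model.selected_variables].to_numpy(dtype=float)
    Xn = (X - model.feature_means) / model.feature_sds
    pred = model._predict_normalized(Xn) * model.objective_sd + model.objective_mean
    if not np.all(np.isfinite(pred)):
        raise ValueError("non-finite prediction; check input features")
    if model.feature_mins is not None and model.feature_maxs is not None:
        span = np.maximum(model.feature_maxs - model.feature_mins, 1e-12)
        outside = (X < model.feature_mins - 0.05 * span) | (
            X > model.feature_maxs + 0.05 * span
        )
        n_out = int(np.any(outside, axis=1).sum())
        if n_out:
            warnings.warn(
                f"{n_out} row(s) lie outside the training feature range "
                "(extrapolation; accuracy degrades sharply)",
                RuntimeWarning,
                stacklevel=2,
            )
    return pred


@dataclass
class EvaluationReport:
    """Validation metrics for predicted vs. true peak torque."""

    r2: float
    pearson_r: float
    mse: float
    mse_normalized: float
    frac_within_20pct: float
    n_within: int
    n_total: int
    points: pd.DataFrame  # true_nm, predicted_nm, within_20pct

    def summary(self) -> str:
        return (
            f"n = {self.n_total}: R^2 = {self.r2:.3f}, r = {self.pearson_r:.3f}, "
            f"MSE = {self.mse:.4g} Nm^2 ({self.mse_normalized:.4g} normalized), "
            f"{self.n_within}/{self.n_total} "
            f"({100 * self.frac_within_20pct:.1f}%) within +/-20%"
        )


def evaluate(true: np.ndarray, predicted: np.ndarray) -> EvaluationReport:
    """R-squared, Pearson r, MSE and the +/-20 % band fraction.

    A prediction is "within band" when |pred - true| <= 0.2 * true. MSE is
    reported both on the raw Nm scale and on the z-scale of the true
    torques (variance-normalized).
    """
    true = np.asarray(true, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if true.shape != predicted.shape or true.ndim != 1 or len(true) < 2:
        raise ValueError("true and predicted must be equal-length vectors (n >= 2)")
    sst = float(np.sum((true - true.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("true torques have zero variance; R^2 undefined")
    ss_res = float(np.sum((true - predicted) ** 2))
    r2 = 1.0 - ss_res / sst
    pearson = float(sps.pearsonr(true, predicted).statistic)
    mse = float(np.mean((true - predicted) ** 2))
    mse_norm = mse / (sst / (len(true) - 1))
    within = np.abs(predicted - true) <= 0.2 * true
    points = pd.DataFrame(
        {"true_nm": true, "predicted_nm": predicted, "within_20pct": within}
    )
    return EvaluationReport(
        r2=r2,
        pearson_r=pearson,
        mse=mse,
        mse_normalized=float(mse_norm),
        frac_within_20pct=float(within.mean()),
        n_within=int(within.sum()),
        n_total=len(true),
        points=points,
    )


def fit_log_baseline(
    torques: np.ndarray | list[float], peak_frequencies: np.ndarray | list[float]
) -> tuple[float, float, float]:
    """Conventional single-variable diagnostic: f = a*ln(torque) + b.

    Returns (a, b, r2) where r2 is the coefficient of determination of the
    frequency fit. This is the baseline the multivariate pipeline is
    compared against.
    """
    torques = np.asarray(torques, dtype=float)
    freqs = np.asarray(peak_frequencies, dtype=float)
    if np.any(torques <= 0):
        raise ValueError("torques must be positive for a logarithmic fit")
    if len(torques) < 3 or len(torques) != len(freqs):
        raise ValueError("need >= 3 paired (torque, frequency) points")
    lt = np.log(torques)
    a, b = np.polyfit(lt, freqs, 1)
    fitted = a * lt + b
    sst = float(np.sum((freqs - freqs.mean()) ** 2))
    r2 = 0.0 if sst == 0.0 else 1.0 - float(np.sum((freqs - fitted) ** 2)) / sst
    return float(a), float(b), float(r2)


def predict_from_log_baseline(
    a: float, b: float, peak_frequencies: np.ndarray
) -> np.ndarray:
    """Invert the logarithmic law: torque = exp((f - b) / a)."""
    if a == 0:
        raise ValueError("zero slope; the logarithmic law cannot be inverted")
    return np.exp((np.asarray(peak_frequencies, dtype=float) - b) / a)


def loocv(
    table: pd.DataFrame, variables: list[str], cfg: SVRConfig
) -> EvaluationReport:
    """Leave-one-out cross-validation of the SVR predictor.

    Each measurement in turn is held out, the model is tuned and trained on
    the rest, and the held-out torque is predicted. The per-point table is
    ordered by true torque.
    """
    n = len(table)
    if n < 3:
        raise ValueError("need at least 3 rows for leave-one-out validation")
    true = table[OBJECTIVE_COLUMN].to_numpy(dtype=float)
    preds = np.empty(n)
    for i in range(n):
        rest = table.drop(table.index[i])
        model = train_svr(rest, variables, cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            preds[i] = predict(model, table.iloc[[i]])[0]
    report = evaluate(true, preds)
    report.points = report.points.sort_values("true_nm").reset_index(drop=True)
    return report


# ---------------------------------------------------------------------------
# model persistence (single self-describing JSON archive)


def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "format": "lrfa-svr-model",
        "version": 1,
        "selected_variables": model.selected_variables,
        "feature_means": model.feature_means.tolist(),
        "feature_sds": model.feature_sds.tolist(),
        "objective_mean": model.objective_mean,
        "objective_sd": model.objective_sd,
        "hyperparameters": {
            "epsilon": model.epsilon,
            "C": model.C,
            "gamma": model.gamma,
        },
        "support_vectors": model.support_vectors.tolist(),
        "dual_coefs": model.dual_coefs.tolist(),
        "intercept": model.intercept,
        "training_r2": model.training_r2,
        "tuning_r2": model.tuning_r2,
        "training_torque_range": list(model.training_torque_range),
        "feature_mins": None if model.feature_mins is None else model.feature_mins.tolist(),
        "feature_maxs": None if model.feature_maxs is None else model.feature_maxs.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "lrfa-svr-model":
        raise ValueError(f"{path} is not an lrfa SVR model archive")
    hp = payload["hyperparameters"]
    return TrainedModel(
        selected_variables=payload["selected_variables"],
        feature_means=np.asarray(payload["feature_means"]),
        feature_sds=np.asarray(payload["feature_sds"]),
        objective_mean=payload["objective_mean"],
        objective_sd=payload["objective_sd"],
        epsilon=hp["epsilon"],
        C=hp["C"],
        gamma=hp["gamma"],
        support_vectors=np.asarray(payload["support_vectors"]),
        dual_coefs=np.asarray(payload["dual_coefs"]),
        intercept=payload["intercept"],
        training_r2=payload["training_r2"],
        training_torque_range=tuple(payload["training_torque_range"]),
        tuning_r2=payload.get("tuning_r2", float("nan")),
        feature_mins=(
            None if payload.get("feature_mins") is None else np.asarray(payload["feature_mins"])
        ),
        feature_maxs=(
            None if payload.get("feature_maxs") is None else np.asarray(payload["feature_maxs"])
        ),
    )
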