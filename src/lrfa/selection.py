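"""Bootstrap-Lasso ranking of explanatory variables.

The feature table is standardized (each explanatory column and the torque
objective to zero mean, unit sd) and an L1-regularized linear regression is
fitted on a large number of bootstrap resamples for every candidate
regularization strength. Variables are ranked by how often they receive a
nonzero coefficient at the chosen strength; the strength itself is the one
with the highest best-case in-resample coefficient of determination among
strengths whose selection footprint stays within ``max_variables``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import logging

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .features import OBJECTIVE_COLUMN

logger = logging.getLogger(__name__)

__all__ = [
    "LassoConfig",
    "NormalizationStats",
    "SelectionResult",
    "normalize_columns",
    "bootstrap_lasso",
    "take_top_k",
    "write_selection_result",
]


def default_lambda_grid() -> tuple[float, ...]:
    """20 log-spaced strengths on 1e-3..1 (normalized-data scale)."""
    return tuple(np.logspace(-3, 0, 20))


@dataclass(frozen=True)
class LassoConfig:
    """Settings of the bootstrap-Lasso variable ranking.

    ``max_variables`` caps the selection footprint of an admissible
    regularization strength; ``footprint_mode`` decides whether that cap
    applies to the mean number of variables selected per resample
    (``"mean_per_trial"``, default) or to the number of distinct variables
    selected at least once (``"unique"``).
    """

    n_bootstrap: int = 2000
    lambda_grid: tuple[float, ...] = field(default_factory=default_lambda_grid)
    max_variables: int = 40
    top_k: int = 30
    footprint_mode: str = "mean_per_trial"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if len(self.lambda_grid) == 0 or any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda_grid must be non-empty and positive")
        if self.top_k > self.max_variables:
            raise ValueError("top_k must not exceed max_variables")
        if self.footprint_mode not in ("mean_per_trial", "unique"):
            raise ValueError("footprint_mode must be 'mean_per_trial' or 'unique'")


@dataclass
class NormalizationStats:
    """Column means and sds used for the z-score transform (objective too)."""

    means: pd.Series
    sds: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = [c for c in self.means.index if c in table.columns]
        return (table[cols] - self.means[cols]) / self.sds[cols]

    def inverse_transform_objective(self, y_norm: np.ndarray) -> np.ndarray:
        return (
            np.asarray(y_norm) * self.sds[OBJECTIVE_COLUMN]
            + self.means[OBJECTIVE_COLUMN]
        )

    def transform_objective(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y) - self.means[OBJECTIVE_COLUMN]) / self.sds[
            OBJECTIVE_COLUMN
        ]


def normalize_columns(table: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationStats]:
    """Z-score every column (explanatory and objective) of a feature table.

    Normalization flattens the wildly different orders of magnitude of the
    variables (Hz vs. amplitude vs. dimensionless shape statistics) so that
    a single regularization strength treats them comparably. Constant
    columns are dropped with a warning: their z-score is undefined.
    """
    means = table.mean()
    sds = table.std(ddof=1)
    constant = sds.index[(sds == 0) | sds.isna()].tolist()
    if OBJECTIVE_COLUMN in constant:
        raise ValueError("objective column has zero spread; nothing to regress")
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant column(s): {constant[:5]}"
            + ("..." if len(constant) > 5 else ""),
            RuntimeWarning,
            stacklevel=2,
        )
    keep = [c for c in table.columns if c not in constant]
    stats = NormalizationStats(means=means[keep], sds=sds[keep])
    return stats.transform(table), stats


@dataclass
class SelectionResult:
    """Outcome of the bootstrap-Lasso ranking at the chosen strength."""

    selection_counts: pd.Series  # variable -> times selected, in column order
    chosen_lambda: float
    best_r2: float
    mean_variables_per_trial: float
    ranked_variables: list[str]
    n_bootstrap: int
    per_lambda: pd.DataFrame  # lambda, best_r2, mean_vars_per_trial, n_unique


def _resample_indices(
    n_rows: int, n_bootstrap: int, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, n_rows, size=(n_bootstrap, n_rows))


def bootstrap_lasso(
    table: pd.DataFrame, cfg: LassoConfig, resample_indices: np.ndarray | None = None
) -> SelectionResult:
    """Rank explanatory variables by bootstrap selection frequency.

    For every candidate strength, an L1 regression is fitted on each of
    ``n_bootstrap`` resamples drawn with replacement (the same resamples are
    reused across strengths, so results at different strengths are paired).
    Each fit is centered within its resample, which is equivalent to fitting
    an intercept. The in-resample R-squared of each fit is recorded; the
    chosen strength maximizes the best-case R-squared subject to the
    footprint cap. Fully reproducible under ``cfg.rng_seed``; a precomputed
    ``resample_indices`` array (n_bootstrap x n_rows) may be supplied
    instead.
    """
    x_cols = [c for c in table.columns if c != OBJECTIVE_COLUMN]
    if len(table) < 5:
        raise ValueError("need at least 5 rows for bootstrap resampling")
    if len(x_cols) < 2:
        raise ValueError("need at least 2 explanatory columns")
    X = table[x_cols].to_numpy()
    y = table[OBJECTIVE_COLUMN].to_numpy()
    n, p = X.shape
    if resample_indices is None:
        resample_indices = _resample_indices(n, cfg.n_bootstrap, cfg.rng_seed)
    # lasso_path expects alphas in decreasing order; remember the mapping
    lambdas = np.asarray(sorted(set(cfg.lambda_grid), reverse=True))
    n_lam = len(lambdas)

    counts = np.zeros((n_lam, p), dtype=int)
    n_selected_sum = np.zeros(n_lam, dtype=int)
    best_r2 = np.full(n_lam, -np.inf)
    n_nonconverged = 0
    for idx in resample_indices:
        Xb, yb = X[idx], y[idx]
        xm, ym = Xb.mean(axis=0), yb.mean()
        Xc, yc = Xb - xm, yb - ym
        sst = float(np.sum(yc**2))
        if sst == 0.0:
            continue  # degenerate resample: all objectives equal
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            _, coefs, _ = lasso_path(Xc, yc, alphas=lambdas, max_iter=5000, tol=1e-6)
        n_nonconverged += sum(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
        nonzero = coefs.T != 0  # (n_lam, p)
        counts += nonzero
        n_selected_sum += nonzero.sum(axis=1)
        ss_res = np.sum((yc[:, None] - Xc @ coefs) ** 2, axis=0)
        r2 = 1.0 - ss_res / sst
        best_r2 = np.maximum(best_r2, r2)
    if n_nonconverged:
        # non-converged fits are counted like any other resample; the L1 path
        # at tight tolerance routinely hits the iteration cap at tiny lambda
        logger.info(
            "lasso path hit the iteration cap in %d fit(s) across %d resamples",
            n_nonconverged,
            len(resample_indices),
        )

    mean_vars = n_selected_sum / cfg.n_bootstrap
    n_unique = (counts > 0).sum(axis=1)
    footprint = mean_vars if cfg.footprint_mode == "mean_per_trial" else n_unique
    admissible = footprint <= cfg.max_variables
    if not np.any(counts.sum(axis=1) > 0):
        raise ValueError(
            "every candidate strength produced empty models; extend lambda_grid "
            "toward smaller values"
        )
    if not admissible.any():
        # every strength over-selects; fall back to the sparsest one
        warnings.warn(
            "no strength satisfies the max_variables footprint; choosing the "
            "sparsest candidate",
            RuntimeWarning,
            stacklevel=2,
        )
        admissible = footprint == footprint.min()
    cand = np.where(admissible)[0]
    i_best = cand[int(np.argmax(best_r2[cand]))]

    sel = pd.Series(counts[i_best], index=x_cols, name="n_selected")
    order = np.lexsort((np.arange(p), -sel.to_numpy()))  # count desc, column order
    ranked = [x_cols[i] for i in order]
    per_lambda = pd.DataFrame(
        {
            "lambda": lambdas,
            "best_r2": best_r2,
            "mean_vars_per_trial": mean_vars,
            "n_unique": n_unique,
        }
    )
    return SelectionResult(
        selection_counts=sel,
        chosen_lambda=float(lambdas[i_best]),
        best_r2=float(best_r2[i_best]),
        mean_variables_per_trial=float(mean_vars[i_best]),
        ranked_variables=ranked,
        n_bootstrap=cfg.n_bootstrap,
        per_lambda=per_lambda,
    )


def take_top_k(result: SelectionResult, k: int) -> list[str]:
    """First ``k`` variables of the ranking (count desc, ties by column order)."""
    if k > len(result.ranked_variables):
        raise ValueError(
            f"k={k} exceeds the {len(result.ranked_variables)} ranked variables"
        )
    return result.ranked_variables[:k]


def write_selection_result(result: SelectionResult, path: str | Path) -> None:
    """Serialize the ranking as a delimited table (variable, band, feature, count)."""
    rows = []
    for var in result.ranked_variables:
        band, _, feat = var.rpartition(":")
        rows.append(
            {
                "variable": var,
                "band": band,
                "feature": feat,
                "n_selected": int(result.selection_counts[var]),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
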