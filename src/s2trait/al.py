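"""Euclidean-distance-based diversity (EBD) active learning.

Starting from a small random subset of the simulated pool, each iteration
selects the candidate whose minimum squared Euclidean distance (in
standardized band space) to the already-accepted training set is largest,
refits the GP with it, and keeps it only if the validation RMSE strictly
decreases.  Rejected candidates are removed from the pool permanently, so
the loop never re-selects the same farthest point.

R-squared is tracked alongside RMSE for diagnostics but never used for the
accept/reject decision (RMSE is the more reliable acceptance measure; its
trajectory is strictly decreasing by construction, while R2 may wobble).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .gpr import GaussianProcessTraitRegressor, KernelHyperparams

__all__ = ["ALState", "ebd_distance", "select_next", "EBDActiveLearner", "al_loop"]


@dataclass
class ALState:
    """Bookkeeping for one active-learning run."""

    train_indices: list[int]
    pool_indices: list[int]
    rmse_trajectory: list[float]
    r2_trajectory: list[float]
    last_distances: np.ndarray | None = None
    history: list[dict] = field(default_factory=list)

    def history_frame(self) -> pd.DataFrame:
        """Per-iteration log (iteration, candidate_id, accepted, rmse, r2)."""
        return pd.DataFrame(
            self.history,
            columns=["iteration", "candidate_id", "accepted", "rmse", "r2"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.history_frame().to_csv(Path(path), index=False)


def ebd_distance(candidate, train_X) -> float:
    """Minimum squared Euclidean distance from a candidate spectrum to the
    training set."""
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    if train_X.shape[0] == 0:
        raise ValueError("training set is empty")
    diff = train_X - np.asarray(candidate, dtype=float)[None, :]
    return float(np.min(np.sum(diff * diff, axis=1)))


def select_next(pool_X, train_X) -> int:
    """Index (into the pool) of the candidate with the largest minimum
    squared distance to the training set; ties break to the lowest index."""
    pool_X = np.atleast_2d(np.asarray(pool_X, dtype=float))
    if pool_X.shape[0] == 0:
        raise ValueError("candidate pool is empty")
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    d = _min_sq_dists(pool_X, train_X)
    return int(np.argmax(d))  # argmax returns the first (lowest) max index


def _min_sq_dists(pool_X: np.ndarray, train_X: np.ndarray) -> np.ndarray:
    d = (
        np.sum(pool_X * pool_X, axis=1)[:, None]
        + np.sum(train_X * train_X, axis=1)[None, :]
        - 2.0 * pool_X @ train_X.T
    )
    return np.maximum(d, 0.0).min(axis=1)


def _rmse(obs: np.ndarray, pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def _r2(obs: np.ndarray, pred: np.ndarray) -> float:
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0:
        return float("nan")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sstot


class EBDActiveLearner(BaseEstimator):
    """EBD sample selection with accept-on-RMSE-improvement.

    Parameters
    ----------
    n_init : int
        Random initial training samples drawn from the pool (default 10,
        i.e. 1% of the canonical 1000-sample pool).
    max_iter : int
        Iteration cap (default 1000); the loop also stops on pool exhaustion.
    hyp_refresh : int
        Re-optimize kernel hyperparameters (warm-started single restart)
        every this many accepted additions; between refreshes candidates are
        evaluated at the current hyperparameters (Cholesky-only refits).  A
        refreshed model is kept only if it further lowers validation RMSE.
    gpr_params : dict or None
        Extra constructor arguments for the underlying GP regressor.
    random_state : int or None
        Seeds the initial subset draw and the GP restarts.
    """

    def __init__(
        self,
        n_init: int = 10,
        max_iter: int = 1000,
        hyp_refresh: int = 10,
        gpr_params: dict | None = None,
        random_state: int | None = None,
    ):
        self.n_init = n_init
        self.max_iter = max_iter
        self.hyp_refresh = hyp_refresh
        self.gpr_params = gpr_params
        self.random_state = random_state

    def fit(self, X_pool, y_pool, X_val, y_val):
        X_pool = np.asarray(X_pool, dtype=float)
        y_pool = np.asarray(y_pool, dtype=float)
        X_val = np.asarray(X_val, dtype=float)
        y_val = np.asarray(y_val, dtype=float)
        if X_val.shape[0] == 0:
            raise ValueError("validation set must be non-empty")
        n = X_pool.shape[0]
        if self.n_init > n:
            raise ValueError(
                f"n_init={self.n_init} exceeds pool size {n}"
            )
        rng = np.random.default_rng(self.random_state)
        gpr_params = dict(self.gpr_params or {})
        gpr_params.setdefault("random_state", self.random_state)

        init = sorted(rng.choice(n, size=self.n_init, replace=False).tolist())
        train_idx = list(init)
        pool_idx = [i for i in range(n) if i not in set(init)]

        model = GaussianProcessTraitRegressor(**gpr_params).fit(
            X_pool[train_idx], y_pool[train_idx]
        )
        best_rmse = _rmse(y_val, model.predict(X_val))
        best_r2 = _r2(y_val, model.predict(X_val))
        state = ALState(
            train_indices=train_idx,
            pool_indices=pool_idx,
            rmse_trajectory=[best_rmse],
            r2_trajectory=[best_r2],
        )

        # Distances maintained in the band space standardized by pool stats.
        mu = X_pool.mean(axis=0)
        sd = X_pool.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (X_pool - mu) / sd
        dmin = _min_sq_dists(Z[pool_idx], Z[train_idx]) if pool_idx else None
        accepted_since_refresh = 0

        for it in range(self.max_iter):
            if not pool_idx:
                break
            j = int(np.argmax(dmin))
            cand = pool_idx[j]
            trial_idx = train_idx + [cand]
            try:
                trial = GaussianProcessTraitRegressor(
                    **{**gpr_params, "optimize": False,
                       "init_hyp": model.hyp_}
                ).fit(X_pool[trial_idx], y_pool[trial_idx])
                rmse = _rmse(y_val, trial.predict(X_val))
                r2 = _r2(y_val, trial.predict(X_val))
            except np.linalg.LinAlgError:
                rmse, r2 = float("inf"), float("nan")
            accepted = rmse < best_rmse
            if accepted:
                train_idx.append(cand)
                model, best_rmse, best_r2 = trial, rmse, r2
                accepted_since_refresh += 1
                if accepted_since_refresh >= self.hyp_refresh:
                    refreshed = GaussianProcessTraitRegressor(
                        **{**gpr_params, "n_restarts": 0,
                           "init_hyp": model.hyp_}
                    ).fit(X_pool[train_idx], y_pool[train_idx])
                    r_rmse = _rmse(y_val, refreshed.predict(X_val))
                    if r_rmse < best_rmse:
                        model = refreshed
                        best_rmse = r_rmse
                        best_r2 = _r2(y_val, refreshed.predict(X_val))
                    accepted_since_refresh = 0
                state.rmse_trajectory.append(best_rmse)
                state.r2_trajectory.append(best_r2)
            # Removed from the pool either way.
            pool_idx.pop(j)
            dmin = np.delete(dmin, j)
            if accepted and len(pool_idx):
                d_new = np.sum((Z[pool_idx] - Z[cand]) ** 2, axis=1)
                dmin = np.minimum(dmin, d_new)
            state.history.append({
                "iteration": it,
                "candidate_id": cand,
                "accepted": bool(accepted),
                "rmse": rmse,
                "r2": r2,
            })

        state.train_indices = train_idx
        state.pool_indices = pool_idx
        state.last_distances = dmin
        self.model_ = model
        self.state_ = state
        self.selected_indices_ = list(train_idx)
        self.rmse_ = best_rmse
        return self

    def predict(self, X, return_std: bool = False):
        return self.model_.predict(X, return_std=return_std)


def al_loop(
    ts,
    validation: tuple[np.ndarray, np.ndarray],
    trait: str,
    config: dict | None = None,
    seed: int | None = None,
):
    """Run EBD active learning for one trait over a training set.

    Parameters
    ----------
    ts : TrainingSet
        The simulated pool (spectra + labels).
    validation : (X_val, y_val)
        Labeled spectra used both as the acceptance criterion and for the
        reported score.
    trait : {"lai", "ccc", "vwc"}
    config : dict, optional
        Keyword arguments for :class:`EBDActiveLearner`.

    Returns
    -------
    (model, state)
    """
    X_val, y_val = validation
    learner = EBDActiveLearner(random_state=seed, **(config or {}))
    learner.fit(ts.spectra, ts.labels(trait), X_val, y_val)
    learner.model_.trait_name = trait
    return learner.model_, learner.state_
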