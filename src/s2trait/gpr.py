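"""Bespoke Gaussian process regression with an RBF kernel.

The predictive machinery is written from first principles: an RBF
(squared-exponential) covariance, maximum-likelihood hyperparameter fitting
in log space, and Cholesky-based predictive mean and variance.  The reported
standard deviation is the observation-level one, i.e. the noise variance
``sigma_n^2`` is added to the latent predictive variance, since the trait
maps display observation-level uncertainty.

Inputs (spectral bands) and labels are standardized internally using
training statistics; predictions are returned on the original label scale.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "KernelHyperparams",
    "rbf_kernel",
    "GaussianProcessTraitRegressor",
    "fit_gpr",
]

# Jitter escalation ladder applied to the covariance diagonal when the
# Cholesky factorization fails.
JITTER_LADDER = (0.0, 1e-10, 1e-8, 1e-6, 1e-4)


class KernelHyperparams(NamedTuple):
    """RBF kernel hyperparameters (all strictly positive)."""

    sigma_f2: float                    # signal variance [label units^2]
    length_scale: float | np.ndarray   # scalar or per-band vector
    sigma_n2: float                    # noise variance [label units^2]


def _sq_dists(X1: np.ndarray, X2: np.ndarray, length_scale) -> np.ndarray:
    ls = np.asarray(length_scale, dtype=float)
    A = X1 / ls
    B = X2 / ls
    d = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.maximum(d, 0.0)


def rbf_kernel(X1, X2, hyp: KernelHyperparams) -> np.ndarray:
    """Squared-exponential kernel
    ``K[i, j] = sigma_f2 * exp(-||x_i - x_j||^2 / (2 l^2))``.

    With a per-band ``length_scale`` vector the distance is computed in
    per-dimension scaled space (ARD).
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {X1.shape[1]} vs {X2.shape[1]}"
        )
    return hyp.sigma_f2 * np.exp(-0.5 * _sq_dists(X1, X2, hyp.length_scale))


class GaussianProcessTraitRegressor(RegressorMixin, BaseEstimator):
    """GP regressor for a single trait on standardized 10-band spectra.

    Parameters
    ----------
    n_restarts : int
        Number of random hyperparameter starting points for the marginal-
        likelihood optimization (in addition to the default start).
    ard : bool
        If True, fit one length scale per band; otherwise a single isotropic
        length scale (the default, matching the printed kernel form).
    optimize : bool
        If False, skip optimization and use ``init_hyp`` as-is (requires
        ``init_hyp``); used for fast refits at fixed hyperparameters.
    init_hyp : KernelHyperparams or None
        Starting (or, with ``optimize=False``, final) hyperparameters in
        *standardized-label* space.
    max_opt_iter : int
        Iteration cap per optimizer run.
    trait_name : str or None
        Identifier carried through to archives and maps.
    random_state : int or None
        Seeds the restart draws.
    """

    def __init__(
        self,
        n_restarts: int = 5,
        ard: bool = False,
        optimize: bool = True,
        init_hyp: KernelHyperparams | None = None,
        max_opt_iter: int = 100,
        trait_name: str | None = None,
        random_state: int | None = None,
    ):
        self.n_restarts = n_restarts
        self.ard = ard
        self.optimize = optimize
        self.init_hyp = init_hyp
        self.max_opt_iter = max_opt_iter
        self.trait_name = trait_name
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training samples")
        self.n_features_in_ = X.shape[1]
        self.x_mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.x_scale_ = np.where(scale > 0, scale, 1.0)
        self.y_mean_ = float(np.mean(y))
        y_sd = float(np.std(y))
        self.y_scale_ = y_sd if y_sd > 0 else 1.0
        Xs = (X - self.x_mean_) / self.x_scale_
        ys = (y - self.y_mean_) / self.y_scale_
        self.Xs_ = Xs
        self.ys_ = ys
        self.y_train_ = np.asarray(y, dtype=float)

        d = X.shape[1]
        n_ls = d if self.ard else 1
        if self.init_hyp is not None:
            ls = np.atleast_1d(np.asarray(self.init_hyp.length_scale, float))
            if self.ard and ls.size == 1:
                ls = np.full(d, ls[0])
            theta0 = np.concatenate((
                [np.log(self.init_hyp.sigma_f2)],
                np.log(ls),
                [np.log(self.init_hyp.sigma_n2)],
            ))
        else:
            theta0 = np.concatenate((
                [0.0], np.zeros(n_ls), [np.log(0.1)]
            ))

        if not self.optimize:
            if self.init_hyp is None:
                raise ValueError("optimize=False requires init_hyp")
            theta_best = theta0
        else:
            rng = np.random.default_rng(self.random_state)
            starts = [theta0]
            for _ in range(self.n_restarts):
                starts.append(np.concatenate((
                    rng.uniform(np.log(0.1), np.log(10.0), 1),
                    rng.uniform(np.log(0.1), np.log(10.0), n_ls),
                    rng.uniform(np.log(1e-4), np.log(1.0), 1),
                )))
            best_val = np.inf
            theta_best = theta0
            bounds = [(np.log(1e-6), np.log(1e6))] * (n_ls + 2)
            for s in starts:
                res = minimize(
                    self._neg_lml_and_grad, s, jac=True, method="L-BFGS-B",
                    bounds=bounds, options={"maxiter": self.max_opt_iter},
                )
                if np.isfinite(res.fun) and res.fun < best_val:
                    best_val = res.fun
                    theta_best = res.x

        self._finalize(theta_best)
        return self

    def _unpack(self, theta: np.ndarray) -> KernelHyperparams:
        sf2 = float(np.exp(theta[0]))
        ls = np.exp(theta[1:-1])
        sn2 = float(np.exp(theta[-1]))
        return KernelHyperparams(sf2, ls if ls.size > 1 else float(ls[0]), sn2)

    def _factorize(self, hyp: KernelHyperparams):
        n = self.Xs_.shape[0]
        K = rbf_kernel(self.Xs_, self.Xs_, hyp)
        last_err = None
        for jitter in JITTER_LADDER:
            try:
                L = cholesky(K + (hyp.sigma_n2 + jitter) * np.eye(n),
                             lower=True)
                return K, L, jitter
            except np.linalg.LinAlgError as err:
                last_err = err
        raise np.linalg.LinAlgError(
            f"covariance not positive definite after jitter escalation up to "
            f"{JITTER_LADDER[-1]} (n={n}, hyp={hyp}): {last_err}"
        )

    def _neg_lml_and_grad(self, theta: np.ndarray):
        hyp = self._unpack(theta)
        n = self.Xs_.shape[0]
        try:
            K, L, _ = self._factorize(hyp)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(theta)
        alpha = cho_solve((L, True), self.ys_)
        lml = (
            -0.5 * float(self.ys_ @ alpha)
            - float(np.sum(np.log(np.diag(L))))
            - 0.5 * n * np.log(2.0 * np.pi)
        )
        # dLML/dtheta_i = 0.5 tr((alpha alpha^T - K_n^{-1}) dK/dtheta_i)
        Kinv = cho_solve((L, True), np.eye(n))
        W = np.outer(alpha, alpha) - Kinv
        grads = np.empty_like(theta)
        grads[0] = 0.5 * np.sum(W * K)          # d/dlog sigma_f2
        ls = np.atleast_1d(np.asarray(hyp.length_scale, float))
        if ls.size == 1:
            D = _sq_dists(self.Xs_, self.Xs_, ls[0])
            grads[1] = 0.5 * np.sum(W * (K * D))
        else:
            for k in range(ls.size):
                dk = (self.Xs_[:, k][:, None] - self.Xs_[:, k][None, :]) ** 2
                grads[1 + k] = 0.5 * np.sum(W * (K * dk / ls[k] ** 2))
        grads[-1] = 0.5 * hyp.sigma_n2 * np.trace(W)  # d/dlog sigma_n2
        return -lml, -grads

    def _finalize(self, theta: np.ndarray) -> None:
        hyp = self._unpack(theta)
        K, L, jitter = self._factorize(hyp)
        self.hyp_ = hyp
        self.jitter_ = jitter
        self.L_ = L
        self.alpha_ = cho_solve((L, True), self.ys_)
        n = self.Xs_.shape[0]
        self.lml_ = float(
            -0.5 * self.ys_ @ self.alpha_
            - np.sum(np.log(np.diag(L)))
            - 0.5 * n * np.log(2.0 * np.pi)
        )

    # -- prediction --------------------------------------------------------

    def predict(self, X, return_std: bool = False):
        check_is_fitted(self, "alpha_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"band count mismatch: model has {self.n_features_in_}, "
                f"input has {X.shape[1]}"
            )
        Xs = (X - self.x_mean_) / self.x_scale_
        Ks = rbf_kernel(self.Xs_, Xs, self.hyp_)         # (n_train, n_test)
        mu_s = Ks.T @ self.alpha_
        mean = self.y_mean_ + self.y_scale_ * mu_s
        if not return_std:
            return mean
        V = solve_triangular(self.L_, Ks, lower=True)
        var_s = self.hyp_.sigma_f2 - np.sum(V * V, axis=0) + self.hyp_.sigma_n2
        var_s = np.maximum(var_s, 0.0)
        sd = self.y_scale_ * np.sqrt(var_s)
        return mean, sd

    def log_marginal_likelihood(self) -> float:
        check_is_fitted(self, "lml_")
        return self.lml_

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Archive the fitted model as a single portable JSON container."""
        check_is_fitted(self, "alpha_")
        ls = self.hyp_.length_scale
        payload = {
            "format": "s2trait-gpr-v1",
            "trait_name": self.trait_name,
            "params": {
                "n_restarts": self.n_restarts,
                "ard": self.ard,
                "max_opt_iter": self.max_opt_iter,
                "random_state": self.random_state,
            },
            "hyp": {
                "sigma_f2": self.hyp_.sigma_f2,
                "length_scale": (np.asarray(ls).tolist()
                                 if isinstance(ls, np.ndarray) else ls),
                "sigma_n2": self.hyp_.sigma_n2,
            },
            "jitter": self.jitter_,
            "standardizer": {
                "x_mean": self.x_mean_.tolist(),
                "x_scale": self.x_scale_.tolist(),
                "y_mean": self.y_mean_,
                "y_scale": self.y_scale_,
            },
            "Xs": self.Xs_.tolist(),
            "ys": self.ys_.tolist(),
            "y_train": self.y_train_.tolist(),
            "lml": self.lml_,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "GaussianProcessTraitRegressor":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "s2trait-gpr-v1":
            raise ValueError(f"unrecognized model archive: {path}")
        obj = cls(trait_name=payload["trait_name"], **payload["params"])
        obj.Xs_ = np.asarray(payload["Xs"], dtype=float)
        obj.ys_ = np.asarray(payload["ys"], dtype=float)
        obj.y_train_ = np.asarray(payload["y_train"], dtype=float)
        std = payload["standardizer"]
        obj.x_mean_ = np.asarray(std["x_mean"], dtype=float)
        obj.x_scale_ = np.asarray(std["x_scale"], dtype=float)
        obj.y_mean_ = float(std["y_mean"])
        obj.y_scale_ = float(std["y_scale"])
        obj.n_features_in_ = obj.Xs_.shape[1]
        h = payload["hyp"]
        ls = h["length_scale"]
        hyp = KernelHyperparams(
            float(h["sigma_f2"]),
            np.asarray(ls, dtype=float) if isinstance(ls, list) else float(ls),
            float(h["sigma_n2"]),
        )
        n = obj.Xs_.shape[0]
        K = rbf_kernel(obj.Xs_, obj.Xs_, hyp)
        L = cholesky(K + (hyp.sigma_n2 + payload["jitter"]) * np.eye(n),
                     lower=True)
        obj.hyp_ = hyp
        obj.jitter_ = payload["jitter"]
        obj.L_ = L
        obj.alpha_ = cho_solve((L, True), obj.ys_)
        obj.lml_ = float(payload["lml"])
        return obj


def fit_gpr(X, y, **kwargs) -> GaussianProcessTraitRegressor:
    """Thin functional wrapper over :class:`GaussianProcessTraitRegressor`."""
    return GaussianProcessTraitRegressor(**kwargs).fit(X, y)
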