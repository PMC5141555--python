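"""Model equations for finite Poisson mixture regression (FMPR).

A K-component FMPR models a count response y_i as a weighted sum of
Poisson regressions, each with its own log-linear coefficients:

    f(y_i | x_i, w_i) = sum_k pi_k(w_i) * Poisson(y_i; lambda_ik),
    log lambda_ik = beta_0k + x_i' beta_k.

The mixing weights are either a fixed probability vector (``fixed``
mode) or a multinomial-logit function of concomitant covariates w_i
(``concomitant`` mode).  A zero-inflated variant adds a structural
component degenerate at zero that competes through the same gate.

This module holds the densities, gates, likelihood and moments only;
fitting lives in :mod:`poismix.em_fit` and :mod:`poismix.zip_mixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "LINPRED_CLIP",
    "CountDataset",
    "ComponentParams",
    "WeightModel",
    "MixtureModel",
    "Responsibilities",
    "poisson_log_pmf",
    "component_rates",
    "concomitant_weights",
    "mixture_log_likelihood",
    "mixture_moments",
    "rate_ratios",
]

#: Linear predictors are clipped to +/- this value before exponentiation.
#: exp(30) ~ 1e13 keeps every rate finite in double precision while leaving
#: any realistic count model untouched.
LINPRED_CLIP = 30.0


def _check_design(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise ValueError(f"{name} contains non-finite entries")
    if not np.allclose(M[:, 0], 1.0):
        raise ValueError(f"first column of {name} must be an intercept column of ones")
    return M


@dataclass
class CountDataset:
    """Count response with two covariate design blocks.

    ``X`` feeds the component log-rates, ``W`` feeds the gate; both carry a
    leading intercept column and may share columns (the two covariate sets
    may partially or completely overlap).
    """

    y: np.ndarray
    X: np.ndarray
    W: np.ndarray
    row_ids: Optional[Sequence] = None
    x_names: Optional[Sequence[str]] = None
    w_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if y.ndim != 1 or y.size == 0:
            raise ValueError("y must be a nonempty 1-d vector")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite entries")
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("y must contain nonnegative integers")
        self.y = y.astype(np.int64)
        self.X = _check_design(self.X, "X")
        self.W = _check_design(self.W, "W")
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.W.shape[0] != n:
            raise ValueError("X and W must have the same number of rows as y")
        if self.row_ids is None:
            self.row_ids = np.arange(n)
        if self.x_names is None:
            self.x_names = ["(intercept)"] + [f"x{j}" for j in range(1, self.X.shape[1])]
        if self.w_names is None:
            self.w_names = ["(intercept)"] + [f"w{j}" for j in range(1, self.W.shape[1])]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        """Number of component covariates (excluding the intercept)."""
        return self.X.shape[1] - 1

    @property
    def q(self) -> int:
        """Number of gate covariates (excluding the intercept)."""
        return self.W.shape[1] - 1

    def intercept_only(self) -> "CountDataset":
        """Strip covariates from both blocks (plain-mixture / null designs)."""
        ones = np.ones((self.n, 1))
        return CountDataset(self.y, ones, ones, row_ids=self.row_ids)

    def subset(self, idx: np.ndarray) -> "CountDataset":
        return CountDataset(
            self.y[idx],
            self.X[idx],
            self.W[idx],
            row_ids=np.asarray(self.row_ids)[idx],
            x_names=self.x_names,
            w_names=self.w_names,
        )


@dataclass
class ComponentParams:
    """Per-component log-rate coefficients: beta0 (K,) and beta (K, p)."""

    beta0: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta0 = np.atleast_1d(np.asarray(self.beta0, dtype=float))
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim == 1:
            self.beta = self.beta.reshape(self.beta0.shape[0], -1)
        if self.beta.shape[0] != self.beta0.shape[0]:
            raise ValueError("beta0 and beta disagree on the number of components")
        if not (np.all(np.isfinite(self.beta0)) and np.all(np.isfinite(self.beta))):
            raise ValueError("component coefficients must be finite")

    @property
    def K(self) -> int:
        return self.beta0.shape[0]

    @property
    def coef_matrix(self) -> np.ndarray:
        """(K, 1+p) matrix with the intercept in the first column."""
        return np.column_stack([self.beta0, self.beta])

    def permute(self, order: np.ndarray) -> "ComponentParams":
        return ComponentParams(self.beta0[order], self.beta[order])


@dataclass
class WeightModel:
    """Mixing-weight model: a fixed simplex vector or a multinomial-logit gate.

    In concomitant mode the first category is the reference: its gate row is
    identically zero for identification.  A zero-inflated mixture uses a gate
    over K+1 categories with the structural-zero category first (and hence as
    the reference).
    """

    mode: str
    pi: Optional[np.ndarray] = None
    gamma0: Optional[np.ndarray] = None
    gamma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "concomitant"):
            raise ValueError(f"unknown weight mode {self.mode!r}")
        if self.mode == "fixed":
            if self.pi is None:
                raise ValueError("fixed mode requires pi")
            pi = np.asarray(self.pi, dtype=float)
            if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-10:
                raise ValueError("pi must be nonnegative and sum to 1")
            self.pi = pi
        else:
            if self.gamma0 is None or self.gamma is None:
                raise ValueError("concomitant mode requires gamma0 and gamma")
            self.gamma0 = np.atleast_1d(np.asarray(self.gamma0, dtype=float))
            self.gamma = np.asarray(self.gamma, dtype=float)
            if self.gamma.ndim == 1:
                self.gamma = self.gamma.reshape(self.gamma0.shape[0], -1)
            if self.gamma.shape[0] != self.gamma0.shape[0]:
                raise ValueError("gamma0 and gamma disagree on category count")
            if abs(self.gamma0[0]) > 0 or np.any(self.gamma[0] != 0):
                raise ValueError("reference (first) gate row must be exactly zero")

    @property
    def n_categories(self) -> int:
        return self.pi.shape[0] if self.mode == "fixed" else self.gamma0.shape[0]

    @property
    def gate_matrix(self) -> np.ndarray:
        """(K_cat, 1+q) gate coefficients, reference row first (all zero)."""
        if self.mode != "concomitant":
            raise ValueError("gate_matrix is only defined in concomitant mode")
        return np.column_stack([self.gamma0, self.gamma])

    def permute(self, order: np.ndarray) -> "WeightModel":
        """Reorder categories, re-anchoring the reference to the new first row."""
        if self.mode == "fixed":
            return WeightModel("fixed", pi=self.pi[order])
        G = self.gate_matrix[order]
        G = G - G[0]  # new first category becomes the zero reference row
        return WeightModel("concomitant", gamma0=G[:, 0], gamma=G[:, 1:])


@dataclass
class MixtureModel:
    """A (possibly zero-inflated) finite Poisson mixture regression model.

    ``K`` counts the Poisson components.  When ``zero_inflated`` the weight
    model spans K+1 categories, the first being the structural-zero point
    mass, which has no rate parameters.
    """

    K: int
    components: ComponentParams
    weights: WeightModel
    zero_inflated: bool = False
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.components.K != self.K:
            raise ValueError("component parameter block does not match K")
        expected = self.K + (1 if self.zero_inflated else 0)
        if self.weights.n_categories != expected:
            raise ValueError(
                f"weight model has {self.weights.n_categories} categories, expected {expected}"
            )

    @property
    def n_categories(self) -> int:
        return self.K + (1 if self.zero_inflated else 0)

    @property
    def loglik(self) -> float:
        return self.fit_meta.get("loglik", np.nan)

    @property
    def n_params(self) -> int:
        from .model_selection import count_parameters

        return count_parameters(self)


@dataclass
class Responsibilities:
    """Posterior membership probabilities tau (n rows, one column per category).

    For zero-inflated models the first column is the structural-zero
    component; rows with y_i > 0 carry exactly zero mass there.
    """

    tau: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        if tau.ndim != 2:
            raise ValueError("tau must be an n x K matrix")
        if np.any(tau < -1e-12) or np.any(tau > 1 + 1e-12):
            raise ValueError("tau entries must lie in [0, 1]")
        if not np.allclose(tau.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("tau rows must sum to 1")
        self.tau = np.clip(tau, 0.0, 1.0)

    @property
    def n(self) -> int:
        return self.tau.shape[0]

    @property
    def n_categories(self) -> int:
        return self.tau.shape[1]

    def hard_labels(self) -> np.ndarray:
        """Argmax labels; ties break to the lowest column index."""
        return np.argmax(self.tau, axis=1)


# ---------------------------------------------------------------------------
# Densities, gates, likelihood
# ---------------------------------------------------------------------------


def poisson_log_pmf(y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Elementwise log Poisson pmf: y*log(lam) - lam - log(y!).

    Counts outside the support (negative or non-integer) raise rather than
    silently returning the -inf floor; the indicator on the nonnegative
    integers is enforced at the type boundary.
    """
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must contain nonnegative integers")
    if np.any(lam <= 0):
        raise ValueError("lam must be strictly positive")
    yf = y.astype(float)
    return yf * np.log(lam) - lam - gammaln(yf + 1.0)


def component_rates(X: np.ndarray, params: ComponentParams, clip: float = LINPRED_CLIP) -> np.ndarray:
    """Per-row, per-component Poisson rates lambda_ik = exp(beta_0k + x_i' beta_k).

    The linear predictor is clipped at +/- ``clip`` before exponentiation to
    guard against overflow during early EM iterations.
    """
    X = np.asarray(X, dtype=float)
    coef = params.coef_matrix
    if X.shape[1] != coef.shape[1]:
        raise ValueError(
            f"X has {X.shape[1]} columns but parameters expect {coef.shape[1]}"
        )
    eta = X @ coef.T
    return np.exp(np.clip(eta, -clip, clip))


def concomitant_weights(W: np.ndarray, weights: WeightModel) -> np.ndarray:
    """Per-row prior category probabilities (n x K_cat), rows summing to 1.

    Concomitant mode evaluates the multinomial-logit gate with max-subtraction
    for stability; fixed mode broadcasts the constant pi vector.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if weights.mode == "fixed":
        return np.tile(weights.pi, (n, 1))
    G = weights.gate_matrix
    if W.shape[1] != G.shape[1]:
        raise ValueError(f"W has {W.shape[1]} columns but gate expects {G.shape[1]}")
    eta = W @ G.T
    eta -= eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=1, keepdims=True)


def _category_log_densities(data: CountDataset, model: MixtureModel) -> np.ndarray:
    """(n, K_cat) log densities per mixture category.

    The structural-zero category (ZIP models, column 0) has log density 0 at
    y=0 and -inf elsewhere; downstream log-sum-exp tolerates the -inf.
    """
    logf = poisson_log_pmf(data.y[:, None], component_rates(data.X, model.components))
    if not model.zero_inflated:
        return logf
    structural = np.where(data.y == 0, 0.0, -np.inf)
    return np.column_stack([structural, logf])


def mixture_log_likelihood(data: CountDataset, model: MixtureModel) -> float:
    """Observed-data log-likelihood sum_i log sum_k pi_ik f(y_i | lambda_ik)."""
    if data.n == 0:
        raise ValueError("empty dataset")
    pi = concomitant_weights(data.W, model.weights)
    logf = _category_log_densities(data, model)
    with np.errstate(divide="ignore"):
        log_terms = np.log(pi) + logf
    return float(logsumexp(log_terms, axis=1).sum())


def mixture_moments(model: MixtureModel, X: np.ndarray, W: np.ndarray) -> pd.DataFrame:
    """Per-row mixture mean, between-component variance excess v, and variance.

    mean_i = sum_k pi_ik lambda_ik;  v_i = sum_k pi_ik lambda_ik^2 - mean_i^2;
    var_i = mean_i + v_i.  v_i >= 0 with equality iff all component rates for
    row i coincide — the mixture is equi-dispersed only when it degenerates.
    Structural-zero categories enter as a point mass at rate 0.
    """
    pi = concomitant_weights(W, model.weights)
    lam = component_rates(X, model.components)
    if model.zero_inflated:
        lam = np.column_stack([np.zeros(lam.shape[0]), lam])
    mean = (pi * lam).sum(axis=1)
    second = (pi * lam**2).sum(axis=1)
    v = np.maximum(second - mean**2, 0.0)
    return pd.DataFrame({"mean": mean, "v": v, "variance": mean + v})


def rate_ratios(model: MixtureModel, include_gate: bool = False) -> pd.DataFrame:
    """Exponentiated coefficients: multiplicative rate change per unit covariate.

    One column per Poisson component; rows labelled by covariate name.  With
    ``include_gate`` the gate coefficients (odds-ratio scale) are appended for
    concomitant models.
    """
    names = model.fit_meta.get("x_names")
    if names is None:
        names = ["(intercept)"] + [f"x{j}" for j in range(1, model.components.coef_matrix.shape[1])]
    cols = {f"comp_{k + 1}": np.exp(model.components.coef_matrix[k]) for k in range(model.K)}
    out = pd.DataFrame(cols, index=list(names))
    if include_gate and model.weights.mode == "concomitant":
        w_names = model.fit_meta.get("w_names")
        G = model.weights.gate_matrix
        if w_names is None:
            w_names = ["(intercept)"] + [f"w{j}" for j in range(1, G.shape[1])]
        gate_cols = {f"gate_{k}": np.exp(G[k]) for k in range(G.shape[0])}
        gate = pd.DataFrame(gate_cols, index=list(w_names))
        out = pd.concat([out, gate], axis=1)
    return out
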