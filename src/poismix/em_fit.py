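"""EM estimation for finite Poisson mixture regression models.

The E-step computes posterior responsibilities by Bayes' rule in log space;
the M-step fits one responsibility-weighted Poisson GLM per component by
iteratively reweighted least squares (IRLS) and re-estimates the mixing
weights (closed form for fixed weights, Newton iterations on the multinomial
logit for the concomitant gate).  Multiple seeded restarts guard against the
multimodality of mixture likelihoods; within a restart the observed-data
log-likelihood is monotone nondecreasing.

Components are relabelled after fitting so that component 1 has the highest
mean fitted rate, which makes printed comparisons stable across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model_core import (
    LINPRED_CLIP,
    ComponentParams,
    CountDataset,
    MixtureModel,
    Responsibilities,
    WeightModel,
    component_rates,
    concomitant_weights,
    poisson_log_pmf,
)

__all__ = [
    "FitConfig",
    "DegenerateComponentError",
    "FitFailureError",
    "init_responsibilities",
    "e_step",
    "m_step_components",
    "m_step_weights",
    "fit_em",
    "posterior_classify",
    "bootstrap_confidence_intervals",
]


class DegenerateComponentError(RuntimeError):
    """A component's total responsibility collapsed below the floor."""


class FitFailureError(RuntimeError):
    """All EM restarts failed; carries per-restart diagnostics."""

    def __init__(self, message: str, diagnostics: list):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class FitConfig:
    """Knobs for the EM fit.

    tol is applied to the relative log-likelihood change
    |dll| / (|ll| + 1); ridge is a small M-step regulariser that keeps the
    IRLS and gate-Newton linear systems well conditioned; fits in which a
    component's responsibility share drops below min_component_weight are
    treated as degenerate and abandoned.
    """

    max_iter: int = 500
    tol: float = 1e-8
    n_restarts: int = 10
    seed: int = 0
    init_method: str = "random_responsibilities"
    ridge: float = 1e-8
    min_component_weight: float = 1e-4

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("tol > 0, max_iter >= 1, n_restarts >= 1 required")
        if self.init_method not in ("random_responsibilities", "quantile_split"):
            raise ValueError(f"unknown init_method {self.init_method!r}")


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def init_responsibilities(
    n: int,
    K: int,
    config: FitConfig,
    y: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    zero_inflated: bool = False,
) -> Responsibilities:
    """Seeded initial responsibilities over K components (K+1 when zero-inflated).

    ``random_responsibilities`` draws rows from a flat Dirichlet;
    ``quantile_split`` hard-assigns rows by K-quantiles of y and softens the
    winning entry to 0.9 with the rest uniform.  For zero-inflated models the
    structural column (first) is zeroed for y > 0 and rows renormalised.
    """
    if n < K:
        raise ValueError(f"cannot fit {K} components to {n} observations")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_cat = K + (1 if zero_inflated else 0)
    if n_cat == 1:
        return Responsibilities(np.ones((n, 1)))
    if config.init_method == "random_responsibilities":
        tau = rng.dirichlet(np.ones(n_cat), size=n)
    else:
        if y is None:
            raise ValueError("quantile_split requires y")
        y = np.asarray(y)
        # rank-based K-way split of y; ties share the quantile of their rank
        ranks = np.argsort(np.argsort(y, kind="stable"), kind="stable")
        groups = np.minimum((ranks * K) // n, K - 1)
        tau = np.full((n, n_cat), 0.1 / (n_cat - 1))
        tau[np.arange(n), groups + (1 if zero_inflated else 0)] = 0.9
    if zero_inflated:
        tau[np.asarray(y) > 0, 0] = 0.0
        tau /= tau.sum(axis=1, keepdims=True)
    return Responsibilities(tau)


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------


def e_step(data: CountDataset, model: MixtureModel) -> tuple[Responsibilities, float]:
    """Posterior responsibilities and observed-data log-likelihood.

    tau_ik = pi_ik f(y_i|lam_ik) / sum_h pi_ih f(y_i|lam_ih), evaluated in
    log space so the two share one likelihood evaluation.  For zero-inflated
    models the structural category (column 0) contributes only at y_i = 0.
    """
    from .model_core import _category_log_densities

    pi = concomitant_weights(data.W, model.weights)
    logf = _category_log_densities(data, model)
    with np.errstate(divide="ignore"):
        log_terms = np.log(pi) + logf
    row_ll = logsumexp(log_terms, axis=1)
    bad = ~np.isfinite(row_ll)
    if np.any(bad):
        raise FloatingPointError(
            f"all component densities vanished for row(s) {np.flatnonzero(bad)[:5].tolist()}"
        )
    tau = np.exp(log_terms - row_ll[:, None])
    return Responsibilities(tau), float(row_ll.sum())


# ---------------------------------------------------------------------------
# M-step: component coefficients (weighted Poisson IRLS)
# ---------------------------------------------------------------------------


def _weighted_poisson_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    eta = np.clip(X @ beta, -LINPRED_CLIP, LINPRED_CLIP)
    return float(np.sum(w * (y * eta - np.exp(eta))))


def _irls_poisson(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    beta0: Optional[np.ndarray],
    ridge: float,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> np.ndarray:
    """Weighted Poisson GLM by ridge-stabilised IRLS with step halving."""
    n, d = X.shape
    if beta0 is None:
        mu0 = max((w * y).sum() / max(w.sum(), 1e-12), 1e-3)
        beta = np.zeros(d)
        beta[0] = np.log(mu0)
    else:
        beta = beta0.copy()
    ll = _weighted_poisson_loglik(beta, X, y, w)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -LINPRED_CLIP, LINPRED_CLIP)
        mu = np.exp(eta)
        s = w * mu
        z = eta + (y - mu) / np.maximum(mu, 1e-12)
        XtS = X.T * s
        H = XtS @ X + ridge * np.eye(d)
        try:
            new = np.linalg.solve(H, XtS @ z)
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError("singular IRLS system") from exc
        if not np.all(np.isfinite(new)):
            raise FloatingPointError("non-finite IRLS step")
        # step halving keeps the weighted log-likelihood nondecreasing
        step = new - beta
        new_ll = _weighted_poisson_loglik(new, X, y, w)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            step *= 0.5
            new = beta + step
            new_ll = _weighted_poisson_loglik(new, X, y, w)
            halvings += 1
        if np.max(np.abs(new - beta)) < tol:
            beta, ll = new, new_ll
            break
        beta, ll = new, new_ll
    return beta


def m_step_components(
    data: CountDataset,
    tau: Responsibilities,
    config: FitConfig,
    init: Optional[ComponentParams] = None,
    zero_inflated: bool = False,
) -> ComponentParams:
    """Responsibility-weighted Poisson GLM per component (log link, IRLS).

    For zero-inflated responsibilities the structural column is skipped; only
    the Poisson categories carry rate parameters.
    """
    T = tau.tau[:, 1:] if zero_inflated else tau.tau
    K = T.shape[1]
    col_mass = T.sum(axis=0)
    floor = config.min_component_weight * data.n
    if np.any(col_mass < floor):
        k = int(np.argmin(col_mass))
        raise DegenerateComponentError(
            f"component {k + 1} responsibility mass {col_mass[k]:.3g} below floor {floor:.3g}"
        )
    coefs = np.empty((K, data.X.shape[1]))
    for k in range(K):
        b0 = init.coef_matrix[k] if init is not None else None
        coefs[k] = _irls_poisson(data.X, data.y.astype(float), T[:, k], b0, config.ridge)
    return ComponentParams(coefs[:, 0], coefs[:, 1:])


# ---------------------------------------------------------------------------
# M-step: mixing weights
# ---------------------------------------------------------------------------

#: Newton steps for the gate whose norm exceeds this are clipped — a
#: separation guard against unbounded multinomial-logit coefficients.
_GATE_STEP_CLIP = 10.0


def _gate_objective(G_free: np.ndarray, W: np.ndarray, T: np.ndarray, ridge: float) -> float:
    eta = np.column_stack([np.zeros(W.shape[0]), W @ G_free.T])
    lse = logsumexp(eta, axis=1)
    return float((T * (eta - lse[:, None])).sum() - 0.5 * ridge * (G_free**2).sum())


def _fit_gate_newton(
    W: np.ndarray,
    T: np.ndarray,
    ridge: float,
    init: Optional[np.ndarray] = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, bool]:
    """Maximise the tau-weighted multinomial-logit log-likelihood.

    Category 0 is the zero reference row; ``G_free`` holds the remaining
    (K_cat-1, 1+q) rows.  Returns the full gate matrix and a flag set when
    the separation guard clipped a step.
    """
    n, d = W.shape
    n_cat = T.shape[1]
    m = n_cat - 1
    G = np.zeros((m, d)) if init is None else init.copy()
    clipped = False
    obj = _gate_objective(G, W, T, ridge)
    for _ in range(max_iter):
        eta = np.column_stack([np.zeros(n), W @ G.T])
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)
        grad = ((T - P)[:, 1:].T @ W) - ridge * G  # (m, d)
        # Full Hessian over the m*d free parameters
        H = np.empty((m * d, m * d))
        for a in range(m):
            for b in range(m):
                pa, pb = P[:, a + 1], P[:, b + 1]
                wab = pa * ((a == b) - pb)
                H[a * d : (a + 1) * d, b * d : (b + 1) * d] = (W.T * wab) @ W
        H += ridge * np.eye(m * d)
        H += 1e-10 * np.eye(m * d)
        try:
            step = np.linalg.solve(H, grad.ravel()).reshape(m, d)
        except np.linalg.LinAlgError:
            break
        norm = np.linalg.norm(step)
        if norm > _GATE_STEP_CLIP:
            step *= _GATE_STEP_CLIP / norm
            clipped = True
        new = G + step
        new_obj = _gate_objective(new, W, T, ridge)
        halvings = 0
        while new_obj < obj - 1e-12 and halvings < 20:
            step *= 0.5
            new = G + step
            new_obj = _gate_objective(new, W, T, ridge)
            halvings += 1
        if abs(new_obj - obj) < tol * (abs(obj) + 1):
            G, obj = new, new_obj
            break
        G, obj = new, new_obj
    full = np.vstack([np.zeros((1, d)), G])
    return full, clipped


def m_step_weights(
    W: np.ndarray,
    tau: Responsibilities,
    mode: str,
    config: FitConfig,
    init: Optional[WeightModel] = None,
) -> WeightModel:
    """Re-estimate the mixing-weight model from responsibilities.

    Fixed mode has the closed form pi_k = mean_i tau_ik.  Concomitant mode
    runs Newton iterations on the multinomial logit with the first category
    as reference, warm-started from the previous gate when provided.
    """
    T = tau.tau
    if mode == "fixed":
        pi = T.mean(axis=0)
        return WeightModel("fixed", pi=pi / pi.sum())
    G_init = None
    if init is not None and init.mode == "concomitant" and init.gate_matrix.shape == (
        T.shape[1],
        W.shape[1],
    ):
        G_init = init.gate_matrix[1:]
    G, clipped = _fit_gate_newton(np.asarray(W, dtype=float), T, config.ridge, init=G_init)
    wm = WeightModel("concomitant", gamma0=G[:, 0], gamma=G[:, 1:])
    if clipped:
        wm_meta_flag = True  # recorded on the model by the fit driver
        wm._separation_clipped = wm_meta_flag  # type: ignore[attr-defined]
    return wm


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------


def _mean_rate_order(model: MixtureModel, X: np.ndarray) -> np.ndarray:
    lam = component_rates(X, model.components)
    return np.argsort(-lam.mean(axis=0), kind="stable")


def relabel_by_rate(model: MixtureModel, X: np.ndarray) -> MixtureModel:
    """Order Poisson components by mean fitted rate, highest first.

    Resolves label switching so that "component 1" is always the high-rate
    group; for zero-inflated models the structural category stays first.
    """
    order = _mean_rate_order(model, X)
    comp = model.components.permute(order)
    if model.zero_inflated:
        cat_order = np.concatenate([[0], order + 1])
    else:
        cat_order = order
    weights = model.weights.permute(cat_order)
    return MixtureModel(model.K, comp, weights, model.zero_inflated, dict(model.fit_meta))


def _run_em_once(
    data: CountDataset,
    K: int,
    mode: str,
    config: FitConfig,
    rng: np.random.Generator,
    zero_inflated: bool,
    start: Optional[MixtureModel] = None,
    max_iter: Optional[int] = None,
) -> tuple[MixtureModel, Responsibilities, list[float]]:
    """One EM run: returns (model, responsibilities, loglik trace)."""
    max_iter = max_iter or config.max_iter
    comp: Optional[ComponentParams] = None
    weights: Optional[WeightModel] = None
    if start is not None:
        model = start
        tau, _ = e_step(data, model)
        comp, weights = model.components, model.weights
    else:
        tau = init_responsibilities(data.n, K, config, y=data.y, rng=rng, zero_inflated=zero_inflated)
    trace: list[float] = []
    separation_flag = False
    for it in range(max_iter):
        comp = m_step_components(data, tau, config, init=comp, zero_inflated=zero_inflated)
        weights = m_step_weights(data.W, tau, mode, config, init=weights)
        separation_flag = separation_flag or getattr(weights, "_separation_clipped", False)
        model = MixtureModel(K, comp, weights, zero_inflated)
        tau, ll = e_step(data, model)
        trace.append(ll)
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / (abs(trace[-1]) + 1.0)
            if rel < config.tol:
                break
    model.fit_meta.update(
        {
            "loglik": trace[-1],
            "n_obs": data.n,
            "n_iter": len(trace),
            "converged": len(trace) < max_iter,
            "loglik_trace": trace,
            "separation_clipped": separation_flag,
        }
    )
    return model, tau, trace


def fit_em(
    data: CountDataset,
    K: int,
    mode: str = "concomitant",
    config: Optional[FitConfig] = None,
    zero_inflated: bool = False,
) -> MixtureModel:
    """Fit a K-component Poisson mixture regression by best-of-restarts EM.

    Runs ``config.n_restarts`` independently seeded EM runs and keeps the one
    with the highest final log-likelihood; components are then relabelled in
    decreasing order of mean fitted rate.  Raises FitFailureError when every
    restart degenerates.
    """
    config = config or FitConfig()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_restarts)
    best: Optional[tuple[MixtureModel, Responsibilities]] = None
    diagnostics: list[str] = []
    used = 0
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            model, tau, trace = _run_em_once(data, K, mode, config, rng, zero_inflated)
            used += 1
        except (DegenerateComponentError, FloatingPointError) as exc:
            diagnostics.append(f"restart {r}: {exc}")
            continue
        if best is None or model.fit_meta["loglik"] > best[0].fit_meta["loglik"]:
            best = (model, tau)
    if best is None:
        raise FitFailureError(f"all {config.n_restarts} restarts failed", diagnostics)
    model = best[0]
    model.fit_meta.update(
        {
            "seed": config.seed,
            "restarts_used": used,
            "restart_diagnostics": diagnostics,
            "mode": mode,
            "x_names": list(data.x_names),
            "w_names": list(data.w_names),
        }
    )
    model = relabel_by_rate(model, data.X)
    from .model_selection import count_parameters

    model.fit_meta["n_params"] = count_parameters(model)
    return model


# ---------------------------------------------------------------------------
# Classification and uncertainty
# ---------------------------------------------------------------------------


def posterior_classify(model: MixtureModel, data: CountDataset) -> dict:
    """Hard cluster assignment and cluster summaries.

    Returns ``labels`` (1-based component indices; 0 is the structural-zero
    category of zero-inflated models), ``sizes`` per category, and ``priors``
    — mean gate weights per category.
    """
    tau, _ = e_step(data, model)
    raw = tau.hard_labels()
    labels = raw if model.zero_inflated else raw + 1
    n_cat = model.n_categories
    offset = 0 if model.zero_inflated else 1
    sizes = np.bincount(raw, minlength=n_cat)
    priors = concomitant_weights(data.W, model.weights).mean(axis=0)
    return {
        "labels": labels,
        "sizes": {offset + k: int(sizes[k]) for k in range(n_cat)},
        "priors": priors,
        "tau": tau,
    }


def bootstrap_confidence_intervals(
    data: CountDataset,
    model: MixtureModel,
    B: int = 200,
    config: Optional[FitConfig] = None,
    level: float = 0.95,
) -> dict:
    """Nonparametric case-resampling bootstrap percentile CIs.

    Each replicate resamples rows with replacement and refits by EM
    warm-started from the point estimate (one run, no restarts), then labels
    are aligned by the mean-rate ordering rule.  Returns per-coefficient
    (lower, upper) DataFrames for the component block and, for concomitant
    models, the gate, plus a failure-rate warning flag.
    """
    if B < 50:
        raise ValueError("B must be >= 50")
    config = config or FitConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB007]))
    coef_draws, gate_draws = [], []
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, data.n, size=data.n)
        boot = data.subset(idx)
        try:
            m, _, _ = _run_em_once(
                boot, model.K, model.weights.mode, config, rng, model.zero_inflated,
                start=model, max_iter=200,
            )
            m = relabel_by_rate(m, boot.X)
        except (DegenerateComponentError, FloatingPointError):
            failures += 1
            continue
        coef_draws.append(m.components.coef_matrix)
        if m.weights.mode == "concomitant":
            gate_draws.append(m.weights.gate_matrix)
    alpha = (1 - level) / 2
    out: dict = {"n_replicates": B, "n_failed": failures, "high_failure_warning": failures > 0.2 * B}

    def _ci_frame(draws: list[np.ndarray], names: list[str], tag: str) -> pd.DataFrame:
        arr = np.stack(draws)  # (B_ok, rows, d)
        lo = np.quantile(arr, alpha, axis=0)
        hi = np.quantile(arr, 1 - alpha, axis=0)
        frames = []
        for r in range(arr.shape[1]):
            frames.append(
                pd.DataFrame({"coef": names, "group": f"{tag}{r + 1}", "lower": lo[r], "upper": hi[r]})
            )
        return pd.concat(frames, ignore_index=True)

    x_names = model.fit_meta.get("x_names") or [f"x{j}" for j in range(model.components.coef_matrix.shape[1])]
    out["components"] = _ci_frame(coef_draws, list(x_names), "comp_")
    if gate_draws:
        w_names = model.fit_meta.get("w_names") or [f"w{j}" for j in range(model.weights.gate_matrix.shape[1])]
        out["gate"] = _ci_frame(gate_draws, list(w_names), "gate_")
    return out
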