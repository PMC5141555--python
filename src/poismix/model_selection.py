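"""Model selection for Poisson mixture regressions: df counting, AIC/BIC/ICL,
K-scans, and dispersion diagnostics.

ICL here is BIC plus twice the posterior entropy, so it penalises poorly
separated components on top of BIC's complexity penalty and ICL >= BIC
always holds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .em_fit import FitConfig, FitFailureError, e_step, fit_em
from .model_core import CountDataset, MixtureModel

__all__ = [
    "SelectionTable",
    "count_parameters",
    "aic",
    "bic",
    "icl",
    "scan_components",
    "dispersion_check",
]


def count_parameters(model: MixtureModel) -> int:
    """Free-parameter count (df).

    Component block: K*(1+p).  Gate block: (K_cat-1)*(1+q) in concomitant
    mode or K_cat-1 in fixed mode, where K_cat = K+1 for zero-inflated
    models (the structural category adds one full gate row and no rate
    parameters).
    """
    K = model.K
    d_comp = model.components.coef_matrix.shape[1]
    df = K * d_comp
    n_cat = model.n_categories
    if model.weights.mode == "fixed":
        df += n_cat - 1
    else:
        df += (n_cat - 1) * model.weights.gate_matrix.shape[1]
    return df


def _require_fitted(model: MixtureModel) -> float:
    ll = model.fit_meta.get("loglik")
    if ll is None or not np.isfinite(ll):
        raise ValueError("model has no stored log-likelihood; fit it first")
    return float(ll)


def aic(model: MixtureModel) -> float:
    """Akaike information criterion, -2*loglik + 2*df."""
    return -2.0 * _require_fitted(model) + 2.0 * count_parameters(model)


def bic(model: MixtureModel) -> float:
    """Bayesian information criterion, -2*loglik + df*log(n)."""
    n = model.fit_meta.get("n_obs")
    if n is None:
        raise ValueError("model has no stored n_obs; fit it first")
    return -2.0 * _require_fitted(model) + count_parameters(model) * np.log(n)


def posterior_entropy(tau: np.ndarray) -> float:
    """-sum_ik tau_ik log tau_ik with the 0*log(0) = 0 convention."""
    t = np.asarray(tau)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(t), 0.0)
    return float(-terms.sum())


def icl(model: MixtureModel, data: CountDataset) -> float:
    """Integrated completed likelihood: BIC + 2 * posterior entropy."""
    tau, _ = e_step(data, model)
    return bic(model) + 2.0 * posterior_entropy(tau.tau)


@dataclass
class SelectionTable:
    """Per-candidate-model criteria records from a K-scan."""

    table: pd.DataFrame
    best_by_bic: Optional[str]
    models: dict

    def best_model(self) -> MixtureModel:
        if self.best_by_bic is None:
            raise FitFailureError("no candidate model converged", [])
        return self.models[self.best_by_bic]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def scan_components(
    data: CountDataset,
    K_range: Iterable[int],
    mode: str = "concomitant",
    config: Optional[FitConfig] = None,
    zero_inflated: bool = False,
    tag_prefix: Optional[str] = None,
) -> SelectionTable:
    """Fit each candidate K and tabulate df/loglik/AIC/BIC/ICL.

    The best model minimises BIC among converged fits, ties going to the
    smaller K.  Degenerate or failed K are recorded with null criteria.
    """
    K_range = sorted(set(int(k) for k in K_range))
    if not K_range:
        raise ValueError("K_range must be nonempty")
    config = config or FitConfig()
    if tag_prefix is None:
        tag_prefix = ("zip_" if zero_inflated else "") + mode
    rows, models = [], {}
    for K in K_range:
        tag = f"{tag_prefix}_K{K}"
        row = {
            "model_tag": tag,
            "K": K,
            "mode": mode,
            "zero_inflated": zero_inflated,
            "df": np.nan,
            "loglik": np.nan,
            "AIC": np.nan,
            "BIC": np.nan,
            "ICL": np.nan,
            "converged": False,
        }
        try:
            model = fit_em(data, K, mode=mode, config=config, zero_inflated=zero_inflated)
        except (FitFailureError, FloatingPointError, ValueError):
            rows.append(row)
            continue
        row.update(
            df=count_parameters(model),
            loglik=model.fit_meta["loglik"],
            AIC=aic(model),
            BIC=bic(model),
            ICL=icl(model, data),
            converged=bool(model.fit_meta["converged"]),
        )
        models[tag] = model
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["BIC"])
    if ok.empty:
        raise FitFailureError("every candidate K failed to fit", [t for t in table.model_tag])
    # ties to smaller K: stable sort on BIC after sorting by K
    best = ok.sort_values(["BIC", "K"], kind="stable").iloc[0]["model_tag"]
    return SelectionTable(table=table, best_by_bic=str(best), models=models)


def dispersion_check(y: np.ndarray, equi_band: tuple[float, float] = (0.9, 1.1)) -> dict:
    """Sample mean/variance of the counts and an under/equi/over verdict.

    The variance-to-mean ratio is 1 for a Poisson sample; ratios inside
    ``equi_band`` are called equi-dispersed.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    mean = float(y.mean())
    var = float(y.var(ddof=1))
    ratio = var / mean if mean > 0 else 0.0
    if ratio < equi_band[0]:
        verdict = "under"
    elif ratio > equi_band[1]:
        verdict = "over"
    else:
        verdict = "equi"
    return {"mean": mean, "variance": var, "ratio": ratio, "verdict": verdict}
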