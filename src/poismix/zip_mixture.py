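"""Zero-inflated Poisson mixture regression (ZIPMR).

A structural component degenerate at zero is mixed with K ordinary Poisson
regression components.  All K+1 categories compete through one multinomial
gate (fixed or concomitant), so the model remains a strict finite mixture:

    y_i = 0                      with gate mass pi_i0   (structural zero)
    y_i ~ Poisson(lambda_ik)     with gate mass pi_ik,  k = 1..K.

Zeros therefore arise by two routes — the structural point mass and the
Poisson components' own e^{-lambda} mass — and the E-step apportions each
observed zero between them.  "K components" counts the Poisson components;
the structural category is extra and occupies column 0 of responsibilities
and of the gate.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .em_fit import FitConfig, e_step, fit_em
from .model_core import CountDataset, MixtureModel, Responsibilities, concomitant_weights

__all__ = ["zip_e_step", "fit_zip", "structural_zero_probability"]


def zip_e_step(data: CountDataset, model: MixtureModel) -> tuple[Responsibilities, float]:
    """E-step for a zero-inflated mixture.

    Rows with y_i > 0 put exactly zero mass on the structural column; rows
    with y_i = 0 split between the structural point mass and each Poisson
    component's e^{-lambda_ik}.
    """
    if not model.zero_inflated:
        raise ValueError("zip_e_step requires a zero-inflated model")
    return e_step(data, model)


def fit_zip(
    data: CountDataset,
    K: int,
    config: Optional[FitConfig] = None,
    mode: str = "concomitant",
) -> MixtureModel:
    """Fit a ZIPMR with K Poisson components plus the structural-zero category.

    EM alternates the zero-inflated E-step with the usual M-steps; the gate
    M-step includes the structural category as one more multinomial level.
    When the data contain no zeros the structural category is unidentified
    from the likelihood; a warning is issued and the fit proceeds (its gate
    mass is driven toward zero).
    """
    if not np.any(data.y == 0):
        warnings.warn(
            "data contain no zeros; the structural-zero component is vacuous",
            UserWarning,
            stacklevel=2,
        )
    return fit_em(data, K, mode=mode, config=config, zero_inflated=True)


def structural_zero_probability(model: MixtureModel, W: np.ndarray) -> np.ndarray:
    """Per-row gate probability of the structural-zero category, P(s_i = 0)."""
    if not model.zero_inflated:
        raise ValueError("model has no structural-zero component")
    return concomitant_weights(W, model.weights)[:, 0]
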