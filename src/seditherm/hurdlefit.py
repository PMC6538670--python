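"""The three response sub-models of the coral-loss hurdle pathway.

Partial-mortality observations are strongly zero-inflated, so expected loss
is decomposed into a hurdle of three fitted pieces:

1. **Bleaching** — site-level binomial model of bleaching-event counts
   against light and temperature (with a light × temperature interaction
   surface and morphological group factor), site random intercept.
2. **Incidence** — colony-level binary model of whether any partial-mortality
   event occurred in an interval, with a colony random intercept and a
   bleached-status factor (optionally interacting with the smooths).
3. **Loss** — conditional tissue loss, restricted to rows where an event
   occurred, beta regression on (0, 1) with colony random intercept.

Each estimator wraps :class:`seditherm.glmm.MixedGLM` and exposes seeded
parameter draws for Monte-Carlo uncertainty propagation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .glmm import MixedGLM

__all__ = [
    "BleachingModel",
    "IncidenceModel",
    "LossModel",
    "fit_bleaching",
    "fit_incidence",
    "fit_loss",
    "draws",
]


class _ResponseModel(BaseEstimator):
    """Shared plumbing for the three sub-models."""

    response_name: str = ""

    def _fit_glmm(self, data, formula, family, groups, trials_col=None):
        self.glmm_ = MixedGLM(
            formula=formula,
            family=family,
            groups=groups,
            trials_col=trials_col,
            n_quad=self.n_quad,
        ).fit(data)
        self.coef_ = self.glmm_.coef_
        self.coef_names_ = self.glmm_.coef_names_
        self.re_sd_ = self.glmm_.re_sd_
        self.loglik_ = self.glmm_.loglik_
        self.aicc_ = self.glmm_.aicc_
        self.n_obs_ = self.glmm_.n_obs_
        self.n_params_ = self.glmm_.n_params_
        return self

    def predict(self, data: pd.DataFrame, params=None) -> np.ndarray:
        """Mean response at random effects = 0."""
        return self.glmm_.predict(data, params=params)

    def predict_many(self, data: pd.DataFrame, params_matrix) -> np.ndarray:
        """Mean response per draw: array of shape (n_rows, n_draws)."""
        return self.glmm_.predict_many(data, params_matrix)

    def draws(self, n_draws: int, seed: int, scale: float = 1.0) -> np.ndarray:
        """Seeded parameter draws (multivariate normal around the MLE)."""
        return self.glmm_.draws(n_draws, seed, scale=scale)


class BleachingModel(_ResponseModel):
    """Site-level binomial bleaching-probability model.

    Input rows are site × interval × group cells with ``successes`` and
    ``trials`` plus the interval pressure covariates.  The default model is
    a light × temperature tensor-product surface with a group factor and a
    site random intercept; ``interaction="none"`` drops the surface and fits
    additive smooths.
    """

    response_name = "bleach"

    def __init__(
        self,
        formula: str | None = None,
        interaction: str = "tensor",
        k: int = 5,
        n_quad: int = 13,
        group_factor: bool = True,
    ):
        self.formula = formula
        self.interaction = interaction
        self.k = k
        self.n_quad = n_quad
        self.group_factor = group_factor

    def _default_formula(self, data) -> str:
        parts = [f"s(light, k={self.k})", f"s(temp, k={self.k})"]
        if self.interaction == "tensor":
            parts.append("te(light, temp)")
        elif self.interaction == "product":
            parts.append("light:temp")
        if self.group_factor and data["group"].nunique() > 1:
            parts.append("C(group)")
        return "successes ~ " + " + ".join(parts)

    def fit(self, data: pd.DataFrame, y=None):
        if (data["trials"] > 0).sum() < 10:
            raise ValueError("need trials > 0 in at least 10 cells")
        if data["site_id"].nunique() < 2:
            raise ValueError("need at least 2 sites")
        formula = self.formula or self._default_formula(data)
        return self._fit_glmm(data, formula, "binomial", "site_id", trials_col="trials")


class IncidenceModel(_ResponseModel):
    """Colony-level binary partial-mortality incidence model.

    Binary ``mort_event`` against interval pressure covariates with a
    ``bleached_status`` factor and a colony random intercept.  With
    ``by_bleached=True`` the light smooth is allowed to differ by bleached
    status (factor-by-smooth interaction).
    """

    response_name = "incidence"

    def __init__(
        self,
        formula: str | None = None,
        predictors=("light", "temp"),
        by_bleached: bool = False,
        k: int = 5,
        n_quad: int = 13,
    ):
        self.formula = formula
        self.predictors = predictors
        self.by_bleached = by_bleached
        self.k = k
        self.n_quad = n_quad

    def _default_formula(self) -> str:
        parts = [f"s({p}, k={self.k})" for p in self.predictors]
        parts.append("bleached_status")
        if self.by_bleached and "light" in self.predictors:
            parts.append(f"bleached_status:s(light, k={self.k})")
        return "mort_event ~ " + " + ".join(parts)

    def fit(self, data: pd.DataFrame, y=None):
        if data["colony_id"].nunique() < 20:
            raise ValueError("need at least 20 colonies")
        for p in self.predictors:
            if np.std(data[p].to_numpy(dtype=float)) == 0:
                raise ValueError(f"predictor {p!r} has zero variance")
        formula = self.formula or self._default_formula()
        return self._fit_glmm(data, formula, "binomial", "colony_id")


class LossModel(_ResponseModel):
    """Conditional tissue-loss model (beta regression on (0, 1]).

    Fitted only to rows where a partial-mortality event occurred; the hurdle
    contract is enforced (``loss > 0``).  Default covariates are the starting
    live cover and bleached status; a colony random intercept absorbs
    colony-level frailty.
    """

    response_name = "loss"

    def __init__(
        self,
        formula: str | None = None,
        predictors=("live_cover_t",),
        k: int = 5,
        n_quad: int = 13,
        min_rows: int = 30,
    ):
        self.formula = formula
        self.predictors = predictors
        self.k = k
        self.n_quad = n_quad
        self.min_rows = min_rows

    def _default_formula(self) -> str:
        parts = [p if p == "live_cover_t" else f"s({p}, k={self.k})" for p in self.predictors]
        parts.append("bleached_status")
        return "loss ~ " + " + ".join(parts)

    def fit(self, data: pd.DataFrame, y=None):
        if len(data) < self.min_rows:
            raise ValueError(f"need at least {self.min_rows} loss rows")
        if (data["loss"] <= 0).any():
            raise ValueError("loss rows must be strictly positive (hurdle violated)")
        formula = self.formula or self._default_formula()
        fitted = self._fit_glmm(data, formula, "beta", "colony_id")
        self.phi_ = self.glmm_.phi_
        return fitted


# -- thin functional wrappers -------------------------------------------


def fit_bleaching(cells: pd.DataFrame, **kwargs) -> BleachingModel:
    """Fit the site-level binomial bleaching model (see BleachingModel)."""
    return BleachingModel(**kwargs).fit(cells)


def fit_incidence(events: pd.DataFrame, **kwargs) -> IncidenceModel:
    """Fit the colony-level incidence model (see IncidenceModel)."""
    return IncidenceModel(**kwargs).fit(events)


def fit_loss(loss_rows: pd.DataFrame, **kwargs) -> LossModel:
    """Fit the conditional loss model (see LossModel)."""
    return LossModel(**kwargs).fit(loss_rows)


def draws(model: _ResponseModel, n_draws: int, seed: int) -> np.ndarray:
    """Seeded parameter draws from a fitted sub-model."""
    return model.draws(n_draws, seed)
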