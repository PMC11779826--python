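"""Multivariate logistic-regression benchmark.

Maximum-likelihood fit (statsmodels) of the outcome on all predictors,
odds ratios with Wald 95% CIs, benchmark AUC on a held-out split, and
the Pearson correlation between finite-difference impact scores and the
fitted coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, pearsonr
from sklearn.metrics import roc_auc_score

from .attribution import ScoreResult
from .cohort import Cohort
from .nn import encode_features

__all__ = ["LogisticFit", "fit_logistic", "coefficient_correlation"]


@dataclass
class LogisticFit:
    coefficients: dict[str, float]
    intercept: float
    or_ci: dict[str, tuple[float, float, float]]  # (OR, low, high)
    auc: float | None
    std_errors: dict[str, float]


class _LogisticModel:
    """Thin raw-space wrapper so attribution can interrogate the fit."""

    def __init__(self, result, specs):
        self._result = result
        self._specs = specs

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        X, _ = encode_features(features, self._specs)
        return np.asarray(self._result.predict(sm.add_constant(X, has_constant="add")))


def fit_logistic(
    cohort: Cohort,
    indices: np.ndarray | None = None,
    eval_indices: np.ndarray | None = None,
    outcome: str = "y",
    level: float = 0.95,
) -> tuple[LogisticFit, "_LogisticModel"]:
    """ML logistic fit on the given rows (all rows when None).

    Wald CIs: exp(beta ± z*SE).  AUC is computed on ``eval_indices``
    when provided.  Returns the fit summary and a raw-space prediction
    wrapper usable by the attribution module.
    """
    idx = np.arange(len(cohort)) if indices is None else np.asarray(indices)
    y = cohort.labels(outcome)[idx]
    if y.min() == y.max():
        raise ValueError("both outcome classes required for a logistic fit")
    X, names = encode_features(cohort.features, cohort.feature_specs)
    Xd = sm.add_constant(X[idx], has_constant="add")
    model = sm.Logit(y, Xd)
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # pragma: no cover - separation is data-dependent
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(
            "logistic fit did not converge (possible separation in "
            + ", ".join(names)
            + ")"
        )
    params = np.asarray(res.params)
    ses = np.asarray(res.bse)
    z = norm.ppf(0.5 + level / 2)
    coefs = dict(zip(names, params[1:]))
    or_ci = {
        nm: (float(np.exp(b)), float(np.exp(b - z * se)), float(np.exp(b + z * se)))
        for nm, b, se in zip(names, params[1:], ses[1:])
    }
    wrapper = _LogisticModel(res, cohort.feature_specs)
    auc = None
    if eval_indices is not None:
        ev = np.asarray(eval_indices)
        ye = cohort.labels(outcome)[ev]
        if ye.min() != ye.max():
            auc = float(
                roc_auc_score(ye, wrapper.predict_proba(cohort.features.iloc[ev]))
            )
    fit = LogisticFit(
        coefficients={k: float(v) for k, v in coefs.items()},
        intercept=float(params[0]),
        or_ci=or_ci,
        auc=auc,
        std_errors={nm: float(se) for nm, se in zip(names, ses[1:])},
    )
    return fit, wrapper


def coefficient_correlation(
    impacts: list[ScoreResult], fit: LogisticFit
) -> float:
    """Pearson correlation between population impact scores and logistic
    coefficients across the shared feature set."""
    shared = [r for r in impacts if r.name in fit.coefficients]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared features for a correlation")
    scores = [r.population for r in shared]
    coefs = [fit.coefficients[r.name] for r in shared]
    return float(pearsonr(scores, coefs)[0])
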