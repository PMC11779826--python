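"""Finite-difference attribution for black-box probability models.

Impact scores measure the change in model output when a feature is
toggled (binary), increased by one perturbation unit (continuous), or
moved from the reference level (categorical); interaction scores are
the second finite difference over simultaneous changes in two features
— the residual beyond the sum of the individual impacts.  Both are
computed per instance with both counterfactual states imposed on every
instance, then averaged; on the logit scale the impact of a pure
logistic model equals its coefficient and the interaction of a
logit-additive model vanishes, which makes the scores directly
comparable to regression coefficients.

Confidence intervals come from a percentile bootstrap over the full
pipeline: resample the cohort with replacement, re-split, re-balance,
re-train, re-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit as _logit_fn

from .cohort import Cohort, FeatureSpec

__all__ = [
    "ScoreResult",
    "impact_score",
    "interaction_score",
    "score_all",
    "bootstrap_scores",
    "scores_frame",
]

LOGIT_EPS = 1e-12


@dataclass
class ScoreResult:
    """An impact or interaction score.

    ``population`` is exactly the mean of ``per_instance``; ``ci`` is a
    percentile interval over pipeline re-runs when bootstrapping was
    requested.
    """

    target: str | tuple[str, str]
    scale: str  # probability | logit
    per_instance: np.ndarray
    population: float
    ci: tuple[float, float] | None = None
    n_bootstrap: int | None = None

    @property
    def name(self) -> str:
        if isinstance(self.target, tuple):
            return " x ".join(self.target)
        return self.target


def _g(prob: np.ndarray, scale: str) -> np.ndarray:
    if scale == "probability":
        return prob
    if scale == "logit":
        clipped = np.clip(prob, LOGIT_EPS, 1 - LOGIT_EPS)
        if np.any(clipped != prob):
            warnings.warn(
                f"model output at 0 or 1 clipped to eps={LOGIT_EPS} for logit scale"
            )
        return _logit_fn(clipped)
    raise ValueError(f"unknown scale {scale!r}")


def _states(spec: FeatureSpec, observed: pd.Series):
    """(low, high) counterfactual values for the feature change."""
    if spec.kind == "binary":
        return 0, 1
    if spec.kind == "continuous":
        return observed, observed + spec.perturbation_unit
    raise ValueError("categorical features need an explicit level")


def _with(features: pd.DataFrame, name: str, value) -> pd.DataFrame:
    out = features.copy()
    out[name] = value
    return out


def impact_score(
    model,
    cohort: Cohort,
    feature: FeatureSpec | str,
    scale: str = "probability",
    level: str | None = None,
) -> ScoreResult | list[ScoreResult]:
    """Population and per-instance impact of one feature.

    Binary: g(f(x | x_j=1)) - g(f(x | x_j=0)).  Continuous:
    g(f(x | x_j + u)) - g(f(x)) with u the declared perturbation unit.
    Categorical: one result per non-reference level (or the requested
    ``level``), contrasting that level against the reference.
    """
    spec = cohort.spec(feature) if isinstance(feature, str) else feature
    feats = cohort.features
    if spec.kind == "categorical":
        levels = [level] if level is not None else [
            lv for lv in spec.categories if lv != spec.reference_level
        ]
        results = []
        for lv in levels:
            hi = _g(model.predict_proba(_with(feats, spec.name, lv)), scale)
            lo = _g(
                model.predict_proba(_with(feats, spec.name, spec.reference_level)),
                scale,
            )
            per = hi - lo
            results.append(
                ScoreResult(f"{spec.name}={lv}", scale, per, float(per.mean()))
            )
        return results[0] if level is not None else results
    lo_v, hi_v = _states(spec, feats[spec.name])
    hi = _g(model.predict_proba(_with(feats, spec.name, hi_v)), scale)
    lo = _g(model.predict_proba(_with(feats, spec.name, lo_v)), scale)
    per = hi - lo
    return ScoreResult(spec.name, scale, per, float(per.mean()))


def interaction_score(
    model,
    cohort: Cohort,
    feature_j: FeatureSpec | str,
    feature_k: FeatureSpec | str,
    scale: str = "probability",
) -> ScoreResult:
    """Second finite difference over simultaneous changes in two features.

    s_i = g(f(both changed)) - g(f(only j)) - g(f(only k)) + g(f(neither)),
    where "neither" sets binary features to 0 and leaves continuous
    features at their observed values.  Symmetric in (j, k) by
    construction.
    """
    sj = cohort.spec(feature_j) if isinstance(feature_j, str) else feature_j
    sk = cohort.spec(feature_k) if isinstance(feature_k, str) else feature_k
    if sj.name == sk.name:
        raise ValueError("interaction requires two distinct features")
    for s in (sj, sk):
        if s.kind == "categorical":
            raise ValueError(
                "categorical interactions are scored per level; pass a binary "
                "indicator feature instead"
            )
    feats = cohort.features
    lo_j, hi_j = _states(sj, feats[sj.name])
    lo_k, hi_k = _states(sk, feats[sk.name])
    both = _with(_with(feats, sj.name, hi_j), sk.name, hi_k)
    only_j = _with(_with(feats, sj.name, hi_j), sk.name, lo_k)
    only_k = _with(_with(feats, sj.name, lo_j), sk.name, hi_k)
    neither = _with(_with(feats, sj.name, lo_j), sk.name, lo_k)
    per = (
        _g(model.predict_proba(both), scale)
        - _g(model.predict_proba(only_j), scale)
        - _g(model.predict_proba(only_k), scale)
        + _g(model.predict_proba(neither), scale)
    )
    key = tuple(sorted((sj.name, sk.name)))
    return ScoreResult(key, scale, per, float(per.mean()))


def score_all(
    model,
    cohort: Cohort,
    anchor: str,
    scale: str = "probability",
) -> tuple[list[ScoreResult], list[ScoreResult]]:
    """Impact scores for every feature plus interaction scores of every
    other (non-categorical) feature with the anchor, each list sorted
    by descending population score (ties broken by name)."""
    cohort.spec(anchor)  # raises KeyError if undeclared
    impacts: list[ScoreResult] = []
    for spec in cohort.feature_specs:
        res = impact_score(model, cohort, spec, scale)
        impacts.extend(res if isinstance(res, list) else [res])
    interactions = [
        interaction_score(model, cohort, spec.name, anchor, scale)
        for spec in cohort.feature_specs
        if spec.name != anchor and spec.kind != "categorical"
    ]
    keyfn = lambda r: (-r.population, r.name)
    return sorted(impacts, key=keyfn), sorted(interactions, key=keyfn)


def bootstrap_scores(
    cohort: Cohort,
    pipeline_fn,
    B: int = 200,
    level: float = 0.95,
    seed: int = 0,
    max_retries: int = 10,
    point: tuple[list[ScoreResult], list[ScoreResult]] | None = None,
) -> tuple[list[ScoreResult], list[ScoreResult]]:
    """Pipeline-level percentile bootstrap for impact/interaction scores.

    ``pipeline_fn(cohort, seed) -> (impacts, interactions)`` must run the
    full split/under-sample/train/score pipeline.  The point estimate
    comes from the un-resampled cohort (precomputed results may be
    passed as ``point`` so it does not depend on the bootstrap seed);
    each of the B replicates resamples n instances with replacement, and
    the CI per target is the (lower, upper) percentile of the replicate
    population scores.  Replicates that draw a single outcome class are
    redrawn (bounded).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    if point is None:
        point = pipeline_fn(cohort, int(rng.integers(2**31)))
    point_imp, point_int = point
    reps_imp: dict[str, list[float]] = {r.name: [] for r in point_imp}
    reps_int: dict[str, list[float]] = {r.name: [] for r in point_int}
    n = len(cohort)
    for b in range(B):
        for attempt in range(max_retries):
            idx = rng.integers(0, n, size=n)
            resampled = cohort.subset(idx)
            if 0 < resampled.y.sum() < n:
                break
        else:
            raise RuntimeError("bootstrap replicate kept drawing one outcome class")
        imp, inter = pipeline_fn(resampled, int(rng.integers(2**31)))
        for r in imp:
            reps_imp[r.name].append(r.population)
        for r in inter:
            reps_int[r.name].append(r.population)
    alpha = (1 - level) / 2
    def attach(results: list[ScoreResult], reps: dict[str, list[float]]):
        for r in results:
            vals = np.asarray(reps[r.name])
            # order-statistic percentiles: (min, max) at B=2
            r.ci = (
                float(np.percentile(vals, 100 * alpha, method="lower")),
                float(np.percentile(vals, 100 * (1 - alpha), method="higher")),
            )
            r.n_bootstrap = B
    attach(point_imp, reps_imp)
    attach(point_int, reps_int)
    return point_imp, point_int


def scores_frame(results: list[ScoreResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "target": [r.name for r in results],
            "scale": [r.scale for r in results],
            "population": [r.population for r in results],
            "ci_low": [None if r.ci is None else r.ci[0] for r in results],
            "ci_high": [None if r.ci is None else r.ci[1] for r in results],
            "n_bootstrap": [r.n_bootstrap for r in results],
        }
    )
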