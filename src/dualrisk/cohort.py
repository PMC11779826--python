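"""Synthetic EHR-like cohort generation.

Builds cross-sectional cohorts that mimic the structure of a large
VA-style outpatient population: a binary dual-system-use exposure,
continuous age, correlated binary comorbidities, and a rare binary
outcome (opioid use disorder) observed through two noisy channels — a
note-derived "documented" label with realistic sensitivity/specificity
and a much rarer diagnosis-code ("coded") label.  The latent outcome
follows a logistic model with configurable main effects and pairwise
interactions, so downstream attribution methods can be validated
against planted ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, truncnorm

__all__ = [
    "FeatureSpec",
    "GenerativeModel",
    "Cohort",
    "default_scenario",
    "calibrate_intercept",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "CohortFormatError",
    "CalibrationError",
]

LABEL_COLUMNS = ("y", "y_documented", "y_coded")


class CohortFormatError(ValueError):
    """A cohort table violates the on-disk contract."""


class CalibrationError(RuntimeError):
    """Intercept calibration failed to reach the target prevalence."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one predictor column.

    ``perturbation_unit`` is the step used by attribution for continuous
    features (e.g. one year of age); categorical features list their
    levels and the reference level against which effects are measured.
    """

    name: str
    kind: str  # binary | continuous | categorical
    categories: tuple[str, ...] | None = None
    reference_level: str | None = None
    perturbation_unit: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous", "categorical"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.categories or len(self.categories) < 2:
                raise ValueError(f"{self.name}: categorical needs >=2 categories")
            if self.reference_level not in self.categories:
                raise ValueError(
                    f"{self.name}: reference_level {self.reference_level!r} "
                    "not among categories"
                )
        if self.kind == "continuous":
            if self.perturbation_unit is None or self.perturbation_unit <= 0:
                raise ValueError(f"{self.name}: perturbation_unit must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["categories"] is not None:
            d["categories"] = list(d["categories"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        d = dict(d)
        if d.get("categories") is not None:
            d["categories"] = tuple(d["categories"])
        return cls(**d)


@dataclass
class LabelNoise:
    """Measurement model linking the latent outcome to observed labels.

    ``documented_sensitivity``/``documented_specificity`` define the
    note-derived label; ``coded_given_true`` is the probability that a
    true case also carries a diagnosis code (under-coding).
    """

    documented_sensitivity: float = 0.884
    documented_specificity: float = 0.966
    coded_given_true: float = 0.113

    def __post_init__(self) -> None:
        if not 0 < self.documented_sensitivity <= 1:
            raise ValueError("documented_sensitivity must be in (0,1]")
        if not 0 < self.documented_specificity <= 1:
            raise ValueError("documented_specificity must be in (0,1]")
        if not 0 <= self.coded_given_true <= 1:
            raise ValueError("coded_given_true must be in [0,1]")


def _pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered feature-pair key."""
    return (a, b) if a <= b else (b, a)


@dataclass
class GenerativeModel:
    """Fully parameterised synthetic cohort model.

    The latent outcome is Bernoulli(sigmoid(beta0 + sum beta_j x_j +
    sum gamma_jk x_j x_k)), with continuous features centred at
    ``centering[name]`` before entering the linear predictor so that
    main effects read as effects at the centre.  The exposure feature
    has its own logistic sub-model on the covariates (younger, female
    and comorbid instances are more likely exposed), and binary
    comorbidities share a latent liability factor that induces
    realistic co-occurrence.
    """

    feature_specs: list[FeatureSpec]
    marginal_params: dict[str, dict]
    beta: dict[str, float]
    gamma: dict[tuple[str, str], float]
    target_prevalence: float
    beta0: float | None = None
    label_noise: LabelNoise = field(default_factory=LabelNoise)
    centering: dict[str, float] = field(default_factory=dict)
    exposure_name: str | None = None
    exposure_model: dict[str, float] = field(default_factory=dict)
    exposure_intercept: float = 0.0
    liability_loadings: dict[str, float] = field(default_factory=dict)
    age_bounds: tuple[float, float] = (18.0, 100.0)
    exclude_prior_outcome: float = 0.0

    def __post_init__(self) -> None:
        names = [s.name for s in self.feature_specs]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must be in (0,1)")
        self.gamma = {_pair_key(*k): v for k, v in self.gamma.items()}
        known = set(names)
        for j, k in self.gamma:
            if j not in known or k not in known:
                raise ValueError(f"gamma key ({j},{k}) references undeclared feature")
        for j in self.beta:
            if j not in known:
                raise ValueError(f"beta key {j} references undeclared feature")
        if not 0 <= self.exclude_prior_outcome < 1:
            raise ValueError("exclude_prior_outcome must be in [0,1)")

    @property
    def calibrated(self) -> bool:
        return self.beta0 is not None

    def spec(self, name: str) -> FeatureSpec:
        for s in self.feature_specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def linear_predictor(self, features: pd.DataFrame, beta0: float) -> np.ndarray:
        """Latent logit for each row (centres continuous features)."""
        X = {}
        for s in self.feature_specs:
            col = features[s.name].to_numpy(dtype=float)
            if s.kind == "continuous":
                col = col - self.centering.get(s.name, 0.0)
            X[s.name] = col
        eta = np.full(len(features), beta0, dtype=float)
        for name, b in self.beta.items():
            eta += b * X[name]
        for (j, k), g in self.gamma.items():
            eta += g * X[j] * X[k]
        return eta


# ---------------------------------------------------------------------------
# Default scenario
# ---------------------------------------------------------------------------

def default_scenario() -> GenerativeModel:
    """The reference synthetic cohort.

    Marginals follow the no-outcome column of the study's baseline
    table (exposure ~9%, mean age 61 with SD 16, comorbidity
    prevalences in the 10-50% range); effects are positive for
    substance-use comorbidities and prior opioid prescription, negative
    for age; the planted interactions reproduce the published sign
    pattern — positive age x exposure, negative PTSD x exposure and
    other-drug x exposure.  Label noise uses the published NLP
    operating characteristics (88.4% sensitivity, 96.6% specificity)
    and an 11.3% coding rate among true cases.  The outcome intercept
    is left uncalibrated; call :func:`calibrate_intercept`.
    """
    exposure = "dual_system_use"
    specs = [
        FeatureSpec("age", "continuous", perturbation_unit=1.0),
        FeatureSpec(exposure, "binary"),
        FeatureSpec("female", "binary"),
        FeatureSpec("prior_opioid_rx", "binary"),
        FeatureSpec("alcohol_use_disorder", "binary"),
        FeatureSpec("other_drug_disorder", "binary"),
        FeatureSpec("ptsd", "binary"),
        FeatureSpec("tobacco_use_disorder", "binary"),
        FeatureSpec("depression", "binary"),
        FeatureSpec("anxiety", "binary"),
    ]
    marginals = {
        "age": {"mean": 61.0, "sd": 16.0},
        exposure: {"prevalence": 0.09},
        "female": {"prevalence": 0.14},
        "prior_opioid_rx": {"prevalence": 0.50},
        "alcohol_use_disorder": {"prevalence": 0.18},
        "other_drug_disorder": {"prevalence": 0.14},
        "ptsd": {"prevalence": 0.20},
        "tobacco_use_disorder": {"prevalence": 0.26},
        "depression": {"prevalence": 0.29},
        "anxiety": {"prevalence": 0.24},
    }
    beta = {
        "age": -0.022,
        exposure: 0.70,
        "female": 0.10,
        "prior_opioid_rx": 0.85,
        "alcohol_use_disorder": 0.75,
        "other_drug_disorder": 1.40,
        "ptsd": 0.45,
        "tobacco_use_disorder": 0.65,
        "depression": 0.30,
        "anxiety": 0.35,
    }
    gamma = {
        _pair_key("age", exposure): 0.020,
        _pair_key("ptsd", exposure): -0.55,
        _pair_key("other_drug_disorder", exposure): -0.45,
    }
    # Exposure sub-model coefficients act on centred age (per year) and the
    # raw binaries; the intercept was calibrated once by simulation to give
    # ~9% exposure prevalence and is kept fixed.
    exposure_model = {
        "age": -0.020,
        "female": 0.30,
        "ptsd": 0.35,
        "depression": 0.25,
        "other_drug_disorder": 0.25,
    }
    liability = {
        "alcohol_use_disorder": 0.55,
        "other_drug_disorder": 0.65,
        "ptsd": 0.45,
        "tobacco_use_disorder": 0.55,
        "depression": 0.50,
        "anxiety": 0.50,
    }
    return GenerativeModel(
        feature_specs=specs,
        marginal_params=marginals,
        beta=beta,
        gamma=gamma,
        target_prevalence=0.17,
        label_noise=LabelNoise(0.884, 0.966, 0.113),
        centering={"age": 61.0},
        exposure_name=exposure,
        exposure_model=exposure_model,
        exposure_intercept=-2.59,
        liability_loadings=liability,
    )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample_features(model: GenerativeModel, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    liability = rng.standard_normal(n)
    for s in model.feature_specs:
        if s.name == model.exposure_name:
            continue  # drawn after covariates
        p = model.marginal_params[s.name]
        if s.kind == "continuous":
            lo, hi = model.age_bounds
            a = (lo - p["mean"]) / p["sd"]
            b = (hi - p["mean"]) / p["sd"]
            cols[s.name] = truncnorm.rvs(
                a, b, loc=p["mean"], scale=p["sd"], size=n, random_state=rng
            )
        elif s.kind == "binary":
            lam = model.liability_loadings.get(s.name, 0.0)
            if lam:
                # Probit threshold on a shared latent factor: marginal
                # prevalence is exact, co-occurrence comes from the factor.
                z = lam * liability + np.sqrt(1 - lam**2) * rng.standard_normal(n)
                cols[s.name] = (z < norm.ppf(p["prevalence"])).astype(np.int64)
            else:
                cols[s.name] = (rng.random(n) < p["prevalence"]).astype(np.int64)
        else:  # categorical
            probs = np.asarray(p["proportions"], dtype=float)
            idx = rng.choice(len(s.categories), size=n, p=probs / probs.sum())
            cols[s.name] = np.asarray(s.categories, dtype=object)[idx]
    if model.exposure_name is not None:
        eta = np.full(n, model.exposure_intercept)
        for name, coef in model.exposure_model.items():
            x = np.asarray(cols[name], dtype=float)
            x = x - model.centering.get(name, 0.0)
            eta += coef * x
        cols[model.exposure_name] = (rng.random(n) < expit(eta)).astype(np.int64)
    order = [s.name for s in model.feature_specs]
    return pd.DataFrame(cols)[order]


def calibrate_intercept(
    model: GenerativeModel, n_probe: int = 100_000, seed: int = 0
) -> float:
    """Bisect the outcome intercept to hit ``target_prevalence``.

    Uses the expected prevalence mean(sigmoid(eta)) over a fixed probe
    sample of covariates, which is smooth and monotone in beta0, so the
    search is deterministic given the seed.  The calibrated value is
    stored on the model and returned.
    """
    if n_probe < 10_000:
        raise ValueError("n_probe must be >= 10,000 for a stable calibration")
    rng = np.random.default_rng(seed)
    feats = _sample_features(model, n_probe, rng)
    eta0 = model.linear_predictor(feats, beta0=0.0)
    target = model.target_prevalence

    def prev(b0: float) -> float:
        return float(expit(eta0 + b0).mean())

    lo, hi = -30.0, 30.0
    if not (prev(lo) < target < prev(hi)):
        raise CalibrationError("target prevalence unreachable in bisection bracket")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if prev(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    b0 = 0.5 * (lo + hi)
    if abs(prev(b0) - target) > 0.005:
        raise CalibrationError("bisection did not reach target prevalence")
    model.beta0 = b0
    return b0


@dataclass
class Cohort:
    """Instances x features plus outcome labels.

    ``y_true`` is the latent status (synthetic cohorts only; None for
    cohorts read from user files without it), ``y_documented`` the
    note-derived label, ``y_coded`` the diagnosis-code label, and ``y``
    the analysis outcome (documented OR coded).
    """

    features: pd.DataFrame
    y: np.ndarray
    y_documented: np.ndarray
    y_coded: np.ndarray
    y_true: np.ndarray | None = None
    feature_specs: list[FeatureSpec] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.features)
        for name in ("y", "y_documented", "y_coded"):
            v = np.asarray(getattr(self, name))
            if v.shape != (n,):
                raise ValueError(f"label {name} has wrong length")
            if not np.isin(v, (0, 1)).all():
                raise ValueError(f"label {name} must be binary")
            setattr(self, name, v.astype(np.int64))
        if not np.array_equal(self.y, self.y_documented | self.y_coded):
            raise ValueError("y must equal y_documented OR y_coded")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def n(self) -> int:
        return len(self.features)

    def spec(self, name: str) -> FeatureSpec:
        for s in self.feature_specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def labels(self, name: str = "y") -> np.ndarray:
        if name == "y_true":
            if self.y_true is None:
                raise KeyError("cohort has no latent labels")
            return self.y_true
        if name not in LABEL_COLUMNS:
            raise KeyError(name)
        return getattr(self, name)

    def subset(self, indices: np.ndarray) -> "Cohort":
        idx = np.asarray(indices)
        return Cohort(
            features=self.features.iloc[idx].reset_index(drop=True),
            y=self.y[idx],
            y_documented=self.y_documented[idx],
            y_coded=self.y_coded[idx],
            y_true=None if self.y_true is None else self.y_true[idx],
            feature_specs=self.feature_specs,
            seed=self.seed,
        )


def generate_cohort(model: GenerativeModel, n: int, seed: int) -> Cohort:
    """Draw a cohort of ``n`` instances from a calibrated model."""
    if not model.calibrated:
        raise ValueError("model is not calibrated; run calibrate_intercept first")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    feats = _sample_features(model, n, rng)
    eta = model.linear_predictor(feats, model.beta0)
    y_true = (rng.random(n) < expit(eta)).astype(np.int64)
    ln = model.label_noise
    u = rng.random(n)
    y_doc = np.where(
        y_true == 1, u < ln.documented_sensitivity, u > ln.documented_specificity
    ).astype(np.int64)
    y_coded = ((rng.random(n) < ln.coded_given_true) & (y_true == 1)).astype(np.int64)
    if model.exclude_prior_outcome > 0:
        # Sensitivity-analysis mechanism: drop a fraction of prevalent cases.
        drop = (y_true == 1) & (rng.random(n) < model.exclude_prior_outcome)
        keep = ~drop
        feats = feats.loc[keep].reset_index(drop=True)
        y_true, y_doc, y_coded = y_true[keep], y_doc[keep], y_coded[keep]
    return Cohort(
        features=feats,
        y=y_doc | y_coded,
        y_documented=y_doc,
        y_coded=y_coded,
        y_true=y_true,
        feature_specs=list(model.feature_specs),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# I/O: CSV table + JSON side-car for the feature declarations
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV with a ``<path>.specs.json`` side-car."""
    path = Path(path)
    table = cohort.features.copy()
    table["y"] = cohort.y
    table["y_documented"] = cohort.y_documented
    table["y_coded"] = cohort.y_coded
    if cohort.y_true is not None:
        table["y_true"] = cohort.y_true
    table.to_csv(path, index=False)
    sidecar = {
        "feature_specs": [s.to_dict() for s in cohort.feature_specs],
        "seed": cohort.seed,
        "has_latent": cohort.y_true is not None,
    }
    Path(str(path) + ".specs.json").write_text(json.dumps(sidecar, indent=1))


def read_cohort(path: str | Path, specs: list[FeatureSpec] | None = None) -> Cohort:
    """Read a cohort CSV, validating against its feature declarations.

    Raises :class:`CohortFormatError` naming the offending row/column on
    missing cells, unknown columns or non-binary labels.
    """
    path = Path(path)
    sidecar_path = Path(str(path) + ".specs.json")
    seed = None
    if specs is None:
        if not sidecar_path.exists():
            raise CohortFormatError(f"no feature specs given and {sidecar_path} missing")
        meta = json.loads(sidecar_path.read_text())
        specs = [FeatureSpec.from_dict(d) for d in meta["feature_specs"]]
        seed = meta.get("seed")
    table = pd.read_csv(path)
    declared = {s.name for s in specs}
    allowed = declared | set(LABEL_COLUMNS) | {"y_true"}
    for col in table.columns:
        if col not in allowed:
            raise CohortFormatError(f"unknown column {col!r}")
    for col in declared | set(LABEL_COLUMNS):
        if col not in table.columns:
            raise CohortFormatError(f"missing column {col!r}")
    na = table.isna()
    if na.to_numpy().any():
        col = table.columns[na.any(axis=0)][0]
        row = int(na[col].idxmax())
        raise CohortFormatError(f"missing cell at row {row}, column {col!r}")
    for col in LABEL_COLUMNS:
        vals = table[col].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = int(np.flatnonzero(~np.isin(vals, (0, 1)))[0])
            raise CohortFormatError(
                f"non-binary outcome value {vals[bad]!r} in column {col!r}, row {bad}"
            )
    for s in specs:
        if s.kind == "binary" and not np.isin(table[s.name].to_numpy(), (0, 1)).all():
            raise CohortFormatError(f"non-binary value in binary feature {s.name!r}")
    return Cohort(
        features=table[[s.name for s in specs]].copy(),
        y=table["y"].to_numpy(),
        y_documented=table["y_documented"].to_numpy(),
        y_coded=table["y_coded"].to_numpy(),
        y_true=table["y_true"].to_numpy() if "y_true" in table else None,
        feature_specs=list(specs),
        seed=seed,
    )
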