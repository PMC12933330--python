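"""Caco-2 permeability regression on PROTAC fingerprints.

The model maps a PROTAC SMILES to a predictive distribution of its log10
apical-to-basolateral apparent permeability (μcm/s, log10 scale). The default
regressor is a gradient-boosted tree quantile ensemble: one point model for
the mean plus one quantile model per requested percentile, all on count-based
Morgan fingerprints (radius 2, folded to 500 dimensions). Left-censored
training values enter at their x/2 surrogate.

:class:`PermeabilityRegressor` follows the scikit-learn estimator contract
(``fit``/``predict``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore) and accepts a sequence of SMILES strings as ``X``, so it
composes with scikit-learn model selection. Small-sample evaluation uses
leave-one-out cross-validation (:func:`loocv_evaluate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import mean_squared_error, r2_score

from .chem import (
    BIT_FP_2048,
    FingerprintSpec,
    PermeabilityRecord,
    canonical_smiles,
    make_permeability_record,
    morgan_fingerprint,
    tanimoto,
)
from .errors import ConfigError, FitError, InvalidSmiles

DEFAULT_QUANTILES = (10, 30, 50, 70, 90)


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class PermeabilityDataset:
    """Curated PROTAC permeability training table.

    SMILES are canonicalized and must be unique; at least 3 records are
    required for any fit.
    """

    records: list[PermeabilityRecord]
    spec: FingerprintSpec = field(default_factory=lambda: FingerprintSpec(2, 500, True))

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            if rec.smiles in seen:
                raise ValueError(f"duplicate canonical SMILES in dataset: {rec.smiles}")
            seen.add(rec.smiles)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def y(self) -> np.ndarray:
        return np.array([r.log_papp for r in self.records])

    @classmethod
    def from_table(cls, df: pd.DataFrame, spec: FingerprintSpec | None = None):
        """Build from a table with columns ``smiles`` and ``raw_papp``."""
        records = [
            make_permeability_record(row["smiles"], row["raw_papp"])
            for _, row in df.iterrows()
        ]
        return cls(records, spec or FingerprintSpec(2, 500, True))

    @classmethod
    def from_csv(cls, path, spec: FingerprintSpec | None = None):
        return cls.from_table(pd.read_csv(path, dtype={"raw_papp": str}), spec)

    def to_csv(self, path):
        pd.DataFrame(
            {
                "smiles": self.smiles,
                "raw_papp": [r.raw_value for r in self.records],
                "papp": [r.papp for r in self.records],
                "log_papp": [r.log_papp for r in self.records],
                "censored": [r.censored for r in self.records],
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# predictive distribution
# ---------------------------------------------------------------------------

@dataclass
class PredictiveDistribution:
    """Mean plus percentile queries of a predicted log10 P_app.

    Quantile values are rearranged to be non-decreasing (quantile crossing in
    the underlying per-quantile models is resolved by sorting); queries at
    other levels interpolate linearly and clamp at the outermost trained
    levels.
    """

    mean: float
    levels: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        order = np.argsort(self.levels)
        self.levels = tuple(np.asarray(self.levels)[order])
        self.values = tuple(np.sort(np.asarray(self.values))[: len(self.levels)])

    def percentile(self, q: float) -> float:
        if not (0 < q < 100):
            raise ValueError("percentile level must be in (0, 100)")
        return float(np.interp(q, self.levels, self.values))


@dataclass(frozen=True)
class EvalMetrics:
    """Pooled held-out metrics: R², Pearson r, RMSE (log10 units)."""

    r2: float
    r: float
    rmse: float


# ---------------------------------------------------------------------------
# regressor registry
# ---------------------------------------------------------------------------

def _make_lightgbm(params: dict, random_state: int, quantile: float | None):
    from lightgbm import LGBMRegressor

    kw = dict(
        n_estimators=300,
        learning_rate=0.05,
        num_leaves=15,
        min_child_samples=2,
        subsample=1.0,
        colsample_bytree=0.8,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
        random_state=random_state,
    )
    kw.update(params)
    if quantile is not None:
        kw.update(objective="quantile", alpha=quantile / 100.0)
    return LGBMRegressor(**kw)


def _make_sklearn_gbt(params: dict, random_state: int, quantile: float | None):
    from sklearn.ensemble import GradientBoostingRegressor

    kw = dict(
        n_estimators=200,
        learning_rate=0.05,
        max_depth=3,
        min_samples_leaf=2,
        random_state=random_state,
    )
    kw.update(params)
    if quantile is not None:
        kw.update(loss="quantile", alpha=quantile / 100.0)
    return GradientBoostingRegressor(**kw)


#: name -> factory(params, random_state, quantile) for the point / quantile models.
#: External regressors (e.g. a prior-data fitted network) can be registered here.
REGRESSOR_FACTORIES = {
    "lightgbm": _make_lightgbm,
    "gbt": _make_sklearn_gbt,
}


def register_regressor(name: str, factory) -> None:
    """Register a custom regressor factory under ``name``.

    The factory signature is ``factory(params, random_state, quantile)`` where
    ``quantile`` is a percentile level in (0, 100) or ``None`` for the point
    model; it must return a fitted-API (fit/predict) regressor.
    """
    REGRESSOR_FACTORIES[name] = factory


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class PermeabilityRegressor(BaseEstimator, RegressorMixin):
    """Fingerprint-based regressor of log10 Caco-2 P_app with percentile output.

    Parameters
    ----------
    regressor : str
        Key into the regressor registry ("gbt", the scikit-learn gradient
        boosting default, "lightgbm", or a user-registered name).
    radius, dim, counted : fingerprint parameters (Morgan).
    quantiles : tuple of percentile levels fitted as separate quantile models;
        empty tuple fits the point model only (no distribution queries).
    regressor_params : dict passed through to the underlying factory.
    random_state : seed for the tree ensembles; fits are deterministic.
    """

    def __init__(
        self,
        regressor: str = "gbt",
        radius: int = 2,
        dim: int = 500,
        counted: bool = True,
        quantiles: tuple = DEFAULT_QUANTILES,
        regressor_params: dict | None = None,
        random_state: int = 0,
    ):
        self.regressor = regressor
        self.radius = radius
        self.dim = dim
        self.counted = counted
        self.quantiles = quantiles
        self.regressor_params = regressor_params
        self.random_state = random_state

    # -- featurization ----------------------------------------------------
    @property
    def fingerprint_spec(self) -> FingerprintSpec:
        return FingerprintSpec(self.radius, self.dim, self.counted)

    def _featurize(self, X) -> pd.DataFrame:
        spec = self.fingerprint_spec
        arr = np.vstack([morgan_fingerprint(s, spec) for s in X]).astype(np.float64)
        # named columns keep fit/predict feature bookkeeping consistent
        return pd.DataFrame(arr, columns=[f"fp{i}" for i in range(arr.shape[1])])

    def _factory(self):
        if self.regressor not in REGRESSOR_FACTORIES:
            raise ConfigError(
                f"unknown regressor {self.regressor!r}; "
                f"known: {sorted(REGRESSOR_FACTORIES)}"
            )
        return REGRESSOR_FACTORIES[self.regressor]

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y):
        """Fit on SMILES strings ``X`` and log10 P_app targets ``y``."""
        X = list(X)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) < 3:
            raise ValueError(f"need at least 3 records to fit, got {len(X)}")
        factory = self._factory()
        params = dict(self.regressor_params or {})
        F = self._featurize(X)
        self.model_ = factory(params, self.random_state, None).fit(F, y)
        self.quantile_models_ = {}
        for q in self.quantiles:
            self.quantile_models_[q] = factory(params, self.random_state, q).fit(F, y)
        self.train_smiles_ = [canonical_smiles(s, lenient=True) for s in X]
        self.train_y_ = y.copy()
        self.train_fps_ = [morgan_fingerprint(s, self.fingerprint_spec) for s in X]
        self.train_ad_fps_ = [morgan_fingerprint(s, BIT_FP_2048) for s in X]
        self.n_features_in_ = F.shape[1]
        return self

    def fit_dataset(self, dataset: PermeabilityDataset):
        return self.fit(dataset.smiles, dataset.y)

    def predict(self, X) -> np.ndarray:
        """Point predictions (predictive mean) for a sequence of SMILES."""
        self._check_fitted()
        return self.model_.predict(self._featurize(list(X)))

    def predict_distribution(self, smiles: str) -> PredictiveDistribution:
        """Full predictive distribution for one SMILES."""
        self._check_fitted()
        F = self._featurize([smiles])
        mean = float(np.asarray(self.model_.predict(F))[0])
        if not self.quantile_models_:
            # point model only: degenerate distribution at the mean
            return PredictiveDistribution(mean, (50.0,), (mean,))
        levels = tuple(float(q) for q in self.quantiles)
        values = tuple(float(m.predict(F)[0]) for m in self.quantile_models_.values())
        return PredictiveDistribution(mean, levels, values)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise FitError("regressor is not fitted")

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Persist the fitted model (with training fingerprints, needed by the
        applicability-domain filter) to a single archive file."""
        self._check_fitted()
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "PermeabilityRegressor":
        model = joblib.load(path)
        if not isinstance(model, PermeabilityRegressor):
            raise ConfigError(f"{path} does not contain a PermeabilityRegressor")
        return model


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> EvalMetrics:
    """R², Pearson r and RMSE of pooled held-out predictions."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    rmse = float(np.sqrt(mean_squared_error(y_true, y_pred)))
    r = float(stats.pearsonr(y_true, y_pred)[0]) if np.std(y_pred) > 0 else 0.0
    return EvalMetrics(r2=float(r2_score(y_true, y_pred)), r=r, rmse=rmse)


def loocv_evaluate(
    dataset: PermeabilityDataset | tuple,
    estimator: PermeabilityRegressor | None = None,
) -> tuple[EvalMetrics, pd.DataFrame]:
    """Leave-one-out cross-validation of the permeability model.

    Each compound is predicted by a model trained on the other n−1; metrics
    are computed on the pooled held-out predictions. Returns the metrics and a
    per-compound table (smiles, y_true, y_pred plus the trained percentiles).

    The estimator's hyperparameters are cloned per fold; a failing fold raises
    :class:`FitError` carrying the fold index.
    """
    if isinstance(dataset, PermeabilityDataset):
        X, y = dataset.smiles, dataset.y
    else:
        X, y = list(dataset[0]), np.asarray(dataset[1], dtype=float)
    n = len(X)
    if n < 3:
        raise ValueError(f"LOOCV needs at least 3 records, got {n}")
    est = estimator if estimator is not None else PermeabilityRegressor()
    factory = est._factory()
    params = dict(est.regressor_params or {})
    F = est._featurize(X)

    preds = np.empty(n)
    qpreds = {q: np.empty(n) for q in est.quantiles}
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            model = factory(params, est.random_state, None).fit(F[mask], y[mask])
            preds[i] = model.predict(F.iloc[i : i + 1])[0]
            for q in est.quantiles:
                qm = factory(params, est.random_state, q).fit(F[mask], y[mask])
                qpreds[q][i] = qm.predict(F.iloc[i : i + 1])[0]
        except Exception as exc:
            raise FitError(f"LOOCV fold {i} failed: {exc}", fold=i) from exc

    table = pd.DataFrame({"smiles": X, "y_true": y, "y_pred": preds})
    for q in est.quantiles:
        table[f"p{int(q)}"] = qpreds[q]
    return compute_metrics(y, preds), table


def max_tanimoto_to_reference(
    smiles: str,
    reference_fps: list[np.ndarray],
    spec: FingerprintSpec = BIT_FP_2048,
) -> float:
    """Maximum Tanimoto similarity of a query molecule to a reference set."""
    if not reference_fps:
        raise ValueError("reference fingerprint set is empty")
    fp = morgan_fingerprint(smiles, spec)
    return max(tanimoto(fp, ref) for ref in reference_fps)
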