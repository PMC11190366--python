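"""Log-log regression of the lethal electric-field threshold on pulse parameters.

The core model is a power law

    EFT = exp(c0) * p#^c1 * t_p^c2 * f^c3        (EFT in kV/cm)

fitted as ordinary least squares of ln(EFT) on (ln p#, ln t_p[µs], ln f[kHz])
with an intercept. The published full-precision coefficients are available as
the *frozen* model; :func:`fit_loglog` refits on any observation table, and
:func:`cross_validate` reproduces the shuffled 10-fold cross-validation used
to qualify the fit.

`LogLogEFTRegressor` is a scikit-learn estimator: ``X`` is an ``(n, 3)``
array of raw, positive ``(pulse_count, phase_duration_us, prf_khz)`` columns
(or a DataFrame with those columns) and ``y`` the threshold in kV/cm; the log
transforms happen inside the estimator, so it composes with sklearn model
selection directly on physical parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .datasets import ObservationTable, PulseTrain

__all__ = [
    "LogLogEFTRegressor",
    "CVReport",
    "ResidualReport",
    "FROZEN_COEFFICIENTS",
    "frozen_model",
    "log_features",
    "predict_eft",
    "fit_loglog",
    "cross_validate",
    "residual_diagnostics",
    "DegenerateDesignError",
]

#: Published full-precision coefficients (c0, c1, c2, c3) of the lethal-EFT
#: power law for biphasic trains on cardiomyocyte monolayers.
FROZEN_COEFFICIENTS = (
    2.4178579179273973,
    -0.3311596538518343,
    -0.5105374744505103,
    0.0200345703712249,
)

_FEATURE_NAMES = ("pulse_count", "phase_duration_us", "prf_khz")


class DegenerateDesignError(ValueError):
    """The design matrix is rank deficient; the message names the feature."""


def _as_param_matrix(X) -> np.ndarray:
    """Coerce input to an (n, 3) float array of raw pulse parameters."""
    if isinstance(X, pd.DataFrame):
        X = X[list(_FEATURE_NAMES)].to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(
            f"expected (n, 3) array of (pulse_count, phase_duration_us, prf_khz), "
            f"got shape {X.shape}"
        )
    if not np.all(np.isfinite(X)) or np.any(X <= 0):
        raise ValueError("all pulse parameters must be finite and strictly positive")
    return X


def log_features(train: PulseTrain) -> np.ndarray:
    """Feature vector (ln p#, ln t_p[µs], ln f[kHz]) for one pulse train."""
    return np.log(
        _as_param_matrix([[train.pulse_count, train.phase_duration, train.prf]])
    )[0]


class LogLogEFTRegressor(RegressorMixin, BaseEstimator):
    """Power-law (log-log OLS) regression of lethal EFT on pulse parameters.

    Parameters
    ----------
    response : {"ca_eft", "pi_eft"}
        Which stain's threshold :meth:`fit_table` uses. Calcein-AM is the
        study's reference stain; PI is available but non-default.

    Attributes
    ----------
    intercept_ : float
        c0 — log threshold (ln kV/cm) of a single 1 µs pulse at 1 kHz.
    coef_ : ndarray of shape (3,)
        (c1, c2, c3) — elasticities of the threshold with respect to pulse
        count, phase duration and PRF.
    provenance_ : {"fitted", "frozen-table"}
    """

    def __init__(self, response: str = "ca_eft"):
        self.response = response

    # -- sklearn interface ------------------------------------------------

    def fit(self, X, y):
        """OLS of ln(y) on log features. X holds raw positive parameters."""
        X = _as_param_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if X.shape[0] < 5:
            raise ValueError(f"need at least 5 observations, got {X.shape[0]}")
        if np.any(y <= 0):
            raise ValueError("responses must be strictly positive")
        L = np.log(X)
        for j, name in enumerate(_FEATURE_NAMES):
            if np.ptp(L[:, j]) == 0:
                raise DegenerateDesignError(
                    f"feature {name!r} takes a single value; "
                    "the log-log design is rank deficient"
                )
        A = np.column_stack([np.ones(len(L)), L])
        beta, _, rank, _ = np.linalg.lstsq(A, np.log(y), rcond=None)
        if rank < 4:
            raise DegenerateDesignError("log-feature design matrix is rank deficient")
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.n_features_in_ = 3
        self.provenance_ = "fitted"
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted lethal EFT in kV/cm (strictly positive)."""
        check_is_fitted(self, "coef_")
        L = np.log(_as_param_matrix(X))
        return np.exp(self.intercept_ + L @ self.coef_)

    def score(self, X, y, sample_weight=None) -> float:
        """R² of the fit **in log space**, the scale the model is trained on."""
        y = np.asarray(y, dtype=float).ravel()
        resid = np.log(y) - np.log(self.predict(X))
        ss_tot = np.sum((np.log(y) - np.log(y).mean()) ** 2)
        return 1.0 - float(np.sum(resid**2) / ss_tot)

    # -- domain interface -------------------------------------------------

    @classmethod
    def from_coefficients(
        cls, c0: float, c1: float, c2: float, c3: float, provenance: str = "fitted"
    ) -> "LogLogEFTRegressor":
        m = cls()
        m.intercept_ = float(c0)
        m.coef_ = np.array([c1, c2, c3], dtype=float)
        m.n_features_in_ = 3
        m.provenance_ = provenance
        return m

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        """(c0, c1, c2, c3)."""
        check_is_fitted(self, "coef_")
        return (self.intercept_, *map(float, self.coef_))

    def fit_table(self, table: ObservationTable) -> "LogLogEFTRegressor":
        """Fit on an observation table using the configured response stain."""
        X, y = _table_xy(table, self.response)
        return self.fit(X, y)

    def predict_train(self, train: PulseTrain) -> float:
        """Lethal EFT (kV/cm) for a single pulse train."""
        return float(
            self.predict([[train.pulse_count, train.phase_duration, train.prf]])[0]
        )


def frozen_model() -> LogLogEFTRegressor:
    """The published-coefficient predictor."""
    return LogLogEFTRegressor.from_coefficients(
        *FROZEN_COEFFICIENTS, provenance="frozen-table"
    )


def _table_xy(table: ObservationTable, response: str) -> tuple[np.ndarray, np.ndarray]:
    if response not in ("ca_eft", "pi_eft"):
        raise ValueError(f"response must be 'ca_eft' or 'pi_eft', got {response!r}")
    X, y = [], []
    for r in table:
        v = getattr(r, response)
        if math.isnan(v):
            raise ValueError(
                f"record {r.train.key} has no {response} value; cannot fit"
            )
        X.append([r.train.pulse_count, r.train.phase_duration, r.train.prf])
        y.append(v)
    return np.asarray(X, float), np.asarray(y, float)


def predict_eft(model: LogLogEFTRegressor, train: PulseTrain) -> float:
    """Lethal EFT in kV/cm for one pulse train under ``model``."""
    return model.predict_train(train)


def fit_loglog(table: ObservationTable, response: str = "ca_eft") -> LogLogEFTRegressor:
    """Ordinary least squares log-log fit on an observation table."""
    return LogLogEFTRegressor(response=response).fit_table(table)


@dataclass(frozen=True)
class CVReport:
    """Shuffled k-fold cross-validation summary.

    Held-out R² uses the training-set mean as the baseline (SS_tot about the
    training mean): with 5–6-point folds, a fold-local baseline is dominated
    by sampling noise. Training R² is the ordinary in-sample value. Both are
    computed in log space.
    """

    k: int
    seed: int
    r2_train_mean: float
    r2_train_sd: float
    r2_test_mean: float
    r2_test_sd: float
    fold_assignments: tuple[tuple[int, ...], ...]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "r2_train_mean": self.r2_train_mean,
            "r2_train_sd": self.r2_train_sd,
            "r2_test_mean": self.r2_test_mean,
            "r2_test_sd": self.r2_test_sd,
            "fold_assignments": [list(f) for f in self.fold_assignments],
        }


def cross_validate(
    table: ObservationTable,
    k: int = 10,
    seed: int = 0,
    response: str = "ca_eft",
) -> CVReport:
    """Shuffle records with ``seed``, split into ``k`` folds, refit per fold.

    Folds partition the record indices exactly; fold sizes differ by at most
    one. Deterministic for a fixed seed.
    """
    X, y = _table_xy(table, response)
    n = len(y)
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of records ({n})")
    logy = np.log(y)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    r2_train, r2_test, folds = [], [], []
    for train_idx, test_idx in kf.split(X):
        m = LogLogEFTRegressor().fit(X[train_idx], y[train_idx])
        pred_tr = np.log(m.predict(X[train_idx]))
        pred_te = np.log(m.predict(X[test_idx]))
        mu_tr = logy[train_idx].mean()
        ss = lambda a: float(np.sum(a**2))  # noqa: E731
        r2_train.append(
            1 - ss(logy[train_idx] - pred_tr) / ss(logy[train_idx] - mu_tr)
        )
        r2_test.append(
            1 - ss(logy[test_idx] - pred_te) / ss(logy[test_idx] - mu_tr)
        )
        folds.append(tuple(int(i) for i in test_idx))
    return CVReport(
        k=k,
        seed=seed,
        r2_train_mean=float(np.mean(r2_train)),
        r2_train_sd=float(np.std(r2_train)),
        r2_test_mean=float(np.mean(r2_test)),
        r2_test_sd=float(np.std(r2_test)),
        fold_assignments=tuple(folds),
    )


@dataclass(frozen=True)
class ResidualReport:
    """Per-condition prediction errors and parameter correlations.

    ``relative_errors`` use the *predicted* threshold as denominator.
    ``corr_*`` are Pearson correlations of the observed threshold with the
    raw (unlogged) pulse parameters.
    """

    predicted: np.ndarray  # kV/cm
    observed: np.ndarray  # kV/cm
    absolute_errors: np.ndarray  # kV/cm
    relative_errors: np.ndarray  # fraction of predicted
    max_abs_err: float
    max_rel_err: float
    corr_tp: float
    corr_pnum: float
    corr_prf: float

    def to_dict(self) -> dict:
        return {
            "max_abs_err_kvcm": self.max_abs_err,
            "max_rel_err": self.max_rel_err,
            "corr_phase_duration": self.corr_tp,
            "corr_pulse_count": self.corr_pnum,
            "corr_prf": self.corr_prf,
            "predicted_kvcm": self.predicted.tolist(),
            "observed_kvcm": self.observed.tolist(),
            "absolute_errors_kvcm": self.absolute_errors.tolist(),
            "relative_errors": self.relative_errors.tolist(),
        }


def residual_diagnostics(
    model: LogLogEFTRegressor,
    table: ObservationTable,
    response: str = "ca_eft",
) -> ResidualReport:
    """Evaluate ``model`` against every condition in ``table``."""
    X, y = _table_xy(table, response)
    if len(y) == 0:
        raise ValueError("observation table is empty")
    pred = model.predict(X)
    abs_err = np.abs(y - pred)
    rel_err = abs_err / pred
    corr = lambda a, b: float(np.corrcoef(a, b)[0, 1])  # noqa: E731
    return ResidualReport(
        predicted=pred,
        observed=y,
        absolute_errors=abs_err,
        relative_errors=rel_err,
        max_abs_err=float(abs_err.max()),
        max_rel_err=float(rel_err.max()),
        corr_tp=corr(X[:, 1], y),
        corr_pnum=corr(X[:, 0], y),
        corr_prf=corr(X[:, 2], y),
    )
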