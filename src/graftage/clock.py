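"""The epigenetic clock: calibrated age transform, training, prediction.

A multi-tissue epigenetic clock is a penalized linear regression of a
calibrated age transform on CpG beta values.  The calibration F maps
chronologic age onto a scale that is logarithmic through development and
linear in adulthood, anchored so F(adult_age) = 0:

    F(a) = log(a + 1) - log(adult_age + 1)      for a <= adult_age
    F(a) = (a - adult_age) / (adult_age + 1)    for a >  adult_age

F is continuous, strictly increasing on (-1, inf), and has a closed-form
inverse, so predicted transformed ages map back to years.  Training fits
F(age) ~ betas with an elastic-net penalty whose strength is chosen by
seeded k-fold cross-validation; the fitted model is sparse, keeping only
age-associated CpGs.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .errors import CoverageError, DegenerateDataError, ValidationError
from .io import BetaMatrix, ClockModel

__all__ = [
    "DEFAULT_ADULT_AGE",
    "transform_age",
    "inverse_transform_age",
    "train_clock",
    "predict_age",
]

DEFAULT_ADULT_AGE = 20.0


def transform_age(age, adult_age: float = DEFAULT_ADULT_AGE):
    """Calibrated age transform F; vectorized over ``age``.

    Raises :class:`ValidationError` for ages <= -1 (outside F's domain).
    """
    if adult_age <= 0:
        raise ValidationError("adult_age must be positive")
    a = np.asarray(age, dtype=float)
    if np.any(a <= -1):
        raise ValidationError("age must be > -1 for the log calibration")
    out = np.where(
        a <= adult_age,
        np.log1p(a) - np.log1p(adult_age),
        (a - adult_age) / (adult_age + 1.0),
    )
    return out if out.ndim else float(out)


def inverse_transform_age(t, adult_age: float = DEFAULT_ADULT_AGE):
    """Inverse of :func:`transform_age`: transformed scale back to years."""
    if adult_age <= 0:
        raise ValidationError("adult_age must be positive")
    x = np.asarray(t, dtype=float)
    out = np.where(
        x <= 0,
        np.expm1(x + np.log1p(adult_age)),
        adult_age + x * (adult_age + 1.0),
    )
    return out if out.ndim else float(out)


def train_clock(
    betas: BetaMatrix,
    ages,
    *,
    adult_age: float = DEFAULT_ADULT_AGE,
    l1_ratio: float = 0.5,
    alpha: float | None = None,
    n_alphas: int = 50,
    cv: int = 10,
    one_se_rule: bool = True,
    seed: int = 0,
    max_iter: int = 50000,
) -> ClockModel:
    """Fit an elastic-net clock of F(age) on beta values.

    Parameters
    ----------
    betas : training beta matrix (samples x CpGs), no missing values.
    ages : chronologic ages in years, one per sample.
    l1_ratio : elastic-net mixing (1 = lasso, 0 = ridge); default 0.5.
    alpha : fixed penalty strength.  When None (default) the strength is
        chosen on a log-spaced path by ``cv``-fold cross-validation; with
        ``one_se_rule`` ties are broken toward the strongest penalty whose
        CV error is within one standard error of the minimum.
    seed : seeds the CV fold shuffle, making training deterministic.

    Returns a :class:`ClockModel` whose ``training_meta`` records per-CpG
    training means (for imputation at prediction time), the chosen penalty,
    and the nonzero-CpG count.
    """
    y_age = np.asarray(ages, dtype=float)
    if y_age.size != betas.shape[0]:
        raise ValidationError(
            f"{betas.shape[0]} samples but {y_age.size} ages"
        )
    if y_age.size < 10:
        raise ValidationError("need >= 10 training samples")
    if np.allclose(y_age, y_age[0]):
        raise DegenerateDataError("training ages are constant")
    X = betas.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("training betas contain missing values")
    y = transform_age(y_age, adult_age)

    n = X.shape[0]
    folds = KFold(n_splits=min(cv, n), shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if alpha is None:
            cv_fit = ElasticNetCV(
                l1_ratio=l1_ratio, alphas=n_alphas, cv=folds,
                max_iter=max_iter, random_state=seed,
            ).fit(X, y)
            chosen = float(cv_fit.alpha_)
            if one_se_rule:
                # largest alpha whose mean CV MSE is within 1 SE of the best
                mse = cv_fit.mse_path_.mean(axis=1)
                se = cv_fit.mse_path_.std(axis=1, ddof=1) / np.sqrt(
                    cv_fit.mse_path_.shape[1]
                )
                best = int(np.argmin(mse))
                ok = np.flatnonzero(mse <= mse[best] + se[best])
                # alphas_ are sorted descending: smallest index = strongest
                chosen = float(cv_fit.alphas_[ok.min()])
            fit = ElasticNet(alpha=chosen, l1_ratio=l1_ratio,
                             max_iter=max_iter).fit(X, y)
        else:
            chosen = float(alpha)
            fit = ElasticNet(alpha=chosen, l1_ratio=l1_ratio,
                             max_iter=max_iter).fit(X, y)

    weights = np.asarray(fit.coef_, dtype=float)
    model = ClockModel(
        cpg_ids=betas.cpg_ids,
        weights=weights,
        intercept=float(fit.intercept_),
        adult_age=float(adult_age),
        training_meta={
            "cpg_means": X.mean(axis=0),
            "alpha": chosen,
            "l1_ratio": float(l1_ratio),
            "n_train": int(n),
            "n_nonzero": int(np.count_nonzero(weights)),
            "seed": int(seed),
        },
    )
    return model


def predict_age(
    model: ClockModel,
    betas: BetaMatrix,
    *,
    min_overlap: float = 0.9,
) -> np.ndarray:
    """Predict epigenetic age in years for each sample of ``betas``.

    Prediction is per-sample: ``inverse_transform(b0 + sum_j w_j beta_ij)``.
    CpG columns are matched by id, so column order is irrelevant.  Model CpGs
    absent from the matrix (or missing in a sample) are imputed with the
    clock's stored training means; a warning reports the imputed fraction.
    If fewer than ``min_overlap`` of the model's CpGs are present a
    :class:`CoverageError` lists what is missing.
    """
    cols = {c: i for i, c in enumerate(betas.cpg_ids)}
    present = [c for c in model.cpg_ids if c in cols]
    missing = [c for c in model.cpg_ids if c not in cols]
    frac_present = len(present) / len(model.cpg_ids)
    if frac_present < min_overlap:
        raise CoverageError(
            f"only {frac_present:.1%} of clock CpGs present "
            f"(need >= {min_overlap:.0%}); {len(missing)} missing",
            missing=missing,
        )

    means = model.training_means()
    X = np.empty((betas.shape[0], len(model.cpg_ids)), dtype=float)
    for j, cpg in enumerate(model.cpg_ids):
        if cpg in cols:
            X[:, j] = betas.values.iloc[:, cols[cpg]].to_numpy(dtype=float)
        else:
            X[:, j] = np.nan
    nan_mask = np.isnan(X)
    n_imputed = int(nan_mask.sum())
    if n_imputed:
        if means is None:
            raise CoverageError(
                "missing clock CpGs but model carries no training means "
                "to impute with", missing=missing,
            )
        X = np.where(nan_mask, np.broadcast_to(means, X.shape), X)
        warnings.warn(
            f"imputed {n_imputed / X.size:.2%} of clock beta entries with "
            f"training means ({len(missing)} probes absent)",
            stacklevel=2,
        )
    t = model.intercept + X @ model.weights
    return np.asarray(inverse_transform_age(t, model.adult_age), dtype=float)
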