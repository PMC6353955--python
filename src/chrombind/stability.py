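"""Lasso stability selection of MBF-predictive sequence features.

The model is a lasso-penalized linear regression of log(MBF) on the
normalized feature matrix.  One run draws a random train/holdout split
(e.g. 401 train / 100 holdout TFs), selects the penalty by K-fold
cross-validation on the training rows, and records which coefficients are
nonzero plus the holdout predictions.  Repeating the run many times (500
in the reference protocol) yields a per-feature retention frequency;
features retained in at least 90% of the runs are called stably selected.
Retention is judged on a *nonzero* coefficient — negative associations
(e.g. hydrophobic content) are selected too, with the sign reported via
the mean coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted


@dataclass
class StabilityResult:
    feature_names: list[str]
    retention_frequency: np.ndarray
    mean_coefficient: np.ndarray
    selected: np.ndarray  # boolean
    holdout_predictions: pd.DataFrame  # columns: run, row, y_true, y_pred
    n_runs: int

    @property
    def selected_features(self) -> list[str]:
        return [f for f, s in zip(self.feature_names, self.selected) if s]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def fit_lasso_once(
    X,
    y,
    train_ids,
    seed: int | None = None,
    cv: int = 10,
    n_alphas: int = 60,
    penalty_rule: str = "1se",
    eps: float = 1e-3,
    tol: float = 1e-4,
):
    """One lasso fit: CV-selected penalty on the training rows, holdout predictions.

    The penalty is chosen by K-fold cross-validation on the training rows;
    ``penalty_rule="1se"`` (default) takes the sparsest penalty whose CV
    error is within one standard error of the minimum — the standard rule
    when the goal is support recovery rather than pure prediction —
    while ``"min"`` takes the CV-error minimizer.  Predictors are
    standardized on the training rows before penalization; coefficients
    are returned on the original feature scale.  Returns ``(coef,
    intercept, holdout_pred)`` where ``holdout_pred`` is a DataFrame with
    columns ``row``, ``y_true``, ``y_pred``.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if len(X) < 20:
        raise ValueError("need at least 20 rows")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    train_ids = np.asarray(train_ids, dtype=int)
    mask = np.zeros(len(X), dtype=bool)
    mask[train_ids] = True
    Xtr = X.values[mask]
    ytr = y[mask]

    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    keep = sd > 0  # constant (e.g. all-zero) columns get coefficient 0
    Xs = (Xtr[:, keep] - mu[keep]) / sd[keep]

    model = LassoCV(
        cv=KFold(n_splits=cv, shuffle=True, random_state=None if seed is None else seed % (2**32)),
        alphas=n_alphas,
        eps=eps,
        max_iter=5000,
        tol=tol,
    )
    model.fit(Xs, ytr)

    if penalty_rule == "1se":
        mse_mean = model.mse_path_.mean(axis=1)
        mse_se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
        best = int(np.argmin(mse_mean))
        # alphas_ are descending; the sparsest admissible penalty is the largest
        admissible = np.flatnonzero(mse_mean <= mse_mean[best] + mse_se[best])
        alpha = float(model.alphas_[admissible.min()])
        final = Lasso(alpha=alpha, max_iter=5000, tol=1e-6)
        final.fit(Xs, ytr)
        fitted_coef, fitted_intercept = final.coef_, float(final.intercept_)
    elif penalty_rule == "min":
        fitted_coef, fitted_intercept = model.coef_, float(model.intercept_)
    else:
        raise ValueError("penalty_rule must be '1se' or 'min'")

    coef = np.zeros(X.shape[1])
    coef[keep] = fitted_coef / sd[keep]
    # coordinate descent can leave numerically-zero dust on redundant columns
    coef[np.abs(coef) < 1e-10 * max(1.0, np.abs(coef).max())] = 0.0
    intercept = float(fitted_intercept - np.dot(coef[keep], mu[keep]))

    hold = np.flatnonzero(~mask)
    y_pred = X.values[hold] @ coef + intercept
    holdout = pd.DataFrame({"row": hold, "y_true": y[hold], "y_pred": y_pred})
    return coef, intercept, holdout


class StabilityLasso(BaseEstimator):
    """Repeated-split lasso stability selection (scikit-learn estimator).

    Parameters
    ----------
    n_runs : int
        Number of independent train/holdout splits (reference protocol: 500).
    holdout_size : int
        Rows held out per run (reference protocol: 100 of 501).
    retention_threshold : float
        Minimum fraction of runs with a nonzero coefficient for a feature
        to be called selected (reference protocol: 0.9).
    cv : int
        Folds of the per-run penalty cross-validation.
    fixed_split : bool
        Reuse the first split for every run instead of redrawing.
    random_state : int or None
        Master seed; per-run substreams are spawned from it.
    """

    def __init__(
        self,
        n_runs: int = 500,
        holdout_size: int = 100,
        retention_threshold: float = 0.9,
        cv: int = 10,
        n_alphas: int = 60,
        penalty_rule: str = "1se",
        fixed_split: bool = False,
        random_state: int | None = None,
    ):
        self.n_runs = n_runs
        self.holdout_size = holdout_size
        self.retention_threshold = retention_threshold
        self.cv = cv
        self.n_alphas = n_alphas
        self.penalty_rule = penalty_rule
        self.fixed_split = fixed_split
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.holdout_size >= len(X):
            raise ValueError("holdout_size must be smaller than the number of rows")
        n, p = X.shape
        master = np.random.SeedSequence(self.random_state)
        streams = master.spawn(self.n_runs)

        nonzero = np.zeros(p)
        coef_sum = np.zeros(p)
        holdouts = []
        first_split: np.ndarray | None = None
        for run, ss in enumerate(streams):
            rng = np.random.default_rng(ss)
            if self.fixed_split and first_split is not None:
                train = first_split
            else:
                train = rng.permutation(n)[self.holdout_size:]
                if first_split is None:
                    first_split = train
            run_seed = int(ss.generate_state(1)[0] % (2**31))
            coef, _, hold = fit_lasso_once(
                X, y, train, seed=run_seed, cv=self.cv, n_alphas=self.n_alphas,
                penalty_rule=self.penalty_rule,
            )
            nonzero += coef != 0
            coef_sum += coef
            hold.insert(0, "run", run)
            holdouts.append(hold)

        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = p
        self.retention_frequency_ = nonzero / self.n_runs
        self.mean_coefficient_ = coef_sum / self.n_runs
        self.selected_ = self.retention_frequency_ >= self.retention_threshold
        self.holdout_predictions_ = pd.concat(holdouts, ignore_index=True)
        self.n_runs_ = self.n_runs
        return self

    def transform(self, X):
        """Reduce a feature matrix to the stably selected columns."""
        check_is_fitted(self, "selected_")
        X = _as_frame(X)
        return X.loc[:, self.selected_]

    def get_support(self):
        check_is_fitted(self, "selected_")
        return self.selected_

    def result_(self) -> StabilityResult:
        check_is_fitted(self, "selected_")
        return StabilityResult(
            feature_names=list(self.feature_names_in_),
            retention_frequency=self.retention_frequency_,
            mean_coefficient=self.mean_coefficient_,
            selected=self.selected_,
            holdout_predictions=self.holdout_predictions_,
            n_runs=self.n_runs_,
        )


def stability_select(
    X,
    y,
    n_runs: int = 500,
    holdout_size: int = 100,
    retention_threshold: float = 0.9,
    seed: int | None = None,
    **kwargs,
) -> StabilityResult:
    """Functional wrapper around :class:`StabilityLasso`."""
    est = StabilityLasso(
        n_runs=n_runs,
        holdout_size=holdout_size,
        retention_threshold=retention_threshold,
        random_state=seed,
        **kwargs,
    )
    est.fit(X, y)
    return est.result_()
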