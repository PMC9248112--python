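"""The proteomic gestational-age clock.

A sparse linear predictor of gestational age (weeks) from protein log2
abundances plus mandatory clinical covariates (maternal age, BMI,
nulliparity). Protein selection uses stability selection over elastic-net
regularization paths: the training participants are repeatedly subsampled
(half of them at a time, always at the participant level because visits of
one participant are dependent), an elastic-net path of GA on the
standardized candidate proteins is fitted on each subsample, and a protein
counts as selected in that subsample if it enters the active set while the
active set is still small enough to bound the per-family error rate. The
stable set is the proteins selected in at least a fraction ``pi`` of
subsamples.

Mandatory covariates are kept unpenalized by partialling them out
(Frisch–Waugh): within each subsample the response and every candidate
protein are replaced by their residuals after OLS on the covariates, and the
penalized path is run on the residuals.

The final clock is an ordinary least-squares fit of GA on the stable
proteins plus the covariates, evaluated by leave-one-participant-out
cross-validation on the training cohort and on a held-out validation cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import enet_path

from .errors import DataError, FitError, InsufficientDataError

MANDATORY_COVARIATES = ("age_years", "bmi", "nulliparity")

__all__ = [
    "MANDATORY_COVARIATES",
    "ClockModel",
    "StabilitySelector",
    "GestationalAgeClock",
    "split_participants",
    "enss_select",
    "fit_clock",
    "lopo_cv",
    "evaluate_clock",
    "build_clock",
]


def split_participants(participant_ids, train_fraction: float = 2.0 / 3.0,
                       seed: int = 0) -> tuple[list, list]:
    """Disjoint participant-level train/validation split.

    All visits of a participant land on the same side. Train size is
    round(train_fraction × n); the split is a deterministic function of
    ``seed``.
    """
    ids = list(pd.unique(pd.Series(list(participant_ids))))
    n = len(ids)
    if n < 6:
        raise InsufficientDataError(f"need >= 6 participants to split, got {n}")
    if not 0.0 < train_fraction < 1.0:
        raise DataError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    train = [ids[i] for i in sorted(order[:n_train])]
    val = [ids[i] for i in sorted(order[n_train:])]
    return train, val


class StabilitySelector(BaseEstimator):
    """Stability selection over elastic-net paths with participant subsampling.

    Parameters
    ----------
    pi : float
        Selection-frequency threshold in (0.5, 1]. Default 0.6.
    n_subsamples : int
        Number of half-cohort subsamples. Default 100.
    l1_ratio : float
        Elastic-net mixing weight (1 = lasso). Default 0.5.
    n_alphas : int
        Length of each regularization path. Default 50.
    pfer : float
        Per-family error-rate bound E[V]; caps the admissible active-set
        size per subsample at q = floor(sqrt(pfer · (2·pi − 1) · p)).
    random_state : int
        Seed for the subsampling.

    Attributes
    ----------
    selection_frequency_ : pd.Series
        Fraction of subsamples in which each candidate entered the bounded
        active set.
    selected_ : list[str]
        Candidates with frequency >= ``pi``.
    q_ : int
        Active-set size bound used per subsample.
    """

    def __init__(self, pi: float = 0.6, n_subsamples: int = 100,
                 l1_ratio: float = 0.5, n_alphas: int = 50,
                 pfer: float = 1.0, random_state: int = 0):
        self.pi = pi
        self.n_subsamples = n_subsamples
        self.l1_ratio = l1_ratio
        self.n_alphas = n_alphas
        self.pfer = pfer
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y, groups, mandatory=MANDATORY_COVARIATES):
        """Select stable predictors of ``y`` among the non-mandatory columns of ``X``.

        ``groups`` are participant ids aligned with the rows of ``X``;
        ``mandatory`` columns of ``X`` are kept unpenalized in every subfit.
        """
        if not 0.5 < self.pi <= 1.0:
            raise DataError(f"pi must be in (0.5, 1], got {self.pi}")
        y = np.asarray(y, float)
        groups = np.asarray(groups)
        mandatory = [m for m in mandatory if m in X.columns]
        candidates = [c for c in X.columns if c not in mandatory]
        p = len(candidates)
        uniq = pd.unique(groups)
        if len(uniq) < 10:
            raise InsufficientDataError(
                f"need >= 10 training participants for stability selection, got {len(uniq)}"
            )
        self.q_ = max(1, int(np.floor(np.sqrt(self.pfer * (2 * self.pi - 1) * p))))
        rng = np.random.default_rng(self.random_state)
        half = len(uniq) // 2

        Xc = X[candidates].to_numpy(float)
        Z = np.column_stack([np.ones(len(X))] +
                            [X[m].to_numpy(float) for m in mandatory])
        counts = np.zeros(p)
        for _ in range(self.n_subsamples):
            keep = rng.choice(uniq, size=half, replace=False)
            rows = np.isin(groups, keep)
            Zs, ys, Xs = Z[rows], y[rows], Xc[rows]
            # partial out the mandatory covariates (unpenalized by construction)
            beta, *_ = np.linalg.lstsq(Zs, ys, rcond=None)
            y_res = ys - Zs @ beta
            gamma, *_ = np.linalg.lstsq(Zs, Xs, rcond=None)
            X_res = Xs - Zs @ gamma
            sd = X_res.std(axis=0)
            ok = sd > 0
            X_std = np.zeros_like(X_res)
            X_std[:, ok] = X_res[:, ok] / sd[ok]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, coefs, _ = enet_path(X_std, y_res, l1_ratio=self.l1_ratio,
                                        n_alphas=self.n_alphas)
            active_size = (coefs != 0).sum(axis=0)  # per alpha, alphas decreasing
            admissible = active_size <= self.q_
            if admissible.any():
                hit = (coefs[:, admissible] != 0).any(axis=1)
                counts[hit] += 1

        self.selection_frequency_ = pd.Series(counts / self.n_subsamples,
                                              index=candidates, name="selection_frequency")
        self.selected_ = list(self.selection_frequency_.index[
            self.selection_frequency_ >= self.pi])
        return self


def enss_select(train: pd.DataFrame, candidates, mandatory=MANDATORY_COVARIATES,
                pi: float = 0.6, n_subsamples: int = 100,
                seed: int = 0, **kwargs) -> tuple[pd.Series, list]:
    """Stability-select gestational-age predictors on a training table.

    ``train`` is a long-format longitudinal table with ``ga_weeks``,
    ``participant_id``, the covariates and candidate protein columns.
    Returns (selection frequencies, stable set).
    """
    missing = [c for c in candidates if c not in train.columns]
    if missing:
        raise DataError(f"candidate proteins missing from table: {missing[:5]}")
    cols = list(mandatory) + list(candidates)
    sel = StabilitySelector(pi=pi, n_subsamples=n_subsamples,
                            random_state=seed, **kwargs)
    sel.fit(train[cols], train["ga_weeks"], train["participant_id"],
            mandatory=mandatory)
    return sel.selection_frequency_, sel.selected_


class GestationalAgeClock(BaseEstimator, RegressorMixin):
    """OLS linear model: GA (weeks) ~ selected proteins + clinical covariates.

    Coefficients are on the original (unstandardized) scales, so each protein
    coefficient reads as weeks per log2 RFU and each covariate coefficient as
    weeks per covariate unit.

    Parameters
    ----------
    proteins : list[str]
        Selected protein columns.
    covariates : list[str]
        Mandatory clinical covariates, always included.

    Attributes
    ----------
    coef_ : pd.Series  — one entry per predictor column.
    intercept_ : float
    """

    def __init__(self, proteins=(), covariates=MANDATORY_COVARIATES):
        self.proteins = proteins
        self.covariates = covariates

    @property
    def _columns(self) -> list[str]:
        return list(self.proteins) + list(self.covariates)

    def fit(self, X: pd.DataFrame, y):
        cols = self._columns
        if not cols:
            raise DataError("clock needs at least one predictor column")
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise DataError(f"predictor columns missing: {missing}")
        A = np.column_stack([np.ones(len(X)), X[cols].to_numpy(float)])
        if np.linalg.matrix_rank(A) < A.shape[1]:
            raise FitError(f"collinear clock design over columns {cols}")
        beta, *_ = np.linalg.lstsq(A, np.asarray(y, float), rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = pd.Series(beta[1:], index=cols)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self._columns if c not in X.columns]
        if missing:
            raise DataError(f"predictor columns missing: {missing}")
        return self.intercept_ + X[self._columns].to_numpy(float) @ self.coef_.to_numpy()


@dataclass
class ClockModel:
    """A fitted proteomic clock with its selection provenance and performance."""

    selected_proteins: list
    protein_coefficients: dict
    covariate_coefficients: dict
    intercept: float
    stability_threshold: float
    selection_frequency: dict = field(default_factory=dict)
    performance: dict = field(default_factory=dict)
    seed: int | None = None
    estimator: GestationalAgeClock | None = field(default=None, repr=False)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(X)

    def equation(self) -> str:
        terms = [f"{self.intercept:.5f}"]
        terms += [f"{name}*{coef:.5f}" for name, coef in
                  {**self.protein_coefficients, **self.covariate_coefficients}.items()]
        return "GA in weeks = " + " + ".join(terms)


def fit_clock(train: pd.DataFrame, selected_proteins,
              covariates=MANDATORY_COVARIATES,
              pi: float = 0.6, selection_frequency=None,
              seed: int | None = None) -> ClockModel:
    """OLS fit of the clock on training samples."""
    selected_proteins = list(selected_proteins)
    if not selected_proteins and not covariates:
        raise DataError("no predictors: selected set empty and no covariates")
    est = GestationalAgeClock(proteins=selected_proteins,
                              covariates=list(covariates))
    est.fit(train, train["ga_weeks"])
    return ClockModel(
        selected_proteins=selected_proteins,
        protein_coefficients={p: float(est.coef_[p]) for p in selected_proteins},
        covariate_coefficients={c: float(est.coef_[c]) for c in covariates},
        intercept=est.intercept_,
        stability_threshold=pi,
        selection_frequency=(dict(selection_frequency)
                             if selection_frequency is not None else {}),
        seed=seed,
        estimator=est,
    )


def _pearson(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def lopo_cv(train: pd.DataFrame, selected_proteins, covariates=MANDATORY_COVARIATES
            ) -> tuple[float, float, pd.DataFrame]:
    """Leave-one-participant-out CV of the clock on the training cohort.

    Each fold refits the OLS clock without one participant and predicts all
    of that participant's visits; performance is computed on the pooled
    held-out predictions. Folds whose refit fails are flagged, excluded and
    counted in the returned prediction table's attrs.
    """
    participants = pd.unique(train["participant_id"])
    if len(participants) < 3:
        raise InsufficientDataError("leave-one-participant-out CV needs >= 3 participants")
    preds, failed = [], []
    for pid in participants:
        held = train["participant_id"] == pid
        try:
            model = fit_clock(train.loc[~held], selected_proteins, covariates)
        except (FitError, DataError) as exc:
            failed.append((pid, str(exc)))
            continue
        out = train.loc[held, ["participant_id", "visit", "ga_weeks"]].copy()
        out["ga_predicted"] = model.predict(train.loc[held])
        preds.append(out)
    table = pd.concat(preds, ignore_index=True)
    table.attrs["failed_folds"] = failed
    r_cv = _pearson(table["ga_predicted"], table["ga_weeks"])
    rmse = float(np.sqrt(np.mean((table["ga_predicted"] - table["ga_weeks"]) ** 2)))
    return r_cv, rmse, table


def evaluate_clock(model: ClockModel, validation: pd.DataFrame
                   ) -> tuple[float, float, pd.DataFrame]:
    """Frozen-model performance on a held-out cohort.

    Returns (Pearson r, RMSE in weeks, prediction table). A constant
    prediction vector makes r undefined; it is returned as NaN with
    ``degenerate`` set in the table's attrs, while RMSE is still reported.
    """
    preds = model.predict(validation)
    table = validation[["participant_id", "visit", "ga_weeks"]].copy()
    table["ga_predicted"] = preds
    r = _pearson(preds, validation["ga_weeks"])
    table.attrs["degenerate"] = bool(np.isnan(r))
    rmse = float(np.sqrt(np.mean((preds - validation["ga_weeks"]) ** 2)))
    return r, rmse, table


@dataclass
class ClockWorkflowResult:
    """End-to-end clock build: split, selection, fit, CV and validation."""

    model: ClockModel
    train_ids: list
    validation_ids: list
    r_cv: float
    rmse_cv: float
    r_validation: float
    rmse_validation: float


def build_clock(data: pd.DataFrame, candidates, covariates=MANDATORY_COVARIATES,
                pi: float = 0.6, n_subsamples: int = 100,
                train_fraction: float = 2.0 / 3.0, seed: int = 17,
                **kwargs) -> ClockWorkflowResult:
    """Full clock workflow on a longitudinal table.

    Participant-level 2/3 split, stability selection on the training side,
    OLS clock fit, leave-one-participant-out CV, and frozen evaluation on
    the held-out third.
    """
    train_ids, val_ids = split_participants(data["participant_id"],
                                            train_fraction=train_fraction, seed=seed)
    train = data[data["participant_id"].isin(train_ids)]
    val = data[data["participant_id"].isin(val_ids)]
    freq, selected = enss_select(train, candidates, mandatory=covariates,
                                 pi=pi, n_subsamples=n_subsamples, seed=seed, **kwargs)
    model = fit_clock(train, selected, covariates, pi=pi,
                      selection_frequency=freq, seed=seed)
    r_cv, rmse_cv, _ = lopo_cv(train, selected, covariates)
    r_val, rmse_val, _ = evaluate_clock(model, val)
    model.performance = {"r_cv": r_cv, "rmse_cv": rmse_cv,
                         "r_validation": r_val, "rmse_validation": rmse_val}
    return ClockWorkflowResult(model=model, train_ids=train_ids, validation_ids=val_ids,
                               r_cv=r_cv, rmse_cv=rmse_cv,
                               r_validation=r_val, rmse_validation=rmse_val)
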