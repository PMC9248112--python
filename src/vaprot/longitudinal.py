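"""Gestational trajectories: spline mixed models and curve clustering.

Each protein's log2 abundance across gestation is modeled with a linear
mixed-effects model: a fixed intercept plus a cubic B-spline basis of
gestational age as fixed effects, and a participant-level random intercept
absorbing stable between-participant abundance differences. The fixed part
evaluated on a gestational-age grid is the protein's mean trajectory.

Mean trajectories are compared by shape: pairwise distance 1 − Pearson
correlation across the grid, complete-linkage hierarchical clustering, and
the number of clusters chosen by maximizing the mean silhouette width
computed on the same distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.metrics import silhouette_score
import statsmodels.api as sm

from .errors import DataError, FitError, InsufficientDataError, UsageError
from .preprocess import protein_columns

__all__ = [
    "CurveFit",
    "ClusterResult",
    "TrajectoryClusterer",
    "fit_protein_curve",
    "fit_all_curves",
    "evaluate_mean_curves",
    "cluster_mean_curves",
    "scale_curves_to_zero_start",
    "default_ga_grid",
]


@dataclass
class CurveFit:
    """Fitted mean gestational trajectory of one protein."""

    seq_id: str
    ga_grid: np.ndarray
    mean_curve: np.ndarray
    fixed_coefficients: np.ndarray
    random_intercept_sd: float
    residual_sd: float
    spline_df: int
    converged: bool
    message: str = ""


def default_ga_grid(ga_weeks, spacing: float = 0.5) -> np.ndarray:
    """Half-week grid spanning the observed gestational-age range."""
    lo, hi = float(np.min(ga_weeks)), float(np.max(ga_weeks))
    return np.arange(lo, hi + 1e-9, spacing)


def fit_protein_curve(
    data: pd.DataFrame,
    protein: str,
    spline_df: int = 3,
    ga_grid: np.ndarray | None = None,
) -> CurveFit:
    """REML fit of one protein's spline mixed model.

    ``data`` is a long-format longitudinal table with ``participant_id`` and
    ``ga_weeks`` columns. The fixed design is an intercept plus a cubic
    B-spline basis of gestational age with ``spline_df`` columns (boundary
    knots at the observed GA extremes, no interior knots at the default
    df=3); the random part is a participant intercept. Non-convergence is
    reported on the returned :class:`CurveFit`, not raised.
    """
    if protein not in data.columns:
        raise DataError(f"protein {protein!r} not in table")
    sub = data[["participant_id", "ga_weeks", protein]].dropna()
    visits = sub.groupby("participant_id").size()
    if (visits >= 2).sum() < 10:
        raise InsufficientDataError(
            "need >= 10 participants with >= 2 visits for a mixed-model fit"
        )
    ga = sub["ga_weeks"].to_numpy(float)
    if np.ptp(ga) == 0:
        raise FitError(
            "all gestational ages identical: spline design is rank-deficient"
        )
    if ga_grid is None:
        ga_grid = default_ga_grid(ga)

    basis = dmatrix(
        "bs(ga_weeks, df=df, degree=3, include_intercept=False)",
        {"ga_weeks": ga, "df": spline_df},
        return_type="dataframe",
    )
    X = np.asarray(basis)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("spline design is rank-deficient for this GA distribution")
    (X_grid,) = build_design_matrices([basis.design_info], {"ga_weeks": ga_grid, "df": spline_df})
    X_grid = np.asarray(X_grid)

    y = sub[protein].to_numpy(float)
    if np.ptp(y) == 0:
        # constant response: REML is singular but the answer is exact
        fe = np.zeros(X.shape[1])
        fe[0] = y[0]
        return CurveFit(seq_id=protein, ga_grid=np.asarray(ga_grid, float),
                        mean_curve=X_grid @ fe, fixed_coefficients=fe,
                        random_intercept_sd=0.0, residual_sd=0.0,
                        spline_df=spline_df, converged=True,
                        message="constant response")
    converged, message = True, ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, X, groups=sub["participant_id"].to_numpy())
            res = model.fit(reml=True)
            converged = bool(getattr(res, "converged", True))
            if not converged:
                for method in ("lbfgs", "powell"):
                    try:
                        retry = model.fit(reml=True, method=method)
                    except Exception:  # noqa: BLE001 - keep the original fit
                        continue
                    if getattr(retry, "converged", False):
                        res, converged = retry, True
                        break
            fe = np.asarray(res.fe_params)
            ri_sd = float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0)))
            resid_sd = float(np.sqrt(max(res.scale, 0.0)))
            if not converged and np.all(np.isfinite(fe)) and np.isfinite(resid_sd):
                # optimizer flag at a variance boundary (e.g. zero residual or
                # zero intercept variance); estimates are finite and usable
                converged, message = True, "variance at boundary"
        except Exception as exc:  # noqa: BLE001 - fit failures are data, not bugs
            converged, message = False, str(exc)
            fe = np.full(X.shape[1], np.nan)
            ri_sd, resid_sd = float("nan"), float("nan")

    return CurveFit(
        seq_id=protein,
        ga_grid=np.asarray(ga_grid, float),
        mean_curve=X_grid @ fe,
        fixed_coefficients=fe,
        random_intercept_sd=ri_sd,
        residual_sd=resid_sd,
        spline_df=spline_df,
        converged=converged,
        message=message,
    )


def fit_all_curves(
    data: pd.DataFrame,
    proteins: list[str] | None = None,
    spline_df: int = 3,
    ga_grid: np.ndarray | None = None,
) -> list[CurveFit]:
    """Fit :func:`fit_protein_curve` for each protein on a shared grid."""
    if proteins is None:
        proteins = protein_columns(data)
    if ga_grid is None:
        ga_grid = default_ga_grid(data["ga_weeks"])
    return [fit_protein_curve(data, p, spline_df=spline_df, ga_grid=ga_grid)
            for p in proteins]


def evaluate_mean_curves(fits: list[CurveFit], ga_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Assemble converged mean curves into a proteins × grid matrix.

    Non-converged fits are excluded with a warning reporting their count;
    mismatched grids are a usage error.
    """
    if not fits:
        raise UsageError("no curve fits supplied")
    if ga_grid is None:
        ga_grid = fits[0].ga_grid
    kept, dropped = [], 0
    for f in fits:
        if f.ga_grid.shape != np.shape(ga_grid) or not np.allclose(f.ga_grid, ga_grid):
            raise UsageError(f"curve fit {f.seq_id!r} is on a different GA grid")
        if f.converged and np.all(np.isfinite(f.mean_curve)):
            kept.append(f)
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"excluded {dropped} non-converged curve fit(s)", stacklevel=2)
    if not kept:
        raise InsufficientDataError("no converged curve fits to assemble")
    mat = pd.DataFrame(
        [f.mean_curve for f in kept],
        index=pd.Index([f.seq_id for f in kept], name="seq_id"),
        columns=np.asarray(ga_grid, float),
    )
    return mat


@dataclass
class ClusterResult:
    """Shape clustering of mean trajectories."""

    k_candidates: list
    mean_silhouette: pd.Series
    chosen_k: int
    assignment: pd.Series
    distance: pd.DataFrame
    linkage_matrix: np.ndarray = field(repr=False, default=None)


class TrajectoryClusterer(BaseEstimator):
    """Complete-linkage clustering of curves on 1 − Pearson correlation.

    The number of clusters is chosen among ``k_candidates`` by maximizing
    the mean silhouette width computed on the same correlation distance
    (internal consistency of the selection criterion).

    Attributes (after ``fit``)
    --------------------------
    distance_ : pd.DataFrame
        Symmetric 1 − Pearson distance matrix (entries in [0, 2]).
    mean_silhouette_ : pd.Series
        Mean silhouette width per candidate k.
    chosen_k_ : int
    labels_ : pd.Series
        Cluster label (1..chosen_k) per curve.
    """

    def __init__(self, k_candidates=tuple(range(2, 9))):
        self.k_candidates = k_candidates

    def fit(self, X: pd.DataFrame, y=None):
        ks = sorted(int(k) for k in self.k_candidates)
        if len(X) < max(ks) + 1:
            raise InsufficientDataError(
                f"need >= {max(ks) + 1} curves to consider k up to {max(ks)}, got {len(X)}"
            )
        M = X.to_numpy(float)
        sd = M.std(axis=1)
        if np.any(sd == 0):
            bad = X.index[np.where(sd == 0)[0][0]]
            raise DataError(f"curve {bad!r} is constant: Pearson correlation undefined")
        corr = np.corrcoef(M)
        dist = 1.0 - corr
        dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        self.distance_ = pd.DataFrame(dist, index=X.index, columns=X.index)

        Z = linkage(squareform(dist, checks=False), method="complete")
        self.linkage_matrix_ = Z
        sil = {}
        labels_at_k = {}
        for k in ks:
            labels = fcluster(Z, t=k, criterion="maxclust")
            labels_at_k[k] = labels
            n_found = len(np.unique(labels))
            if 2 <= n_found <= len(X) - 1:
                sil[k] = float(silhouette_score(dist, labels, metric="precomputed"))
            else:
                sil[k] = float("-inf")  # degenerate cut; never optimal
        self.mean_silhouette_ = pd.Series(sil).sort_index()
        self.chosen_k_ = int(self.mean_silhouette_.idxmax())
        raw = labels_at_k[self.chosen_k_]
        # relabel to 1..k in order of first appearance for determinism
        order = {lab: i + 1 for i, lab in enumerate(pd.unique(raw))}
        self.labels_ = pd.Series([order[v] for v in raw], index=X.index, name="cluster")
        return self


def cluster_mean_curves(curves: pd.DataFrame, k_candidates=tuple(range(2, 9))) -> ClusterResult:
    """Cluster a proteins × grid curve matrix; choose k by mean silhouette."""
    est = TrajectoryClusterer(k_candidates=k_candidates).fit(curves)
    return ClusterResult(
        k_candidates=sorted(int(k) for k in k_candidates),
        mean_silhouette=est.mean_silhouette_,
        chosen_k=est.chosen_k_,
        assignment=est.labels_,
        distance=est.distance_,
        linkage_matrix=est.linkage_matrix_,
    )


def scale_curves_to_zero_start(curves: pd.DataFrame) -> pd.DataFrame:
    """Shift each curve so its first grid value is zero (for display)."""
    if curves.shape[1] == 0:
        raise UsageError("curves have an empty grid")
    return curves.sub(curves.iloc[:, 0], axis=0)
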