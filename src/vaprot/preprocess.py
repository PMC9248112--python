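"""Pre-test transformations and QC.

log2 transformation of raw RFU values, winsorization of extreme-abundance
trajectories, robust detection of atypical samples, and restriction to
QC-passing proteins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, DataError, InsufficientDataError

ID_COLUMNS = ("participant_id", "vessel", "visit", "ga_weeks",
              "age_years", "bmi", "nulliparity")

__all__ = [
    "protein_columns",
    "log2_transform",
    "Winsorizer",
    "winsorize_high_abundance",
    "detect_atypical_samples",
    "filter_qc",
]


def protein_columns(table: pd.DataFrame) -> list[str]:
    """Columns of ``table`` holding protein values (everything not an id/covariate)."""
    return [c for c in table.columns if c not in ID_COLUMNS]


def log2_transform(raw: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2 of the protein columns; id columns and missingness preserved.

    Raises :class:`DataError` naming the first offending cell if any
    non-missing value is not strictly positive.
    """
    out = raw.copy()
    cols = protein_columns(raw)
    block = out[cols].astype(float)
    bad = (block <= 0) & block.notna()
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise DataError(
            f"non-positive RFU value at row {row}, column {col!r}: {block.at[row, col]}"
        )
    out[cols] = np.log2(block)
    return out


class Winsorizer(BaseEstimator, TransformerMixin):
    """Shift extreme-abundance trajectories down to a quantile threshold.

    Operates on a long-format longitudinal table (one row per participant ×
    visit, log2 scale). The unit of winsorization is a (participant, protein)
    trajectory: its mean across that participant's visits is compared with
    the ``q``-th quantile of all trajectory means (pooled over participants
    and proteins); trajectories above the threshold are shifted down by
    (mean − threshold), so the new mean equals the threshold and within-
    trajectory visit-to-visit changes are preserved exactly.

    Parameters
    ----------
    q : float
        Quantile defining the shift threshold, in (0, 1). Default 0.98.

    Attributes
    ----------
    threshold_ : float
        The fitted quantile of trajectory means (linear interpolation
        between order statistics).
    n_shifted_ : int
        Number of trajectories shifted by the last ``transform``.
    """

    def __init__(self, q: float = 0.98):
        self.q = q

    def fit(self, X: pd.DataFrame, y=None):
        if not 0.0 < self.q < 1.0:
            raise ConfigurationError(f"winsorization quantile must be in (0, 1), got {self.q}")
        cols = protein_columns(X)
        means = X.groupby("participant_id", sort=False)[cols].mean()
        self.threshold_ = float(np.quantile(means.to_numpy().ravel(), self.q))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = protein_columns(X)
        out = X.copy()
        means = out.groupby("participant_id", sort=False)[cols].transform("mean")
        excess = (means - self.threshold_).clip(lower=0.0)
        self.n_shifted_ = int(
            (excess.groupby(out["participant_id"].values, sort=False).max() > 0).sum().sum()
        )
        out[cols] = out[cols] - excess
        return out


def winsorize_high_abundance(data: pd.DataFrame, q: float = 0.98) -> pd.DataFrame:
    """Functional wrapper around :class:`Winsorizer` (fit and transform on ``data``)."""
    return Winsorizer(q=q).fit(data).transform(data)


def detect_atypical_samples(matrix: pd.DataFrame, mad_threshold: float = 5.0) -> list:
    """Flag samples whose global log2 RFU level is atypical for the cohort.

    A sample's level is summarized by its median across proteins; samples
    whose median deviates from the cohort median of sample medians by more
    than ``mad_threshold`` robust SDs (MAD × 1.4826) are flagged. Replaces
    the by-eye exclusion of whole-sample distributional outliers with a
    reproducible rule.

    Returns the flagged row labels of ``matrix``.
    """
    cols = protein_columns(matrix)
    if len(matrix) < 3:
        raise InsufficientDataError(
            f"need >= 3 samples to assess typicality, got {len(matrix)}"
        )
    sample_medians = matrix[cols].median(axis=1)
    center = sample_medians.median()
    mad = (sample_medians - center).abs().median()
    robust_sd = 1.4826 * mad
    if robust_sd == 0.0:
        dev = (sample_medians - center).abs()
        return list(sample_medians.index[dev > 0]) if np.isfinite(mad_threshold) else []
    flagged = (sample_medians - center).abs() > mad_threshold * robust_sd
    return list(sample_medians.index[flagged])


def filter_qc(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Restrict protein columns to those with ``qc_pass`` true in ``meta``.

    ``meta`` must have columns ``seq_id`` and ``qc_pass`` and cover every
    protein column of ``matrix``; column order is preserved.
    """
    cols = protein_columns(matrix)
    qc = meta.set_index("seq_id")["qc_pass"]
    unknown = [c for c in cols if c not in qc.index]
    if unknown:
        raise DataError(f"protein columns missing from metadata: {unknown[:5]}")
    keep = [c for c in cols if bool(qc[c])]
    id_cols = [c for c in matrix.columns if c not in cols]
    return matrix[id_cols + keep]
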