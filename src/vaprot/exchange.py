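"""Paired venoarterial difference screening.

The test quantity for each protein is the per-participant paired difference

    d = log2(RFU_vein) − log2(RFU_artery)

between a draining vein and a feeding artery. A positive mean difference
across participants indicates net release of the protein by the intervening
tissue, a negative mean indicates net uptake. Because net movement of plasma
water between artery and vein concentrates or dilutes *all* proteins in a
sample at once (the "water shift"), the per-participant median of d across
the protein panel is removed before testing (median normalization), under
the assumption that most proteins are not exchanged.

Per protein the screen is a two-sided one-sample t-test of H0: mean d = 0,
with Benjamini-Hochberg FDR control across the panel; significant proteins
are classified ``released`` (t > 0) or ``uptake`` (t < 0). Log2 differences
are also reported as percent higher RFU in the vein than the artery,

    pct = (mean over participants of 2^d  −  1) × 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .errors import DataError, InsufficientDataError, UsageError
from .preprocess import protein_columns

__all__ = [
    "VenoarterialDiffs",
    "ExchangeResult",
    "MedianNormalizer",
    "ExchangeScreen",
    "venoarterial_diffs",
    "median_normalize",
    "paired_exchange_test",
    "bh_adjust",
    "percent_change",
    "pvalue_histogram_diagnostic",
    "PValueHistogram",
]


@dataclass
class VenoarterialDiffs:
    """Per-participant, per-protein paired log2 differences for one vessel pair.

    ``data`` is participants × proteins; only participants with both vessels
    present contribute rows.
    """

    data: pd.DataFrame
    vein: str
    artery: str
    normalized: bool = False

    @property
    def pair(self) -> tuple[str, str]:
        return (self.vein, self.artery)


@dataclass
class ExchangeResult:
    """Per-protein screen statistics and release/uptake classification.

    ``table`` is indexed by protein id with columns ``n_pairs``, ``mean_diff``,
    ``t_stat``, ``p_raw``, ``p_fdr``, ``exchange_class``, ``pct_change`` and
    ``degenerate`` (zero-variance difference vectors, excluded from testing).
    """

    table: pd.DataFrame
    vein: str
    artery: str
    alpha: float

    @property
    def released(self) -> pd.Index:
        return self.table.index[self.table["exchange_class"] == "released"]

    @property
    def uptake(self) -> pd.Index:
        return self.table.index[self.table["exchange_class"] == "uptake"]


def venoarterial_diffs(matrix: pd.DataFrame, vein: str, artery: str) -> VenoarterialDiffs:
    """Compute paired log2 differences vein − artery from a long-format vessel table.

    ``matrix`` has one row per (participant, vessel); pairing is complete-case:
    a participant contributes iff both vessels are present. Participants
    missing one vessel are still usable for other vessel pairs.
    """
    if "vessel" not in matrix.columns or "participant_id" not in matrix.columns:
        raise DataError("matrix must have 'participant_id' and 'vessel' columns")
    present = set(matrix["vessel"])
    for label in (vein, artery):
        if label not in present:
            raise DataError(f"vessel {label!r} not present in matrix")
    cols = protein_columns(matrix)
    wide = {
        v: matrix.loc[matrix["vessel"] == v].set_index("participant_id")[cols]
        for v in (vein, artery)
    }
    for v, block in wide.items():
        if block.index.duplicated().any():
            dup = block.index[block.index.duplicated()][0]
            raise DataError(f"duplicate ({dup!r}, {v!r}) rows in matrix")
    shared = wide[vein].index.intersection(wide[artery].index)
    if len(shared) < 2:
        raise InsufficientDataError(
            f"need >= 2 participants with both {vein} and {artery}, got {len(shared)}"
        )
    d = wide[vein].loc[shared] - wide[artery].loc[shared]
    return VenoarterialDiffs(data=d, vein=vein, artery=artery, normalized=False)


class MedianNormalizer(BaseEstimator, TransformerMixin):
    """Remove each sample's global venoarterial bias.

    Subtracts from every difference of a participant the median of that
    participant's differences across the protein panel, so that the
    per-participant median becomes exactly zero. This cancels any additive
    per-sample constant on the log2 scale (equivalently, any multiplicative
    bias on the RFU scale such as the water shift), and is justified when
    the majority of proteins are not exchanged.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.sub(X.median(axis=1), axis=0)


def median_normalize(diffs: VenoarterialDiffs) -> VenoarterialDiffs:
    """Median-normalize a :class:`VenoarterialDiffs` (per participant, per pair)."""
    if diffs.normalized:
        raise UsageError("differences are already median-normalized")
    if diffs.data.shape[1] < 10:
        raise InsufficientDataError(
            "median normalization needs >= 10 proteins per participant "
            f"(got {diffs.data.shape[1]}); the most-proteins-unchanged assumption "
            "is meaningless on a tiny panel"
        )
    data = MedianNormalizer().fit_transform(diffs.data)
    return VenoarterialDiffs(data=data, vein=diffs.vein, artery=diffs.artery,
                             normalized=True)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must be finite and in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


class ExchangeScreen(BaseEstimator):
    """Per-protein paired t screen with BH-FDR classification.

    Parameters
    ----------
    alpha : float
        FDR level for the released/uptake call. Default 0.05.
    min_pairs : int
        Minimum complete pairs per protein for the t-test. Default 3.

    Attributes
    ----------
    results_ : pd.DataFrame
        One row per protein: ``n_pairs, mean_diff, t_stat, p_raw, p_fdr,
        exchange_class, pct_change, degenerate``. The BH family is all
        non-degenerate tested proteins of this screen.
    """

    def __init__(self, alpha: float = 0.05, min_pairs: int = 3):
        self.alpha = alpha
        self.min_pairs = min_pairs

    def fit(self, X: pd.DataFrame, y=None):
        D = X.to_numpy(dtype=float)
        n_pairs = np.sum(np.isfinite(D), axis=0)
        if np.all(n_pairs < self.min_pairs):
            raise InsufficientDataError(
                f"no protein has >= {self.min_pairs} complete pairs"
            )
        mean = np.nanmean(np.where(np.isfinite(D), D, np.nan), axis=0)
        sd = np.nanstd(np.where(np.isfinite(D), D, np.nan), axis=0, ddof=1)

        testable = (n_pairs >= self.min_pairs)
        degenerate = testable & (sd == 0)
        tested = testable & ~degenerate

        t = np.full(D.shape[1], np.nan)
        p = np.full(D.shape[1], np.nan)
        se = sd[tested] / np.sqrt(n_pairs[tested])
        t[tested] = mean[tested] / se
        p[tested] = 2.0 * stats.t.sf(np.abs(t[tested]), df=n_pairs[tested] - 1)

        p_fdr = np.full(D.shape[1], np.nan)
        if tested.any():
            p_fdr[tested] = bh_adjust(p[tested])

        cls = np.full(D.shape[1], "none", dtype=object)
        sig = tested & (p_fdr < self.alpha)
        cls[sig & (t > 0)] = "released"
        cls[sig & (t < 0)] = "uptake"

        with np.errstate(over="ignore"):
            pct = (np.nanmean(np.where(np.isfinite(D), 2.0 ** D, np.nan), axis=0) - 1.0) * 100.0

        self.results_ = pd.DataFrame(
            {
                "n_pairs": n_pairs,
                "mean_diff": mean,
                "t_stat": t,
                "p_raw": p,
                "p_fdr": p_fdr,
                "exchange_class": cls,
                "pct_change": pct,
                "degenerate": degenerate,
            },
            index=X.columns,
        )
        self.results_.index.name = "seq_id"
        return self


def paired_exchange_test(diffs: VenoarterialDiffs, alpha: float = 0.05) -> ExchangeResult:
    """Run the release/uptake screen on median-normalized differences."""
    if not diffs.normalized:
        raise UsageError(
            "differences must be median-normalized before testing "
            "(or explicitly screened raw via ExchangeScreen)"
        )
    screen = ExchangeScreen(alpha=alpha).fit(diffs.data)
    return ExchangeResult(table=screen.results_, vein=diffs.vein,
                          artery=diffs.artery, alpha=alpha)


def percent_change(diffs_for_protein) -> float:
    """Percent higher RFU in the vein than the artery: (mean(2^d) − 1) × 100."""
    d = np.asarray(diffs_for_protein, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise InsufficientDataError("no finite differences supplied")
    return float((np.mean(2.0 ** d) - 1.0) * 100.0)


@dataclass
class PValueHistogram:
    """Equal-width p-value histogram with a uniformity check on the right tail."""

    bin_edges: np.ndarray
    bin_counts: np.ndarray
    uniform_tail_ok: bool
    degenerate: bool
    chi2_p: float = float("nan")


def pvalue_histogram_diagnostic(p_values, n_bins: int = 20) -> PValueHistogram:
    """Diagnose a p-value distribution for experimental bias.

    A healthy screen shows an overabundance of very small p-values (true
    positives) on top of a uniform distribution at larger p (well-calibrated
    nulls). Counts over p > 0.5 are tested for uniformity with a chi-square
    goodness-of-fit test at level 0.01; a flat tail passes. The check is
    flagged degenerate when the tail holds too little mass for the
    chi-square approximation (expected < 5 per tail bin).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must be finite and in [0, 1]")
    counts, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    tail = counts[edges[:-1] >= 0.5]
    if len(tail) < 2 or tail.sum() < 5 * len(tail):
        return PValueHistogram(edges, counts, uniform_tail_ok=False, degenerate=True)
    chi2_p = float(stats.chisquare(tail).pvalue)
    return PValueHistogram(edges, counts, uniform_tail_ok=chi2_p > 0.01,
                           degenerate=False, chi2_p=chi2_p)
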