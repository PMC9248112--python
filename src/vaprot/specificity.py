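"""Placenta-specific release: the arm as a systemic negative control.

A protein released across the uteroplacental unit (UV−RA) may simply show a
generic vein-vs-artery difference. The antecubital-vein screen (AV−RA) is
used as a proxy for any systemic venoarterial difference. A released protein
is classified *placenta-specific* if either

* criterion 1 — its placental venoarterial difference is significantly
  larger than its arm difference (paired t-test on the per-participant
  contrast (UV−RA) − (AV−RA), BH-adjusted), or
* criterion 2 — its arm difference is negative or not significantly
  different from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InsufficientDataError, UsageError
from .exchange import ExchangeResult, ExchangeScreen, VenoarterialDiffs

__all__ = ["SpecificityResult", "specificity_contrast", "classify_specific"]


@dataclass
class SpecificityResult:
    """Per-protein placenta-specificity call.

    ``table`` is indexed by protein id with columns ``delta_mean``,
    ``delta_t``, ``delta_p_fdr``, ``arm_class``, ``criterion`` (1, 2 or 0)
    and ``is_specific``.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def specific(self) -> pd.Index:
        return self.table.index[self.table["is_specific"]]


def specificity_contrast(uv_ra: VenoarterialDiffs, av_ra: VenoarterialDiffs) -> pd.DataFrame:
    """Per-protein paired t statistics of the contrast (UV−RA) − (AV−RA).

    Only participants with all three vessels (i.e., present in both
    difference sets) contribute. Returns a DataFrame indexed by protein with
    columns ``n_pairs``, ``delta_mean``, ``delta_t``, ``delta_p_raw``,
    ``delta_p_fdr`` and ``degenerate``; the BH family is the contrast tests.
    """
    for d in (uv_ra, av_ra):
        if not d.normalized:
            raise UsageError("both difference sets must be median-normalized")
    if list(uv_ra.data.columns) != list(av_ra.data.columns):
        raise DataError("difference sets cover different protein panels")
    shared = uv_ra.data.index.intersection(av_ra.data.index)
    if len(shared) < 3:
        raise InsufficientDataError(
            f"need >= 3 participants with all three vessels, got {len(shared)}"
        )
    contrast = uv_ra.data.loc[shared] - av_ra.data.loc[shared]
    screen = ExchangeScreen(alpha=1.0).fit(contrast)
    t = screen.results_
    return pd.DataFrame(
        {
            "n_pairs": t["n_pairs"],
            "delta_mean": t["mean_diff"],
            "delta_t": t["t_stat"],
            "delta_p_raw": t["p_raw"],
            "delta_p_fdr": t["p_fdr"],
            "degenerate": t["degenerate"],
        },
        index=t.index,
    )


def classify_specific(
    released: ExchangeResult,
    arm: ExchangeResult,
    contrast: pd.DataFrame,
    alpha: float = 0.05,
) -> SpecificityResult:
    """Classify placenta-released proteins as placenta-specific or not.

    Only proteins with ``exchange_class == "released"`` in the placental
    (UV−RA) screen are eligible. Criterion 1 uses the contrast's FDR-adjusted
    p and sign; criterion 2 uses the arm screen's own t statistic and
    FDR-adjusted p at the same ``alpha``.
    """
    idx = released.table.index
    if not (idx.equals(arm.table.index) and idx.equals(contrast.index)):
        raise DataError("released, arm and contrast results must cover the same proteins")

    is_released = released.table["exchange_class"] == "released"
    crit1 = (contrast["delta_p_fdr"] < alpha) & (contrast["delta_t"] > 0)
    arm_null_or_neg = (arm.table["t_stat"] <= 0) | (arm.table["p_fdr"] >= alpha)
    # degenerate arm tests (zero variance, p undefined) count as null
    arm_null_or_neg |= arm.table["degenerate"]
    crit1 = crit1.fillna(False)

    arm_class = np.where(arm_null_or_neg, "negative_or_null", "positive_significant")
    is_specific = is_released & (crit1 | arm_null_or_neg)
    criterion = np.zeros(len(idx), dtype=int)
    criterion[(is_released & crit1).to_numpy()] = 1
    # criterion 2 recorded where it is the (only) route
    crit2_only = (is_released & arm_null_or_neg & ~crit1).to_numpy()
    criterion[crit2_only] = 2

    table = pd.DataFrame(
        {
            "delta_mean": contrast["delta_mean"],
            "delta_t": contrast["delta_t"],
            "delta_p_fdr": contrast["delta_p_fdr"],
            "arm_class": arm_class,
            "criterion": criterion,
            "is_specific": is_specific,
        },
        index=idx,
    )
    return SpecificityResult(table=table, alpha=alpha)
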