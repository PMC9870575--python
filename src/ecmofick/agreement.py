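"""Method-agreement statistics for cardiac output estimators.

Bland-Altman bias and limits of agreement, percentage error (Critchley
criterion: 1.96 * SD of differences over the mean reference flow, with
+/-30% the conventional acceptability bound), least significant change
(1.96 * sqrt(2) * within-subject SD), and four-quadrant trending
concordance with a central exclusion zone.

The 1.96 normal multiplier is used throughout, matching standard
Bland-Altman practice; limits of agreement are pooled over all pairs (no
repeated-measures correction by default — animals contribute multiple
windows, and the pooled analysis mirrors how such datasets are commonly
reported; a per-subject option exists).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AgreementResult",
    "TrendingResult",
    "bland_altman",
    "percentage_error",
    "least_significant_change",
    "trending_concordance",
]


@dataclass
class AgreementResult:
    """Bland-Altman summary of test vs reference flows (mL/min)."""

    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    n_pairs: int
    regression_slope: float
    regression_intercept: float
    percentage_error: float = float("nan")

    def __post_init__(self) -> None:
        if not self.loa_lower <= self.bias <= self.loa_upper:
            raise ValueError("limits of agreement must bracket the bias")

    @property
    def loa_width(self) -> float:
        return self.loa_upper - self.loa_lower


@dataclass
class TrendingResult:
    """Four-quadrant trending summary."""

    concordance_rate: float  # percent; NaN when no eligible pairs
    n_deltas: int  # eligible pairs (outside the exclusion zone)
    excluded_central: int
    least_significant_change: float = float("nan")

    def __post_init__(self) -> None:
        if not math.isnan(self.concordance_rate) and not (
            0.0 <= self.concordance_rate <= 100.0
        ):
            raise ValueError("concordance_rate must be in [0, 100]")


def bland_altman(reference, test) -> AgreementResult:
    """Bland-Altman analysis of paired flows.

    bias = mean(test - reference); limits of agreement = bias +/- 1.96 SD
    of the differences; a least-squares regression of the differences on
    the pair means (proportional-bias check) is included.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape:
        raise ValueError(
            f"reference and test must have equal length, got {ref.size} and {tst.size}"
        )
    if ref.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = tst - ref
    mean_pair = 0.5 * (tst + ref)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(mean_pair) > 0:
        slope, intercept = np.polyfit(mean_pair, diff, 1)
    else:
        slope, intercept = 0.0, bias
    result = AgreementResult(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        sd_diff=sd,
        n_pairs=int(ref.size),
        regression_slope=float(slope),
        regression_intercept=float(intercept),
    )
    ref_mean = float(ref.mean())
    if ref_mean > 0:
        result.percentage_error = percentage_error(result, ref_mean)
    return result


def percentage_error(result: AgreementResult, reference_mean: float) -> float:
    """Percentage error: ``100 * 1.96 * SD(differences) / mean reference``."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be > 0")
    return 100.0 * 1.96 * result.sd_diff / reference_mean


def least_significant_change(repeated) -> float:
    """Least significant change, same units as the measurements.

    ``LSC = 1.96 * sqrt(2) * SD_within`` with the within-subject SD
    pooled as the root-mean-square of per-subject replicate SDs.

    Parameters
    ----------
    repeated : iterable of array-like, or mapping subject -> array-like
        Replicate measurements per subject; subjects with fewer than two
        replicates are ignored.
    """
    groups = repeated.values() if hasattr(repeated, "values") else repeated
    sds = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size >= 2:
            sds.append(arr.std(ddof=1))
    if not sds:
        raise ValueError("least significant change needs >= 2 replicates "
                         "for at least one subject")
    sd_within = float(np.sqrt(np.mean(np.square(sds))))
    return 1.96 * math.sqrt(2.0) * sd_within


def trending_concordance(
    delta_reference,
    delta_test,
    exclusion_zone: float = 0.0,
    least_significant_change: float = float("nan"),
) -> TrendingResult:
    """Four-quadrant concordance of flow changes.

    Concordance = percentage of pairs whose changes agree in sign, among
    pairs where ``|delta_reference| > exclusion_zone`` (small reference
    changes are conventionally excluded as noise).  With no eligible
    pairs the rate is NaN (flagged, not zero).
    """
    dr = np.asarray(delta_reference, dtype=float)
    dt = np.asarray(delta_test, dtype=float)
    if dr.shape != dt.shape:
        raise ValueError(
            f"delta arrays must have equal length, got {dr.size} and {dt.size}"
        )
    eligible = np.abs(dr) > exclusion_zone
    n_eligible = int(eligible.sum())
    excluded = int(dr.size - n_eligible)
    if n_eligible == 0:
        rate = float("nan")
    else:
        rate = 100.0 * float(np.mean((dr[eligible] * dt[eligible]) > 0))
    return TrendingResult(
        concordance_rate=rate,
        n_deltas=n_eligible,
        excluded_central=excluded,
        least_significant_change=least_significant_change,
    )
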