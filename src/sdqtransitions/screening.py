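"""Univariate and multivariate outlier screening within partition groups.

Children are screened separately within each (wave, group) stratum:
univariate outliers lie more than ``k_sd`` standard deviations from the
subscale median on any subscale; multivariate outliers have a squared
Mahalanobis distance to the group mean (classical sample covariance)
exceeding the chi-square(df=5) quantile at ``alpha``.  The union of both
flag sets is removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from sdqtransitions.scoring import SUBSCALES

__all__ = ["ScreenReport", "univariate_flags", "mahalanobis_flags", "apply_screen"]


@dataclass
class ScreenReport:
    """Per-stratum exclusion accounting."""

    wave: str
    group: str
    n_input: int
    n_univariate_flagged: int
    n_multivariate_flagged: int
    n_retained: int
    flagged: dict[str, list] = field(default_factory=dict)  # reason -> child ids

    def to_dict(self) -> dict:
        return asdict(self)


def univariate_flags(scores: pd.DataFrame, k_sd: float = 3.0) -> np.ndarray:
    """Flag children > k_sd SDs from the median on any subscale.

    Both statistics are computed within the supplied group; the boundary
    is a strict inequality.  Zero-variance subscales are skipped with a
    warning (they cannot produce outliers under a scale-relative rule).
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 children for univariate screening")
    flags = np.zeros(len(scores), dtype=bool)
    for name in SUBSCALES:
        col = scores[name].to_numpy(dtype=float)
        sd = col.std(ddof=1)
        if sd == 0:
            warnings.warn(f"subscale {name!r} has zero variance; skipped in screening")
            continue
        flags |= np.abs(col - np.median(col)) > k_sd * sd
    return flags


def mahalanobis_flags(scores: pd.DataFrame, alpha: float = 0.999) -> np.ndarray:
    """Flag children whose squared Mahalanobis distance exceeds the
    chi-square(df=5) quantile at ``alpha`` (strict inequality)."""
    if len(scores) < 6:
        raise ValueError("need at least 6 children for multivariate screening")
    x = scores[list(SUBSCALES)].to_numpy(dtype=float)
    center = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular covariance matrix; consider a ridge term or dropping a "
            "degenerate subscale"
        ) from exc
    diff = x - center
    d2 = np.einsum("ij,jk,ik->i", diff, cov_inv, diff)
    threshold = stats.chi2.ppf(alpha, df=len(SUBSCALES))
    return d2 > threshold


def apply_screen(
    subscales: pd.DataFrame,
    partition: pd.DataFrame,
    k_sd: float = 3.0,
    alpha: float = 0.999,
) -> tuple[pd.DataFrame, list[ScreenReport]]:
    """Run both outlier rules within each (wave, label) stratum.

    Flags are computed in parallel on the same input and unioned; the
    retained table drops flagged children.  Returns the retained scores
    (with the partition label merged in) and one report per stratum.
    """
    merged = subscales.merge(
        partition[["child_id", "wave", "label"]], on=["child_id", "wave"], how="inner"
    )
    retained_frames = []
    reports = []
    for (wave, label), stratum in merged.groupby(["wave", "label"], sort=True):
        uni = univariate_flags(stratum, k_sd=k_sd)
        multi = mahalanobis_flags(stratum, alpha=alpha)
        union = uni | multi
        ids = stratum["child_id"].to_numpy()
        reports.append(
            ScreenReport(
                wave=wave,
                group=label,
                n_input=len(stratum),
                n_univariate_flagged=int(uni.sum()),
                n_multivariate_flagged=int(multi.sum()),
                n_retained=int((~union).sum()),
                flagged={
                    "univariate": ids[uni].tolist(),
                    "multivariate": ids[multi].tolist(),
                },
            )
        )
        retained_frames.append(stratum.loc[~union])
    retained = pd.concat(retained_frames, ignore_index=True)
    return retained, reports
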