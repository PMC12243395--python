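"""Cluster-to-cluster transition tables and equal-split proportion tests.

Children present in two consecutive waves are linked by id; each
(source group, destination group) cell's transition proportion is tested
against the equal-split null p0 = 1/K (K destination groups) with a
two-sided one-sample proportion z test, Bonferroni-corrected over all
cells of the wave pair.  A cell is flagged significant only when its
adjusted p value is below alpha AND its proportion exceeds p0 — the
study reports only above-chance transitions.  Flagged cells can be
validated by comparing the transitioning children's source-wave
silhouette scores to the whole source cluster's distribution
(two-sample Kolmogorov–Smirnov), guarding against transitions driven by
borderline cluster members.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "link_waves",
    "equal_split_null",
    "proportion_ztest",
    "bonferroni",
    "test_transitions",
    "validate_transition",
    "TransitionValidation",
]


def link_waves(labels_t: pd.DataFrame, labels_t1: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two waves' group labels on child id.

    Each input needs ``child_id`` and ``group`` columns.  Children absent
    at the later wave drop out of all denominators.  Duplicate child ids
    within a wave are an error.
    """
    for name, df in (("source", labels_t), ("destination", labels_t1)):
        if df["child_id"].duplicated().any():
            raise ValueError(f"duplicate child ids in {name} wave labels")
    linked = labels_t[["child_id", "group"]].merge(
        labels_t1[["child_id", "group"]],
        on="child_id",
        suffixes=("_source", "_dest"),
    )
    if linked.empty:
        warnings.warn("no children linked across the two waves")
    logging.getLogger(__name__).info(
        "linked %d of %d source-wave children", len(linked), len(labels_t)
    )
    return linked


def equal_split_null(K: int) -> float:
    """Equal-split null proportion 1/K over K destination groups."""
    if K < 2:
        raise ValueError("need at least 2 destination groups")
    return 1.0 / K


def proportion_ztest(x: int, n: int, p0: float) -> tuple[float, float]:
    """One-sample proportion z test against p0, two-sided normal p value."""
    if n == 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("count x must lie in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly in (0, 1)")
    if n * p0 < 5 or n * (1 - p0) < 5:
        warnings.warn("normal approximation dubious: n*p0 or n*(1-p0) below 5")
    z = (x / n - p0) / np.sqrt(p0 * (1 - p0) / n)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment min(1, p*m); order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be at least 1")
    return np.minimum(1.0, p * m)


def test_transitions(
    linked: pd.DataFrame,
    alpha: float = 0.05,
    destination_groups: list | None = None,
) -> pd.DataFrame:
    """Test every transition cell against the equal-split null.

    Returns one row per (source, destination) cell with count, row total,
    proportion, null p0, z, raw and Bonferroni-adjusted p (family = all
    cells of this wave pair), and the above-chance significance flag.
    ``destination_groups`` defaults to all groups observed at the later
    wave (the non-elevated group counts toward K).
    """
    if linked.empty:
        raise ValueError("no linked children to test")
    dests = (
        sorted(linked["group_dest"].unique())
        if destination_groups is None
        else list(destination_groups)
    )
    K = len(dests)
    if K < 2:
        raise ValueError("need at least 2 destination groups to test against equal split")
    p0 = equal_split_null(K)
    counts = pd.crosstab(linked["group_source"], linked["group_dest"]).reindex(
        columns=dests, fill_value=0
    )
    rows = []
    for src in counts.index:
        n_row = int(counts.loc[src].sum())
        for dest in dests:
            x = int(counts.loc[src, dest])
            z, p = proportion_ztest(x, n_row, p0)
            rows.append(
                {
                    "source": src,
                    "destination": dest,
                    "count": x,
                    "row_total": n_row,
                    "proportion": x / n_row,
                    "p0": p0,
                    "z": z,
                    "p_raw": p,
                }
            )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bonferroni(table["p_raw"], m=len(table))
    table["significant"] = (table["p_adjusted"] < alpha) & (table["proportion"] > p0)
    return table


@dataclass
class TransitionValidation:
    """KS comparison of a flagged cell's members against their source
    cluster's silhouette distribution."""

    source: object
    destination: object
    member_scores: np.ndarray
    cluster_scores: np.ndarray
    statistic: float | None
    p_value: float | None
    skipped_reason: str | None = None


def validate_transition(
    cluster_scores: np.ndarray,
    member_scores: np.ndarray,
    source="",
    destination="",
    min_members: int = 5,
) -> TransitionValidation:
    """Compare transitioning members' silhouettes to the full cluster.

    ``cluster_scores`` are the source-wave per-child silhouette values of
    the entire source cluster; ``member_scores`` the subset belonging to
    the flagged transition.  A small member set skips validation with a
    reason instead of testing.
    """
    member_scores = np.asarray(member_scores, dtype=float)
    cluster_scores = np.asarray(cluster_scores, dtype=float)
    if len(member_scores) < min_members:
        return TransitionValidation(
            source, destination, member_scores, cluster_scores, None, None,
            skipped_reason=f"fewer than {min_members} transitioning members",
        )
    stat, p = stats.ks_2samp(member_scores, cluster_scores)
    return TransitionValidation(
        source, destination, member_scores, cluster_scores, float(stat), float(p)
    )
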