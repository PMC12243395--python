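"""SDQ subscale scoring, three-band categorisation, and sample partitioning.

The parent-report Strengths and Difficulties Questionnaire (SDQ) has 25
items in five 5-item subscales (emotional symptoms, conduct problems,
hyperactivity, peer problems, prosocial behaviour), each item rated 0/1/2.
Subscale scores are the sums of their five items (range 0-10); the
prosocial subscale is reverse-scored to "antisocial" so that higher scores
always mean greater difficulty.  Published cutpoints divide each subscale
into normal / borderline / abnormal bands; a child with any non-normal
band belongs to the "elevated" group, otherwise to "non_elevated".

Tables here use a layout in which ``item_01``..``item_25`` carry the five
subscales in consecutive blocks of five, ordered emotional, conduct,
hyperactivity, peer, prosocial (raw, un-reversed).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

SUBSCALES = ("emotional", "conduct", "hyperactivity", "peer", "antisocial")

ITEM_COLUMNS = tuple(f"item_{i:02d}" for i in range(1, 26))

#: item columns per subscale; the "antisocial" block holds the raw
#: prosocial items, which score_subscales reverse-scores.
ITEM_BLOCKS = {
    name: ITEM_COLUMNS[5 * i : 5 * i + 5] for i, name in enumerate(SUBSCALES)
}

BANDS = ("normal", "borderline", "abnormal")


@dataclass(frozen=True)
class BandTable:
    """Three-band cutpoints per subscale.

    ``cuts[s] = (cut1, cut2)``: scores ``<= cut1`` are normal,
    ``cut1 < score <= cut2`` borderline, ``> cut2`` abnormal.
    """

    cuts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(SUBSCALES) - set(self.cuts)
        if missing:
            raise ValueError(f"band table missing subscales: {sorted(missing)}")
        for name, (c1, c2) in self.cuts.items():
            if not (0 <= c1 < c2 <= 10):
                raise ValueError(
                    f"band cutpoints for {name!r} must satisfy 0 <= cut1 < cut2 <= 10, "
                    f"got ({c1}, {c2})"
                )

    @classmethod
    def from_yaml(cls, path) -> "BandTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({k: (int(v[0]), int(v[1])) for k, v in raw.items()})


def default_bands() -> BandTable:
    """Goodman's published parent-SDQ cutpoints, shipped as package data."""
    ref = importlib.resources.files("sdqtransitions") / "data" / "default_bands.yaml"
    raw = yaml.safe_load(ref.read_text())
    return BandTable({k: (int(v[0]), int(v[1])) for k, v in raw.items()})


def _check_items(items: pd.DataFrame) -> None:
    missing_cols = [c for c in ITEM_COLUMNS if c not in items.columns]
    if missing_cols:
        raise ValueError(f"records table missing item columns: {missing_cols}")
    vals = items[list(ITEM_COLUMNS)].to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size and (np.any(finite < 0) | np.any(finite > 2) | np.any(finite != np.round(finite))):
        raise ValueError("item responses must be 0, 1 or 2 (or missing)")


def score_subscales(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum items into the five subscale scores, reverse-scoring prosocial.

    Parameters
    ----------
    records
        Table with ``child_id``, ``wave`` and ``item_01``..``item_25``
        columns; responses in {0, 1, 2} or missing (NaN).

    Returns
    -------
    scores, excluded
        ``scores`` has one row per (child, wave) with complete items and
        integer columns for the five subscales; ``antisocial`` is
        ``10 - sum(prosocial items)``.  ``excluded`` lists the (child,
        wave) rows dropped for incomplete SDQ responses — mirroring an
        analysis restricted to complete responders.
    """
    _check_items(records)
    items = records[list(ITEM_COLUMNS)]
    complete = items.notna().all(axis=1)
    excluded = records.loc[~complete, ["child_id", "wave"]].reset_index(drop=True)
    kept = records.loc[complete]

    out = kept[["child_id", "wave"]].copy()
    for name in SUBSCALES:
        block = kept[list(ITEM_BLOCKS[name])].to_numpy(dtype=int).sum(axis=1)
        out[name] = 10 - block if name == "antisocial" else block
    return out.reset_index(drop=True), excluded


def band_subscale(score: int, subscale: str, bands: BandTable) -> str:
    """Place one subscale score into its normal/borderline/abnormal band."""
    if subscale not in bands.cuts:
        raise ValueError(f"unknown subscale {subscale!r}")
    if not 0 <= score <= 10:
        raise ValueError(f"score must be in [0, 10], got {score}")
    c1, c2 = bands.cuts[subscale]
    if score <= c1:
        return "normal"
    if score <= c2:
        return "borderline"
    return "abnormal"


def partition_sample(
    scores: pd.DataFrame, bands: BandTable | None = None
) -> pd.DataFrame:
    """Label each child elevated / non_elevated from their subscale bands.

    A child is ``non_elevated`` only if every subscale falls in the normal
    band; any borderline or abnormal band makes them ``elevated``.
    Returns a table with ``child_id``, ``wave``, per-subscale
    ``band_<subscale>`` columns, and ``label``.
    """
    if bands is None:
        bands = default_bands()
    missing = [s for s in SUBSCALES if s not in scores.columns]
    if missing:
        raise ValueError(f"scores table missing subscales: {missing}")
    out = scores[["child_id", "wave"]].copy()
    any_elevated = np.zeros(len(scores), dtype=bool)
    for name in SUBSCALES:
        c1, c2 = bands.cuts[name]
        vals = scores[name].to_numpy()
        if np.any((vals < 0) | (vals > 10)):
            raise ValueError(f"{name} scores outside [0, 10]")
        band = np.where(vals <= c1, "normal", np.where(vals <= c2, "borderline", "abnormal"))
        out[f"band_{name}"] = band
        any_elevated |= band != "normal"
    out["label"] = np.where(any_elevated, "elevated", "non_elevated")
    return out


def zscore_subscales(scores: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardise the five subscales within the supplied group.

    Means and SDs are computed over the rows given (one wave's elevated
    group in the study pipeline), with the sample-SD convention
    (``ddof=1``) by default.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 children to z-score")
    out = scores.copy()
    for name in SUBSCALES:
        col = scores[name].to_numpy(dtype=float)
        sd = col.std(ddof=ddof)
        if sd == 0:
            raise ValueError(f"subscale {name!r} has zero variance; cannot z-score")
        out[name] = (col - col.mean()) / sd
    return out
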