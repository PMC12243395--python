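"""End-to-end study pipeline on a cohort of item records.

Chains the stages in study order: score SDQ items, partition into
elevated / non-elevated, screen outliers per stratum, embed + cluster
each wave's elevated group, test cluster-to-cluster transitions between
consecutive waves against the equal-split null, validate flagged cells
by silhouette comparison, and (optionally) fit the risk-factor model for
flagged elevated-to-elevated cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sdqtransitions.clustering import ClusterSolution, EmbeddingParams, embed, select_k
from sdqtransitions.cohort import SyntheticCohort
from sdqtransitions.riskfactors import (
    ModelConfig,
    RiskFactorResult,
    build_contrast,
    identify_risk_factors,
)
from sdqtransitions.scoring import (
    BandTable,
    partition_sample,
    score_subscales,
    zscore_subscales,
)
from sdqtransitions.screening import ScreenReport, apply_screen
from sdqtransitions.transitions import (
    TransitionValidation,
    link_waves,
    test_transitions,
    validate_transition,
)

__all__ = ["StudyResult", "run_study"]

NON_ELEVATED_GROUP = "non_elevated"


@dataclass
class StudyResult:
    """Everything the pipeline computed, keyed by wave / wave pair."""

    scores: pd.DataFrame
    partition: pd.DataFrame
    screen_reports: list[ScreenReport]
    solutions: dict[str, ClusterSolution]
    group_labels: dict[str, pd.DataFrame]  # wave -> child_id, group
    transition_tables: dict[tuple[str, str], pd.DataFrame]
    validations: dict[tuple[str, str], list[TransitionValidation]] = field(default_factory=dict)
    risk_results: dict[tuple, RiskFactorResult] = field(default_factory=dict)


def _wave_groups(
    retained: pd.DataFrame, wave: str, solution: ClusterSolution, elevated_ids: np.ndarray
) -> pd.DataFrame:
    """Per-child group label for one wave: cluster id for elevated
    children, the non-elevated marker otherwise."""
    elevated = pd.DataFrame(
        {"child_id": elevated_ids, "group": [f"C{l}" for l in solution.labels]}
    )
    ne_ids = retained.loc[
        (retained["wave"] == wave) & (retained["label"] == NON_ELEVATED_GROUP), "child_id"
    ]
    non_elev = pd.DataFrame({"child_id": ne_ids, "group": NON_ELEVATED_GROUP})
    return pd.concat([elevated, non_elev], ignore_index=True)


def run_study(
    cohort: SyntheticCohort | pd.DataFrame,
    bands: BandTable | None = None,
    embedding: EmbeddingParams | None = None,
    k_range: range = range(2, 11),
    bootstrap_B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    run_risk_factors: bool = False,
    model_config: ModelConfig | None = None,
    max_risk_cells: int = 2,
) -> StudyResult:
    """Run the full analysis on a cohort.

    ``cohort`` is a :class:`~sdqtransitions.cohort.SyntheticCohort` or a
    bare records table (``child_id``, ``wave``, ``item_01``..``item_25``);
    risk-factor modelling needs the cohort's covariate table and is only
    run when ``run_risk_factors`` is set.
    """
    records = cohort.records if isinstance(cohort, SyntheticCohort) else cohort
    covariates = cohort.covariates if isinstance(cohort, SyntheticCohort) else None
    waves = list(pd.unique(records["wave"]))

    scores, _excluded = score_subscales(records)
    partition = partition_sample(scores, bands)
    retained, reports = apply_screen(scores, partition)

    solutions: dict[str, ClusterSolution] = {}
    group_labels: dict[str, pd.DataFrame] = {}
    for wave in waves:
        elev = retained[(retained["wave"] == wave) & (retained["label"] == "elevated")]
        z = zscore_subscales(elev)
        params = embedding or EmbeddingParams(seed=seed)
        coords = embed(z, params)
        solution = select_k(coords, wave=wave, k_range=k_range, B=bootstrap_B, seed=seed)
        solutions[wave] = solution
        group_labels[wave] = _wave_groups(
            retained, wave, solution, elev["child_id"].to_numpy()
        )

    transition_tables: dict[tuple[str, str], pd.DataFrame] = {}
    validations: dict[tuple[str, str], list[TransitionValidation]] = {}
    linked_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for w1, w2 in zip(waves[:-1], waves[1:]):
        linked = link_waves(group_labels[w1], group_labels[w2])
        linked_tables[(w1, w2)] = linked
        table = test_transitions(linked, alpha=alpha)
        transition_tables[(w1, w2)] = table

        sol = solutions[w1]
        sil = sol.silhouette_scores()
        id_to_pos = {
            cid: i
            for i, cid in enumerate(
                group_labels[w1].loc[group_labels[w1]["group"] != NON_ELEVATED_GROUP, "child_id"]
            )
        }
        checks = []
        flagged = table[table["significant"] & (table["source"] != NON_ELEVATED_GROUP)]
        for _, row in flagged.iterrows():
            cluster_pos = [
                id_to_pos[c]
                for c in group_labels[w1].loc[
                    group_labels[w1]["group"] == row["source"], "child_id"
                ]
            ]
            member_ids = linked.loc[
                (linked["group_source"] == row["source"])
                & (linked["group_dest"] == row["destination"]),
                "child_id",
            ]
            member_pos = [id_to_pos[c] for c in member_ids if c in id_to_pos]
            checks.append(
                validate_transition(
                    sil[cluster_pos], sil[member_pos], row["source"], row["destination"]
                )
            )
        validations[(w1, w2)] = checks

    result = StudyResult(
        scores=scores,
        partition=partition,
        screen_reports=reports,
        solutions=solutions,
        group_labels=group_labels,
        transition_tables=transition_tables,
        validations=validations,
    )

    if run_risk_factors:
        if covariates is None:
            raise ValueError("risk-factor modelling needs the cohort covariate table")
        for (w1, w2), table in transition_tables.items():
            flagged = table[
                table["significant"]
                & (table["source"] != NON_ELEVATED_GROUP)
                & (table["destination"] != NON_ELEVATED_GROUP)
            ].sort_values("proportion", ascending=False)
            for _, row in flagged.head(max_risk_cells).iterrows():
                contrast = build_contrast(
                    linked_tables[(w1, w2)], row["source"], row["destination"], NON_ELEVATED_GROUP
                )
                result.risk_results[(w1, w2, row["source"], row["destination"])] = (
                    identify_risk_factors(covariates, contrast, model_config)
                )
    return result
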