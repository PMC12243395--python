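import numpy as np
import pandas as pd
import pytest

from sdqtransitions.cohort import CohortSpec


NE_PROFILE = (0.5, 0.5, 1.0, 0.5, 0.5)


def make_spec(
    n_children: int = 500,
    seed: int = 0,
    profiles: dict | None = None,
    transition: pd.DataFrame | None = None,
    dispersion: float = 0.05,
    initial_distribution: dict | None = None,
    **kwargs,
) -> CohortSpec:
    """Small two-wave spec with three well-separated elevated profiles."""
    if profiles is None:
        profiles = {
            "w1": {
                "P1": (8.0, 2.0, 2.0, 2.0, 2.0),
                "P2": (2.0, 8.0, 2.0, 2.0, 2.0),
                "P3": (2.0, 2.0, 2.0, 8.0, 2.0),
                "NE": NE_PROFILE,
            },
            "w2": {
                "Q1": (8.0, 2.0, 2.0, 2.0, 2.0),
                "Q2": (2.0, 2.0, 8.0, 2.0, 2.0),
                "NE": NE_PROFILE,
            },
        }
    waves = tuple(profiles)
    if transition is None:
        w1, w2 = waves
        dests = list(profiles[w2])
        transition = pd.DataFrame(
            np.full((len(profiles[w1]), len(dests)), 1.0 / len(dests)),
            index=list(profiles[w1]),
            columns=dests,
        )
    return CohortSpec(
        n_children=n_children,
        waves=waves,
        cluster_profiles=profiles,
        non_elevated={w: "NE" for w in waves},
        profile_dispersion=dispersion,
        transition_matrices={(waves[0], waves[1]): transition},
        initial_distribution=initial_distribution,
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blob_coords(rng):
    """Three well-separated planted 2-D blobs with truth labels."""
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    labels = np.repeat(np.arange(3), 200)
    coords = centers[labels] + rng.normal(0, 0.5, size=(600, 2))
    return coords, labels
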