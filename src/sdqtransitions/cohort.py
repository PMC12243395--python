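"""Synthetic longitudinal cohorts with known profile-cluster ground truth.

The restricted birth-cohort data this kind of analysis targets cannot
be redistributed, so every downstream stage is exercised on simulated
cohorts: per wave, children belong to latent behavioural-profile groups
(one designated non-elevated) defined by mean vectors over the five SDQ
subscales; item responses are drawn per subscale as Binomial(2, p) with
p = mean/10 plus Gaussian profile noise; group membership evolves across
waves through a row-stochastic transition matrix whose destination logits
are shifted by planted covariate effects (a multinomial-logit model); and
covariate cells are masked MCAR or MAR to exercise missing-data handling.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from sdqtransitions.scoring import SUBSCALES, ITEM_COLUMNS

__all__ = [
    "Covariate",
    "Effect",
    "Missingness",
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "sample_items",
    "assign_transitions",
    "inject_missingness",
    "example_spec",
]


@dataclass(frozen=True)
class Covariate:
    """One child-level covariate: ``family`` is 'normal', 'bernoulli' or
    'uniform'; ``params`` are (mean, sd), (p,), or (lo, hi)."""

    name: str
    family: str
    params: tuple[float, ...]


@dataclass(frozen=True)
class Effect:
    """Planted log-odds shift: children in ``source`` with high
    ``covariate`` values are pushed toward ``dest``."""

    source: str
    dest: str
    covariate: str
    coef: float


@dataclass(frozen=True)
class Missingness:
    """Per-covariate masking: MCAR at ``rate``, or MAR with the cell's
    missing probability expit(logit(rate) + slope * z(conditioning))."""

    rate: float
    mechanism: str = "MCAR"
    conditioning: str | None = None
    slope: float = 1.0


@dataclass
class CohortSpec:
    """Full parameterisation of a synthetic cohort."""

    n_children: int
    waves: tuple[str, ...]
    #: wave -> group name -> length-5 subscale mean vector (difficulty scale)
    cluster_profiles: dict[str, dict[str, tuple[float, ...]]]
    #: wave -> the designated non-elevated group name
    non_elevated: dict[str, str]
    #: SD of the Gaussian perturbation on the item-probability scale,
    #: shared by a subscale's five items; scalar or length-5
    profile_dispersion: float | tuple[float, ...] = 0.08
    #: (wave_t, wave_t+1) -> row-stochastic DataFrame (rows: source groups)
    transition_matrices: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    #: wave-1 group -> probability; None = non-elevated share
    #: ``initial_non_elevated_share``, uniform over elevated groups
    initial_distribution: dict[str, float] | None = None
    initial_non_elevated_share: float = 0.6
    covariates: list[Covariate] = field(default_factory=list)
    effects: list[Effect] = field(default_factory=list)
    missingness: dict[str, Missingness] = field(default_factory=dict)
    #: wave -> probability a child (still present) drops out before it
    dropout: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def dispersion_vector(self) -> np.ndarray:
        d = self.profile_dispersion
        vec = np.full(5, float(d)) if np.isscalar(d) else np.asarray(d, dtype=float)
        if vec.shape != (5,):
            raise ValueError("profile_dispersion must be a scalar or length-5")
        return vec

    def validate(self) -> None:
        if self.n_children <= 0:
            raise ValueError("n_children must be positive")
        if len(self.waves) < 2:
            raise ValueError("need at least 2 waves")
        if np.any(self.dispersion_vector() < 0):
            raise ValueError("profile_dispersion must be nonnegative")
        for wave in self.waves:
            if wave not in self.cluster_profiles:
                raise ValueError(f"no cluster profiles for wave {wave!r}")
            if self.non_elevated.get(wave) not in self.cluster_profiles[wave]:
                raise ValueError(f"non_elevated group for wave {wave!r} not among its profiles")
            for group, means in self.cluster_profiles[wave].items():
                m = np.asarray(means, dtype=float)
                if m.shape != (5,):
                    raise ValueError(f"profile {wave}/{group} must have 5 subscale means")
                if np.any((m < 0) | (m > 10)):
                    raise ValueError(f"profile {wave}/{group} means must lie in [0, 10]")
        for (w1, w2), mat in self.transition_matrices.items():
            if w1 not in self.waves or w2 not in self.waves:
                raise ValueError(f"transition matrix references unknown waves ({w1}, {w2})")
            rows = set(mat.index)
            cols = set(mat.columns)
            if rows != set(self.cluster_profiles[w1]):
                raise ValueError(f"transition matrix ({w1}, {w2}) rows must match {w1} groups")
            if cols != set(self.cluster_profiles[w2]):
                raise ValueError(f"transition matrix ({w1}, {w2}) columns must match {w2} groups")
            vals = mat.to_numpy(dtype=float)
            if np.any(vals < 0):
                raise ValueError(f"transition matrix ({w1}, {w2}) has negative entries")
            if np.any(np.abs(vals.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError(f"transition matrix ({w1}, {w2}) rows must sum to 1")
        for i in range(len(self.waves) - 1):
            pair = (self.waves[i], self.waves[i + 1])
            if pair not in self.transition_matrices:
                raise ValueError(f"missing transition matrix for wave pair {pair}")
        cov_names = {c.name for c in self.covariates}
        for eff in self.effects:
            if eff.covariate not in cov_names:
                raise ValueError(f"effect references unknown covariate {eff.covariate!r}")
        for name, miss in self.missingness.items():
            if name not in cov_names:
                raise ValueError(f"missingness references unknown covariate {name!r}")
            if not 0.0 <= miss.rate <= 1.0:
                raise ValueError(f"missing rate for {name!r} must lie in [0, 1]")
            if miss.mechanism not in ("MCAR", "MAR"):
                raise ValueError(f"unknown missingness mechanism {miss.mechanism!r}")
            if miss.mechanism == "MAR" and miss.conditioning not in cov_names:
                raise ValueError(f"MAR conditioning covariate for {name!r} not defined")
        if self.initial_distribution is not None:
            groups = set(self.cluster_profiles[self.waves[0]])
            if set(self.initial_distribution) != groups:
                raise ValueError("initial_distribution keys must match wave-1 groups")
            total = sum(self.initial_distribution.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("initial_distribution must sum to 1")
        for wave, p in self.dropout.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"dropout probability for wave {wave!r} must lie in [0, 1]")

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["waves"] = list(self.waves)
        d["cluster_profiles"] = {
            w: {g: [float(m) for m in means] for g, means in groups.items()}
            for w, groups in self.cluster_profiles.items()
        }
        disp = self.profile_dispersion
        d["profile_dispersion"] = (
            float(disp) if np.isscalar(disp) else [float(v) for v in disp]
        )
        d["transition_matrices"] = {
            f"{w1}->{w2}": {
                src: {dest: float(mat.loc[src, dest]) for dest in mat.columns}
                for src in mat.index
            }
            for (w1, w2), mat in self.transition_matrices.items()
        }
        d["covariates"] = [
            {"name": c.name, "family": c.family, "params": [float(p) for p in c.params]}
            for c in self.covariates
        ]
        d["effects"] = [asdict(e) for e in self.effects]
        d["missingness"] = {k: asdict(v) for k, v in self.missingness.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        mats = {}
        for key, rows in d.get("transition_matrices", {}).items():
            w1, w2 = key.split("->")
            mats[(w1, w2)] = pd.DataFrame.from_dict(rows, orient="index")
        kwargs = dict(d)
        kwargs["waves"] = tuple(d["waves"])
        kwargs["cluster_profiles"] = {
            w: {g: tuple(m) for g, m in groups.items()}
            for w, groups in d["cluster_profiles"].items()
        }
        kwargs["transition_matrices"] = mats
        kwargs["covariates"] = [
            Covariate(c["name"], c["family"], tuple(c["params"]))
            for c in d.get("covariates", [])
        ]
        kwargs["effects"] = [
            Effect(e["source"], e["dest"], e["covariate"], e["coef"])
            for e in d.get("effects", [])
        ]
        kwargs["missingness"] = {
            k: Missingness(**v) for k, v in d.get("missingness", {}).items()
        }
        if "profile_dispersion" in d and not np.isscalar(d["profile_dispersion"]):
            kwargs["profile_dispersion"] = tuple(d["profile_dispersion"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SyntheticCohort:
    """Generated tables: item records, child covariates, true group labels."""

    records: pd.DataFrame    # child_id, wave, item_01..item_25
    covariates: pd.DataFrame  # child_id + one column per covariate
    truth: pd.DataFrame      # child_id, wave, group
    spec: CohortSpec

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def sample_items(
    profile_means, dispersion, rng: np.random.Generator
) -> np.ndarray:
    """Draw 25 item responses for one or more children.

    ``profile_means`` is a length-5 difficulty-scale mean vector (or an
    (n, 5) array).  For each (child, subscale) a shared Gaussian
    perturbation with SD ``dispersion`` is added to p = mean/10, clamped
    to [0, 1], and the subscale's five items are drawn independently as
    Binomial(2, p).  The prosocial block's probability is reversed
    (1 - p) so that the reverse-scored antisocial sum matches the stated
    difficulty mean.
    """
    means = np.atleast_2d(np.asarray(profile_means, dtype=float))
    if means.shape[1] != 5:
        raise ValueError("profile_means must have 5 entries per child")
    if np.any((means < 0) | (means > 10)):
        raise ValueError("profile means must lie in [0, 10]")
    disp = np.full(5, float(dispersion)) if np.isscalar(dispersion) else np.asarray(dispersion, dtype=float)
    if np.any(disp < 0):
        raise ValueError("dispersion must be nonnegative")

    n = means.shape[0]
    p = means / 10.0 + rng.normal(0.0, 1.0, size=(n, 5)) * disp
    p = np.clip(p, 0.0, 1.0)
    p[:, 4] = 1.0 - p[:, 4]  # prosocial items are reverse of antisocial difficulty
    item_p = np.repeat(p, 5, axis=1)  # blocks of five per subscale
    items = rng.binomial(2, item_p)
    return items[0] if np.asarray(profile_means).ndim == 1 else items


def assign_transitions(
    labels_t: np.ndarray | pd.Series,
    transition_matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    effects: list[Effect],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw each child's next-wave group from covariate-shifted logits.

    Destination probabilities start from the child's source row of the
    base matrix; each matching effect adds ``coef * covariate_value`` to
    the log of the destination's base probability before renormalising.
    With no effects this reduces exactly to sampling from the base row.
    ``covariates`` must be indexed like ``labels_t`` (positionally
    aligned, one row per child).
    """
    labels = np.asarray(labels_t)
    vals = transition_matrix.to_numpy(dtype=float)
    if np.any(np.abs(vals.sum(axis=1) - 1.0) > 1e-9) or np.any(vals < 0):
        raise ValueError("transition matrix must be row-stochastic")
    unknown = set(labels) - set(transition_matrix.index)
    if unknown:
        raise ValueError(f"labels not present in transition matrix rows: {sorted(unknown)}")
    for eff in effects:
        if eff.covariate not in covariates.columns:
            raise ValueError(f"covariate {eff.covariate!r} named in effects is absent")

    dests = np.asarray(transition_matrix.columns)
    n = len(labels)
    out = np.empty(n, dtype=object)
    for src in transition_matrix.index:
        mask = labels == src
        if not mask.any():
            continue
        base = transition_matrix.loc[src].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            logits = np.tile(np.log(base), (int(mask.sum()), 1))
        for eff in effects:
            if eff.source != src:
                continue
            j = int(np.flatnonzero(dests == eff.dest)[0])
            logits[:, j] += eff.coef * covariates.loc[mask, eff.covariate].to_numpy(dtype=float)
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(int(mask.sum()))
        idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        out[mask] = dests[idx]
    return out


def inject_missingness(
    covariates: pd.DataFrame,
    missingness: dict[str, Missingness],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Mask covariate cells MCAR or MAR; never touches truth labels.

    MAR masks a cell with probability expit(logit(rate) +
    slope * z(conditioning covariate)), so the marginal rate stays near
    the nominal rate while depending on an observed covariate.
    """
    from scipy.special import expit, logit

    out = covariates.copy()
    for name, miss in missingness.items():
        if name not in out.columns:
            raise ValueError(f"missingness names unknown covariate {name!r}")
        n = len(out)
        if miss.rate == 0.0:
            continue
        if miss.rate == 1.0:
            out[name] = np.nan
            continue
        if miss.mechanism == "MCAR":
            p = np.full(n, miss.rate)
        else:
            cond = out[miss.conditioning].to_numpy(dtype=float)
            sd = cond.std()
            z = (cond - cond.mean()) / sd if sd > 0 else np.zeros(n)
            p = expit(logit(miss.rate) + miss.slope * z)
        mask = rng.random(n) < p
        col = out[name].astype(float)
        col[mask] = np.nan
        out[name] = col
    return out


def _sample_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    cols = {"child_id": np.arange(spec.n_children)}
    for cov in spec.covariates:
        if cov.family == "normal":
            mu, sd = cov.params
            cols[cov.name] = rng.normal(mu, sd, spec.n_children)
        elif cov.family == "bernoulli":
            (p,) = cov.params
            cols[cov.name] = rng.binomial(1, p, spec.n_children).astype(float)
        elif cov.family == "uniform":
            lo, hi = cov.params
            cols[cov.name] = rng.uniform(lo, hi, spec.n_children)
        else:
            raise ValueError(f"unknown covariate family {cov.family!r}")
    return pd.DataFrame(cols)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate a full longitudinal cohort from a validated spec.

    Wave-1 groups come from the initial distribution; each later wave is
    drawn via :func:`assign_transitions`; item responses per (child,
    wave) via :func:`sample_items`; per-wave dropout (if configured)
    removes children from the records monotonically; covariate
    missingness is injected last.  The truth table keeps every child's
    generating group at every wave they are present.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_children
    covariates = _sample_covariates(spec, rng)

    wave1 = spec.waves[0]
    groups1 = sorted(spec.cluster_profiles[wave1])
    if spec.initial_distribution is not None:
        probs = np.array([spec.initial_distribution[g] for g in groups1])
    else:
        ne = spec.non_elevated[wave1]
        share = spec.initial_non_elevated_share
        k_elev = len(groups1) - 1
        probs = np.array(
            [share if g == ne else (1.0 - share) / k_elev for g in groups1]
        )
    labels = np.asarray(groups1, dtype=object)[rng.choice(len(groups1), size=n, p=probs)]

    labels_by_wave = {wave1: labels}
    for i in range(len(spec.waves) - 1):
        w1, w2 = spec.waves[i], spec.waves[i + 1]
        labels_by_wave[w2] = assign_transitions(
            labels_by_wave[w1],
            spec.transition_matrices[(w1, w2)],
            covariates,
            spec.effects,
            rng,
        )

    present = np.ones(n, dtype=bool)
    present_by_wave = {}
    for wave in spec.waves:
        p_drop = spec.dropout.get(wave, 0.0)
        if p_drop > 0:
            present = present & (rng.random(n) >= p_drop)
        present_by_wave[wave] = present.copy()

    disp = spec.dispersion_vector()
    rec_frames = []
    truth_frames = []
    for wave in spec.waves:
        mask = present_by_wave[wave]
        ids = covariates.loc[mask, "child_id"].to_numpy()
        wave_labels = labels_by_wave[wave][mask]
        means = np.array(
            [spec.cluster_profiles[wave][g] for g in wave_labels], dtype=float
        )
        items = sample_items(means, disp, rng) if len(ids) else np.empty((0, 25), dtype=int)
        rec = pd.DataFrame(items, columns=list(ITEM_COLUMNS))
        rec.insert(0, "wave", wave)
        rec.insert(0, "child_id", ids)
        rec_frames.append(rec)
        truth_frames.append(
            pd.DataFrame({"child_id": ids, "wave": wave, "group": wave_labels})
        )

    records = pd.concat(rec_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    covariates = inject_missingness(covariates, spec.missingness, rng)
    return SyntheticCohort(records=records, covariates=covariates, truth=truth, spec=spec)


def _rows(mat: dict[str, dict[str, float]]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(mat, orient="index").fillna(0.0)
    return df


def example_spec(n_children: int = 8000, seed: int = 0) -> CohortSpec:
    """Default study conditions: three waves shaped like a 3/5/3-cluster
    cohort with a non-elevated majority, above-chance planted transitions,
    and covariate effects on two of them.

    Profile means are on the 0-10 difficulty scale (the fifth entry is
    the reverse-scored antisocial subscale).  The non-elevated share at
    wave 1 is 0.6; planted transition cells (e.g. A1→B2 at 0.23,
    B5→C3 at 0.46) sit well above the equal-split nulls of 1/6 and 1/4.
    """
    profiles = {
        "age5": {
            "A1": (6.5, 6.5, 3.0, 2.0, 2.0),  # conduct + emotional
            "A2": (2.0, 2.0, 2.0, 2.0, 7.0),  # antisocial
            "A3": (2.0, 6.5, 3.0, 2.0, 7.0),  # conduct + antisocial
            "NE": (0.5, 0.5, 1.0, 0.5, 0.5),
        },
        "age11": {
            "B1": (2.0, 7.0, 3.0, 2.0, 2.0),  # conduct
            "B2": (5.0, 5.0, 5.5, 7.0, 2.0),  # complex peer
            "B3": (3.5, 2.0, 2.0, 7.0, 2.0),  # peer
            "B4": (7.0, 2.0, 2.0, 2.0, 2.0),  # emotional
            "B5": (2.0, 2.0, 2.0, 2.0, 7.0),  # antisocial
            "NE": (0.5, 0.5, 1.0, 0.5, 0.5),
        },
        "age17": {
            "C1": (7.0, 4.0, 2.0, 2.0, 2.0),  # emotional (+conduct)
            "C2": (4.0, 2.0, 2.0, 7.0, 2.0),  # peer (+emotional)
            "C3": (2.0, 5.0, 5.0, 5.0, 7.0),  # complex antisocial
            "NE": (0.5, 0.5, 1.0, 0.5, 0.5),
        },
    }
    t12 = _rows(
        {
            "A1": {"B1": 0.08, "B2": 0.23, "B3": 0.11, "B4": 0.11, "B5": 0.10, "NE": 0.37},
            "A2": {"B1": 0.10, "B2": 0.10, "B3": 0.11, "B4": 0.10, "B5": 0.22, "NE": 0.37},
            "A3": {"B1": 0.21, "B2": 0.10, "B3": 0.11, "B4": 0.10, "B5": 0.11, "NE": 0.37},
            "NE": {"B1": 0.05, "B2": 0.05, "B3": 0.05, "B4": 0.05, "B5": 0.05, "NE": 0.75},
        }
    )
    t23 = _rows(
        {
            "B1": {"C1": 0.15, "C2": 0.15, "C3": 0.32, "NE": 0.38},
            "B2": {"C1": 0.20, "C2": 0.30, "C3": 0.15, "NE": 0.35},
            "B3": {"C1": 0.19, "C2": 0.33, "C3": 0.15, "NE": 0.33},
            "B4": {"C1": 0.35, "C2": 0.15, "C3": 0.13, "NE": 0.37},
            "B5": {"C1": 0.07, "C2": 0.10, "C3": 0.46, "NE": 0.37},
            "NE": {"C1": 0.06, "C2": 0.07, "C3": 0.07, "NE": 0.80},
        }
    )
    covariates = [
        Covariate("gender", "bernoulli", (0.5,)),
        Covariate("maternal_depression", "bernoulli", (0.3,)),
        Covariate("income_low", "bernoulli", (0.32,)),
        Covariate("home_chaos", "normal", (0.0, 1.0)),
        Covariate("cognitive_score", "normal", (0.0, 1.0)),
        Covariate("longstanding_illness", "bernoulli", (0.15,)),
    ]
    effects = [
        Effect("A1", "B2", "home_chaos", 0.8),
        Effect("A1", "B2", "longstanding_illness", 0.9),
        Effect("B5", "C3", "maternal_depression", 0.9),
        Effect("B3", "C2", "maternal_depression", 0.7),
    ]
    missingness = {
        "maternal_depression": Missingness(0.05, "MCAR"),
        "home_chaos": Missingness(0.05, "MCAR"),
        "cognitive_score": Missingness(0.10, "MAR", conditioning="income_low"),
    }
    return CohortSpec(
        n_children=n_children,
        waves=("age5", "age11", "age17"),
        cluster_profiles=profiles,
        non_elevated={"age5": "NE", "age11": "NE", "age17": "NE"},
        profile_dispersion=0.08,
        transition_matrices={("age5", "age11"): t12, ("age11", "age17"): t23},
        initial_non_elevated_share=0.6,
        covariates=covariates,
        effects=effects,
        missingness=missingness,
        dropout={"age11": 0.05, "age17": 0.10},
        seed=seed,
    )
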