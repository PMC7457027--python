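"""Random-parameter ensembles of the metabolic circuit (RACIPE-style).

Each ensemble draws many parameter sets uniformly from a relative window
around the frozen baseline, collects all stable steady states, and
characterizes the resulting state population statistically: z-scoring
against a reference scenario, hierarchical clustering (Ward) cut at four
clusters, labelling clusters by their centroid sign patterns as the four
metabolic phenotypes (O, W, W/O, L/L), and per-scenario phenotype
fractions with across-repeat error bars.

The canonical 2x2 scenario grid varies HIF-1 degradation (0.25 vs 0.45
per hour) and mtROS production (45 vs 30 mM/min); the scenario with high
mtROS and high HIF-1 (low degradation) is the reference whose mean/sd
and PCA loadings normalize and project every other scenario.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA

from .core import SteadyStateRecord, find_steady_states
from .params import ConfigError, ModelParameters, SolverSettings

logger = logging.getLogger(__name__)

#: Feature (column) order of state tables, matching the heat-map layout
FEATURES = ("F", "Rmt", "G1", "A", "Rnox", "H", "G2")

STATE_NAMES = ("O", "W", "W/O", "L/L")

#: canonical centroid sign prototypes in z-score space, per feature order
_PROTOTYPES = pd.DataFrame(
    {
        "O":   [+1, +1, +1, +1, -1, -1, -1],
        "W":   [-1, -1, -1, -1, +1, +1, +1],
        "W/O": [+1, +1, +1, +1, +1, +1, +1],
        "L/L": [-1, -1, -1, -1, -1, -1, -1],
    },
    index=list(FEATURES),
).T


@dataclass(frozen=True)
class Scenario:
    """One cell of the 2x2 (mtROS production x HIF-1 degradation) grid.

    ``g_Rmt`` is in mM/min (converted internally), ``k_H`` in 1/hour.
    High HIF-1 means slow degradation (k_H = 0.25); low means fast
    (k_H = 0.45).
    """

    name: str
    g_Rmt: float
    k_H: float

    def overrides(self) -> dict[str, float]:
        # internal canonical units are per-hour
        return {"g_Rmt": self.g_Rmt * 60.0, "k_H": self.k_H}


REFERENCE_SCENARIO = Scenario("high_mtROS_high_HIF1", g_Rmt=45.0, k_H=0.25)

CANONICAL_SCENARIOS: tuple[Scenario, ...] = (
    REFERENCE_SCENARIO,
    Scenario("high_mtROS_low_HIF1", g_Rmt=45.0, k_H=0.45),
    Scenario("low_mtROS_high_HIF1", g_Rmt=30.0, k_H=0.25),
    Scenario("low_mtROS_low_HIF1", g_Rmt=30.0, k_H=0.45),
)


@dataclass
class EnsembleResult:
    """Stable steady-state records of one scenario plus, once fitted,
    the normalization statistics, PCA loadings and cluster labels."""

    scenario: Scenario
    records: pd.DataFrame
    norm_mean: pd.Series | None = None
    norm_sd: pd.Series | None = None
    pc_loadings: np.ndarray | None = None        # (2, n_features)
    explained_variance_ratio: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None
    fractions: pd.Series | None = None


def sample_parameters(
    baseline: ModelParameters,
    fraction: float = 0.25,
    fixed: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> ModelParameters:
    """Draw one random parameter set from the relative window
    ``((1-fraction)*P0, (1+fraction)*P0)`` around the baseline.

    Hill coefficients are resampled in the same relative window but
    rounded to integers (minimum 1).  Parameters named in ``fixed`` are
    set exactly to the override (internal per-hour units) and excluded
    from sampling -- this is how scenarios pin HIF-1 degradation and
    mtROS production.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    rng = rng or np.random.default_rng()
    fixed = dict(fixed or {})
    base = baseline.flatten()
    unknown = set(fixed) - set(base)
    if unknown:
        raise ConfigError(f"fixed overrides name unknown parameter(s): {sorted(unknown)}")
    values: dict[str, float] = {}
    for name, p0 in base.items():
        if name in fixed:
            values[name] = float(fixed[name])
            continue
        val = rng.uniform((1 - fraction) * p0, (1 + fraction) * p0)
        if name.startswith("n_"):
            val = max(1, int(round(val)))
        values[name] = val
    return baseline.with_values(values)


def records_to_frame(records: Sequence[SteadyStateRecord]) -> pd.DataFrame:
    """Flatten steady-state records into the canonical table layout."""
    rows = [
        {
            "param_set_id": r.param_set_id,
            "A": r.state.A, "H": r.state.H, "Rmt": r.state.Rmt, "Rnox": r.state.Rnox,
            "G1": r.rates.G1, "G2": r.rates.G2, "F": r.rates.F,
            "G1_atp": r.rates.G1_atp, "G2_atp": r.rates.G2_atp, "F_atp": r.rates.F_atp,
            "stable": r.stable, "max_eig_real": r.max_eig_real,
        }
        for r in records
    ]
    cols = ["param_set_id", "A", "H", "Rmt", "Rnox", "G1", "G2", "F",
            "G1_atp", "G2_atp", "F_atp", "stable", "max_eig_real"]
    return pd.DataFrame(rows, columns=cols)


def run_ensemble(
    baseline: ModelParameters,
    scenario: Scenario,
    n_sets: int,
    rng: np.random.Generator,
    fraction: float = 0.25,
    settings: SolverSettings | None = None,
) -> EnsembleResult:
    """Collect stable steady states across ``n_sets`` random parameter
    sets with the scenario's rates pinned.  Parameter sets yielding no
    converged root are logged and skipped."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    settings = settings or SolverSettings()
    fixed = scenario.overrides()
    all_records: list[SteadyStateRecord] = []
    for set_id in range(n_sets):
        p = sample_parameters(baseline, fraction=fraction, fixed=fixed, rng=rng)
        recs = find_steady_states(p, rng=rng, settings=settings, param_set_id=set_id)
        all_records.extend(r for r in recs if r.stable)
    frame = records_to_frame(all_records)
    return EnsembleResult(scenario=scenario, records=frame)


def _feature_table(records: pd.DataFrame) -> pd.DataFrame:
    """log10 feature table (all circuit quantities are strictly positive
    at steady state; multiplicative parameter sampling makes the log
    scale the natural one for z-scoring)."""
    return np.log10(records.loc[:, list(FEATURES)])


def fit_reference(result: EnsembleResult) -> EnsembleResult:
    """Compute mean/sd normalization statistics and the first two PCA
    loading vectors on a (reference) scenario's own records."""
    feats = _feature_table(result.records)
    mean = feats.mean(axis=0)
    sd = feats.std(axis=0, ddof=1)
    dead = sd.index[~(sd > 1e-12 * np.maximum(1.0, mean.abs()))]
    if len(dead):
        raise ValueError(f"zero-variance feature(s) in reference: {list(dead)}")
    Z = (feats - mean) / sd
    pca = PCA(n_components=2).fit(Z.to_numpy())
    return replace(
        result,
        norm_mean=mean,
        norm_sd=sd,
        pc_loadings=pca.components_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def normalize_and_project(
    records: pd.DataFrame, reference: EnsembleResult
) -> tuple[pd.DataFrame, np.ndarray]:
    """z-normalize records with the reference scenario's mean/sd only,
    and project onto the reference's first two principal axes."""
    if reference.norm_mean is None or reference.pc_loadings is None:
        raise ValueError("reference has no fitted statistics; call fit_reference")
    feats = _feature_table(records)
    Z = (feats - reference.norm_mean) / reference.norm_sd
    pcs = Z.to_numpy() @ reference.pc_loadings.T
    return Z, pcs


def _rule_label(c: pd.Series) -> str | None:
    if c["A"] > 0 and c["H"] > 0:
        return "W/O"
    if c["A"] > 0 and c["H"] < 0 and (c["G1"] > 0 or c["F"] > 0) and c["G2"] < 0:
        return "O"
    if c["A"] < 0 and c["H"] > 0 and c["G2"] > 0:
        return "W"
    if c["A"] < 0 and c["H"] < 0 and c["G1"] < 0 and c["G2"] < 0:
        return "L/L"
    return None


def cluster_and_label(Z: pd.DataFrame, k: int = 4, method: str = "ward") -> np.ndarray:
    """Agglomerative clustering of z-scored states, tree cut at ``k``,
    each cluster named by its centroid sign pattern.

    If the rule patterns are ambiguous (a centroid matching none, or two
    clusters claiming the same phenotype) the clusters are assigned to
    the nearest canonical prototypes one-to-one, with a warning.
    """
    if len(Z) < k:
        raise ValueError(f"need at least {k} records to cut {k} clusters")
    link = linkage(Z.to_numpy(), method=method)
    assignments = fcluster(link, t=k, criterion="maxclust")
    centroids = Z.groupby(assignments).mean()
    labels = {cid: _rule_label(c) for cid, c in centroids.iterrows()}
    named = [v for v in labels.values() if v is not None]
    if len(set(named)) != len(named) or None in labels.values():
        logger.warning("ambiguous centroid sign patterns; assigning clusters "
                       "to nearest canonical prototypes")
        proto = _PROTOTYPES.loc[:, list(FEATURES)].to_numpy()
        # normalize centroid rows so distance compares direction not size
        C = centroids.to_numpy()
        C = C / np.maximum(np.linalg.norm(C, axis=1, keepdims=True), 1e-12)
        P = proto / np.linalg.norm(proto, axis=1, keepdims=True)
        cost = ((C[:, None, :] - P[None, :, :]) ** 2).sum(axis=2)
        rows, cols = linear_sum_assignment(cost)
        labels = {centroids.index[i]: _PROTOTYPES.index[j] for i, j in zip(rows, cols)}
    return np.array([labels[cid] for cid in assignments])


def state_fractions(labels: np.ndarray) -> pd.Series:
    """Fraction of records per phenotype (all four states reported,
    absent ones as 0); sums to 1."""
    counts = pd.Series(labels).value_counts()
    frac = pd.Series({s: counts.get(s, 0) / len(labels) for s in STATE_NAMES})
    frac.name = "fraction"
    return frac


@dataclass
class FractionSummary:
    """Per-scenario phenotype fractions: across-repeat mean and sd."""

    mean: pd.DataFrame          # scenario x state
    sd: pd.DataFrame
    per_repeat: list[pd.DataFrame] = field(default_factory=list)


def scenario_fractions(
    baseline: ModelParameters,
    scenarios: Sequence[Scenario] = CANONICAL_SCENARIOS,
    n_sets: int = 500,
    n_repeats: int = 3,
    rng: np.random.Generator | None = None,
    fraction: float = 0.25,
    settings: SolverSettings | None = None,
    reference_name: str = REFERENCE_SCENARIO.name,
) -> FractionSummary:
    """Full scenario pipeline: per repeat, run every scenario's ensemble
    with fresh sub-seeds, normalize and label using the reference
    scenario of that repeat, and summarize phenotype fractions across
    repeats."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = rng or np.random.default_rng()
    by_name = {s.name: s for s in scenarios}
    if reference_name not in by_name:
        raise ConfigError(f"reference scenario {reference_name!r} not among scenarios")
    per_repeat: list[pd.DataFrame] = []
    for rep in range(n_repeats):
        sub = {s.name: g for s, g in zip(scenarios, rng.spawn(len(scenarios)))}
        results = {
            s.name: run_ensemble(baseline, s, n_sets, sub[s.name],
                                 fraction=fraction, settings=settings)
            for s in scenarios
        }
        reference = fit_reference(results[reference_name])
        rows = {}
        for name, res in results.items():
            Z, _ = normalize_and_project(res.records, reference)
            labels = cluster_and_label(Z)
            res.cluster_labels = labels
            res.fractions = state_fractions(labels)
            rows[name] = res.fractions
        per_repeat.append(pd.DataFrame(rows).T.loc[[s.name for s in scenarios]])
    stacked = np.stack([df.to_numpy() for df in per_repeat])
    idx, cols = per_repeat[0].index, per_repeat[0].columns
    mean = pd.DataFrame(stacked.mean(axis=0), index=idx, columns=cols)
    sd = pd.DataFrame(
        stacked.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros_like(stacked[0]),
        index=idx, columns=cols,
    )
    return FractionSummary(mean=mean, sd=sd, per_repeat=per_repeat)
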