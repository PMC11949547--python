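"""Genetic-algorithm search for constrained synaptic weight sets.

The search is a mutate-and-filter scheme: a pool of accepted weight
sets is grown by picking a parent uniformly at random, multiplying a
Poisson-distributed number of its weights by independent Uniform(0.1,
2) factors (signs never change), and keeping the child only if it
satisfies all constraints:

Primary (at baseline, nothing removed, no STIM):
  - PYR theta and gamma peak powers >= 60% of the reference set's
    baseline powers;
  - ratio of maximal PV to maximal BiC firing rate >= 0.67;
  - maximal CCK firing rate > 4 Hz.
Secondary (theta must break down under critical removals):
  - removing any one of PYR->PYR, CCK->PV, PV->PYR, BiC->PYR leaves
    PYR theta peak power < 10% of the reference baseline.

Accepted pools are clustered by k-means in the 9-dimensional weight
space (k chosen by silhouette), clusters are retained only if some
member reaches a PV/BiC activity ratio >= 0.70, and up to 10 cluster
medoids become the representative sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .model import CellType, ModelParams, WeightSet, MASK_EDGES
from .simulate import SimConfig, simulate, remove_connection
from .spectral import spectral_summary

__all__ = ["GAConfig", "ConstraintReport", "SearchResult", "mutate",
           "evaluate_primary", "evaluate_secondary", "evaluate_constraints",
           "run_ga", "cluster_and_select", "select_study_sets",
           "weight_structure_report", "CRITICAL_EDGES", "GA_CELL_CODING"]

log = logging.getLogger(__name__)

#: Removals that must abolish theta (secondary constraint).
CRITICAL_EDGES = (
    (CellType.PYR, CellType.PYR),
    (CellType.CCK, CellType.PV),
    (CellType.PV, CellType.PYR),
    (CellType.BiC, CellType.PYR),
)

#: Integer coding used when sampling connections to mutate.
GA_CELL_CODING = {0: CellType.PYR, 1: CellType.BiC,
                  2: CellType.PV, 3: CellType.CCK}


@dataclass(frozen=True)
class GAConfig:
    target_count: int = 200
    mutation_count_mean: float = 2.0
    factor_range: tuple = (0.1, 2.0)
    primary_power_fraction: float = 0.60
    pv_bic_ratio_min: float = 0.67
    cck_min_rate: float = 4.0
    secondary_theta_fraction: float = 0.10
    cluster_ratio_min: float = 0.70
    max_evaluations: int = 100_000
    seed: int = 0

    def __post_init__(self):
        for name in ("primary_power_fraction", "secondary_theta_fraction",
                     "cluster_ratio_min"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.target_count < 1:
            raise ValueError("target_count must be >= 1")
        lo, hi = self.factor_range
        if lo <= 0 or hi <= lo:
            raise ValueError("factor_range must be positive and increasing")


@dataclass(frozen=True)
class ConstraintReport:
    """Measured values and pass/fail flags for one weight set."""

    theta_power: float = np.nan
    gamma_power: float = np.nan
    theta_freq: float = np.nan
    gamma_freq: float = np.nan
    pv_bic_ratio: float = np.nan
    ratio_defined: bool = True
    cck_max_rate: float = np.nan
    primary_power_ok: bool = False
    ratio_ok: bool = False
    cck_ok: bool = False
    removal_theta_powers: dict = field(default_factory=dict)
    removal_ok: dict = field(default_factory=dict)

    @property
    def primary_pass(self) -> bool:
        return self.primary_power_ok and self.ratio_ok and self.cck_ok

    @property
    def secondary_pass(self) -> bool:
        return bool(self.removal_ok) and all(self.removal_ok.values())

    @property
    def overall_pass(self) -> bool:
        return self.primary_pass and self.secondary_pass

    def failing(self) -> list:
        out = []
        if not self.primary_power_ok:
            out.append("primary_power")
        if not self.ratio_ok:
            out.append("pv_bic_ratio" + ("" if self.ratio_defined
                                         else " (undefined)"))
        if not self.cck_ok:
            out.append("cck_max_rate")
        out.extend(f"removal {k}" for k, ok in self.removal_ok.items()
                   if not ok)
        return out

    def to_dict(self) -> dict:
        return {"theta_power": self.theta_power, "gamma_power": self.gamma_power,
                "theta_freq": self.theta_freq, "gamma_freq": self.gamma_freq,
                "pv_bic_ratio": self.pv_bic_ratio,
                "ratio_defined": self.ratio_defined,
                "cck_max_rate": self.cck_max_rate,
                "removal_theta_powers": dict(self.removal_theta_powers),
                "overall_pass": self.overall_pass}


def mutate(parent: WeightSet, rng: np.random.Generator,
           config: GAConfig | None = None) -> WeightSet:
    """Mutated child of ``parent``.

    Draws n ~ Poisson(mean) (redrawn until n >= 1: a zero-mutation
    child would be a duplicate), selects n distinct mask edges by
    sampling ordered (source, target) integer pairs under the coding
    0=PYR, 1=BiC, 2=PV, 3=CCK and rejecting pairs that are not circuit
    connections, then multiplies each selected weight by an independent
    Uniform(0.1, 2) factor.  Signs are preserved by construction.
    """
    config = config or GAConfig()
    n = 0
    while n < 1:
        n = rng.poisson(config.mutation_count_mean)
    n = min(n, len(MASK_EDGES))
    chosen: list = []
    while len(chosen) < n:
        i, j = rng.integers(0, 4, size=2)
        edge = (GA_CELL_CODING[int(i)], GA_CELL_CODING[int(j)])
        from .model import MASK
        if edge not in MASK or edge in chosen:
            continue
        chosen.append(edge)
    lo, hi = config.factor_range
    w = dict(parent.w)
    for edge in chosen:
        w[edge] = w[edge] * rng.uniform(lo, hi)
    return WeightSet(w)


def _baseline_metrics(weights: WeightSet, params: ModelParams,
                      sim_config: SimConfig):
    trial = params.with_weights(weights)
    trace = simulate(trial, config=sim_config)
    summary = spectral_summary(trace, sim_config)
    post = trace.after(sim_config.transient_discard)
    max_rates = {c: float(post.cell(c).max()) for c in CellType}
    return summary, max_rates


def evaluate_primary(weights: WeightSet, reference_powers,
                     params: ModelParams | None = None,
                     config: GAConfig | None = None,
                     sim_config: SimConfig | None = None) -> ConstraintReport:
    """Baseline constraints against the reference powers."""
    params = params or ModelParams()
    config = config or GAConfig()
    sim_config = sim_config or SimConfig()
    theta_ref, gamma_ref = reference_powers
    summary, max_rates = _baseline_metrics(weights, params, sim_config)

    power_ok = (summary.theta_power >= config.primary_power_fraction * theta_ref
                and summary.gamma_power >= config.primary_power_fraction * gamma_ref)
    bic_max = max_rates[CellType.BiC]
    ratio_defined = bic_max > 1e-6
    ratio = max_rates[CellType.PV] / bic_max if ratio_defined else np.nan
    ratio_ok = ratio_defined and ratio >= config.pv_bic_ratio_min
    cck_ok = max_rates[CellType.CCK] > config.cck_min_rate
    return ConstraintReport(
        theta_power=summary.theta_power, gamma_power=summary.gamma_power,
        theta_freq=summary.theta_freq, gamma_freq=summary.gamma_freq,
        pv_bic_ratio=ratio, ratio_defined=ratio_defined,
        cck_max_rate=max_rates[CellType.CCK],
        primary_power_ok=power_ok, ratio_ok=ratio_ok, cck_ok=cck_ok)


def evaluate_secondary(weights: WeightSet, reference_theta_power: float,
                       params: ModelParams | None = None,
                       config: GAConfig | None = None,
                       sim_config: SimConfig | None = None) -> dict:
    """Theta breakdown under each critical removal.

    Returns per-edge theta powers and pass flags (power < 10% of the
    reference baseline theta power).
    """
    params = params or ModelParams()
    config = config or GAConfig()
    sim_config = sim_config or SimConfig()
    powers, flags = {}, {}
    for edge in CRITICAL_EDGES:
        trial = remove_connection(params.with_weights(weights), edge)
        trace = simulate(trial, config=sim_config)
        summary = spectral_summary(trace, sim_config)
        key = f"{edge[0].name}->{edge[1].name}"
        powers[key] = summary.theta_power
        flags[key] = bool(summary.theta_power
                          < config.secondary_theta_fraction
                          * reference_theta_power)
    return {"removal_theta_powers": powers, "removal_ok": flags}


def evaluate_constraints(weights: WeightSet, reference_powers,
                         params: ModelParams | None = None,
                         config: GAConfig | None = None,
                         sim_config: SimConfig | None = None) -> ConstraintReport:
    """Primary + secondary constraint battery for one weight set."""
    primary = evaluate_primary(weights, reference_powers, params, config,
                               sim_config)
    if not primary.primary_pass:
        # secondary simulations are skipped for a child already rejected
        return primary
    secondary = evaluate_secondary(weights, reference_powers[0], params,
                                   config, sim_config)
    from dataclasses import replace
    return replace(primary, **secondary)


@dataclass
class SearchResult:
    accepted: list                  # list of (WeightSet, ConstraintReport)
    evaluations: int
    seed: int
    reference_powers: tuple
    cluster_labels: np.ndarray | None = None
    representatives: list = field(default_factory=list)
    complete: bool = True

    @property
    def weight_matrix(self) -> np.ndarray:
        return np.array([ws.as_vector() for ws, _ in self.accepted])


def run_ga(start: WeightSet, config: GAConfig,
           params: ModelParams | None = None,
           sim_config: SimConfig | None = None,
           reference_powers=None,
           progress=None) -> SearchResult:
    """Grow a pool of constrained weight sets from a passing start set.

    The reference powers default to the start set's own baseline theta
    and gamma peak powers.  Stops when ``target_count`` sets are
    accepted or ``max_evaluations`` children have been tested (the
    partial pool is then returned flagged incomplete).
    """
    params = params or ModelParams()
    sim_config = sim_config or SimConfig()
    rng = np.random.default_rng(config.seed)

    if reference_powers is None:
        summary, _ = _baseline_metrics(start, params, sim_config)
        reference_powers = (summary.theta_power, summary.gamma_power)

    start_report = evaluate_constraints(start, reference_powers, params,
                                        config, sim_config)
    if not start_report.overall_pass:
        raise ValueError(
            "start weight set fails the constraints "
            f"({', '.join(start_report.failing())}); hand-tune it or use "
            "the shipped reference set")

    pool = [(start, start_report)]
    evaluations = 0
    while len(pool) < config.target_count:
        if evaluations >= config.max_evaluations:
            return SearchResult(pool, evaluations, config.seed,
                                tuple(reference_powers), complete=False)
        parent, _ = pool[rng.integers(0, len(pool))]
        child = mutate(parent, rng, config)
        report = evaluate_constraints(child, reference_powers, params,
                                      config, sim_config)
        evaluations += 1
        if report.overall_pass:
            pool.append((child, report))
            if progress is not None:
                progress(len(pool), evaluations)
    result = SearchResult(pool, evaluations, config.seed,
                          tuple(reference_powers), complete=True)
    weight_structure_report(result)
    return result


def weight_structure_report(result: SearchResult) -> dict:
    """Soft check of the accepted pool's weight-magnitude structure.

    In large constrained ensembles the PYR->PYR median magnitude tends
    to dominate the excitatory edges and the CCK-involving medians the
    inhibitory ones.  Deviations are logged as warnings, never raised:
    the structure is an empirical tendency, not a constraint.
    """
    from .model import MASK, edge_key
    X = np.abs(result.weight_matrix)
    medians = {edge_key(e): float(np.median(X[:, i]))
               for i, e in enumerate(MASK.edges)}
    exc = {k: medians[k] for k in ("PYR->PYR", "PYR->BiC", "PYR->PV")}
    inh = {k: v for k, v in medians.items() if k not in exc}
    report = {"medians": medians,
              "pyr_pyr_largest_excitatory":
                  max(exc, key=exc.get) == "PYR->PYR",
              "cck_edges_lead_inhibitory":
                  all(k.startswith("CCK") for k in
                      sorted(inh, key=inh.get, reverse=True)[:2])}
    if not report["pyr_pyr_largest_excitatory"]:
        log.warning("accepted pool: PYR->PYR median |w| is not the largest "
                    "excitatory weight (%s)", exc)
    if not report["cck_edges_lead_inhibitory"]:
        log.warning("accepted pool: CCK->CCK / CCK->PV medians are not the "
                    "largest inhibitory weights (%s)", inh)
    return report


def cluster_and_select(result: SearchResult,
                       config: GAConfig | None = None,
                       max_k: int = 20,
                       max_representatives: int = 10) -> list:
    """k-means degeneracy clustering and medoid selection.

    k maximizes the mean silhouette over 2..max_k in raw weight space.
    Clusters are retained only if at least one member's PV/BiC maximal-
    rate ratio reaches the (stricter) cluster threshold; medoids of the
    retained clusters, at most ``max_representatives`` ordered by
    cluster size, become the representatives.  Updates ``result`` in
    place and returns the representative WeightSets.
    """
    config = config or GAConfig()
    X = result.weight_matrix
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 accepted sets to cluster")
    uniq = np.unique(X, axis=0)
    if len(uniq) == 1:
        result.cluster_labels = np.zeros(n, dtype=int)
        result.representatives = [result.accepted[0][0]]
        return result.representatives

    best_k, best_score, best_labels = None, -np.inf, None
    for k in range(2, min(max_k, len(uniq), n - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=config.seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(X, labels)
        if score > best_score:
            best_k, best_score, best_labels = k, score, labels
    if best_labels is None:
        # pool too small for silhouette selection: one cluster per
        # distinct weight vector
        _, best_labels = np.unique(X, axis=0, return_inverse=True)
    labels = best_labels
    result.cluster_labels = labels

    ratios = np.array([rep.pv_bic_ratio if rep.ratio_defined else -np.inf
                       for _, rep in result.accepted])
    retained = [k for k in np.unique(labels)
                if np.any(ratios[labels == k] >= config.cluster_ratio_min)]
    if not retained:
        raise RuntimeError(
            "no cluster contains a member with PV/BiC ratio >= "
            f"{config.cluster_ratio_min}; consider relaxing the threshold")

    sizes = {k: int(np.sum(labels == k)) for k in retained}
    reps = []
    for k in sorted(retained, key=lambda k: -sizes[k])[:max_representatives]:
        members = np.where(labels == k)[0]
        centroid = X[members].mean(axis=0)
        medoid = members[int(np.argmin(
            np.linalg.norm(X[members] - centroid, axis=1)))]
        reps.append(result.accepted[medoid][0])
    result.representatives = reps
    return reps


def select_study_sets(result: SearchResult, min_sets: int = 5,
                      config: GAConfig | None = None) -> list:
    """Representative sets, padded to ``min_sets`` for small pools.

    Large searches yield enough clusters that the medoids alone form
    the study ensemble; scaled-down pools can collapse to very few
    clusters.  In that case the ensemble is topped up with the accepted
    sets farthest (max-min Euclidean distance in weight space) from the
    sets already chosen, preserving diversity without touching the
    clustering itself.
    """
    reps = list(result.representatives or
                cluster_and_select(result, config))
    if len(reps) >= min_sets:
        return reps
    X = result.weight_matrix
    chosen_vecs = [ws.as_vector() for ws in reps]
    chosen_idx = {i for i, (ws, _) in enumerate(result.accepted)
                  if any(np.array_equal(ws.as_vector(), v)
                         for v in chosen_vecs)}
    while len(reps) < min(min_sets, len(result.accepted)):
        dists = [min(np.linalg.norm(X[i] - v) for v in chosen_vecs)
                 if i not in chosen_idx else -1.0
                 for i in range(len(X))]
        i = int(np.argmax(dists))
        if dists[i] < 0:
            break
        chosen_idx.add(i)
        chosen_vecs.append(X[i])
        reps.append(result.accepted[i][0])
    return reps
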