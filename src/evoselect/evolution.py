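"""Integrated evolutionary learning: a genetic meta-learner that jointly
selects feature subsets and tunes hyperparameters against a BIC fitness.

One candidate ("chromosome") is a hyperparameter assignment over a declared
search space plus a feature-subset index list.  Each generation every
candidate is scored by cross-validated BIC; the population is then ranked and
bred: the best models are split into recombination parents (adjacent-rank
pairs averaged after a midpoint pivot), mutated models (one hyperparameter
shifted by its declared step) and discards, while fresh random models keep the
search exploring.  Feature subsets are inherited whole: the subsets of the
top-ranked models are reallocated rank-order to the bred children.

When the best-so-far BIC plateaus, a warm restart constrains the feature pool
to features whose aggregated importance clears the fitness-vs-feature-count
elbow, then escalates the cutoff (mean + m*SD, m = 2..10) with a reduced
generation schedule, concentrating the search on the features that matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .estimators import EstimatorSpec, FitnessRecord, cv_fit
from .search_space import SearchSpace

__all__ = [
    "Chromosome",
    "EvolutionConfig",
    "GenerationLog",
    "OptimizationResult",
    "init_population",
    "recombine",
    "mutate",
    "allocate_feature_sets",
    "step_generation",
    "detect_plateau",
    "fitness_elbow",
    "escalation_pools",
    "IELClassifier",
    "run_iel",
]


@dataclass(frozen=True)
class Chromosome:
    """One candidate solution: hyperparameters + feature-subset indices."""

    hyperparams: tuple[tuple[str, object], ...]
    feature_subset: tuple[int, ...]
    lineage: str = "fresh"

    @classmethod
    def make(cls, hyperparams: dict, subset, lineage: str = "fresh") -> "Chromosome":
        return cls(
            tuple(sorted(hyperparams.items())),
            tuple(sorted(int(i) for i in subset)),
            lineage,
        )

    @property
    def params(self) -> dict:
        return dict(self.hyperparams)

    def key(self) -> tuple:
        """Identity for caching: lineage does not change the fit."""
        return (self.hyperparams, self.feature_subset)


@dataclass
class EvolutionConfig:
    """Population bookkeeping for the main run and the warm-restart phases.

    Defaults follow the published schedule: generations of 100 models whose
    best 80 split into 40 recombination parents (-> 20 children), 20 mutated
    and 20 discarded, topped up with 60 fresh random models; warm-restart
    generations shrink to 50 models with 20 recombined children, 10 mutated
    and 20 fresh.
    """

    population: int = 100
    n_best: int = 80
    n_recombine_parents: int = 40
    n_children_recombine: int = 20
    n_mutate: int = 20
    n_discard: int = 20
    n_fresh: int = 60
    n_donors: int = 60
    #: how many top records (across generations) feed the aggregated
    #: importance used for warm-restart thresholds
    importance_window: int = 60
    subset_min: int = 2
    subset_max: int = 50
    plateau_window: int = 10
    plateau_tol: float = 1e-3
    max_generations: int = 100
    # warm-restart schedule
    warm_population: int = 50
    warm_n_best: int = 50
    warm_n_recombine_parents: int = 40
    warm_n_children_recombine: int = 20
    warm_n_mutate: int = 10
    warm_n_discard: int = -1  # derived in __post_init__
    warm_n_fresh: int = 20
    warm_n_donors: int = 30
    warm_max_generations: int = 30
    sd_multipliers: tuple[int, ...] = tuple(range(2, 11))

    def __post_init__(self) -> None:
        if self.warm_n_discard < 0:
            self.warm_n_discard = (
                self.warm_n_best - self.warm_n_recombine_parents - self.warm_n_mutate
            )
        self.validate()

    def validate(self) -> None:
        if self.n_recombine_parents != 2 * self.n_children_recombine:
            raise ValueError("recombination parents must be twice the children")
        if self.n_best != self.n_recombine_parents + self.n_mutate + self.n_discard:
            raise ValueError("n_best must equal parents + mutated + discarded")
        nxt = self.n_children_recombine + self.n_mutate + self.n_fresh
        if nxt != self.population:
            raise ValueError("children + mutated + fresh must equal the population")
        if self.n_best > self.population:
            raise ValueError("n_best cannot exceed the population")
        if self.n_donors < self.n_children_recombine + self.n_mutate:
            raise ValueError("donor pool smaller than the number of children")
        if not 1 <= self.subset_min <= self.subset_max:
            raise ValueError("invalid subset bounds")
        wn = self.warm_n_children_recombine + self.warm_n_mutate + self.warm_n_fresh
        if wn != self.warm_population:
            raise ValueError("warm children + mutated + fresh must equal warm population")

    def warm(self) -> "EvolutionConfig":
        """The reduced-schedule configuration used after the warm restart."""
        return replace(
            self,
            population=self.warm_population,
            n_best=self.warm_n_best,
            n_recombine_parents=self.warm_n_recombine_parents,
            n_children_recombine=self.warm_n_children_recombine,
            n_mutate=self.warm_n_mutate,
            n_discard=self.warm_n_discard,
            n_fresh=self.warm_n_fresh,
            n_donors=self.warm_n_donors,
            max_generations=self.warm_max_generations,
        )

    @classmethod
    def desk(cls, population: int = 20, max_generations: int = 15, subset_max: int = 8) -> "EvolutionConfig":
        """Small-footprint configuration with the same 20/20/60-shaped ratios."""
        return cls(
            population=population,
            n_best=int(population * 0.8),
            n_recombine_parents=int(population * 0.4),
            n_children_recombine=int(population * 0.2),
            n_mutate=int(population * 0.2),
            n_discard=int(population * 0.2),
            n_fresh=int(population * 0.6),
            n_donors=int(population * 0.6),
            subset_max=subset_max,
            max_generations=max_generations,
            plateau_window=6,
            warm_population=max(10, population // 2),
            warm_n_best=max(8, int(population * 0.4)),
            warm_n_recombine_parents=max(4, int(population * 0.2)),
            warm_n_children_recombine=max(2, int(population * 0.1)),
            warm_n_mutate=max(2, int(population * 0.1)),
            warm_n_discard=-1,
            warm_n_fresh=max(10, population // 2) - max(2, int(population * 0.1)) * 2,
            warm_n_donors=max(6, int(population * 0.3)),
            warm_max_generations=max(6, max_generations // 2),
        )


@dataclass
class GenerationLog:
    index: int
    phase: str  # 'main' or 'warm:<m>'
    records: list[FitnessRecord]
    best_bic: float
    best_chromosome: Chromosome
    lineage_counts: dict[str, int]


@dataclass
class OptimizationResult:
    """Outcome of one full optimization: ranked records, logs, bookkeeping."""

    best_record: FitnessRecord
    best_chromosome: Chromosome
    ranked_records: list[FitnessRecord]
    generation_logs: list[GenerationLog]
    best_bic_trace: list[float]
    n_fits: int
    feature_pool_history: list[list[int]]


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------


def _sample_subset(
    pool: np.ndarray, lo: int, hi: int, rng: np.random.Generator
) -> tuple[int, ...]:
    hi = min(hi, len(pool))
    lo = min(lo, hi)
    size = int(rng.integers(lo, hi + 1))
    return tuple(sorted(int(i) for i in rng.choice(pool, size=size, replace=False)))


def init_population(
    space: SearchSpace,
    config: EvolutionConfig,
    feature_pool,
    rng: np.random.Generator,
) -> list[Chromosome]:
    """Random first generation: uniform hyperparameters (log-uniform where
    declared), subset sizes uniform on the configured range, subsets sampled
    without replacement from the pool."""
    pool = np.asarray(list(feature_pool), dtype=int)
    hi = config.subset_max
    if hi > len(pool):
        warnings.warn(
            f"feature pool ({len(pool)}) smaller than subset_max ({hi}); shrinking"
        )
        hi = len(pool)
    lo = min(config.subset_min, hi)
    return [
        Chromosome.make(space.sample(rng), _sample_subset(pool, lo, hi, rng), "fresh")
        for _ in range(config.population)
    ]


def recombine(parent_a: Chromosome, parent_b: Chromosome, space: SearchSpace, rng: np.random.Generator) -> Chromosome:
    """Midpoint-pivot crossover in declared hyperparameter order.

    Genes before the pivot copy parent_a; genes from the pivot onward are the
    element-wise parent average (categoricals: seeded parent choice).  The
    child's feature subset is assigned separately by donor allocation; parent
    A's subset is a placeholder.
    """
    a, b = parent_a.params, parent_b.params
    pivot = len(space.names) // 2
    child = {}
    for i, name in enumerate(space.names):
        if i < pivot:
            child[name] = a[name]
        else:
            child[name] = space[name].average(a[name], b[name], rng)
    return Chromosome.make(child, parent_a.feature_subset, "recombined")


def mutate(c: Chromosome, space: SearchSpace, rng: np.random.Generator) -> Chromosome:
    """Shift one (seeded) hyperparameter by its mutation step, reflecting at
    the bounds; the feature subset is untouched here."""
    params = c.params
    name = space.names[rng.integers(len(space.names))]
    params[name] = space[name].mutate(params[name], rng)
    return Chromosome.make(params, c.feature_subset, "mutated")


def allocate_feature_sets(
    donor_subsets: list[tuple[int, ...]], children: list[Chromosome]
) -> list[Chromosome]:
    """Assign donor subsets (ranked best-first) to children in rank order;
    surplus donors are discarded, shortages recycle from the top."""
    if not donor_subsets:
        raise ValueError("no donor subsets available")
    if len(donor_subsets) < len(children):
        warnings.warn("fewer donor subsets than children; recycling from the top")
    out = []
    for i, child in enumerate(children):
        subset = donor_subsets[i % len(donor_subsets)]
        out.append(Chromosome.make(child.params, subset, child.lineage))
    return out


def step_generation(
    records: list[FitnessRecord],
    config: EvolutionConfig,
    space: SearchSpace,
    feature_pool,
    rng: np.random.Generator,
) -> list[Chromosome]:
    """Breed the next population from evaluated records.

    Rank ascending by BIC; of the best ``n_best``: the top
    ``n_recombine_parents`` pair off adjacently into recombined children, the
    next ``n_mutate`` are mutated, the rest are discarded.  Children receive
    the subsets of the best ``n_donors`` records in rank order; ``n_fresh``
    random models complete the population.
    """
    if any(r.bic is None for r in records):
        raise ValueError("records must carry evaluated BICs")
    ranked = sorted(records, key=lambda r: r.bic)
    chroms = [Chromosome.make(r.hyperparams, r.feature_subset) for r in ranked]
    parents = chroms[: config.n_recombine_parents]
    to_mutate = chroms[
        config.n_recombine_parents : config.n_recombine_parents + config.n_mutate
    ]

    children = [
        recombine(parents[2 * i], parents[2 * i + 1], space, rng)
        for i in range(config.n_children_recombine)
    ]
    children += [mutate(c, space, rng) for c in to_mutate]

    if children:
        donors = [c.feature_subset for c in chroms[: config.n_donors]]
        children = allocate_feature_sets(donors, children)

    pool = np.asarray(list(feature_pool), dtype=int)
    hi = min(config.subset_max, len(pool))
    lo = min(config.subset_min, hi)
    fresh = [
        Chromosome.make(space.sample(rng), _sample_subset(pool, lo, hi, rng), "fresh")
        for _ in range(config.n_fresh)
    ]
    nxt = children + fresh
    if len(nxt) != config.population:
        raise RuntimeError(
            f"population bookkeeping bug: bred {len(nxt)} != {config.population}"
        )
    return nxt


def detect_plateau(best_bic_trace, window: int, tol: float) -> bool:
    """True iff the best-so-far BIC improved by less than ``tol`` (relative)
    over the last ``window`` generations."""
    trace = list(best_bic_trace)
    if len(trace) < window + 1:
        return False
    then, now = trace[-window - 1], trace[-1]
    denom = max(abs(then), 1e-30)
    return (then - now) / denom < tol


def fitness_elbow(
    records: list[FitnessRecord], aggregated_importance: np.ndarray
) -> tuple[int, float, bool]:
    """Elbow of best-BIC-per-feature-count; returns (count, threshold, degenerate).

    The elbow is the point of maximum perpendicular distance to the chord of
    the normalized (feature count, best BIC at that count) curve.  The
    importance threshold is the aggregated importance of the feature ranked at
    the elbow count.  With fewer than 3 distinct counts, or a perfectly linear
    curve (elbow at an endpoint), the result is flagged degenerate and the max
    feature count is used.
    """
    by_p: dict[int, float] = {}
    for r in records:
        by_p[r.p] = min(by_p.get(r.p, np.inf), r.bic)
    ps = np.array(sorted(by_p), dtype=float)
    ranked_imp = np.sort(aggregated_importance)[::-1]

    def threshold_at(count: int) -> float:
        count = int(min(max(count, 1), len(ranked_imp)))
        return float(ranked_imp[count - 1])

    if len(ps) < 3:
        warnings.warn("fewer than 3 distinct feature counts; elbow degenerate")
        p_max = int(ps.max())
        return p_max, threshold_at(p_max), True
    ys = np.array([by_p[int(p)] for p in ps])
    xs_n = (ps - ps.min()) / (ps.max() - ps.min())
    rng_y = ys.max() - ys.min()
    ys_n = (ys - ys.min()) / (rng_y if rng_y > 0 else 1.0)
    p0 = np.array([xs_n[0], ys_n[0]])
    p1 = np.array([xs_n[-1], ys_n[-1]])
    chord = p1 - p0
    chord = chord / np.linalg.norm(chord)
    rel = np.column_stack([xs_n, ys_n]) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    i = int(np.argmax(dist))
    degenerate = i in (0, len(ps) - 1) or dist[i] < 1e-12
    if degenerate:
        warnings.warn("fitness curve is linear; elbow at an endpoint")
    elbow_p = int(ps[i])
    return elbow_p, threshold_at(elbow_p), degenerate


def escalation_pools(
    aggregated_importance: np.ndarray,
    pool,
    elbow_threshold: float,
    sd_multipliers,
    min_size: int,
) -> list[tuple[str, list[int]]]:
    """Warm-restart feature pools: the elbow-thresholded pool, then cutoffs at
    mean + m*SD of the original importances.  Escalation stops at the first
    pool smaller than ``min_size``; duplicate consecutive pools are skipped.
    """
    agg = np.asarray(aggregated_importance, dtype=float)
    pool = list(pool)
    pools = [("warm:0", [i for i in pool if agg[i] >= elbow_threshold])]
    mean, sd = float(agg.mean()), float(agg.std())
    for m in sd_multipliers:
        cut = mean + m * sd
        pm = [i for i in pool if agg[i] >= cut]
        if len(pm) < min_size:
            break
        if pm == pools[-1][1]:
            continue
        pools.append((f"warm:{m}", pm))
    return [p for p in pools if len(p[1]) >= min_size]


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


class IELClassifier:
    """Evolutionary joint feature selection + hyperparameter tuning classifier.

    scikit-learn-compatible estimator: ``fit(X, y)`` runs the full
    evolutionary loop (init -> evaluate -> breed -> plateau -> warm restart),
    refits the best chromosome on the full training data and exposes
    ``predict`` / ``predict_proba``.  Identical ``random_state`` gives
    identical generation logs for the logistic and tree families.

    Parameters
    ----------
    family : str
        'logistic_elasticnet' (default), 'boosted_trees' or 'neural_net'.
    config : EvolutionConfig, optional
        Population schedule; defaults to the full 100-model schedule.
    cv_cap : int or None
        Upper bound on the adaptive fold count (None = uncapped).
    warm_restart : bool
        Whether to run the importance-thresholded recursive phase.
    """

    def __init__(
        self,
        family: str = "logistic_elasticnet",
        config: EvolutionConfig | None = None,
        estimator_spec: EstimatorSpec | None = None,
        cv_cap: int | None = 10,
        warm_restart: bool = True,
        top_n: int = 100,
        random_state: int = 0,
    ):
        self.family = family
        self.config = config
        self.estimator_spec = estimator_spec
        self.cv_cap = cv_cap
        self.warm_restart = warm_restart
        self.top_n = top_n
        self.random_state = random_state

    # -- internals ----------------------------------------------------------
    def _evaluate(self, pop, X, y, spec, cache, counter) -> list[FitnessRecord]:
        records = []
        for chrom in pop:
            key = chrom.key()
            if key in cache:
                rec = cache[key]
            else:
                rec = cv_fit(
                    spec,
                    chrom.params,
                    X,
                    y,
                    chrom.feature_subset,
                    seed=self._eval_seed,
                    cap=self.cv_cap,
                )
                cache[key] = rec
                counter[0] += 1
            rec = replace_lineage(rec, chrom.lineage)
            records.append(rec)
        return records

    def _run_phase(
        self, X, y, spec, config, pool, rng, phase, cache, counter, logs, trace
    ) -> None:
        pop = init_population(spec.space, config, pool, rng)
        for gen in range(config.max_generations):
            records = self._evaluate(pop, X, y, spec, cache, counter)
            best = min(records, key=lambda r: r.bic)
            counts: dict[str, int] = {}
            for r in records:
                counts[r.lineage] = counts.get(r.lineage, 0) + 1
            best_so_far = min(best.bic, trace[-1]) if trace else best.bic
            trace.append(best_so_far)
            logs.append(
                GenerationLog(
                    len(logs),
                    phase,
                    records,
                    best.bic,
                    Chromosome.make(best.hyperparams, best.feature_subset),
                    counts,
                )
            )
            phase_trace = [l.best_bic for l in logs if l.phase == phase]
            running = np.minimum.accumulate(phase_trace).tolist()
            if detect_plateau(running, config.plateau_window, config.plateau_tol):
                break
            if gen == config.max_generations - 1:
                break
            pop = step_generation(records, config, spec.space, pool, rng)

    def _aggregate_importance(self, cache, n_features, n_donors) -> np.ndarray:
        ranked = sorted(cache.values(), key=lambda r: r.bic)[:n_donors]
        imps = [r.importances for r in ranked if r.importances is not None]
        if not imps:
            return np.zeros(n_features)
        return np.mean(imps, axis=0)

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        config = self.config or EvolutionConfig()
        spec = self.estimator_spec or EstimatorSpec(self.family)
        rng = np.random.default_rng(self.random_state)
        self._eval_seed = int(np.random.default_rng(self.random_state).integers(2**31 - 1))

        cache: dict[tuple, FitnessRecord] = {}
        counter = [0]
        logs: list[GenerationLog] = []
        trace: list[float] = []
        pool = list(range(X.shape[1]))
        pools = [list(pool)]

        self._run_phase(X, y, spec, config, pool, rng, "main", cache, counter, logs, trace)

        if self.warm_restart:
            agg = self._aggregate_importance(cache, X.shape[1], config.importance_window)
            main_records = [r for l in logs for r in l.records]
            elbow_p, thr, _ = fitness_elbow(main_records, agg)
            self.elbow_ = (elbow_p, thr)
            warm_cfg = config.warm()
            phases = escalation_pools(
                agg, pool, thr, config.sd_multipliers, warm_cfg.subset_min
            )
            for phase, p in phases:
                pools.append(list(p))
                self._run_phase(
                    X, y, spec, warm_cfg, p, rng, phase, cache, counter, logs, trace
                )

        ranked = sorted(cache.values(), key=lambda r: r.bic)
        best = ranked[0]
        self.result_ = OptimizationResult(
            best_record=best,
            best_chromosome=Chromosome.make(best.hyperparams, best.feature_subset),
            ranked_records=ranked[: self.top_n],
            generation_logs=logs,
            best_bic_trace=trace,
            n_fits=counter[0],
            feature_pool_history=pools,
        )
        self.best_bic_ = best.bic
        self.best_subset_ = best.feature_subset
        self.best_hyperparams_ = dict(best.hyperparams)
        from .estimators import make_estimator

        self.best_estimator_ = make_estimator(spec, self.best_hyperparams_, seed=self._eval_seed)
        self.best_estimator_.fit(X[:, list(self.best_subset_)], y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.best_estimator_.predict_proba(X[:, list(self.best_subset_)])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # minimal get/set_params for sklearn compatibility
    def get_params(self, deep: bool = True) -> dict:
        return {
            "family": self.family,
            "config": self.config,
            "estimator_spec": self.estimator_spec,
            "cv_cap": self.cv_cap,
            "warm_restart": self.warm_restart,
            "top_n": self.top_n,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self


def replace_lineage(rec: FitnessRecord, lineage: str) -> FitnessRecord:
    """Records are cached by chromosome identity; lineage is per-appearance."""
    from dataclasses import replace as _r

    return _r(rec, lineage=lineage)


def run_iel(
    X,
    y,
    family: str = "logistic_elasticnet",
    config: EvolutionConfig | None = None,
    seed: int = 0,
    cv_cap: int | None = 10,
    warm_restart: bool = True,
    estimator_spec: EstimatorSpec | None = None,
) -> OptimizationResult:
    """Functional wrapper: run the full loop and return the optimization result."""
    clf = IELClassifier(
        family=family,
        config=config,
        estimator_spec=estimator_spec,
        cv_cap=cv_cap,
        warm_restart=warm_restart,
        random_state=seed,
    )
    clf.fit(X, y)
    return clf.result_
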