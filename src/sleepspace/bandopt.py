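"""Optimization of the four state-space frequency bands.

The eight band edges (two numerator/denominator bands per ratio) are tuned
to maximize the agreement of the LDA staging with reference scoring: a
genetic algorithm searches globally (fitness = overall positive predictive
value of the classifier; crossover regroups the four bands as intact
(lo, hi) pairs; 10% per-gene mutation), then a Nelder-Mead simplex refines
the best genome locally. The optimization fits on the whole provided
cohort; held-out evaluation is a separate, post-hoc protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .spectral import BandRatioPair, EpochSpectra, hann_smooth, ratio_coordinates
from .statespace import fit_classifier, positive_predictive_value

logger = logging.getLogger(__name__)

#: Admissible range for any band edge, Hz. Excludes DC drift and
#: mains-adjacent frequencies while containing all default optimized edges
#: (1.0-31.5 Hz).
EDGE_BOUNDS = (0.5, 45.0)


@dataclass
class BandGenome:
    """Eight band edges (ratio1_num.lo ... ratio2_den.hi) plus fitness."""

    edges: np.ndarray
    fitness: float | None = None

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.shape != (8,):
            raise ValueError("genome must hold 8 band edges")

    def bands(self) -> BandRatioPair:
        return BandRatioPair.from_edges(self.edges)

    def is_valid(self, bounds=EDGE_BOUNDS) -> bool:
        e = self.edges
        within = np.all(e >= bounds[0]) and np.all(e <= bounds[1])
        ordered = all(e[2 * i] < e[2 * i + 1] for i in range(4))
        return bool(within and ordered)


@dataclass
class GAConfig:
    population: int = 50
    generations: int = 100
    mutation_rate: float = 0.1
    elite: int = 1
    tournament: int = 3
    seed: int = 0
    bounds: tuple[float, float] = EDGE_BOUNDS
    mutation_sigma_hz: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 <= self.elite < self.population:
            raise ValueError("elite must be < population")
        if self.tournament < 1:
            raise ValueError("tournament size must be >= 1")


def fitness(
    genome: BandGenome | np.ndarray,
    spectra_by_subject: dict[object, EpochSpectra],
    labels_by_subject: dict[object, np.ndarray],
    smooth_window: int = 10,
) -> float:
    """Overall PPV of LDA staging with the genome's bands, on the full cohort.

    Coordinates are computed per subject (the running Hann average must not
    bleed across subjects), then the classifier is fitted and evaluated on
    the pooled epochs. A band containing no spectral bins is a hard penalty
    (fitness 0). Deterministic given its inputs.
    """
    g = genome if isinstance(genome, BandGenome) else BandGenome(np.asarray(genome))
    try:
        bands = g.bands()
    except ValueError:
        return 0.0
    coords, labels = [], []
    for sid, spectra in spectra_by_subject.items():
        try:
            c = ratio_coordinates(spectra, bands)
        except ValueError as e:  # empty band: no bins
            logger.info("fitness penalty for %s: %s", g.edges, e)
            return 0.0
        if smooth_window and smooth_window > 1 and len(c) > 1:
            c = hann_smooth(c, smooth_window)
        coords.append(c)
        labels.append(np.asarray(labels_by_subject[sid], dtype=object))
    X = np.vstack(coords)
    y = np.concatenate(labels)
    try:
        model = fit_classifier(X, y)
    except ValueError:
        # fully collapsed coordinates (e.g. numerator == denominator):
        # the classifier degenerates to its priors and stages everything as
        # the most frequent class
        return float(max(np.mean(y == s) for s in set(y)))
    return positive_predictive_value(model.predict(X), y)["overall"]


def _random_genome(rng, bounds) -> np.ndarray:
    e = np.empty(8)
    for i in range(4):
        lo, hi = np.sort(rng.uniform(bounds[0], bounds[1], 2))
        if hi - lo < 0.2:
            hi = min(lo + 0.2, bounds[1])
            lo = hi - 0.2
        e[2 * i], e[2 * i + 1] = lo, hi
    return e


def _repair(e: np.ndarray, bounds) -> np.ndarray:
    e = np.clip(e, bounds[0], bounds[1])
    for i in range(4):
        lo, hi = e[2 * i], e[2 * i + 1]
        if lo > hi:
            lo, hi = hi, lo
        if hi - lo < 1e-6:  # zero-width band after clipping
            hi = min(lo + 0.2, bounds[1])
            lo = max(hi - 0.2, bounds[0])
        e[2 * i], e[2 * i + 1] = lo, hi
    return e


def _crossover(rng, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Paired regrouping: each of the four bands is inherited as an intact
    (lo, hi) pair from either parent."""
    child = np.empty(8)
    for i in range(4):
        src = a if rng.random() < 0.5 else b
        child[2 * i : 2 * i + 2] = src[2 * i : 2 * i + 2]
    return child


def _mutate(rng, e: np.ndarray, cfg: GAConfig) -> np.ndarray:
    e = e.copy()
    hit = rng.random(8) < cfg.mutation_rate
    e[hit] += rng.normal(0.0, cfg.mutation_sigma_hz, int(hit.sum()))
    return _repair(e, cfg.bounds)


def ga_optimize(
    spectra_by_subject: dict | None,
    labels_by_subject: dict | None,
    cfg: GAConfig,
    fitness_fn=None,
    initial: BandGenome | None = None,
) -> tuple[BandGenome, list[dict]]:
    """Global genetic-algorithm search over band edges.

    ``fitness_fn(edges) -> float`` may replace the LDA fitness (surrogate
    objectives for calibration). Elitism keeps the best genome, so the
    best-so-far fitness trace is monotone non-decreasing; the whole run is
    reproducible from ``cfg.seed``. Returns (best genome, per-generation
    trace of best/mean fitness).
    """
    if fitness_fn is None:
        if spectra_by_subject is None or labels_by_subject is None:
            raise ValueError("need spectra and labels (or a fitness_fn)")

        def fitness_fn(edges):
            return fitness(edges, spectra_by_subject, labels_by_subject)

    rng = np.random.default_rng(cfg.seed)
    pop = [_random_genome(rng, cfg.bounds) for _ in range(cfg.population)]
    if initial is not None:
        pop[0] = _repair(initial.edges.copy(), cfg.bounds)
    fits = np.array([fitness_fn(e) for e in pop])

    best_idx = int(np.argmax(fits))
    best = BandGenome(pop[best_idx].copy(), float(fits[best_idx]))
    trace = [{"generation": 0, "best": best.fitness, "mean": float(fits.mean())}]

    for gen in range(1, cfg.generations + 1):
        order = np.argsort(fits)[::-1]
        new_pop = [pop[i].copy() for i in order[: cfg.elite]]
        while len(new_pop) < cfg.population:
            contenders = rng.integers(0, cfg.population, cfg.tournament)
            pa = pop[contenders[np.argmax(fits[contenders])]]
            contenders = rng.integers(0, cfg.population, cfg.tournament)
            pb = pop[contenders[np.argmax(fits[contenders])]]
            child = _mutate(rng, _crossover(rng, pa, pb), cfg)
            new_pop.append(child)
        pop = new_pop
        fits = np.array([fitness_fn(e) for e in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best.fitness:
            best = BandGenome(pop[gen_best].copy(), float(fits[gen_best]))
        trace.append(
            {"generation": gen, "best": best.fitness, "mean": float(fits.mean())}
        )
        logger.debug("generation %d: best %.4f mean %.4f", gen, best.fitness,
                     float(fits.mean()))
    return best, trace


def nelder_mead_refine(
    genome: BandGenome,
    spectra_by_subject: dict | None = None,
    labels_by_subject: dict | None = None,
    fitness_fn=None,
    bounds=EDGE_BOUNDS,
    maxiter: int = 400,
) -> BandGenome:
    """Local simplex refinement of a genome.

    Minimizes 1 - fitness from the genome's edges; edges violating the
    band constraints score fitness 0 (penalty), which keeps the simplex
    inside the feasible region. The refined genome is returned only if it
    is no worse than the input (acceptance rule), so fitness never
    decreases across this step.
    """
    if fitness_fn is None:
        if spectra_by_subject is None or labels_by_subject is None:
            raise ValueError("need spectra and labels (or a fitness_fn)")

        def fitness_fn(edges):
            return fitness(edges, spectra_by_subject, labels_by_subject)

    def objective(e):
        g = BandGenome(e)
        if not g.is_valid(bounds):
            return 1.0
        return 1.0 - fitness_fn(e)

    start_fit = fitness_fn(genome.edges) if genome.fitness is None else genome.fitness
    res = minimize(
        objective,
        genome.edges,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-6},
    )
    refined = BandGenome(_repair(res.x.copy(), bounds))
    refined.fitness = fitness_fn(refined.edges)
    if refined.fitness >= start_fit:
        return refined
    return BandGenome(genome.edges.copy(), start_fit)
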