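"""Binary wrapper feature selection via three swarm metaheuristics.

Harris Hawks Optimization (HHO), a modified Gorilla Troops Optimization
(mGTO) and the Zebra Optimization Algorithm (ZOA) search the binary mask
space over a feature namespace, minimizing a wrapper fitness (classifier
cross-validation error, see :func:`fitness_error`).  All three follow the
standard binary-metaheuristic recipe: positions evolve continuously in
[0,1]^d under each algorithm's canonical update equations, and candidates
are evaluated after transfer-function binarization (logistic squash centered
at 0.5, strict threshold).  Elitism retains the best mask ever seen, making
per-iteration best-fitness traces monotone nonincreasing.

Fitness evaluations are memoized on the binary mask, which matters because a
wrapper fitness retrains a classifier per evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit, gamma
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import LinearSVC

from .table import SampleTable

__all__ = [
    "OptimizerConfig",
    "Candidate",
    "FitnessSpec",
    "fitness_error",
    "make_fitness",
    "binarize",
    "run_hho",
    "run_mgto",
    "run_zoa",
    "run_multi",
    "ALGORITHMS",
]

FitnessFn = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class OptimizerConfig:
    """Shared search-budget settings for all three optimizers.

    Defaults follow standard wrapper-selection practice for ~100-feature
    radiomics tables: 20 search agents, 50 iterations, 10 independent
    seeded runs with the average reported.
    """

    population: int = 20
    iterations: int = 50
    runs: int = 10
    threshold: float = 0.5
    transfer_gain: float = 10.0
    init_density: float = 0.15

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class Candidate:
    """A search agent: continuous position, its binary mask, and fitness."""

    position: np.ndarray
    mask: np.ndarray
    fitness: float = np.inf


@dataclass(frozen=True)
class FitnessSpec:
    """Wrapper-fitness settings: classifier CV error on masked features.

    The default classifier is a linear max-margin classifier (suited to
    high-dimensional, small-sample radiomics data); the score is
    1 − stratified-CV accuracy, evaluated strictly on the table it is given
    (callers pass training folds only).
    """

    cv_folds: int = 5
    C: float = 1.0
    max_iter: int = 2000
    seed: int = 0


def fitness_error(mask: np.ndarray, table: SampleTable, spec: FitnessSpec | None = None) -> float:
    """1 − stratified-CV accuracy of a linear SVM on the masked features.

    An all-zero mask is maximally penalized (returns exactly 1.0).
    """
    spec = spec or FitnessSpec()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 1.0
    y = table.labels
    if len(np.unique(y)) < 2:
        raise ValueError("fitness requires at least two classes")
    x = table.features[:, mask]
    clf = LinearSVC(C=spec.C, max_iter=spec.max_iter, random_state=spec.seed)
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    acc = cross_val_score(clf, x, y, cv=cv, scoring="accuracy").mean()
    return float(1.0 - acc)


def make_fitness(table: SampleTable, spec: FitnessSpec | None = None) -> FitnessFn:
    """Memoized mask -> CV-error callable bound to one (training) table."""
    cache: dict[bytes, float] = {}

    def fn(mask: np.ndarray) -> float:
        key = np.packbits(np.asarray(mask, dtype=bool)).tobytes()
        if key not in cache:
            cache[key] = fitness_error(mask, table, spec)
        return cache[key]

    return fn


def binarize(position: np.ndarray, threshold: float = 0.5, gain: float = 10.0) -> np.ndarray:
    """Transfer-function binarization: sigmoid centered at 0.5, strict cut.

    ``mask_j = 1`` iff ``sigmoid(gain * (x_j - 0.5)) > threshold``; with the
    default threshold 0.5 this selects exactly the coordinates above 0.5
    (a position of exactly 0.5 maps to 0 — strict inequality).
    """
    return expit(gain * (np.asarray(position, dtype=float) - 0.5)) > threshold


def _levy(rng: np.random.Generator, d: int, beta: float = 1.5) -> np.ndarray:
    """Lévy flight step (Mantegna's algorithm), used by HHO rapid dives."""
    sigma = (
        gamma(1 + beta) * np.sin(np.pi * beta / 2)
        / (gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
    ) ** (1 / beta)
    u = rng.normal(0, sigma, d)
    v = rng.normal(0, 1, d)
    return u / np.abs(v) ** (1 / beta)


def _clip(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


class _Memo:
    """Binarize-then-evaluate helper tracking the elitist best."""

    def __init__(self, fitness: FitnessFn, config: OptimizerConfig):
        self.fitness = fitness
        self.config = config
        self.best = Candidate(position=None, mask=None, fitness=np.inf)

    def eval(self, position: np.ndarray) -> float:
        mask = binarize(position, self.config.threshold, self.config.transfer_gain)
        f = self.fitness(mask)
        if f < self.best.fitness:
            self.best = Candidate(position=position.copy(), mask=mask.copy(), fitness=f)
        return f


def _init_population(
    rng: np.random.Generator, n: int, d: int, density: float = 0.15
) -> np.ndarray:
    """Sparse initialization: each coordinate lands above the binarization
    threshold with probability ``density``.

    Starting from small subsets biases the wrapper search toward parsimony:
    features enter a mask only when doing so lowers the cross-validation
    error, so informative features are enriched before the error plateaus —
    dense random starts on easily separable data already sit at zero error
    and give the search no signal.
    """
    on = rng.random((n, d)) < density
    low = rng.uniform(0.0, 0.5, size=(n, d))
    high = rng.uniform(0.5, 1.0, size=(n, d))
    return np.where(on, high, low)


def run_hho(
    config: OptimizerConfig, fitness: FitnessFn, d: int, seed: int = 0
) -> tuple[Candidate, list[float]]:
    """Harris Hawks Optimization in [0,1]^d with binarized evaluation.

    Phases are driven by the prey escape energy E = 2·E0·(1 − t/T):
    |E| ≥ 1 explores (perch on random hawk or on the mean); |E| < 1 exploits
    via soft/hard besiege, with Lévy-flight rapid dives when the prey's
    escape chance r < 0.5.  Greedy elitism keeps the best mask ever seen.
    """
    rng = np.random.default_rng(seed)
    memo = _Memo(fitness, config)
    pop = _init_population(rng, config.population, d, config.init_density)
    fit = np.array([memo.eval(p) for p in pop])
    trace: list[float] = []
    for t in range(config.iterations):
        rabbit = memo.best.position  # prey = best-so-far position
        x_mean = pop.mean(axis=0)
        for i in range(config.population):
            e0 = 2 * rng.random() - 1
            e = 2 * e0 * (1 - t / config.iterations)  # escape energy
            j = 2 * (1 - rng.random())  # random jump strength
            x = pop[i]
            if abs(e) >= 1:  # exploration
                q = rng.random()
                if q >= 0.5:  # perch based on a random hawk
                    xr = pop[rng.integers(config.population)]
                    new = xr - rng.random() * np.abs(xr - 2 * rng.random() * x)
                else:  # perch based on family mean and prey
                    new = (rabbit - x_mean) - rng.random() * rng.random(d)
            else:  # exploitation
                r = rng.random()
                if r >= 0.5 and abs(e) >= 0.5:  # soft besiege
                    new = (rabbit - x) - e * np.abs(j * rabbit - x)
                elif r >= 0.5:  # hard besiege
                    new = rabbit - e * np.abs(rabbit - x)
                elif abs(e) >= 0.5:  # soft besiege, progressive rapid dives
                    y = rabbit - e * np.abs(j * rabbit - x)
                    z = _clip(y + rng.random(d) * _levy(rng, d))
                    y = _clip(y)
                    new = y if memo.eval(y) < fit[i] else (z if memo.eval(z) < fit[i] else x)
                else:  # hard besiege, progressive rapid dives
                    y = rabbit - e * np.abs(j * rabbit - x_mean)
                    z = _clip(y + rng.random(d) * _levy(rng, d))
                    y = _clip(y)
                    new = y if memo.eval(y) < fit[i] else (z if memo.eval(z) < fit[i] else x)
            new = _clip(new)
            f_new = memo.eval(new)
            if f_new <= fit[i]:  # greedy replacement
                pop[i], fit[i] = new, f_new
        trace.append(memo.best.fitness)
    return memo.best, trace


def run_mgto(
    config: OptimizerConfig, fitness: FitnessFn, d: int, seed: int = 0
) -> tuple[Candidate, list[float]]:
    """Modified Gorilla Troops Optimization with binarized evaluation.

    Exploration migrates to unknown places (uniform resample), toward other
    gorillas, or to a known place; exploitation either follows the
    silverback (best-so-far) or competes for adult females.  The
    modification is a nonlinear (cosine) decay of the exploration-control
    parameter C, sharpening the exploration→exploitation handover relative
    to the original linear schedule.
    """
    rng = np.random.default_rng(seed)
    memo = _Memo(fitness, config)
    p_migrate, beta, w = 0.03, 3.0, 0.8
    pop = _init_population(rng, config.population, d, config.init_density)
    fit = np.array([memo.eval(p) for p in pop])
    trace: list[float] = []
    for t in range(config.iterations):
        # nonlinear exploration decay (the "modified" refinement)
        f_ctrl = np.cos(2 * rng.random()) + 1
        c = f_ctrl * np.cos(np.pi / 2 * t / config.iterations)
        lcoef = c * (2 * rng.random() - 1)
        silverback = memo.best.position
        # exploration phase
        for i in range(config.population):
            x = pop[i]
            r1 = rng.random()
            if rng.random() < p_migrate:  # migrate to an unknown place
                new = rng.random(d)
            elif r1 >= 0.5:  # move toward another gorilla
                xr = pop[rng.integers(config.population)]
                z = rng.uniform(-c, c, d)
                new = (rng.random() - c) * xr + lcoef * (z * x)
            else:  # migrate to a known place
                xr = pop[rng.integers(config.population)]
                new = x - lcoef * (lcoef * (x - xr) + rng.random() * (x - xr))
            new = _clip(new)
            f_new = memo.eval(new)
            if f_new < fit[i]:
                pop[i], fit[i] = new, f_new
        silverback = memo.best.position
        # exploitation phase
        for i in range(config.population):
            x = pop[i]
            if c >= w:  # follow the silverback
                g = 2.0 ** lcoef
                m = (np.abs(pop.mean(axis=0)) ** g + 1e-12) ** (1.0 / g)
                new = lcoef * m * (x - silverback) + x
            else:  # competition for adult females
                q = 2 * rng.random() - 1
                if rng.random() >= 0.5:
                    a = beta * rng.normal(size=d)
                else:
                    a = beta * rng.normal()
                new = silverback - (silverback * q - x * q) * a
            new = _clip(new)
            f_new = memo.eval(new)
            if f_new < fit[i]:
                pop[i], fit[i] = new, f_new
        trace.append(memo.best.fitness)
    return memo.best, trace


def run_zoa(
    config: OptimizerConfig, fitness: FitnessFn, d: int, seed: int = 0
) -> tuple[Candidate, list[float]]:
    """Zebra Optimization Algorithm with binarized evaluation.

    Phase 1 (foraging): each zebra moves toward the pioneer zebra (the
    best-so-far member).  Phase 2 (defense): with probability one half the
    herd flees a lion (scaled in-place escape shrinking with time),
    otherwise it converges on a herd-mate under attack.  Moves are accepted
    greedily.
    """
    rng = np.random.default_rng(seed)
    memo = _Memo(fitness, config)
    pop = _init_population(rng, config.population, d, config.init_density)
    fit = np.array([memo.eval(p) for p in pop])
    trace: list[float] = []
    for t in range(1, config.iterations + 1):
        pioneer = memo.best.position
        for i in range(config.population):
            x = pop[i]
            # phase 1: foraging toward the pioneer zebra
            ii = 1 + rng.integers(2)  # intensity I in {1, 2}
            new = _clip(x + rng.random(d) * (pioneer - ii * x))
            f_new = memo.eval(new)
            if f_new <= fit[i]:
                pop[i], fit[i] = new, f_new
                x = pop[i]
            # phase 2: defense against predators
            if rng.random() < 0.5:  # lion attack: flee in place
                r = 0.01
                step = r * (2 * rng.random(d) - 1) * (1 - t / config.iterations)
                new = _clip(x + step * x)
            else:  # other predator: converge on the attacked zebra
                az = pop[rng.integers(config.population)]
                ii = 1 + rng.integers(2)
                new = _clip(x + rng.random(d) * (az - ii * x))
            f_new = memo.eval(new)
            if f_new <= fit[i]:
                pop[i], fit[i] = new, f_new
        trace.append(memo.best.fitness)
    return memo.best, trace


ALGORITHMS: dict[str, Callable] = {"hho": run_hho, "mgto": run_mgto, "zoa": run_zoa}


@dataclass
class MultiRunResult:
    """Per-run best masks and the accuracy summary over independent runs."""

    algorithm: str
    best: Candidate
    masks: list[np.ndarray]
    fitnesses: list[float]
    traces: list[list[float]]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([1.0 - f for f in self.fitnesses]))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std([1.0 - f for f in self.fitnesses]))


def run_multi(
    algorithm: str,
    config: OptimizerConfig,
    fitness: FitnessFn,
    d: int,
    seed: int = 0,
) -> MultiRunResult:
    """Execute ``config.runs`` independent seeded runs of one algorithm.

    Reports every run's best mask and the mean/sd of (1 − best fitness),
    i.e. the average wrapper accuracy across runs.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}")
    runner = ALGORITHMS[algorithm]
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=config.runs)
    masks, fits, traces = [], [], []
    best: Candidate | None = None
    for s in seeds:
        cand, trace = runner(config, fitness, d, seed=int(s))
        masks.append(cand.mask)
        fits.append(cand.fitness)
        traces.append(trace)
        if best is None or cand.fitness < best.fitness:
            best = cand
    return MultiRunResult(algorithm=algorithm, best=best, masks=masks, fitnesses=fits, traces=traces)
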