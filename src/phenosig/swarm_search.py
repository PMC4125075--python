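"""Swarm-based reverse engineering of growth models.

Two levels of search are provided.  The inner level is a standard particle
swarm (global-best topology, inertia 0.72, cognitive/social coefficients
1.49) fitting the kinetic parameters of a *fixed* model structure to one or
more measured growth-rate series; fitness is the mean absolute growth-rate
error per time point (1/hour), averaged over strains.  The outer level
evolves the structure itself: candidate models are assembled from a library
of 12 basic equation components — polynomial terms (constant, linear,
quadratic, two-species product) and Michaelis-Menten terms (saturating
activation and inhibition), each usable as production or consumption — and
after each round every non-best structure adopts components of the current
best with probability ``p_adopt``, otherwise resampling from its options.

Structures with indistinguishable fitness (within 1e-4) are ranked by term
count, preferring parsimonious models.  Parameter vectors are initialized
log-uniformly in the search bounds so that kinetic constants spanning
several orders of magnitude are reachable.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ParameterError, SearchError, ValidationError
from .growth_io import GrowthRateSeries
from .growth_model import DEFAULT_X0, batch_mu

__all__ = [
    "SwarmConfig",
    "SearchConfig",
    "TermTemplate",
    "Term",
    "TERM_TEMPLATES",
    "COMPONENT_LIBRARY",
    "TermStructure",
    "StructureSpace",
    "GrowthModelStructure",
    "FitResult",
    "SearchResult",
    "pso_minimize",
    "swarm_fit_params",
    "swarm_search_structure",
    "enumerate_structures",
]

logger = logging.getLogger(__name__)

_STATE_CAP = 1e6


# ---------------------------------------------------------------------------
# equation-component library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermTemplate:
    """A kinetic rate-law template with free constants.

    ``arity`` is the number of state slots, ``n_params`` the number of
    fitted constants (a rate c, plus a half-saturation K for the
    Michaelis-Menten forms).
    """

    name: str
    arity: int
    n_params: int

    def evaluate(self, params, values):
        c = params[0]
        if self.name == "const":
            return c * np.ones_like(values[0]) if values else c
        if self.name == "linear":
            return c * values[0]
        if self.name == "square":
            return c * values[0] ** 2
        if self.name == "product":
            return c * values[0] * values[1]
        if self.name == "mm":
            return c * values[0] / (params[1] + values[0])
        if self.name == "mm_inh":
            return c * params[1] / (params[1] + values[0])
        raise ParameterError(f"unknown template {self.name!r}")


TERM_TEMPLATES = {
    t.name: t
    for t in (
        TermTemplate("const", 0, 1),
        TermTemplate("linear", 1, 1),
        TermTemplate("square", 1, 1),
        TermTemplate("product", 2, 1),
        TermTemplate("mm", 1, 2),
        TermTemplate("mm_inh", 1, 2),
    )
}

#: The 12 basic equation components: each rate-law template applied as
#: production (+1) or consumption (-1).
COMPONENT_LIBRARY = tuple(
    (name, sign) for name in TERM_TEMPLATES for sign in (+1, -1)
)


@dataclass(frozen=True)
class Term:
    """A template instantiated on concrete states with a sign."""

    template: str
    states: tuple
    sign: int = +1

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        tpl = TERM_TEMPLATES.get(self.template)
        if tpl is None:
            raise ParameterError(f"unknown template {self.template!r}")
        if len(self.states) != tpl.arity:
            raise ValidationError(
                f"template {self.template!r} takes {tpl.arity} state(s), "
                f"got {self.states}"
            )
        if self.sign not in (+1, -1):
            raise ValidationError("sign must be +1 or -1")

    @property
    def n_params(self) -> int:
        return TERM_TEMPLATES[self.template].n_params


class TermStructure:
    """A model structure assembled from library terms.

    Parameters
    ----------
    equations : mapping
        ``state -> sequence of Term``.  States default to (N, P, Q, G); the
        last state is the growth-rate modulator whose trajectory is the
        predicted mu(t).
    x0 : tuple
        Initial state.
    """

    def __init__(self, equations, states=("N", "P", "Q", "G"), x0=(1.0, 0.0, 0.0, 0.05)):
        self.states = tuple(states)
        self.x0 = tuple(float(v) for v in x0)
        if len(self.x0) != len(self.states):
            raise ValidationError("x0 must match the number of states")
        self.equations = {s: tuple(equations.get(s, ())) for s in self.states}
        for s, terms in self.equations.items():
            for t in terms:
                for st in t.states:
                    if st not in self.states:
                        raise ValidationError(f"unknown state {st!r} in term {t}")
        self._index = {s: i for i, s in enumerate(self.states)}

    @property
    def n_params(self) -> int:
        return sum(t.n_params for terms in self.equations.values() for t in terms)

    @property
    def n_terms(self) -> int:
        return sum(len(terms) for terms in self.equations.values())

    def describe(self) -> dict:
        return {
            s: [(t.sign, t.template, list(t.states)) for t in terms]
            for s, terms in self.equations.items()
        }

    def _rhs(self, x, params_by_term):
        dx = np.zeros_like(x)
        pi = 0
        for s, terms in self.equations.items():
            row = self._index[s]
            for t in terms:
                tpl = TERM_TEMPLATES[t.template]
                p = params_by_term[pi]
                pi += 1
                values = [x[self._index[st]] for st in t.states]
                dx[row] += t.sign * tpl.evaluate(p, values)
        return dx

    def mu_batch(self, param_matrix, times, substeps: int = 3) -> np.ndarray:
        """Vectorized RK4 integration; returns mu rows, one per parameter set."""
        P = np.asarray(param_matrix, dtype=float)
        if P.ndim != 2 or P.shape[1] != self.n_params:
            raise ValidationError(f"expected (m, {self.n_params}) parameter matrix")
        m = P.shape[0]
        # split columns into per-term parameter tuples
        params_by_term = []
        col = 0
        for terms in self.equations.values():
            for t in terms:
                k = t.n_params
                params_by_term.append(tuple(P[:, col + j] for j in range(k)))
                col += k
        x = np.tile(np.asarray(self.x0)[:, None], (1, m))
        g_row = len(self.states) - 1
        mu = np.empty((m, len(times)))
        mu[:, 0] = x[g_row]
        with np.errstate(over="ignore", invalid="ignore"):
            for i in range(1, len(times)):
                h = (times[i] - times[i - 1]) / substeps
                for _ in range(substeps):
                    K1 = self._rhs(x, params_by_term)
                    K2 = self._rhs(x + h / 2 * K1, params_by_term)
                    K3 = self._rhs(x + h / 2 * K2, params_by_term)
                    K4 = self._rhs(x + h * K3, params_by_term)
                    x = np.clip(x + h / 6 * (K1 + 2 * K2 + 2 * K3 + K4), 0.0, _STATE_CAP)
                    x = np.nan_to_num(x, nan=_STATE_CAP, posinf=_STATE_CAP, neginf=0.0)
                mu[:, i] = x[g_row]
        return mu


class GrowthModelStructure:
    """Adapter exposing the reference growth ODE as a fittable structure."""

    n_params = 10
    n_terms = 8

    def __init__(self, x0=DEFAULT_X0, substeps: int = 4):
        self.x0 = x0
        self.substeps = substeps

    def mu_batch(self, param_matrix, times, substeps=None):
        return batch_mu(param_matrix, times, x0=self.x0,
                        substeps=substeps or self.substeps)

    def describe(self) -> dict:
        return {"model": "reference growth ODE", "n_params": self.n_params}


# ---------------------------------------------------------------------------
# particle swarm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwarmConfig:
    """Hyperparameters of the inner parameter swarm."""

    n_particles: int = 50
    n_iters: int = 300
    inertia: float = 0.72
    c_personal: float = 1.49
    c_global: float = 1.49
    bounds: tuple = (1e-3, 10.0)
    restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ParameterError("need at least 2 particles")
        lo, hi = self.bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ParameterError("bounds must be finite with lo < hi")


def pso_minimize(objective, n_dim: int, config: SwarmConfig):
    """Global-best particle swarm minimization of a batched objective.

    ``objective`` maps an (n_particles, n_dim) matrix to a fitness vector;
    non-finite fitness values are treated as +inf (the particle is penalized,
    not crashed).  Positions are clipped to the bounds; initial positions are
    log-uniform in the bounds.  Returns ``(best_x, trace)`` where the trace
    of per-iteration global-best fitness is monotone non-increasing by
    construction.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    if lo > 0:
        # log-uniform start positions span kinetic scales
        X = np.exp(rng.uniform(math.log(lo), math.log(hi), (config.n_particles, n_dim)))
    else:
        X = rng.uniform(lo, hi, (config.n_particles, n_dim))
    V = np.zeros_like(X)
    F = np.asarray(objective(X), dtype=float)
    F = np.where(np.isfinite(F), F, np.inf)
    pbest, f_pbest = X.copy(), F.copy()
    trace = [float(f_pbest.min())]
    for _ in range(config.n_iters):
        g = int(np.argmin(f_pbest))
        r1 = rng.random(X.shape)
        r2 = rng.random(X.shape)
        V = (config.inertia * V
             + config.c_personal * r1 * (pbest - X)
             + config.c_global * r2 * (pbest[g] - X))
        X = np.clip(X + V, lo, hi)
        F = np.asarray(objective(X), dtype=float)
        F = np.where(np.isfinite(F), F, np.inf)
        improved = F < f_pbest
        pbest[improved] = X[improved]
        f_pbest[improved] = F[improved]
        trace.append(float(f_pbest.min()))
    g = int(np.argmin(f_pbest))
    return pbest[g], np.asarray(trace)


@dataclass
class FitResult:
    """Outcome of fitting one structure to one or more growth-rate series."""

    params: list          # one parameter vector per series
    fitness: float        # mean absolute mu error per time point, over series
    traces: list          # per-series best-fitness traces
    per_series: np.ndarray

    @property
    def trace(self) -> np.ndarray:
        """Mean best-fitness trace across series (monotone non-increasing)."""
        return np.mean(self.traces, axis=0)


def _as_series_list(data):
    if isinstance(data, GrowthRateSeries):
        return [data]
    if isinstance(data, np.ndarray):
        return [data] if data.ndim == 1 else list(data)
    data = list(data)
    if data and np.isscalar(data[0]):
        return [np.asarray(data, dtype=float)]
    return data


def _series_arrays(series, dt=None):
    if isinstance(series, GrowthRateSeries):
        return series.times, series.mu
    arr = np.asarray(series, dtype=float)
    if dt is None:
        raise ValidationError("bare arrays need an explicit dt")
    return np.arange(1, len(arr) + 1) * dt, arr


def swarm_fit_params(structure, data, config: SwarmConfig | None = None,
                     dt: float | None = None) -> FitResult:
    """Fit the parameters of a fixed structure to growth-rate data.

    ``data`` is a :class:`~phenosig.growth_io.GrowthRateSeries` (or bare
    array with ``dt``), or a list of them — one strain per series, each
    fitted independently with its own swarm; the reported fitness is the
    mean over strains.  Simulation starts from the structure's initial state
    at t = 0 and is sampled on the data grid.
    """
    if config is None:
        config = SwarmConfig()
    series_list = _as_series_list(data)
    if not series_list:
        raise ValidationError("no data series supplied")
    params, traces, fits = [], [], []
    for si, series in enumerate(series_list):
        times, target = _series_arrays(series, dt)
        step = times[1] - times[0] if len(times) > 1 else (dt or 1.0)
        offset = int(round(times[0] / step))
        grid = np.arange(0, offset + len(times)) * step

        def objective(X):
            mu = structure.mu_batch(X, grid)[:, offset:]
            with np.errstate(invalid="ignore"):
                f = np.mean(np.abs(mu - target), axis=1)
            return np.where(np.isfinite(f), f, np.inf)

        best_x, best_trace = None, None
        for r in range(config.restarts):
            cfg = replace(config, seed=(config.seed + 1000003 * si + 7919 * r) % 2**31)
            x, tr = pso_minimize(objective, structure.n_params, cfg)
            if best_trace is None or tr[-1] < best_trace[-1]:
                best_x, best_trace = x, tr
        params.append(best_x)
        traces.append(best_trace)
        fits.append(best_trace[-1])
    per_series = np.asarray(fits)
    return FitResult(params=params, fitness=float(per_series.mean()),
                     traces=traces, per_series=per_series)


# ---------------------------------------------------------------------------
# structure search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureSpace:
    """A structure search space: a fixed scaffold plus variable slots.

    ``base`` maps each state to its fixed terms; each slot is a pair
    ``(state, options)`` where ``options`` is a tuple of candidate
    :class:`Term` objects for that slot.  A candidate structure is one
    option index per slot.
    """

    base: dict
    slots: tuple
    states: tuple = ("N", "P", "Q", "G")
    x0: tuple = (1.0, 0.0, 0.0, 0.05)

    def n_candidates(self) -> int:
        n = 1
        for _, options in self.slots:
            n *= len(options)
        return n

    def build(self, choices) -> TermStructure:
        if len(choices) != len(self.slots):
            raise ValidationError("one choice per slot is required")
        eqs = {s: list(self.base.get(s, ())) for s in self.states}
        for (state, options), c in zip(self.slots, choices):
            eqs[state].append(options[c])
        return TermStructure(eqs, states=self.states, x0=self.x0)

    def random_choices(self, rng) -> tuple:
        return tuple(int(rng.integers(len(opts))) for _, opts in self.slots)


def enumerate_structures(space: StructureSpace, cap: int = 100_000):
    """Deterministic, duplicate-free iterator over all candidate choices.

    Refuses (with the candidate count in the message) when the space exceeds
    ``cap``.
    """
    total = space.n_candidates()
    if total > cap:
        raise ParameterError(
            f"structure space has {total} candidates, exceeding the cap of {cap}"
        )
    ranges = [range(len(opts)) for _, opts in space.slots]
    return itertools.product(*ranges)


@dataclass(frozen=True)
class SearchConfig:
    """Hyperparameters of the outer structure search."""

    n_models: int = 6
    n_outer_iters: int = 3
    p_adopt: float = 0.5
    # wide-and-short swarms: particle batches are vectorized, iterations are
    # the serial cost, and width is what escapes the deceptive broad basins
    inner: SwarmConfig = field(default_factory=lambda: SwarmConfig(
        n_particles=150, n_iters=60, restarts=2))
    seed: int = 0
    fitness_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ParameterError("need at least 2 candidate structures")
        if not 0 <= self.p_adopt <= 1:
            raise ParameterError("p_adopt must be in [0, 1]")


@dataclass
class SearchResult:
    """Best structure found by the swarm structure search."""

    choices: tuple
    structure: TermStructure
    fit: FitResult
    history: list            # per-round list of (choices, fitness)

    @property
    def fitness(self) -> float:
        return self.fit.fitness


def swarm_search_structure(data, space: StructureSpace,
                           config: SearchConfig | None = None,
                           dt: float | None = None) -> SearchResult:
    """Evolve model structures toward the best fit of the growth data.

    A population of ``n_models`` candidate structures is evaluated by the
    inner parameter swarm (one shared structure, strain-specific parameters
    when several series are given).  After each outer round the non-best
    candidates adopt each slot of the current best with probability
    ``p_adopt``, otherwise resample the slot from its options; the best
    candidate is kept unchanged (elitism).  With ``n_outer_iters=0`` the
    best of the initial random population is returned.  Candidates whose
    fitness ties the best within ``fitness_tol`` are ranked by term count
    (parsimony).
    """
    if config is None:
        config = SearchConfig()
    rng = np.random.default_rng(config.seed)
    cache: dict = {}

    def evaluate(choices) -> FitResult:
        if choices not in cache:
            structure = space.build(choices)
            inner = replace(config.inner,
                            seed=(config.seed + hash(choices) % 1_000_000) % 2**31)
            cache[choices] = swarm_fit_params(structure, data, inner, dt=dt)
        return cache[choices]

    def rank_key(item):
        choices, fit = item
        if not np.isfinite(fit.fitness):
            return (float("inf"), space.build(choices).n_terms)
        return (round(fit.fitness / config.fitness_tol),
                space.build(choices).n_terms)

    population = []
    seen = set()
    attempts = 0
    while len(population) < config.n_models and attempts < 50 * config.n_models:
        c = space.random_choices(rng)
        attempts += 1
        if c in seen and len(seen) < space.n_candidates():
            continue
        seen.add(c)
        population.append(c)
    if not population:
        raise SearchError("could not draw any candidate structures")

    history = []
    evaluated = [(c, evaluate(c)) for c in population]
    if not any(np.isfinite(f.fitness) for _, f in evaluated):
        raise SearchError("all candidate structures failed to integrate")
    for round_ in range(config.n_outer_iters):
        evaluated.sort(key=rank_key)
        history.append([(c, f.fitness) for c, f in evaluated])
        best_choices = evaluated[0][0]
        new_pop = [best_choices]
        for c, _ in evaluated[1:]:
            mutated = tuple(
                best_choices[i] if rng.random() < config.p_adopt
                else int(rng.integers(len(space.slots[i][1])))
                for i in range(len(space.slots))
            )
            new_pop.append(mutated)
        evaluated = [(c, evaluate(c)) for c in new_pop]
    evaluated.sort(key=rank_key)
    history.append([(c, f.fitness) for c, f in evaluated])
    best_choices, best_fit = evaluated[0]
    return SearchResult(choices=best_choices, structure=space.build(best_choices),
                        fit=best_fit, history=history)
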