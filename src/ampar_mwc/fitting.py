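"""Fitting allosteric and dissociation constants to conductance-frequency data.

The observable is a matrix of relative frequencies of the conductance
states at a handful of agonist concentrations.  The objective is the sum
of squared differences between log10 of the predicted state functions and
log10 of the observed frequencies, which weights rare and common states
comparably (the curves are read on a semilog axis).  Because the free
parameters span many decades and the objective is multimodal, the search
runs a genetic algorithm on log10-transformed parameters inside box
bounds (L in [1, 1e6], K in [1e-10, 1e-3] by default), optionally
followed by a deterministic local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core import AllostericModel, state_fractions

__all__ = [
    "FrequencyDataset",
    "GAParams",
    "FitSpec",
    "FitResult",
    "objective_value",
    "fit_thermodynamic",
    "pearson_fit_report",
]

#: default observed-frequency floor: one event in a million is below
#: single-channel detection, so log10(0) is clipped there.
DEFAULT_LOG_FLOOR = 1e-6


@dataclass(frozen=True)
class FrequencyDataset:
    """Relative conductance-state frequencies y[state, concentration].

    ``frequencies`` may contain NaN for missing cells; datasets without a
    basal row (closed receptors are invisible in open-channel records) are
    simply missing that state.
    """

    concentrations: np.ndarray
    frequencies: np.ndarray
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, float)
        y = np.asarray(self.frequencies, float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "frequencies", y)
        object.__setattr__(self, "states", tuple(self.states))
        if y.shape != (len(self.states), conc.size):
            raise ValueError("frequencies must be (n_states, n_concentrations)")
        if np.any(conc < 0):
            raise ValueError("concentrations must be nonnegative")
        vals = y[~np.isnan(y)]
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        sums = np.nansum(y, axis=0)
        if np.any(sums > 1 + 1e-6):
            raise ValueError("column sums exceed 1")

    @property
    def n_points(self) -> int:
        return int(np.sum(~np.isnan(self.frequencies)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.frequencies, index=list(self.states), columns=self.concentrations)


@dataclass(frozen=True)
class GAParams:
    """Genetic-algorithm hyperparameters (genes are log10 parameters)."""

    population_size: int = 100
    generations: int = 500
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    mutation_sigma: float = 0.3
    tournament_size: int = 3
    elite: int = 2
    restarts: int = 3


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``template`` fixes the model structure and all non-free parameter
    values; ``free_L``/``free_K`` name the conformations whose L or K are
    searched.  Fitting a partial agonist, for instance, frees only the
    three K values and keeps the full-agonist L constants fixed.
    """

    template: AllostericModel
    free_L: tuple[str, ...]
    free_K: tuple[str, ...]
    seed: int = 0
    L_bounds: tuple[float, float] = (1.0, 1e6)
    K_bounds: tuple[float, float] = (1e-10, 1e-3)
    log_floor: float = DEFAULT_LOG_FLOOR
    normalization: str = "auto"
    ga: GAParams = field(default_factory=GAParams)
    polish: bool = True
    initial_guess: AllostericModel | None = None

    def __post_init__(self) -> None:
        for lo, hi in (self.L_bounds, self.K_bounds):
            if not (0 < lo < hi):
                raise ValueError("bounds must satisfy 0 < lower < upper")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")
        ref = self.template.reference.name
        if ref in self.free_L:
            raise ValueError("the reference conformation's L is fixed at 1")
        for name in self.free_K:
            if not self.template[name].binds_ligand:
                raise ValueError(f"cannot free K of non-binding conformation {name!r}")

    @classmethod
    def default(cls, template: AllostericModel, **kw) -> "FitSpec":
        """Free every non-reference L and every present K."""
        free_L = tuple(c.name for c in template.conformations[1:])
        free_K = tuple(c.name for c in template.conformations if c.binds_ligand)
        return cls(template=template, free_L=free_L, free_K=free_K, **kw)

    # -- parameter vector <-> model -------------------------------------

    @property
    def n_free(self) -> int:
        return len(self.free_L) + len(self.free_K)

    def bounds_log10(self) -> np.ndarray:
        lb = [np.log10(self.L_bounds[0])] * len(self.free_L)
        lb += [np.log10(self.K_bounds[0])] * len(self.free_K)
        ub = [np.log10(self.L_bounds[1])] * len(self.free_L)
        ub += [np.log10(self.K_bounds[1])] * len(self.free_K)
        return np.array([lb, ub])

    def vector_from_model(self, model: AllostericModel) -> np.ndarray:
        vals = [model[n].L for n in self.free_L] + [model[n].K for n in self.free_K]
        return np.log10(np.asarray(vals, float))

    def model_from_vector(self, x: np.ndarray) -> AllostericModel:
        x = np.asarray(x, float)
        vals = 10.0**x
        upd: dict[str, dict] = {}
        for name, v in zip(self.free_L, vals[: len(self.free_L)]):
            upd.setdefault(name, {})["L"] = float(v)
        for name, v in zip(self.free_K, vals[len(self.free_L):]):
            upd.setdefault(name, {})["K"] = float(v)
        return self.template.with_updates(**upd)


@dataclass(frozen=True)
class FitResult:
    model: AllostericModel
    objective: float
    residuals: np.ndarray
    pearson_r: float
    pearson_p: float
    trajectory: np.ndarray
    seed: int
    normalization: str
    under_determined: bool
    n_free: int
    n_points: int


def _resolve_normalization(model: AllostericModel, data: FrequencyDataset, mode: str) -> str:
    if mode == "auto":
        return "all" if model.reference.name in data.states else "conductive"
    if mode not in ("all", "conductive"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    return mode


def _log10_residuals(model, data, log_floor, normalization):
    """Matrix log10(predicted) - log10(observed) with NaN for missing cells."""
    mode = _resolve_normalization(model, data, normalization)
    table = state_fractions(model, data.concentrations, mode)
    res = np.full_like(data.frequencies, np.nan)
    for i, s in enumerate(data.states):
        pred = np.maximum(table.row(s), log_floor)
        obs = np.maximum(data.frequencies[i], log_floor)
        res[i] = np.log10(pred) - np.log10(obs)
    return res


def objective_value(
    model: AllostericModel,
    data: FrequencyDataset,
    log_floor: float = DEFAULT_LOG_FLOOR,
    normalization: str = "auto",
) -> float:
    """Sum of squared log10 differences between predicted and observed frequencies.

    Observed frequencies below ``log_floor`` are clipped to it before taking
    the log; missing (NaN) cells are skipped.
    """
    res = _log10_residuals(model, data, log_floor, normalization)
    return float(np.nansum(res**2))


def pearson_fit_report(
    model: AllostericModel, data: FrequencyDataset, normalization: str = "auto"
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between observed and predicted frequencies."""
    mode = _resolve_normalization(model, data, normalization)
    table = state_fractions(model, data.concentrations, mode)
    obs, pred = [], []
    for i, s in enumerate(data.states):
        keep = ~np.isnan(data.frequencies[i])
        obs.append(data.frequencies[i][keep])
        pred.append(table.row(s)[keep])
    obs = np.concatenate(obs)
    pred = np.concatenate(pred)
    if obs.size < 3:
        raise ValueError("need at least 3 paired points for a correlation")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise ValueError("zero variance in observed or predicted frequencies")
    r, p = stats.pearsonr(obs, pred)
    return float(r), float(p)


def _ga_minimize(fun, lb, ub, ga: GAParams, rng: np.random.Generator, x0=None):
    """Seeded elitist GA on a box; returns (best_x, best_f, best_per_generation)."""
    d = lb.size
    pop = rng.uniform(lb, ub, size=(ga.population_size, d))
    if x0 is not None:
        pop[0] = np.clip(x0, lb, ub)
    fit = np.array([fun(x) for x in pop])
    best_hist = []
    for _ in range(ga.generations):
        order = np.argsort(fit)
        pop, fit = pop[order], fit[order]
        best_hist.append(fit[0])
        elite = pop[: ga.elite].copy()
        # tournament selection
        idx = rng.integers(0, ga.population_size, size=(ga.population_size, ga.tournament_size))
        parents = pop[idx[np.arange(ga.population_size), np.argmin(fit[idx], axis=1)]]
        # uniform crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, ga.population_size - 1, 2):
            if rng.random() < ga.crossover_rate:
                swap = rng.random(d) < 0.5
                a, b = children[i].copy(), children[i + 1].copy()
                children[i][swap], children[i + 1][swap] = b[swap], a[swap]
        # per-gene Gaussian mutation
        mask = rng.random(children.shape) < ga.mutation_rate
        children = children + mask * rng.normal(0, ga.mutation_sigma * (ub - lb), children.shape)
        children = np.clip(children, lb, ub)
        children[: ga.elite] = elite
        pop = children
        fit = np.array([fun(x) for x in pop])
    i = int(np.argmin(fit))
    best_hist.append(fit[i])
    return pop[i], fit[i], np.minimum.accumulate(best_hist)


def fit_thermodynamic(data: FrequencyDataset, spec: FitSpec) -> FitResult:
    """GA minimization of the log10 least-squares objective.

    Deterministic given ``spec.seed``; the reported trajectory (best
    objective so far, per generation, across restarts) is non-increasing.
    With ``spec.polish`` a bounded L-BFGS-B refinement is appended.
    """
    if data.concentrations.size < 2:
        # degenerate but legal: result flagged under-determined below
        pass
    lb, ub = spec.bounds_log10()

    def fun(x):
        return objective_value(spec.model_from_vector(x), data, spec.log_floor, spec.normalization)

    guesses = [None] * spec.ga.restarts
    if spec.initial_guess is not None:
        guesses[0] = spec.vector_from_model(spec.initial_guess)

    streams = np.random.SeedSequence(spec.seed).spawn(max(spec.ga.restarts, 1))
    best_x, best_f = None, np.inf
    traj = []
    for g, ss in zip(guesses, streams):
        x, f, hist = _ga_minimize(fun, lb, ub, spec.ga, np.random.default_rng(ss), x0=g)
        traj.append(hist)
        if f < best_f:
            best_x, best_f = x, f
    trajectory = np.minimum.accumulate(np.concatenate(traj))
    if spec.polish:
        res = optimize.minimize(fun, best_x, method="L-BFGS-B", bounds=list(zip(lb, ub)))
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
        trajectory = np.append(trajectory, best_f)

    model = spec.model_from_vector(best_x)
    residuals = _log10_residuals(model, data, spec.log_floor, spec.normalization)
    r, p = pearson_fit_report(model, data, spec.normalization)
    return FitResult(
        model=model,
        objective=float(best_f),
        residuals=residuals,
        pearson_r=r,
        pearson_p=p,
        trajectory=trajectory,
        seed=spec.seed,
        normalization=_resolve_normalization(spec.template, data, spec.normalization),
        under_determined=spec.n_free > data.n_points,
        n_free=spec.n_free,
        n_points=data.n_points,
    )
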