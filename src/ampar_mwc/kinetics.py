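"""The 20-state kinetic scheme: conformation x ligand count, ODE and SSA.

States are (conformation, i ligands bound), i = 0..n_sites, connected by

* binding/unbinding within a conformation — per-site rates with
  combinatorial multiplicity, propensity ``(n - i) * kon * G`` up and
  ``i * koff`` down, with ``koff = K * kon`` so the equilibrium occupancy
  is the binomial of the thermodynamic model; and
* concerted conformational flips between adjacent conformations at each
  shared ligand count.  The flip rates are anchored at the fully-liganded
  value and scaled per ligand removed by the pair's c ratio raised to a
  transition parameter ``a`` (default 0.5): each bound agonist speeds the
  forward (activating) flip by ``c**-a`` and slows the reverse by ``c**a``,
  an even split of the binding free energy.

Two construction modes are exposed.  ``"paper_table"`` uses printed
fully-liganded interconversion anchors verbatim.  ``"thermo_consistent"``
keeps the forward anchors but recomputes each reverse anchor so the
zero-ligand conformational equilibrium reproduces the allosteric constants
L, which makes the stationary distribution of the Markov chain equal the
closed-form MWC distribution at any G (detailed balance throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, linalg
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .core import AllostericModel, c_ratios

__all__ = [
    "KineticScheme",
    "TraceResult",
    "GLUA3_GLUK2_ANCHORS",
    "DEFAULT_KON",
    "koff_from_K",
    "scale_conformational_rate",
    "build_scheme",
    "ode_timecourse",
    "ssa_timecourse",
    "ssa_occupancy_average",
    "steady_state",
    "rise_time_20_80",
    "time_to_occupancy",
    "time_to_fraction_of_steady_state",
]

#: fully-liganded interconversion anchors (s^-1) for the recombinant
#: GluA3/GluK2 receptor: pair -> (forward, reverse)
GLUA3_GLUK2_ANCHORS: dict[str, tuple[float, float]] = {
    "BS": (3e5, 860.0),
    "SM": (2e4, 145.0),
    "ML": (5e4, 691.0),
}

#: association rate constant assumed identical for all conformations (M^-1 s^-1)
DEFAULT_KON = 5e6

#: per-conformation conductance weights for summed traces, arbitrary units
DEFAULT_CONDUCTANCE_WEIGHTS = (0.0, 1.0, 2.0, 3.0)


def koff_from_K(K: float, kon: float) -> float:
    """Dissociation rate from K = koff/kon; returns K * kon (s^-1)."""
    if K <= 0 or kon <= 0:
        raise ValueError("K and kon must be positive")
    return K * kon


def scale_conformational_rate(
    k4: float, c: float, n_bound: int, direction: str, a: float = 0.5, n_sites: int = 4
) -> float:
    """Interconversion rate at ``n_bound`` ligands from the fully-liganded anchor.

    forward: k4 * c**(a * (n_sites - n_bound)); reverse: k4 * c**(-a * (n_sites - n_bound)).
    """
    if not 0 <= n_bound <= n_sites:
        raise ValueError(f"n_bound must be in 0..{n_sites}")
    if c <= 0:
        raise ValueError("c must be positive")
    sign = {"forward": 1.0, "reverse": -1.0}.get(direction)
    if sign is None:
        raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")
    return k4 * c ** (sign * a * (n_sites - n_bound))


@dataclass(frozen=True)
class KineticScheme:
    """Continuous-time Markov model over (conformation, ligand count) states."""

    model: AllostericModel
    G: float
    states: tuple[tuple[str, int], ...]
    kon: dict[str, float]
    koff: dict[str, float]
    reactions: tuple[tuple[int, int, float, str], ...]  # (source, target, rate, kind)
    mode: str
    transition_parameter: float

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def state_labels(self) -> tuple[str, ...]:
        return tuple(f"{c}{i}" for c, i in self.states)

    def state_index(self, conf: str, i: int) -> int:
        return self.states.index((conf, i))

    def rate_matrix(self) -> np.ndarray:
        """Generator matrix Q: Q[i, j] is the rate i -> j, rows sum to 0."""
        Q = np.zeros((self.n_states, self.n_states))
        for s, t, rate, _ in self.reactions:
            Q[s, t] += rate
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        return Q

    def conformation_indicator(self) -> np.ndarray:
        """Matrix A (n_conformations x n_states) summing states per conformation."""
        names = self.model.state_names
        A = np.zeros((len(names), self.n_states))
        for j, (c, _) in enumerate(self.states):
            A[names.index(c), j] = 1.0
        return A


def build_scheme(
    model: AllostericModel,
    G: float,
    anchors: dict[str, tuple[float, float]],
    kon: float | dict[str, float] = DEFAULT_KON,
    mode: str = "paper_table",
    a: float = 0.5,
) -> KineticScheme:
    """Assemble the kinetic scheme at fixed ligand concentration G (molar).

    ``anchors`` maps each adjacent pair (e.g. "BS") to its fully-liganded
    (forward, reverse) rates.  All conformations on the chain must bind
    ligand: the per-ligand scaling needs the pair's c ratio.
    """
    if G < 0:
        raise ValueError("G must be nonnegative")
    if mode not in ("paper_table", "thermo_consistent"):
        raise ValueError(f"unknown scheme mode {mode!r}")
    n = model.n_sites
    names = model.state_names
    if isinstance(kon, dict):
        kon_map = dict(kon)
    else:
        kon_map = {c: float(kon) for c in names}
    koff_map = {}
    for c in model.conformations:
        if c.K is None:
            raise ValueError(
                f"conformation {c.name!r} has no dissociation constant; the "
                "ligand-count scaling of its interconversion rates is undefined"
            )
        koff_map[c.name] = koff_from_K(c.K, kon_map[c.name])

    states = tuple((c, i) for c in names for i in range(n + 1))
    index = {s: j for j, s in enumerate(states)}
    reactions: list[tuple[int, int, float, str]] = []

    for c in names:
        for i in range(n):
            reactions.append((index[(c, i)], index[(c, i + 1)], (n - i) * kon_map[c] * G, "bind"))
            reactions.append((index[(c, i + 1)], index[(c, i)], (i + 1) * koff_map[c], "unbind"))

    ratios = c_ratios(model).ratios
    for lo, hi in zip(model.conformations[:-1], model.conformations[1:]):
        pair = f"{lo.name}{hi.name}"
        if pair not in anchors:
            raise ValueError(f"missing fully-liganded anchor for pair {pair!r}")
        f4, r4 = anchors[pair]
        c = ratios[pair]
        if mode == "thermo_consistent":
            # choose the reverse anchor so k_rev(0)/k_fwd(0) = L_hi / L_lo
            r4 = f4 * c ** (2 * a * n) * (hi.L / lo.L)
        for i in range(n + 1):
            f = scale_conformational_rate(f4, c, i, "forward", a, n)
            r = scale_conformational_rate(r4, c, i, "reverse", a, n)
            reactions.append((index[(lo.name, i)], index[(hi.name, i)], f, "flip_fwd"))
            reactions.append((index[(hi.name, i)], index[(lo.name, i)], r, "flip_rev"))

    return KineticScheme(
        model=model,
        G=float(G),
        states=states,
        kon=kon_map,
        koff=koff_map,
        reactions=tuple(reactions),
        mode=mode,
        transition_parameter=a,
    )


@dataclass(frozen=True)
class TraceResult:
    """Time course of state occupancy.

    Deterministic runs store fractions summing to 1 per time point;
    stochastic runs store receptor counts summing to N, plus optional
    per-receptor jump paths and a summed-conductance trace.
    """

    times: np.ndarray
    occupancy: np.ndarray  # n_states x n_times
    state_labels: tuple[str, ...]
    kind: str  # "ode" | "ssa"
    scheme: KineticScheme | None = None
    n_receptors: int | None = None
    seed: int | None = None
    conductance: np.ndarray | None = None
    paths: tuple | None = None  # per receptor: (jump_times, state_indices)

    def conformation_occupancy(self) -> np.ndarray:
        """Occupancy summed over ligand counts, one row per conformation."""
        return self.scheme.conformation_indicator() @ self.occupancy

    def state_row(self, label: str) -> np.ndarray:
        return self.occupancy[self.state_labels.index(label)]

    def conformation_row(self, name: str) -> np.ndarray:
        return self.conformation_occupancy()[self.scheme.model.state_names.index(name)]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.occupancy.T, columns=list(self.state_labels))
        df.insert(0, "time", self.times)
        if self.conductance is not None:
            df["conductance"] = self.conductance
        return df


def _initial_vector(scheme: KineticScheme, initial) -> np.ndarray:
    if isinstance(initial, str):
        p0 = np.zeros(scheme.n_states)
        p0[scheme.state_labels.index(initial)] = 1.0
        return p0
    if isinstance(initial, tuple) and len(initial) == 2:
        p0 = np.zeros(scheme.n_states)
        p0[scheme.state_index(*initial)] = 1.0
        return p0
    p0 = np.asarray(initial, float)
    if p0.shape != (scheme.n_states,) or np.any(p0 < 0) or not math.isclose(p0.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("initial occupancy must be a probability vector over the states")
    return p0


def ode_timecourse(
    scheme: KineticScheme,
    initial,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> TraceResult:
    """Integrate the master equation dp/dt = Q^T p on the given time grid.

    ``initial`` is a state label like "B0", a (conformation, i) pair, or a
    full probability vector.  The system is stiff (rates span six decades),
    so a BDF integrator with the exact Jacobian is used.
    """
    t = np.asarray(t_grid, float)
    if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be a nonempty strictly increasing 1-D array")
    p0 = _initial_vector(scheme, initial)
    if t.size == 1:
        return TraceResult(t, p0[:, None], scheme.state_labels, "ode", scheme=scheme)
    QT = scheme.rate_matrix().T
    sol = integrate.solve_ivp(
        lambda _, p: QT @ p,
        (t[0], t[-1]),
        p0,
        method="BDF",
        jac=lambda *_: QT,
        t_eval=t,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"master-equation integration failed: {sol.message}")
    occ = sol.y
    sums = occ.sum(axis=0)
    if np.any(np.abs(sums - 1) > 1e-8):
        raise RuntimeError("probability not conserved beyond integrator tolerance")
    occ = occ / sums  # remove residual integrator drift
    return TraceResult(t, occ, scheme.state_labels, "ode", scheme=scheme)


def steady_state(scheme: KineticScheme) -> np.ndarray:
    """Stationary distribution: the normalized null vector of Q^T.

    Requires the chain restricted to positive rates to be irreducible
    (one strongly connected component); otherwise reports the components.
    """
    Q = scheme.rate_matrix()
    adj = csr_matrix((np.abs(Q) > 0).astype(int))
    ncomp, labels = connected_components(adj, directed=True, connection="strong")
    if ncomp > 1:
        groups = [np.flatnonzero(labels == k).tolist() for k in range(ncomp)]
        raise ValueError(f"kinetic scheme is reducible; strongly connected components: {groups}")
    A = np.vstack([Q.T, np.ones(scheme.n_states)])
    b = np.zeros(scheme.n_states + 1)
    b[-1] = 1.0
    p, *_ = linalg.lstsq(A, b)
    p = np.clip(p, 0, None)
    return p / p.sum()


def _per_state_channels(scheme: KineticScheme):
    """Outgoing targets, cumulative rates and exit rate for each state."""
    Q = scheme.rate_matrix()
    targets, cumrates, totals = [], [], np.zeros(scheme.n_states)
    for s in range(scheme.n_states):
        row = Q[s].copy()
        row[s] = 0.0
        idx = np.flatnonzero(row > 0)
        targets.append(idx)
        cr = np.cumsum(row[idx])
        cumrates.append(cr)
        totals[s] = cr[-1] if idx.size else 0.0
    return targets, cumrates, totals


def _conductance_vector(scheme: KineticScheme, weights) -> np.ndarray:
    if weights is None:
        weights = DEFAULT_CONDUCTANCE_WEIGHTS[: len(scheme.model.state_names)]
    w = dict(zip(scheme.model.state_names, weights))
    return np.array([w[c] for c, _ in scheme.states])


def _sample_initial_states(scheme, initial, n, rng) -> np.ndarray:
    p0 = _initial_vector(scheme, initial)
    if np.count_nonzero(p0) == 1:
        return np.full(n, int(np.argmax(p0)))
    return rng.choice(scheme.n_states, size=n, p=p0)


def ssa_timecourse(
    scheme: KineticScheme,
    n_receptors: int,
    initial,
    t_max: float,
    seed: int,
    n_points: int = 200,
    conductance_weights=None,
    record_paths: bool | None = None,
) -> TraceResult:
    """Exact Gillespie simulation of N independent receptors at fixed G.

    Each receptor is an independent jump chain; occupancy counts are
    recorded on a uniform grid of ``n_points`` times.  Per-receptor jump
    paths are kept when ``record_paths`` is true (default: N <= 100).
    A receptor whose exit rate is zero simply holds its state.
    """
    if n_receptors < 1:
        raise ValueError("need at least one receptor")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    rng = np.random.default_rng(seed)
    if record_paths is None:
        record_paths = n_receptors <= 100
    targets, cumrates, totals = _per_state_channels(scheme)
    grid = np.linspace(0.0, t_max, n_points)
    counts = np.zeros((scheme.n_states, n_points), dtype=np.int64)
    init_states = _sample_initial_states(scheme, initial, n_receptors, rng)
    paths = [] if record_paths else None

    for r in range(n_receptors):
        s = int(init_states[r])
        t = 0.0
        gi = 0
        jt, js = [0.0], [s]
        while True:
            tot = totals[s]
            t_next = t + rng.exponential(1.0 / tot) if tot > 0 else t_max
            stop = min(t_next, t_max)
            while gi < n_points and grid[gi] <= stop:
                counts[s, gi] += 1
                gi += 1
            if t_next >= t_max:
                break
            u = rng.random() * tot
            s = int(targets[s][np.searchsorted(cumrates[s], u)])
            t = t_next
            if record_paths:
                jt.append(t)
                js.append(s)
        while gi < n_points:  # numerical tail of the grid
            counts[s, gi] += 1
            gi += 1
        if record_paths:
            paths.append((np.array(jt), np.array(js)))

    cond = _conductance_vector(scheme, conductance_weights) @ counts
    return TraceResult(
        grid,
        counts,
        scheme.state_labels,
        "ssa",
        scheme=scheme,
        n_receptors=n_receptors,
        seed=seed,
        conductance=cond,
        paths=tuple(paths) if paths is not None else None,
    )


def ssa_occupancy_average(
    scheme: KineticScheme,
    n_receptors: int,
    initial,
    t_max: float,
    seed: int,
    burn_in: float = 0.0,
) -> np.ndarray:
    """Dwell-time-weighted average occupancy per state over (burn_in, t_max].

    Runs the same exact SSA as :func:`ssa_timecourse` but accumulates exact
    dwell times instead of grid snapshots; returns fractions summing to 1.
    """
    if not 0 <= burn_in < t_max:
        raise ValueError("need 0 <= burn_in < t_max")
    rng = np.random.default_rng(seed)
    targets, cumrates, totals = _per_state_channels(scheme)
    dwell = np.zeros(scheme.n_states)
    init_states = _sample_initial_states(scheme, initial, n_receptors, rng)
    for r in range(n_receptors):
        s = int(init_states[r])
        t = 0.0
        while t < t_max:
            tot = totals[s]
            t_next = t + rng.exponential(1.0 / tot) if tot > 0 else t_max
            stop = min(t_next, t_max)
            if stop > burn_in:
                dwell[s] += stop - max(t, burn_in)
            if t_next >= t_max:
                break
            u = rng.random() * tot
            s = int(targets[s][np.searchsorted(cumrates[s], u)])
            t = t_next
    return dwell / dwell.sum()


def _plateau_level(times: np.ndarray, y: np.ndarray) -> float:
    tail = y[int(math.ceil(0.9 * y.size)) :]
    if tail.size < 2:
        tail = y[-2:]
    level = float(np.mean(tail))
    spread = np.max(np.abs(tail - level))
    if level == 0 or spread > 0.05 * max(abs(level), 1e-300):
        raise ValueError("trace has no well-defined plateau in its final 10%")
    return level


def rise_time_20_80(times, signal) -> float:
    """20-80% rise time of a rising trace with a plateau (linear interpolation).

    The plateau is the mean of the final 10% of samples (required to lie
    within a 5% band); the rise time is the gap between the first upward
    crossings of 20% and 80% of that level.
    """
    t = np.asarray(times, float)
    y = np.asarray(signal, float)
    level = _plateau_level(t, y)
    out = []
    for frac in (0.2, 0.8):
        thr = frac * level
        above = np.flatnonzero(y >= thr)
        if above.size == 0:
            raise ValueError(f"trace never reaches {frac:.0%} of its plateau")
        k = above[0]
        if k == 0:
            out.append(t[0])
        else:
            out.append(t[k - 1] + (thr - y[k - 1]) * (t[k] - t[k - 1]) / (y[k] - y[k - 1]))
    if out[1] < out[0]:
        raise ValueError("trace is not monotone through the 20-80% band")
    return out[1] - out[0]


def time_to_occupancy(trace: TraceResult, conformations, level: float) -> float | None:
    """First time the summed occupancy of the conformations reaches an
    absolute level (fraction of receptors); None if never reached.

    Unlike :func:`time_to_fraction_of_steady_state` the target does not
    depend on the steady state, so it compares shift speed across ligand
    concentrations on a common scale.
    """
    if isinstance(conformations, str):
        conformations = [conformations]
    scheme = trace.scheme
    mask = np.array([c in conformations for c, _ in scheme.states])
    y = trace.occupancy[mask].sum(axis=0).astype(float)
    if trace.kind == "ssa":
        y = y / trace.n_receptors
    above = np.flatnonzero(y >= level)
    if above.size == 0:
        return None
    k = above[0]
    if k == 0:
        return float(trace.times[0])
    t0, t1 = trace.times[k - 1], trace.times[k]
    return float(t0 + (level - y[k - 1]) * (t1 - t0) / (y[k] - y[k - 1]))


def time_to_fraction_of_steady_state(
    trace: TraceResult, conformations, fraction: float = 0.95
) -> float | None:
    """First time the summed occupancy of the conformations reaches
    ``fraction`` of its steady-state value; None if never reached.

    Steady state is computed from the trace's scheme; deterministic traces
    use fractions, stochastic traces are normalized by N first.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if isinstance(conformations, str):
        conformations = [conformations]
    scheme = trace.scheme
    pss = steady_state(scheme)
    mask = np.array([c in conformations for c, _ in scheme.states])
    target = fraction * float(pss[mask].sum())
    y = trace.occupancy[mask].sum(axis=0).astype(float)
    if trace.kind == "ssa":
        y = y / trace.n_receptors
    above = np.flatnonzero(y >= target)
    if above.size == 0:
        return None
    k = above[0]
    if k == 0:
        return float(trace.times[0])
    t0, t1 = trace.times[k - 1], trace.times[k]
    y0, y1 = y[k - 1], y[k]
    return float(t0 + (target - y0) * (t1 - t0) / (y1 - y0))
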