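"""Closed-form thermodynamics of concerted (MWC-type) receptor gating.

The receptor is a tetramer whose four subunits switch conformation in
concert, like the discrete positions of an iris diaphragm.  Each
conformation ``X`` carries

* an allosteric constant ``L_X = [B_0]/[X_0]`` — the equilibrium ratio of
  the unliganded reference (basal) conformation to the unliganded ``X``
  (``L = 1`` for the reference itself), and
* a dissociation constant ``K_X`` (molar) for the agonist, or none at all
  if the conformation does not bind ligand.

The statistical weight of conformation ``X`` at free agonist concentration
``G`` is ``(1/L_X) * (1 + G/K_X)**n`` with ``n`` binding sites; the state
functions (fractions of receptors per conformation) and the saturation
function (fraction of sites occupied) follow from the partition function.
Weights are accumulated in log space so that extreme ``G/K`` ratios do not
overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ConformationSpec",
    "AllostericModel",
    "StateFractionTable",
    "CRatios",
    "conformation_weight",
    "state_fractions",
    "saturation_fraction",
    "liganded_distribution",
    "c_ratios",
    "log_grid",
]


@dataclass(frozen=True)
class ConformationSpec:
    """One receptor conformation: label, allosteric constant, affinity.

    ``K is None`` means the conformation does not bind ligand; its binding
    polynomial is identically 1.
    """

    name: str
    L: float
    K: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.L) or self.L <= 0:
            raise ValueError(f"allosteric constant L must be positive, got {self.L!r}")
        if self.K is not None and (not np.isfinite(self.K) or self.K <= 0):
            raise ValueError(f"dissociation constant K must be positive, got {self.K!r}")

    @property
    def binds_ligand(self) -> bool:
        return self.K is not None

    def log_weight(self, G, n_sites: int):
        """log of (1/L) * (1 + G/K)**n_sites, elementwise in ``G``."""
        G = np.asarray(G, dtype=float)
        if np.any(G < 0):
            raise ValueError("ligand concentration G must be nonnegative")
        lw = -math.log(self.L) * np.ones_like(G)
        if self.K is not None:
            lw = lw + n_sites * np.log1p(G / self.K)
        return lw


@dataclass(frozen=True)
class AllostericModel:
    """A concerted allosteric receptor: ordered conformations of a tetramer.

    The first conformation is the reference (basal) state and must have
    ``L == 1``; the chain order (e.g. B, S, M, L for basal and the small,
    medium and large conductance states) is the adjacency used by the
    kinetic scheme.
    """

    n_sites: int
    conformations: tuple[ConformationSpec, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be a positive integer")
        confs = tuple(self.conformations)
        object.__setattr__(self, "conformations", confs)
        if len(confs) < 2:
            raise ValueError("need at least a reference and one active conformation")
        names = [c.name for c in confs]
        if len(set(names)) != len(names):
            raise ValueError(f"conformation names must be unique, got {names}")
        if not math.isclose(confs[0].L, 1.0):
            raise ValueError("the first (reference) conformation must have L = 1")

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.conformations)

    @property
    def reference(self) -> ConformationSpec:
        return self.conformations[0]

    def __getitem__(self, name: str) -> ConformationSpec:
        for c in self.conformations:
            if c.name == name:
                return c
        raise KeyError(f"no conformation named {name!r}")

    def with_updates(self, **per_conf: dict) -> "AllostericModel":
        """Return a copy with ``L``/``K`` of named conformations replaced.

        ``per_conf`` maps conformation name -> {"L": value} and/or {"K": value}.
        """
        new = []
        for c in self.conformations:
            upd = per_conf.get(c.name)
            new.append(replace(c, **upd) if upd else c)
        return replace(self, conformations=tuple(new))

    def log_weights(self, G) -> np.ndarray:
        """Matrix of log statistical weights, conformations x len(G)."""
        G = np.atleast_1d(np.asarray(G, dtype=float))
        return np.stack([c.log_weight(G, self.n_sites) for c in self.conformations])


@dataclass(frozen=True)
class StateFractionTable:
    """State-function values over a concentration grid.

    ``fractions[i, j]`` is the fraction of receptors in state ``state_names[i]``
    at ``concentrations[j]``; each column sums to 1.  ``normalization_mode``
    is ``"all"`` (over every conformation) or ``"conductive"`` (basal row
    dropped and columns renormalized over the open states only).
    """

    concentrations: np.ndarray
    fractions: np.ndarray
    state_names: tuple[str, ...]
    normalization_mode: str = "all"

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", np.asarray(self.concentrations, float))
        object.__setattr__(self, "fractions", np.asarray(self.fractions, float))
        if self.fractions.shape != (len(self.state_names), self.concentrations.size):
            raise ValueError("fractions must be (n_states, n_concentrations)")

    def row(self, state: str) -> np.ndarray:
        return self.fractions[self.state_names.index(state)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.fractions, index=list(self.state_names), columns=self.concentrations
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.columns = [f"{g:.12e}" for g in self.concentrations]
        df.to_csv(path, index_label="state", float_format="%.12e")


@dataclass(frozen=True)
class CRatios:
    """Adjacent-pair affinity ratios c = K(more active)/K(less active).

    ``c < 1`` for agonists: the more-active conformation binds more tightly.
    Pairs where either conformation lacks a K are reported as ``None``.
    """

    ratios: dict[str, float | None] = field(default_factory=dict)

    def __getitem__(self, pair: str) -> float | None:
        return self.ratios[pair]

    def product(self) -> float | None:
        """Telescoping product along the chain, K(last)/K(first); None if broken."""
        out = 1.0
        for v in self.ratios.values():
            if v is None:
                return None
            out *= v
        return out


def conformation_weight(model: AllostericModel, conf: ConformationSpec | str, G: float) -> float:
    """Statistical weight (1/L)(1 + G/K)**n of one conformation at ligand G."""
    if isinstance(conf, str):
        conf = model[conf]
    if G < 0:
        raise ValueError("ligand concentration G must be nonnegative")
    return float(np.exp(conf.log_weight(G, model.n_sites)))


def state_fractions(model: AllostericModel, G_grid, normalization_mode: str = "all") -> StateFractionTable:
    """Fractions of receptors per conformation over a concentration grid.

    In ``"conductive"`` mode the reference (basal) row is dropped and the
    remaining rows renormalized, matching how open-channel conductance
    frequencies are reported when closed receptors are invisible.
    """
    G = np.atleast_1d(np.asarray(G_grid, dtype=float))
    if G.size == 0:
        raise ValueError("concentration grid must be nonempty")
    if normalization_mode not in ("all", "conductive"):
        raise ValueError(f"unknown normalization mode {normalization_mode!r}")
    lw = model.log_weights(G)
    names = model.state_names
    if normalization_mode == "conductive":
        lw = lw[1:]
        names = names[1:]
    frac = np.exp(lw - logsumexp(lw, axis=0, keepdims=True))
    return StateFractionTable(G, frac, names, normalization_mode)


def saturation_fraction(model: AllostericModel, G):
    """Fraction of binding sites occupied by ligand, Ybar(G) in [0, 1].

    Ybar = sum_X (1/L_X)(G/K_X)(1+G/K_X)^(n-1) / sum_X (1/L_X)(1+G/K_X)^n;
    conformations without a K contribute nothing to the numerator and 1/L
    to the denominator.
    """
    G = np.asarray(G, dtype=float)
    scalar = G.ndim == 0
    G = np.atleast_1d(G)
    if np.any(G < 0):
        raise ValueError("ligand concentration G must be nonnegative")
    n = model.n_sites
    den = logsumexp(model.log_weights(G), axis=0)
    num_terms = []
    with np.errstate(divide="ignore"):
        logG = np.log(G)
    for c in model.conformations:
        if c.K is None:
            continue
        term = -math.log(c.L) + logG - math.log(c.K) + (n - 1) * np.log1p(G / c.K)
        num_terms.append(term)
    if not num_terms:
        y = np.zeros_like(G)
    else:
        num = logsumexp(np.stack(num_terms), axis=0)
        y = np.where(G > 0, np.exp(num - den), 0.0)
    return float(y[0]) if scalar else y


def liganded_distribution(model: AllostericModel, conf: ConformationSpec | str, G: float) -> np.ndarray:
    """P(i ligands bound | conformation), i = 0..n_sites.

    Within one conformation the sites load independently, so the occupancy
    is binomial with per-site probability (G/K)/(1 + G/K).  A conformation
    without a K returns a point mass at zero ligands.
    """
    if isinstance(conf, str):
        conf = model[conf]
    if G < 0:
        raise ValueError("ligand concentration G must be nonnegative")
    n = model.n_sites
    out = np.zeros(n + 1)
    if conf.K is None or G == 0:
        out[0] = 1.0
        return out
    p = G / (G + conf.K)
    i = np.arange(n + 1)
    out = np.array([math.comb(n, k) for k in i]) * p**i * (1 - p) ** (n - i)
    return out / out.sum()


def c_ratios(model: AllostericModel) -> CRatios:
    """c parameters for each adjacent conformation pair along the chain.

    For pair (X, Y) with Y the more active state, c = K_Y / K_X; absent if
    either conformation does not bind ligand.
    """
    ratios: dict[str, float | None] = {}
    for lo, hi in zip(model.conformations[:-1], model.conformations[1:]):
        key = f"{lo.name}{hi.name}"
        if lo.K is None or hi.K is None:
            ratios[key] = None
        else:
            ratios[key] = hi.K / lo.K
    return CRatios(ratios)


def log_grid(gmin: float, gmax: float, points: int) -> np.ndarray:
    """Log-spaced concentration grid from gmin to gmax inclusive (molar)."""
    if gmin <= 0 or gmax <= gmin or points < 2:
        raise ValueError("need 0 < gmin < gmax and points >= 2")
    return np.logspace(math.log10(gmin), math.log10(gmax), points)
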