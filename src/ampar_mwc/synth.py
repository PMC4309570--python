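"""Synthetic data with the statistical structure the analysis assumes.

Real inputs are relative frequencies of single-channel conductance states
deconvolved from patch-clamp records at a handful of agonist
concentrations, and summed-current traces from receptor populations.  The
generators here emulate both from a known ground-truth model: multinomial
sampling of state frequencies (finite event counts per record) and SSA
population traces with optional additive Gaussian observation noise on the
summed conductance.  Because the truth is known, fitting and simulation
are testable end to end without any external recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AllostericModel, log_grid, state_fractions
from .fitting import FitSpec, FrequencyDataset, fit_thermodynamic, objective_value
from . import kinetics

__all__ = ["SynthSpec", "sample_frequency_table", "simulate_patch_trace", "recovery_experiment"]


@dataclass(frozen=True)
class TraceSettings:
    """Settings for synthetic population traces."""

    n_receptors: int = 50
    G: float = 1e-3
    duration: float = 5e-3
    scheme_mode: str = "thermo_consistent"
    anchors: dict = field(default_factory=lambda: dict(kinetics.GLUA3_GLUK2_ANCHORS))
    kon: float = kinetics.DEFAULT_KON
    conductance_weights: tuple | None = None
    noise_sd: float = 0.0
    n_points: int = 500


@dataclass(frozen=True)
class SynthSpec:
    """Ground-truth model plus sampling conditions for synthetic datasets.

    ``n_events`` is the multinomial sample size per concentration —
    loosely, the number of resolved single-channel events in one record
    (default 500).  The seed is mandatory so every dataset is reproducible.
    """

    model: AllostericModel
    concentrations: np.ndarray
    n_events: int = 500
    normalization: str = "all"
    seed: int = 0
    trace: TraceSettings = field(default_factory=TraceSettings)

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", np.asarray(self.concentrations, float))
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is required")


def sample_frequency_table(spec: SynthSpec) -> FrequencyDataset:
    """Multinomial draw of state frequencies at each concentration.

    Each column of the returned dataset is ``counts / n_events`` with
    counts ~ Multinomial(n_events, state_fractions(G)); as n_events grows
    the table converges to the exact state functions.
    """
    rng = np.random.default_rng(spec.seed)
    table = state_fractions(spec.model, spec.concentrations, spec.normalization)
    freq = np.empty_like(table.fractions)
    for j in range(spec.concentrations.size):
        freq[:, j] = rng.multinomial(spec.n_events, table.fractions[:, j]) / spec.n_events
    return FrequencyDataset(spec.concentrations, freq, table.state_names)


def simulate_patch_trace(spec: SynthSpec):
    """Stochastic population trace of summed conductance.

    Returns ``(trace, noisy_conductance)``: the raw SSA TraceResult (its
    ``conductance`` field is noise-free, for oracle checks) and the same
    summed conductance with additive Gaussian observation noise of the
    requested SD.
    """
    ts = spec.trace
    scheme = kinetics.build_scheme(
        spec.model, ts.G, ts.anchors, kon=ts.kon, mode=ts.scheme_mode
    )
    root = np.random.SeedSequence(spec.seed)
    ssa_seed, noise_seed = root.spawn(2)
    start = (spec.model.reference.name, 0)
    trace = kinetics.ssa_timecourse(
        scheme,
        ts.n_receptors,
        start,
        ts.duration,
        seed=ssa_seed,
        n_points=ts.n_points,
        conductance_weights=ts.conductance_weights,
    )
    noisy = trace.conductance.astype(float).copy()
    if ts.noise_sd > 0:
        noisy = noisy + np.random.default_rng(noise_seed).normal(0, ts.noise_sd, noisy.shape)
    return trace, noisy


def recovery_experiment(
    spec: SynthSpec,
    fitspec: FitSpec,
    analytic: bool = False,
) -> dict:
    """Generate a dataset, fit it, and report curve- and parameter-space error.

    ``analytic=True`` skips the multinomial draw and fits the exact state
    functions (the noiseless limit).  Curve-space error is the maximum
    absolute deviation between generating and fitted state functions over
    the data's concentration range extended one decade on each side —
    the quantity that is actually identifiable when (L, K) pairs trade off.
    """
    if analytic:
        table = state_fractions(spec.model, spec.concentrations, spec.normalization)
        data = FrequencyDataset(spec.concentrations, table.fractions, table.state_names)
    else:
        data = sample_frequency_table(spec)
    result = fit_thermodynamic(data, fitspec)

    gmin, gmax = spec.concentrations.min(), spec.concentrations.max()
    grid = log_grid(gmin / 10, gmax * 10, 60)
    truth = state_fractions(spec.model, grid, spec.normalization).fractions
    fitted = state_fractions(result.model, grid, spec.normalization).fractions
    curve_err = float(np.max(np.abs(truth - fitted)))

    param_dev = {}
    for name in fitspec.free_L:
        param_dev[f"log10_L_{name}"] = float(
            np.log10(result.model[name].L) - np.log10(spec.model[name].L)
        )
    for name in fitspec.free_K:
        param_dev[f"log10_K_{name}"] = float(
            np.log10(result.model[name].K) - np.log10(spec.model[name].K)
        )

    return {
        "seed": spec.seed,
        "n_events": None if analytic else spec.n_events,
        "n_concentrations": int(spec.concentrations.size),
        "objective": result.objective,
        "objective_at_truth": objective_value(
            spec.model, data, fitspec.log_floor, fitspec.normalization
        ),
        "curve_max_abs_error": curve_err,
        "parameter_log10_deviation": param_dev,
        "pearson_r": result.pearson_r,
        "pearson_p": result.pearson_p,
        "under_determined": result.under_determined,
    }
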