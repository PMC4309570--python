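"""Readers and writers: model JSON, frequency CSV, traces, run metadata.

All formats are plain text: JSON for parameter sets and metadata, CSV
(comma-separated, '.' decimal, scientific notation) for tables and
traces.  Four built-in parameter sets ship with the package: the native
cerebellar receptor and the recombinant GluA3/GluK2 chimera fitted to
full-agonist data, and the GluA3/GluK2 allosteric constants combined with
the partial-agonist willardiine affinities (IW, BrW).
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .core import AllostericModel, ConformationSpec
from .fitting import FitResult, FrequencyDataset

__all__ = [
    "BUILTIN_MODELS",
    "load_model",
    "save_model",
    "load_builtin_model",
    "load_frequency_csv",
    "save_frequency_csv",
    "save_trace_csv",
    "save_fit_result",
    "write_metadata",
]

BUILTIN_MODELS = ("native", "glua3_gluk2", "iw", "brw")


def model_to_dict(model: AllostericModel) -> dict:
    return {
        "name": model.name,
        "n_sites": model.n_sites,
        "conformations": [
            {"name": c.name, "L": c.L, "K": c.K} for c in model.conformations
        ],
    }


def model_from_dict(d: dict) -> AllostericModel:
    try:
        confs = tuple(
            ConformationSpec(name=c["name"], L=float(c["L"]), K=None if c["K"] is None else float(c["K"]))
            for c in d["conformations"]
        )
        return AllostericModel(n_sites=int(d["n_sites"]), conformations=confs, name=d.get("name", ""))
    except (KeyError, TypeError) as e:
        raise ValueError(f"malformed model description: missing or bad field {e}") from e


def save_model(model: AllostericModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2)
        fh.write("\n")


def load_model(path) -> AllostericModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def load_builtin_model(name: str) -> AllostericModel:
    """One of the shipped parameter sets: native, glua3_gluk2, iw, brw."""
    if name not in BUILTIN_MODELS:
        raise ValueError(f"unknown built-in model {name!r}; choose from {BUILTIN_MODELS}")
    ref = resources.files("ampar_mwc").joinpath(f"params/{name}.json")
    return model_from_dict(json.loads(ref.read_text()))


def resolve_model(name_or_path: str) -> AllostericModel:
    """Accept either a built-in model name or a JSON file path."""
    if name_or_path in BUILTIN_MODELS:
        return load_builtin_model(name_or_path)
    return load_model(name_or_path)


def save_frequency_csv(data: FrequencyDataset, path) -> None:
    df = pd.DataFrame(
        data.frequencies,
        index=list(data.states),
        columns=[f"{g:.12e}" for g in data.concentrations],
    )
    df.to_csv(path, index_label="state", float_format="%.12e")


def load_frequency_csv(path) -> FrequencyDataset:
    df = pd.read_csv(path, index_col=0)
    conc = np.array([float(c) for c in df.columns])
    return FrequencyDataset(conc, df.to_numpy(float), tuple(df.index))


def save_trace_csv(trace, path) -> None:
    trace.to_frame().to_csv(path, index=False, float_format="%.10e")


def save_fit_result(result: FitResult, path) -> None:
    payload = {
        "model": model_to_dict(result.model),
        "objective": result.objective,
        "pearson_r": result.pearson_r,
        "pearson_p": result.pearson_p,
        "seed": result.seed,
        "normalization": result.normalization,
        "under_determined": result.under_determined,
        "n_free": result.n_free,
        "n_points": result.n_points,
        "trajectory": [float(v) for v in result.trajectory],
        "residuals": np.where(np.isnan(result.residuals), None, result.residuals).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_metadata(path, config: dict) -> None:
    """Sidecar JSON (config + seed + version) sufficient to reproduce a run."""
    from . import __version__

    record = {"package_version": __version__, **config}
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
        fh.write("\n")
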