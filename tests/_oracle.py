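"""Independent brute-force oracle: explicit microstate enumeration.

A microstate is (conformation, binding pattern over the n sites); its
Boltzmann weight is (1/L) * prod over occupied sites of (G/K).  Summing
weights over all 2**n site patterns of a conformation must reproduce the
closed-form factor (1/L)(1 + G/K)**n, so state fractions, saturation and
the within-conformation occupancy distribution all follow by direct
summation with no shared code path with the package.
"""

from itertools import product

import numpy as np


def microstate_weights(model, G):
    """List of (conf_name, n_occupied, weight) over every microstate."""
    out = []
    for conf in model.conformations:
        for pattern in product((0, 1), repeat=model.n_sites):
            k = sum(pattern)
            if conf.K is None:
                w = 0.0 if k > 0 else 1.0 / conf.L
            else:
                w = (1.0 / conf.L) * (G / conf.K) ** k
            out.append((conf.name, k, w))
    return out


def oracle_state_fractions(model, G, conductive_only=False):
    """Fractions per conformation by summing microstate weights."""
    weights = microstate_weights(model, G)
    names = list(model.state_names)
    if conductive_only:
        names = names[1:]
    totals = {n: 0.0 for n in names}
    for name, _, w in weights:
        if name in totals:
            totals[name] += w
    z = sum(totals.values())
    return np.array([totals[n] / z for n in names])


def oracle_saturation(model, G):
    """Fraction of occupied sites: weight-averaged occupancy / n_sites."""
    weights = microstate_weights(model, G)
    num = sum(k * w for _, k, w in weights)
    den = sum(w for _, _, w in weights)
    return num / (model.n_sites * den)


def oracle_liganded_distribution(model, conf_name, G):
    """P(i ligands | conformation) from the conformation's own microstates."""
    weights = [
        (k, w) for name, k, w in microstate_weights(model, G) if name == conf_name
    ]
    z = sum(w for _, w in weights)
    p = np.zeros(model.n_sites + 1)
    for k, w in weights:
        p[k] += w / z
    return p
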