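"""Named positive-support distribution families used throughout the package.

Latencies to the striatal up state are strictly positive, so every family
exposed here has support on (0, inf) with the location parameter pinned at
zero.  The same registry backs the synthetic latency sampler and the
maximum-likelihood fitting / BIC model-selection machinery, so a family name
means the same thing everywhere.

Families
--------
``loglogistic``
    scipy's ``fisk``; parameters ``shape`` (c) and ``scale``.  Used for
    light-evoked latency distributions.
``weibull``
    ``weibull_min``; parameters ``shape`` and ``scale``.  Used for
    spontaneous (random control) latencies.
``lognormal``, ``gamma``, ``exponential``
    Additional candidates for model selection.
``point``
    Degenerate point mass, for exact noiseless tests only; parameter
    ``value``.  Not a fitting candidate.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "FAMILIES",
    "FIT_FAMILIES",
    "N_FREE_PARAMS",
    "frozen",
    "sample",
]


class _PointMass:
    """Degenerate distribution concentrated at a single positive value."""

    def __init__(self, value: float):
        if value <= 0:
            raise ValueError("point-mass value must be positive")
        self.value = float(value)

    def rvs(self, size=None, random_state=None):
        return np.full(size if size is not None else (), self.value)

    def cdf(self, x):
        return (np.asarray(x, dtype=float) >= self.value).astype(float)

    def support(self):
        return (self.value, self.value)


# family name -> (scipy distribution, parameter names in order)
FAMILIES: Mapping[str, tuple] = {
    "loglogistic": (stats.fisk, ("shape", "scale")),
    "weibull": (stats.weibull_min, ("shape", "scale")),
    "lognormal": (stats.lognorm, ("shape", "scale")),
    "gamma": (stats.gamma, ("shape", "scale")),
    "exponential": (stats.expon, ("scale",)),
}

#: candidate order used for deterministic tie-breaking in model selection
FIT_FAMILIES: tuple = ("loglogistic", "weibull", "lognormal", "gamma", "exponential")

#: free parameters per family (loc is pinned at 0 and not counted)
N_FREE_PARAMS: Mapping[str, int] = {
    "loglogistic": 2,
    "weibull": 2,
    "lognormal": 2,
    "gamma": 2,
    "exponential": 1,
}


def frozen(name: str, params: Mapping[str, float]):
    """Return a frozen scipy-like distribution for a named family.

    Parameters
    ----------
    name
        One of the registry families, or ``"point"``.
    params
        Parameter dict; ``shape``/``scale`` for the scipy families,
        ``value`` for the point mass.
    """
    if name == "point":
        return _PointMass(params["value"])
    try:
        dist, pnames = FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown distribution {name!r}; known: {sorted(FAMILIES)} + ['point']"
        ) from None
    args = []
    if "shape" in pnames:
        args.append(float(params["shape"]))
    fr = dist(*args, loc=0.0, scale=float(params["scale"]))
    lo, _ = fr.support()
    if lo < 0:
        raise ValueError(f"{name} with params {params} does not have positive support")
    return fr


def sample(name: str, params: Mapping[str, float], n: int, rng: np.random.Generator):
    """Draw ``n`` i.i.d. values from a named positive-support distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    fr = frozen(name, params)
    return np.asarray(fr.rvs(size=n, random_state=rng), dtype=float)
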