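"""Registry of candidate growth-curve families.

Each family maps a year of life ``t`` (1-based) to a growth quantity
(an increment width in μm, or a mass-specific growth rate).  The same
parameterizations are used to *generate* synthetic growth schedules and
to *fit* observed per-year series, so a round-trip recovery test is
well defined.

Families
--------
linear           y = a + b·t
quadratic        y = a + b·t + c·t²
gaussian         y = a·exp(−(t−b)²/(2c²))
exponential      y = a·exp(b·t)
hill_sigmoid     y = c + (a−c)/(1 + (t/e)^h)      (4-parameter, decreasing for a>c, h>0)
von_bertalanffy  y = a·(1 − b·exp(−k·t))
logistic         y = a / (1 + exp(−b·(t−c)))      (3-parameter)
gompertz         y = a·exp(−b·exp(−c·t))
power            y = a·t^b
logarithmic      y = a + b·ln(t)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["ModelFamily", "FAMILIES", "get_family", "evaluate"]


@dataclass(frozen=True)
class ModelFamily:
    """One candidate growth-curve family.

    Attributes
    ----------
    name:
        Family identifier used throughout the package.
    param_names:
        Parameter symbols in call order.
    func:
        Vectorized ``f(t, *params) -> y``.
    start_ranges:
        Per-parameter ``(lo, hi)`` ranges used to seed multi-start
        fitting; scaled by the data before use (see
        :func:`cementochron.growthfit.fit_models`).
    bounds:
        Hard box bounds for the optimizer.
    """

    name: str
    param_names: tuple[str, ...]
    func: Callable[..., np.ndarray]
    start_ranges: tuple[tuple[float, float], ...]
    bounds: tuple[tuple[float, ...], tuple[float, ...]] = field(default=None)  # type: ignore[assignment]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __call__(self, t, *params):
        return self.func(np.asarray(t, dtype=float), *params)


def _linear(t, a, b):
    return a + b * t


def _quadratic(t, a, b, c):
    return a + b * t + c * t * t


def _gaussian(t, a, b, c):
    return a * np.exp(-((t - b) ** 2) / (2.0 * c * c))


def _exponential(t, a, b):
    return a * np.exp(b * t)


def _hill_sigmoid(t, a, c, e, h):
    return c + (a - c) / (1.0 + (t / e) ** h)


def _von_bertalanffy(t, a, b, k):
    return a * (1.0 - b * np.exp(-k * t))


def _logistic(t, a, b, c):
    return a / (1.0 + np.exp(-b * (t - c)))


def _gompertz(t, a, b, c):
    return a * np.exp(-b * np.exp(-c * t))


def _power(t, a, b):
    return a * np.power(t, b)


def _logarithmic(t, a, b):
    return a + b * np.log(t)


_INF = np.inf

# start_ranges are in "normalized" units: parameters tagged with scale
# 'y' multiply the data amplitude, 't' multiply the time span; see
# growthfit for how they are rescaled per dataset.
FAMILIES: dict[str, ModelFamily] = {
    f.name: f
    for f in (
        ModelFamily(
            "linear",
            ("a", "b"),
            _linear,
            ((0.0, 2.0), (-1.0, 1.0)),
            ((-_INF, -_INF), (_INF, _INF)),
        ),
        ModelFamily(
            "quadratic",
            ("a", "b", "c"),
            _quadratic,
            ((0.0, 2.0), (-1.0, 1.0), (-0.5, 0.5)),
            ((-_INF, -_INF, -_INF), (_INF, _INF, _INF)),
        ),
        ModelFamily(
            "gaussian",
            ("a", "b", "c"),
            _gaussian,
            ((0.2, 2.0), (-1.0, 2.0), (0.1, 3.0)),
            ((0.0, -_INF, 1e-8), (_INF, _INF, _INF)),
        ),
        ModelFamily(
            "exponential",
            ("a", "b"),
            _exponential,
            ((0.2, 2.0), (-1.0, 0.5)),
            ((0.0, -10.0), (_INF, 10.0)),
        ),
        ModelFamily(
            "hill_sigmoid",
            ("a", "c", "e", "h"),
            _hill_sigmoid,
            ((0.5, 2.0), (0.0, 1.0), (0.1, 1.5), (1.0, 8.0)),
            ((0.0, 0.0, 1e-8, 0.1), (_INF, _INF, _INF, 50.0)),
        ),
        ModelFamily(
            "von_bertalanffy",
            ("a", "b", "k"),
            _von_bertalanffy,
            ((0.5, 2.0), (-2.0, 2.0), (0.01, 2.0)),
            ((0.0, -_INF, 1e-8), (_INF, _INF, 20.0)),
        ),
        ModelFamily(
            "logistic",
            ("a", "b", "c"),
            _logistic,
            ((0.5, 2.0), (-3.0, 3.0), (0.0, 1.5)),
            ((0.0, -50.0, -_INF), (_INF, 50.0, _INF)),
        ),
        ModelFamily(
            "gompertz",
            ("a", "b", "c"),
            _gompertz,
            ((0.5, 2.0), (0.01, 5.0), (0.01, 2.0)),
            ((0.0, 1e-8, 1e-8), (_INF, _INF, 20.0)),
        ),
        ModelFamily(
            "power",
            ("a", "b"),
            _power,
            ((0.2, 2.0), (-2.0, 2.0)),
            ((0.0, -10.0), (_INF, 10.0)),
        ),
        ModelFamily(
            "logarithmic",
            ("a", "b"),
            _logarithmic,
            ((0.0, 2.0), (-1.0, 1.0)),
            ((-_INF, -_INF), (_INF, _INF)),
        ),
    )
}

#: scale tags used to map normalized start ranges onto the data: 'y'
#: parameters scale with the response amplitude, 't' with the time span,
#: 'r' (rate/shape) are dimensionless.
PARAM_SCALES: dict[str, tuple[str, ...]] = {
    "linear": ("y", "y"),
    "quadratic": ("y", "y", "y"),
    "gaussian": ("y", "t", "t"),
    "exponential": ("y", "r"),
    "hill_sigmoid": ("y", "y", "t", "r"),
    "von_bertalanffy": ("y", "r", "r"),
    "logistic": ("y", "r", "t"),
    "gompertz": ("y", "r", "r"),
    "power": ("y", "r"),
    "logarithmic": ("y", "y"),
}


def get_family(name: str) -> ModelFamily:
    """Look up a family by name, with a helpful error."""
    try:
        return FAMILIES[name]
    except KeyError:
        raise KeyError(
            f"unknown growth-model family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None


def evaluate(name: str, params: Sequence[float], t) -> np.ndarray:
    """Evaluate family ``name`` with ``params`` at years ``t``."""
    return get_family(name)(t, *params)
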