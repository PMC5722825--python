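"""Frequency-dependent relative fitness of drug-resistant tumour cells.

The central modelling assumption of adaptive therapy is that resistant cells
pay a competitive penalty while they are rare and surrounded by sensitive
cells.  This module defines the map from resistant-cell frequency ``p`` to
relative fitness ``f(p)`` (resistant division rate as a fraction of the
sensitive rate) used by the non-spatial population models.

Three families are provided:

``linear``
    ``f(p) = p``: fitness proportional to frequency, the classical
    assumption.  Unbounded therapy benefit follows from the vanishing
    fitness of rare resistant clones.
``sigmoidal``
    A scaled logistic with lower asymptote ``f_min > 0``: competition for
    diffusion-limited resources is local, so fitness saturates on both
    sides of an abrupt transition at frequency ``c`` with steepness ``k``.
``constant``
    ``f(p) = f_const`` regardless of frequency, for ablation experiments.

Alternative sigmoid shapes can be registered via :func:`register_sigmoid`
without touching the dynamics modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict

import numpy as np
from scipy.special import expit

__all__ = ["FitnessFunctionSpec", "eval_fitness", "register_sigmoid"]


def _scaled_logistic(p, f_min: float, k: float, c: float):
    # expit is overflow-safe for extreme steepness
    return f_min + (1.0 - f_min) * expit(k * (p - c))


#: registry of sigmoid shapes; each maps (p, f_min, k, c) -> fitness
_SIGMOID_FORMS: Dict[str, Callable] = {"logistic": _scaled_logistic}


def register_sigmoid(name: str, func: Callable) -> None:
    """Register an alternative sigmoid family ``func(p, f_min, k, c)``."""
    _SIGMOID_FORMS[name] = func


@dataclass(frozen=True)
class FitnessFunctionSpec:
    """Parameters of the frequency -> relative-fitness map.

    Parameters
    ----------
    kind
        One of ``"linear"``, ``"sigmoidal"``, ``"constant"``.
    f_min
        Lower asymptote of the sigmoid: relative fitness of resistant cells
        when rare (dimensionless, in [0, 1]).
    k
        Sigmoid steepness (dimensionless, > 0).
    c
        Resistant-cell frequency at the sigmoid midpoint (in (0, 1)).
    f_const
        Fitness returned by the ``constant`` kind (ablations only).
    sigmoid_form
        Name of a registered sigmoid family; default the scaled logistic.
    """

    kind: str = "sigmoidal"
    f_min: float = 0.25
    k: float = 20.0
    c: float = 0.5
    f_const: float = 1.0
    sigmoid_form: str = "logistic"

    def __post_init__(self):
        if self.kind not in ("linear", "sigmoidal", "constant"):
            raise ValueError(f"unknown fitness kind {self.kind!r}")
        if not 0.0 <= self.f_min <= 1.0:
            raise ValueError("f_min must lie in [0, 1]")
        if self.k <= 0:
            raise ValueError("steepness k must be positive")
        if not 0.0 < self.c < 1.0:
            raise ValueError("midpoint c must lie in (0, 1)")
        if self.sigmoid_form not in _SIGMOID_FORMS:
            raise ValueError(f"unregistered sigmoid form {self.sigmoid_form!r}")

    def __call__(self, resistant_frequency):
        return eval_fitness(self, resistant_frequency)


def eval_fitness(spec: FitnessFunctionSpec, resistant_frequency):
    """Relative fitness of resistant cells at the given frequency.

    Accepts a scalar or array frequency in [0, 1]; returns the same shape.
    """
    p = np.asarray(resistant_frequency, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0) or not np.all(np.isfinite(p)):
        raise ValueError("resistant frequency must lie in [0, 1]")
    if spec.kind == "linear":
        out = p
    elif spec.kind == "constant":
        out = np.full_like(p, spec.f_const)
    else:
        out = _SIGMOID_FORMS[spec.sigmoid_form](p, spec.f_min, spec.k, spec.c)
    if np.ndim(resistant_frequency) == 0:
        return float(out)
    return out
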