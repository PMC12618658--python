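"""Model explanation: exact Shapley attributions and partial dependence.

Attributions use the exact Shapley value over feature subsets: a feature's
value function is the model evaluated with features inside the coalition
taken from the explained point and the rest masked to a single reference
point (by default the feature means). For |F| features this needs 2^|F|
model evaluations, done in one batched ``predict`` call; the attributions
satisfy the efficiency axiom ``sum(phi) = f(x) - f(reference)`` exactly (to
floating-point round-off).

Partial dependence holds every non-focal feature at its mean and sweeps
one feature across a grid of values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

MAX_FEATURES = 16  # 2^16 evaluations is the exact-enumeration ceiling


@dataclass(frozen=True)
class Attribution:
    """Per-feature Shapley attributions for one explained prediction."""

    phi: np.ndarray
    feature_names: tuple[str, ...]
    baseline: float  # f(reference)
    prediction: float  # f(x)

    def __post_init__(self) -> None:
        if abs(self.phi.sum() - (self.prediction - self.baseline)) > 1e-6 * max(
            1.0, abs(self.prediction - self.baseline)
        ):
            raise ValueError("attributions violate the efficiency axiom")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.feature_names, "phi": self.phi})


def exact_shapley(
    predict: Callable[[np.ndarray], np.ndarray],
    x: Sequence[float],
    reference: Sequence[float],
    feature_names: Sequence[str] | None = None,
) -> Attribution:
    """Exact Shapley attribution by subset enumeration.

    ``predict`` must accept a 2-D array of points mixing coordinates of
    ``x`` and ``reference``. The attribution of feature ``i`` is the
    weighted average, over all subsets ``S`` of the other features, of
    ``f(S + {i}) - f(S)`` with weight ``|S|! (|F|-|S|-1)! / |F|!``.
    """
    x = np.asarray(x, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float).ravel()
    if x.shape != ref.shape:
        raise ValueError("x and reference must have the same length")
    p = x.size
    if p > MAX_FEATURES:
        raise ValueError(
            f"{p} features require 2^{p} evaluations; explain a subset of at "
            f"most {MAX_FEATURES} features (mask the rest to the reference)"
        )
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(p)
    )

    n_sub = 1 << p
    # row s of the evaluation batch = point with features in bitmask s from x
    bits = (np.arange(n_sub)[:, None] >> np.arange(p)[None, :]) & 1  # (2^p, p)
    batch = np.where(bits.astype(bool), x[None, :], ref[None, :])
    values = np.asarray(predict(batch), dtype=float).ravel()
    if values.shape != (n_sub,):
        raise ValueError("predict must return one value per input row")

    sizes = bits.sum(axis=1)
    fact = np.array([math.factorial(k) for k in range(p + 1)], dtype=float)
    phi = np.zeros(p)
    for i in range(p):
        has_i = (bits[:, i] == 1)
        s_with = np.flatnonzero(has_i)
        s_without = s_with ^ (1 << i)
        k = sizes[s_without]  # |S| excluding i
        w = fact[k] * fact[p - k - 1] / fact[p]
        phi[i] = np.sum(w * (values[s_with] - values[s_without]))

    return Attribution(
        phi=phi,
        feature_names=names,
        baseline=float(values[0]),
        prediction=float(values[-1]),
    )


def partial_dependence(
    predict: Callable[[np.ndarray], np.ndarray],
    feature_index: int,
    grid: Sequence[float],
    feature_means: Sequence[float],
) -> pd.DataFrame:
    """Model response along one feature, others held at their means.

    ``grid`` should span the feature's central observed range (e.g. its
    central 95% interval); extrapolating a tree ensemble far outside the
    training support flat-lines the curve.
    """
    grid = np.asarray(grid, dtype=float).ravel()
    if grid.size == 0:
        raise ValueError("empty evaluation grid")
    means = np.asarray(feature_means, dtype=float).ravel()
    if not 0 <= feature_index < means.size:
        raise ValueError("feature index out of range")
    batch = np.tile(means, (grid.size, 1))
    batch[:, feature_index] = grid
    values = np.asarray(predict(batch), dtype=float).ravel()
    return pd.DataFrame({"value": grid, "prediction": values})


def central_range(values: Sequence[float], coverage: float = 0.95) -> tuple[float, float]:
    """The central ``coverage`` interval of observed feature values."""
    v = np.asarray(values, dtype=float)
    tail = (1.0 - coverage) / 2.0
    return float(np.quantile(v, tail)), float(np.quantile(v, 1.0 - tail))
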