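"""Weibull lifetime distribution: closed-form moments, two-moment inversion, sampling.

The Weibull distribution with scale :math:`\\lambda > 0` (years) and shape
:math:`k > 0` has

.. math::

    \\mathrm{mean} = \\lambda\\,\\Gamma(1 + 1/k), \\qquad
    \\mathrm{median} = \\lambda\\,(\\ln 2)^{1/k}.

The scale-free ratio mean/median depends on the shape alone and is strictly
decreasing in :math:`k`, so a (mean, median) target pair determines the
parameters uniquely whenever the ratio is attainable.  :func:`solve_weibull`
exploits this: it root-finds the shape from the ratio equation, then reads the
scale off the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gamma as _gamma

__all__ = [
    "WeibullParams",
    "TargetMoments",
    "SHAPE_BRACKET",
    "weibull_mean",
    "weibull_median",
    "weibull_variance",
    "mean_median_ratio",
    "solve_weibull",
    "sample_lifespans",
]

_LN2 = float(np.log(2.0))

#: Shape bracket searched by :func:`solve_weibull`.  The mean/median ratio is
#: strictly decreasing on it (it reaches a minimum of ~0.98572 near k = 7.1
#: and then creeps back toward 1, so wider brackets would lose root
#: uniqueness); the bracket covers ratios from ~0.98572 up to ~749, far
#: beyond the ~1.2 the survival schedules use.
SHAPE_BRACKET = (0.2, 7.0)


@dataclass(frozen=True)
class WeibullParams:
    """Scale/shape pair defining one birth-year's lifespan distribution.

    Parameters
    ----------
    scale : float
        Scale parameter (lambda), in years.  Must be positive.
    shape : float
        Shape parameter (k), dimensionless.  Must be positive.
    """

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not (self.scale > 0.0):
            raise ValueError(f"scale must be positive, got {self.scale}")
        if not (self.shape > 0.0):
            raise ValueError(f"shape must be positive, got {self.shape}")


@dataclass(frozen=True)
class TargetMoments:
    """(mean, median) survival targets a Weibull distribution must match."""

    mean: float
    median: float

    def __post_init__(self) -> None:
        if not (self.mean > 0.0):
            raise ValueError(f"mean must be positive, got {self.mean}")
        if not (self.median > 0.0):
            raise ValueError(f"median must be positive, got {self.median}")


def weibull_mean(params: WeibullParams) -> float:
    """Distribution mean, ``scale * Gamma(1 + 1/shape)``, in years."""
    return params.scale * float(_gamma(1.0 + 1.0 / params.shape))


def weibull_median(params: WeibullParams) -> float:
    """Distribution median, ``scale * (ln 2)**(1/shape)``, in years."""
    return params.scale * _LN2 ** (1.0 / params.shape)


def weibull_variance(params: WeibullParams) -> float:
    """Distribution variance, in years squared."""
    g1 = float(_gamma(1.0 + 1.0 / params.shape))
    g2 = float(_gamma(1.0 + 2.0 / params.shape))
    return params.scale**2 * (g2 - g1**2)


def mean_median_ratio(shape: float | np.ndarray) -> float | np.ndarray:
    """Mean/median ratio ``Gamma(1 + 1/k) / (ln 2)**(1/k)`` as a function of shape.

    Strictly decreasing in ``k`` on :data:`SHAPE_BRACKET`, which makes the
    root in :func:`solve_weibull` unique.
    """
    return _gamma(1.0 + 1.0 / shape) / _LN2 ** (1.0 / shape)


def solve_weibull(targets: TargetMoments) -> WeibullParams:
    """Invert (mean, median) targets to Weibull (scale, shape).

    Root-finds the shape from the scale-free equation
    ``mean/median = Gamma(1 + 1/k) / (ln 2)**(1/k)`` on :data:`SHAPE_BRACKET`,
    then sets ``scale = mean / Gamma(1 + 1/k)``.

    Raises
    ------
    ValueError
        If the mean/median ratio is outside the range attainable on the
        shape bracket.

    Examples
    --------
    >>> p = solve_weibull(TargetMoments(mean=25.3, median=20.8))
    >>> round(p.scale, 2), round(p.shape, 2)
    (27.46, 1.32)
    """
    ratio = targets.mean / targets.median
    lo, hi = SHAPE_BRACKET
    ratio_hi = float(mean_median_ratio(hi))  # smallest attainable ratio
    ratio_lo = float(mean_median_ratio(lo))  # largest attainable ratio
    if not (ratio_hi < ratio < ratio_lo):
        raise ValueError(
            f"mean/median ratio {ratio:.6g} outside attainable range "
            f"({ratio_hi:.6g}, {ratio_lo:.6g}) for shape in {SHAPE_BRACKET}"
        )
    shape = brentq(
        lambda k: mean_median_ratio(k) - ratio, lo, hi, xtol=1e-13, rtol=1e-12
    )
    scale = targets.mean / float(_gamma(1.0 + 1.0 / shape))
    return WeibullParams(scale=scale, shape=shape)


def sample_lifespans(
    params: WeibullParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` independent lifespans (years) from the Weibull distribution.

    Reproducible given the generator state; returns an empty array for n=0.
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    return params.scale * rng.weibull(params.shape, size=n)
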