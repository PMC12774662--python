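"""Poisson theory of concatemeric product-size heterogeneity.

Writing exponential growth over an interval ``dt`` as its Taylor
series,

    2**(dt/T_theta) = e**(lam) with lam = dt*ln2/T_theta
                    = e**(lam) * sum_m [ e**(-lam) * lam**m / m! ],

identifies the m-th series term with the fraction of products that
acquired exactly ``m`` repeat units during ``dt``: product sizes of a
concatemer-forming amplification (LAMP) are Poisson distributed with
parameter ``lam``, the mean number of repeat units added per template.
The mean size grows linearly with ``lam``, the variance equals ``lam``,
and abundance decays super-exponentially for ``m >> lam`` — so the size
profile marches to larger fragments while broadening as the reaction
runs, with no tuning parameters beyond ``dt`` and ``T_theta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

__all__ = [
    "RepeatUnitDistribution",
    "poisson_lambda",
    "repeat_unit_pmf",
    "size_distribution",
    "taylor_partial_sum",
    "default_m_max",
]


def poisson_lambda(dt: float, T_theta: float) -> float:
    """Poisson parameter ``lam = dt * ln2 / T_theta``.

    Mean number of repeat units appended per template over ``dt``
    minutes at ideal doubling time ``T_theta``.
    """
    if dt < 0:
        raise ValueError(f"dt must be nonnegative, got {dt}")
    if not T_theta > 0:
        raise ValueError(f"T_theta must be positive, got {T_theta}")
    return dt * math.log(2.0) / T_theta


def default_m_max(lam: float) -> int:
    """Truncation index leaving < 1e-9 upper-tail mass."""
    return int(math.ceil(lam + 10.0 * math.sqrt(max(lam, 0.0)) + 10.0))


@dataclass
class RepeatUnitDistribution:
    """Truncated Poisson pmf over repeat-unit counts m = 0..m_max."""

    lam: float
    pmf: np.ndarray
    m_max: int
    S_a: Optional[float] = None  # repeat-unit size, bp

    @property
    def m(self) -> np.ndarray:
        return np.arange(self.m_max + 1)

    @property
    def mean(self) -> float:
        return float(np.sum(self.m * self.pmf))

    @property
    def variance(self) -> float:
        mu = self.mean
        return float(np.sum((self.m - mu) ** 2 * self.pmf))

    @property
    def tail_mass(self) -> float:
        """Probability mass beyond the truncation index."""
        return float(poisson.sf(self.m_max, self.lam))

    @property
    def mode(self) -> int:
        return int(np.argmax(self.pmf))


def repeat_unit_pmf(
    lam: float,
    m_max: Optional[int] = None,
    S_a: Optional[float] = None,
) -> RepeatUnitDistribution:
    """Poisson pmf ``p(m) = e**(-lam) lam**m / m!`` on 0..m_max.

    Evaluated in log space so that large ``lam`` (minutes of
    amplification at sub-minute doubling times) and ``m_max`` up to 1e4
    stay finite.
    """
    if lam < 0:
        raise ValueError(f"lam must be nonnegative, got {lam}")
    if m_max is None:
        m_max = default_m_max(lam)
    if m_max < 0:
        raise ValueError(f"m_max must be nonnegative, got {m_max}")
    m = np.arange(m_max + 1)
    if lam == 0.0:
        pmf = np.zeros(m_max + 1)
        pmf[0] = 1.0
    else:
        logp = -lam + m * math.log(lam) - gammaln(m + 1)
        pmf = np.exp(logp)
    return RepeatUnitDistribution(lam=float(lam), pmf=pmf, m_max=int(m_max), S_a=S_a)


def size_distribution(dist: RepeatUnitDistribution) -> List[Tuple[float, float]]:
    """Map repeat-unit counts to fragment sizes ``m * S_a`` (bp).

    Probabilities are unchanged; only the axis is rescaled.
    """
    if dist.S_a is None:
        raise ValueError("repeat-unit size S_a is not set on this distribution")
    return [(float(m * dist.S_a), float(p)) for m, p in zip(dist.m, dist.pmf)]


def mass_weighted_profile(dist: RepeatUnitDistribution) -> List[Tuple[float, float]]:
    """Electropherogram-like view: each size bin weighted by fragment mass.

    Intercalating-dye or stain signal scales with base pairs, so a gel
    trace weights each fragment class by ``probability * size``.  The
    weights are renormalized to sum to 1.  Non-quantitative convenience
    view for visual comparison with electrophoresis profiles.
    """
    pairs = size_distribution(dist)
    w = np.array([s * p for s, p in pairs])
    total = w.sum()
    if total == 0:
        return [(s, 0.0) for s, _ in pairs]
    return [(s, float(wi / total)) for (s, _), wi in zip(pairs, w)]


def taylor_partial_sum(x: float, M: int) -> float:
    """Partial Taylor sum ``sum_{m=0}^{M} (x ln2)**m / m!`` approximating 2**x.

    Computed via log-space accumulation so large ``x`` and ``M`` do not
    overflow intermediate factorials.
    """
    if x < 0:
        raise ValueError(f"x must be nonnegative, got {x}")
    if M < 0:
        raise ValueError(f"M must be nonnegative, got {M}")
    lam = x * math.log(2.0)
    if lam == 0.0:
        return 1.0
    m = np.arange(M + 1)
    log_terms = m * math.log(lam) - gammaln(m + 1)
    return float(np.exp(logsumexp(log_terms)))
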