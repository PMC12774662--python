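"""Scalar physics of isothermal exponential amplification (IEA).

The model describes any IEA method (LAMP, RPA, SDA, HDA) through three
physical quantities: the polymerase extension rate ``S_e`` (bp/min), the
apparent amplicon size ``S_a`` (bp; for LAMP the repeating-unit length),
and the primer-template binding efficiency ``xi``.  Their combination

    T = T_theta / xi = S_a / (xi * S_e)

is the apparent doubling time of the amplicon population, where
``T_theta = S_a / S_e`` is the ideal doubling time (one polymerase
traversal of one repeat unit) and ``xi = log2(1 + eta)`` converts the
per-doubling template binding rate ``eta`` into an efficiency on the
doubling scale.

``eta`` itself follows from the annealing competition between template
self-annealing and primer-template annealing, collapsed into a single
empirical constant ``K_A`` and concentration exponent ``nu``:

    eta = c_p / (c_p + 2 * K_A * c_t**nu)

with ``c_p`` the free primer and ``c_t`` the amplicon concentration
(both uM).  All functions here are pure and are consumed by the
simulator, the fitter and the quantification layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "AVOGADRO",
    "KineticParameters",
    "ReactionState",
    "binding_rate",
    "binding_efficiency",
    "ideal_doubling_time",
    "apparent_doubling_time",
    "copies_to_micromolar",
    "micromolar_to_copies",
    "NoAmplificationError",
]

#: Avogadro's number as used throughout (1/mol).  Fixed at the rounded
#: value so copies<->uM conversions reproduce published arithmetic.
AVOGADRO = 6.02e23

_ETA_CLAMP_TOL = 1e-9


class NoAmplificationError(ValueError):
    """Raised where a zero binding efficiency makes the doubling time infinite."""


@dataclass(frozen=True)
class KineticParameters:
    """Physical parameters of one amplification reaction.

    Parameters
    ----------
    T_theta:
        Ideal doubling time in minutes (``S_a / S_e``).
    K_A:
        Relative self-annealing constant (empirical, uM^(1-nu)).
    nu:
        Exponent governing how amplicon concentration suppresses primer
        binding; dimensionless.
    c_p0:
        Initial primer concentration, uM.
    S_a:
        Apparent amplicon (repeat-unit) size, bp.
    S_e:
        Polymerase extension rate, bp/min.  Optional; when both ``S_a``
        and ``S_e`` are given, ``T_theta`` must equal ``S_a / S_e``.
    S_p:
        Primer length in bp; only used to seed an initial guess for
        ``K_A`` when fitting (``K_A`` is roughly proportional to
        ``S_a / S_p``).
    """

    T_theta: float
    K_A: float
    nu: float
    c_p0: float
    S_a: float = field(default=145.0)
    S_e: Optional[float] = None
    S_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.T_theta > 0:
            raise ValueError(f"T_theta must be positive, got {self.T_theta}")
        if not self.K_A > 0:
            raise ValueError(f"K_A must be positive, got {self.K_A}")
        if self.nu < 0:
            raise ValueError(f"nu must be nonnegative, got {self.nu}")
        if self.S_a < 1:
            raise ValueError(f"S_a must be >= 1 bp, got {self.S_a}")
        if not self.c_p0 > 0:
            raise ValueError(f"c_p0 must be positive, got {self.c_p0}")
        if self.S_e is not None:
            if not self.S_e > 0:
                raise ValueError(f"S_e must be positive, got {self.S_e}")
            implied = self.S_a / self.S_e
            if abs(implied - self.T_theta) > 1e-9 * max(implied, self.T_theta):
                raise ValueError(
                    f"inconsistent parameters: S_a/S_e = {implied!r} but "
                    f"T_theta = {self.T_theta!r}"
                )

    def with_extension_rate_scaled(self, factor: float) -> "KineticParameters":
        """Return a copy with ``S_e`` multiplied by ``factor``.

        Emulates a global change of polymerase activity (enzyme dilution,
        matrix inhibition): ``T_theta`` scales by ``1/factor`` while the
        annealing parameters are untouched.
        """
        if not factor > 0:
            raise ValueError("scale factor must be positive")
        return KineticParameters(
            T_theta=self.T_theta / factor,
            K_A=self.K_A,
            nu=self.nu,
            c_p0=self.c_p0,
            S_a=self.S_a,
            S_e=None if self.S_e is None else self.S_e * factor,
            S_p=self.S_p,
        )


@dataclass(frozen=True)
class ReactionState:
    """Instantaneous state of the reaction at time ``t`` (minutes)."""

    t: float
    N_t: float  # amplicon copies/ul
    c_t: float  # amplicon concentration, uM
    c_p: float  # free primer concentration, uM
    eta: float  # template binding rate, dimensionless
    xi: float  # binding efficiency, dimensionless


def binding_rate(c_p: float, c_t: float, K_A: float, nu: float) -> float:
    """Template binding rate ``eta = c_p / (c_p + 2*K_A*c_t**nu)``.

    The fraction of templates productively primed per doubling interval.
    Monotonically increasing in primer concentration and, for ``nu > 0``,
    decreasing in amplicon concentration.  ``c_p = c_t = 0`` (with any
    ``nu``) is defined as 0: no primer, no amplification.
    """
    if c_p < 0 or c_t < 0:
        raise ValueError(f"concentrations must be nonnegative, got c_p={c_p}, c_t={c_t}")
    if not K_A > 0:
        raise ValueError(f"K_A must be positive, got {K_A}")
    if nu < 0:
        raise ValueError(f"nu must be nonnegative, got {nu}")
    if c_p == 0.0:
        return 0.0
    denom = c_p + 2.0 * K_A * c_t**nu
    eta = c_p / denom
    if eta < -_ETA_CLAMP_TOL or eta > 1.0 + _ETA_CLAMP_TOL:
        raise ValueError(f"binding rate {eta} outside [0, 1]")
    return min(max(eta, 0.0), 1.0)


def binding_efficiency(eta: float) -> float:
    """Binding efficiency ``xi = log2(1 + eta)`` on the doubling scale."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must lie in [0, 1], got {eta}")
    return math.log2(1.0 + eta)


def ideal_doubling_time(S_a: float, S_e: float) -> float:
    """Ideal doubling time ``T_theta = S_a / S_e`` in minutes."""
    if S_a < 1:
        raise ValueError(f"S_a must be >= 1 bp, got {S_a}")
    if not S_e > 0:
        raise ValueError(f"S_e must be positive, got {S_e}")
    return S_a / S_e


def apparent_doubling_time(T_theta: float, xi: float) -> float:
    """Apparent doubling time ``T = T_theta / xi``.

    Raises :class:`NoAmplificationError` when ``xi == 0`` (the doubling
    time diverges; the reaction does not amplify).
    """
    if not T_theta > 0:
        raise ValueError(f"T_theta must be positive, got {T_theta}")
    if not 0.0 <= xi <= 1.0:
        raise ValueError(f"xi must lie in [0, 1], got {xi}")
    if xi == 0.0:
        raise NoAmplificationError("xi = 0: infinite doubling time (no amplification)")
    return T_theta / xi


def copies_to_micromolar(N: float) -> float:
    """Convert copies/ul to uM: ``c = N / AVOGADRO * 1e12``."""
    if N < 0:
        raise ValueError(f"copy number must be nonnegative, got {N}")
    return N / AVOGADRO * 1e12


def micromolar_to_copies(c: float) -> float:
    """Convert uM to copies/ul (inverse of :func:`copies_to_micromolar`)."""
    if c < 0:
        raise ValueError(f"concentration must be nonnegative, got {c}")
    return c * AVOGADRO * 1e-12
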