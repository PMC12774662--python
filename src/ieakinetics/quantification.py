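"""Standard-curve and relative quantification.

For a serial dilution, the time-to-positive ``t_P`` (first crossing of a
threshold set at <= 10% of the plateau fluorescence) is linear in the
natural log of the relative initial concentration, with slope
``-T / ln 2``: each ln-unit of extra template saves ``T / ln 2`` minutes
of amplification.  The apparent doubling time ``T`` recovered this way
is the dilute-phase value ``T_theta / xi_0``, since dilution translates
an autonomous trajectory in time without changing its shape.

Two targets measured under the same run can be compared without any
absolute calibration through the doubling-time ratio ``K_T = T_s/T_t``,
which is insensitive to global changes in polymerase activity (enzyme
concentration, matrix inhibitors) because those scale both extension
rates equally.  The relative abundance of target t versus reference s is

    R_a = K_S * 2**((t_P,s - K_T * t_P,t) / T_s),       K_S = S_a,s/S_a,t.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .curve_fit import AmplificationCurve

__all__ = [
    "StandardCurve",
    "RelativeQuantResult",
    "ConditionEffect",
    "NEGATIVE",
    "time_to_positive",
    "is_negative",
    "build_standard_curve",
    "doubling_time_from_slope",
    "k_T",
    "apparent_extension_rate",
    "relative_abundance",
    "condition_effect",
]

#: Sentinel for a well that never crosses threshold ("negative" well).
NEGATIVE = float("nan")


def is_negative(t_P: float) -> bool:
    """True when ``t_P`` is the never-crossed sentinel."""
    return isinstance(t_P, float) and math.isnan(t_P)


def time_to_positive(
    curve: AmplificationCurve,
    threshold_frac: float = 0.10,
) -> float:
    """First threshold crossing of a plateau-normalized curve, minutes.

    ``threshold_frac`` must be at most 0.10: above ~10% of the plateau
    the trajectory has already left the clean exponential regime and
    t_P spacing no longer reflects the doubling time.  The crossing is
    linearly interpolated between the bracketing samples.  Returns the
    ``NEGATIVE`` NaN sentinel when the curve never crosses; emits a
    UserWarning (and returns the first time point) when the very first
    sample is already above threshold ("pre-amplified").
    """
    if not 0.0 < threshold_frac <= 0.10:
        raise ValueError(f"threshold_frac must be in (0, 0.10], got {threshold_frac}")
    y = curve.fluorescence
    t = curve.times
    above = y >= threshold_frac
    if not above.any():
        return NEGATIVE
    i = int(np.argmax(above))
    if i == 0:
        warnings.warn(
            f"curve {curve.sample_id!r} pre-amplified: first sample already above "
            f"threshold {threshold_frac}",
            stacklevel=2,
        )
        return float(t[0])
    y0, y1 = y[i - 1], y[i]
    w = (threshold_frac - y0) / (y1 - y0)
    return float(t[i - 1] + w * (t[i] - t[i - 1]))


@dataclass
class StandardCurve:
    """OLS fit of t_P against ln(relative concentration)."""

    x: np.ndarray  # ln(relative concentration), dimensionless
    y: np.ndarray  # t_P, min
    slope: float  # min per ln-unit
    intercept: float  # min
    r_squared: float
    T: float  # doubling time, min
    excluded: List[int] = field(default_factory=list)

    def predict(self, ln_rel_conc: float) -> float:
        return self.intercept + self.slope * ln_rel_conc

    def to_dict(self) -> dict:
        return {
            "slope_min_per_ln": self.slope,
            "intercept_min": self.intercept,
            "r_squared": self.r_squared,
            "T_min": self.T,
            "excluded": list(self.excluded),
            "x": self.x.tolist(),
            "y": self.y.tolist(),
        }


def doubling_time_from_slope(slope: float) -> float:
    """Doubling time from the standard-curve slope: ``T = -slope * ln 2``."""
    if not slope < 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return -slope * math.log(2.0)


def build_standard_curve(
    t_P_list: Sequence[float],
    relative_conc_list: Sequence[float],
    outlier_sigma: float = 3.0,
    min_abs_residual: float = 0.05,
) -> StandardCurve:
    """Regress t_P on ln(relative concentration) with outlier exclusion.

    Outlier policy: while any point's externally studentized residual
    exceeds ``outlier_sigma`` in magnitude, its raw residual exceeds
    ``min_abs_residual`` minutes, and at least 4 points remain, drop the
    single worst point and refit.  The absolute floor (default 0.05 min,
    well under one 20-s sampling interval) keeps the scale-free
    studentized criterion from discarding points of an almost perfect
    line.  Indices of removed points (0-based, in input order) are
    reported.
    """
    t_P = np.asarray(t_P_list, dtype=float)
    conc = np.asarray(relative_conc_list, dtype=float)
    if t_P.size != conc.size:
        raise ValueError("t_P_list and relative_conc_list must have equal length")
    if np.any(conc <= 0):
        raise ValueError("relative concentrations must be positive")
    if np.any(~np.isfinite(t_P)):
        raise ValueError("t_P values must be finite (drop negative wells first)")
    if t_P.size < 4:
        raise ValueError(f"need >= 4 points, got {t_P.size}")

    x = np.log(conc)
    keep = np.arange(t_P.size)
    while True:
        X = sm.add_constant(x[keep])
        fit = sm.OLS(t_P[keep], X).fit()
        if keep.size <= 4:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            # exactly collinear retained points give infinite studentized
            # residuals; the absolute floor below keeps them in place
            resid = OLSInfluence(fit).resid_studentized_external
        worst = int(np.argmax(np.abs(resid)))
        if (
            np.abs(resid[worst]) > outlier_sigma
            and np.abs(fit.resid[worst]) > min_abs_residual
        ):
            keep = np.delete(keep, worst)
        else:
            break

    slope = float(fit.params[1])
    intercept = float(fit.params[0])
    if slope >= 0:
        raise ValueError(
            f"invalid series: nonnegative standard-curve slope {slope:.4g}"
        )
    excluded = sorted(set(range(t_P.size)) - set(keep.tolist()))
    return StandardCurve(
        x=x,
        y=t_P,
        slope=slope,
        intercept=intercept,
        r_squared=float(fit.rsquared),
        T=doubling_time_from_slope(slope),
        excluded=excluded,
    )


def k_T(T_s: float, T_t: float) -> float:
    """Doubling-time ratio ``K_T = T_s / T_t`` of two targets."""
    if not (T_s > 0 and T_t > 0):
        raise ValueError(f"doubling times must be positive, got {T_s}, {T_t}")
    return T_s / T_t


def apparent_extension_rate(S_a: float, T_min: float) -> float:
    """Apparent strand extension rate ``S_e* = S_a / T_min`` (bp/min).

    ``T_min`` is the minimum apparent doubling time observed for the
    target across conditions; ``S_e*`` folds polymerase speed and
    annealing efficiency into one condition-composite rate.
    """
    if S_a < 1:
        raise ValueError(f"S_a must be >= 1 bp, got {S_a}")
    if not T_min > 0:
        raise ValueError(f"T_min must be positive, got {T_min}")
    return S_a / T_min


@dataclass
class RelativeQuantResult:
    """Relative abundance of a target against a reference."""

    R_a: float
    K_S: float
    K_T: float
    T_s: float
    t_P_s: float
    t_P_t: float


def relative_abundance(
    t_P_s: float,
    t_P_t: float,
    T_s: float,
    K_T: float,
    K_S: float = 1.0,
) -> float:
    """Relative abundance ``R_a = K_S * 2**((t_P,s - K_T*t_P,t)/T_s)``.

    ``s`` denotes the reference, ``t`` the target; with ``K_T = 1``,
    ``ln R_a`` is linear in ``delta t_P = t_P,s - t_P,t`` with slope
    ``ln2 / T_s`` — the comparative-threshold analogy that makes the
    estimate robust to matrix effects.
    """
    if not T_s > 0:
        raise ValueError(f"T_s must be positive, got {T_s}")
    if not K_T > 0:
        raise ValueError(f"K_T must be positive, got {K_T}")
    if not K_S > 0:
        raise ValueError(f"K_S must be positive, got {K_S}")
    return K_S * 2.0 ** ((t_P_s - K_T * t_P_t) / T_s)


@dataclass
class ConditionEffect:
    """Per-key percent change in doubling time between two conditions."""

    percent_change: Dict[object, float]
    min: float
    max: float


def condition_effect(
    T_table_a: Mapping[object, float],
    T_table_b: Mapping[object, float],
) -> ConditionEffect:
    """Percent change of doubling time from condition a to condition b.

    Both tables map matched keys (e.g. ``(temperature, gene)``) to
    doubling times; the change per key is ``100 * (T_b/T_a - 1)``,
    rounded to 1 decimal place, with the (min, max) range across keys.
    """
    if set(T_table_a) != set(T_table_b):
        missing = set(T_table_a) ^ set(T_table_b)
        raise ValueError(f"condition tables have mismatched keys: {sorted(map(str, missing))}")
    if not T_table_a:
        raise ValueError("condition tables are empty")
    changes = {}
    for key, Ta in T_table_a.items():
        Tb = T_table_b[key]
        if not (Ta > 0 and Tb > 0):
            raise ValueError(f"doubling times must be positive at key {key!r}")
        changes[key] = round(100.0 * (Tb / Ta - 1.0), 1)
    vals = list(changes.values())
    return ConditionEffect(percent_change=changes, min=min(vals), max=max(vals))
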