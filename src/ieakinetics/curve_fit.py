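"""Estimation of kinetic parameters from real-time fluorescence curves.

A set of amplification curves (typically a serial dilution of one
target, measured every 20 s on a real-time instrument) is fitted jointly
against the simulated model: the free parameters are the ideal doubling
time ``T_theta``, the annealing constant ``K_A``, the concentration
exponent ``nu`` and the initial copy number ``N_0m`` of the stock
(curves at known dilution factors share the stock estimate).  The loss
is the mean squared error between plateau-normalized observed curves and
the simulated amplicon concentration scaled by its plateau
``c_0 + c_p0``, so the fitted MSE is directly comparable across
instruments and gain settings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .model_core import (
    KineticParameters,
    copies_to_micromolar,
    micromolar_to_copies,
)
from .simulator import integrate_concentrations

__all__ = [
    "AmplificationCurve",
    "FitResult",
    "NegativeCurveError",
    "normalize_fluorescence",
    "fit_amplification_curves",
    "mse",
    "DEFAULT_BOUNDS",
]

#: Default box bounds for the fitted parameters.  K_A and N_0m are
#: optimized on a log10 scale.
DEFAULT_BOUNDS = {
    "T_theta": (0.05, 5.0),
    "K_A": (0.1, 100.0),
    "nu": (0.1, 3.0),
    "N_0m": (1e-2, 1e12),
}


class NegativeCurveError(ValueError):
    """The curve shows no amplification above the noise floor."""


@dataclass
class AmplificationCurve:
    """One well's fluorescence trace plus its metadata.

    ``times`` must be strictly increasing and uniformly spaced (default
    instrument spacing 1/3 min, i.e. one reading every 20 s).
    """

    times: np.ndarray  # min
    fluorescence: np.ndarray  # a.u.
    sample_id: str = ""
    target: str = ""
    S_a: float = 145.0  # bp
    c_p0: float = 1.6  # uM
    dilution_factor: float = 1.0  # relative concentration, stock = 1
    replicate: int = 0
    temperature: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.size != self.fluorescence.size:
            raise ValueError("times and fluorescence must have equal length")
        if self.times.size < 10:
            raise ValueError(f"curve needs >= 10 points, got {self.times.size}")
        d = np.diff(self.times)
        if np.any(d <= 0):
            raise ValueError("times must be strictly increasing")
        if np.ptp(d) > 1e-9:
            raise ValueError("times must be uniformly spaced (tolerance 1e-9)")
        if not np.all(np.isfinite(self.fluorescence)):
            bad = int(np.flatnonzero(~np.isfinite(self.fluorescence))[0])
            raise ValueError(f"non-finite fluorescence at point {bad}")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def with_fluorescence(self, values: np.ndarray) -> "AmplificationCurve":
        out = AmplificationCurve(
            times=self.times.copy(),
            fluorescence=np.asarray(values, dtype=float),
            sample_id=self.sample_id,
            target=self.target,
            S_a=self.S_a,
            c_p0=self.c_p0,
            dilution_factor=self.dilution_factor,
            replicate=self.replicate,
            temperature=self.temperature,
            condition=self.condition,
        )
        return out


def normalize_fluorescence(
    curve: AmplificationCurve,
    n_edge: int = 5,
    min_snr: float = 10.0,
) -> AmplificationCurve:
    """Rescale a raw trace to the 0-1 plateau scale.

    Baseline is the median of the first ``n_edge`` points, plateau the
    median of the last ``n_edge``; the result is clipped to
    ``[-0.05, 1.05]``.  A curve whose plateau rise does not exceed
    ``min_snr`` times the early noise level raises
    :class:`NegativeCurveError` (no amplification detected) — callers
    fitting many wells should exclude such curves rather than fail.
    The transform is affine-invariant: ``a*F + k`` normalizes
    identically to ``F`` for any ``a > 0``.
    """
    F = curve.fluorescence
    b = float(np.median(F[:n_edge]))
    P = float(np.median(F[-n_edge:]))
    rise = P - b
    # early noise from first differences; robust to a linear drift
    early = F[: max(2 * n_edge, 10)]
    noise = 1.4826 * float(np.median(np.abs(np.diff(early) - np.median(np.diff(early))))) / math.sqrt(2.0)
    floor = max(min_snr * noise, 1e-9 * max(1.0, abs(b)))
    if rise <= floor:
        raise NegativeCurveError(
            f"curve {curve.sample_id!r}: plateau rise {rise:.3g} below noise floor {floor:.3g}"
        )
    norm = np.clip((F - b) / rise, -0.05, 1.05)
    return curve.with_fluorescence(norm)


def mse(observed_normalized: np.ndarray, simulated_normalized: np.ndarray) -> float:
    """Mean squared residual between two equal-length normalized signals."""
    obs = np.asarray(observed_normalized, dtype=float)
    sim = np.asarray(simulated_normalized, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {sim.shape}")
    return float(np.mean((obs - sim) ** 2))


@dataclass
class FitResult:
    """Outcome of a joint curve fit."""

    params: KineticParameters
    N_0m: float  # fitted stock initial copies/ul
    mse: float
    n_points: int
    converged: bool
    bounds_hit: List[str] = field(default_factory=list)
    excluded: List[str] = field(default_factory=list)
    seed: Optional[int] = None
    n_starts: int = 1

    @property
    def mse_x1e4(self) -> float:
        """MSE scaled by 1e4, the customary reporting magnitude."""
        return self.mse * 1e4

    def to_dict(self) -> dict:
        return {
            "T_theta": self.params.T_theta,
            "K_A": self.params.K_A,
            "nu": self.params.nu,
            "S_a": self.params.S_a,
            "c_p0": self.params.c_p0,
            "N_0m": self.N_0m,
            "mse": self.mse,
            "mse_x1e4": self.mse_x1e4,
            "n_points": self.n_points,
            "converged": self.converged,
            "bounds_hit": self.bounds_hit,
            "excluded": self.excluded,
            "seed": self.seed,
            "n_starts": self.n_starts,
        }


def _estimate_initials(
    curves: Sequence[AmplificationCurve], c_p0: float, S_a: float, S_p: Optional[float]
) -> Tuple[float, float, float, float]:
    """Heuristic starting point (T_theta, K_A, nu, N_0m stock).

    The local doubling time is read off the spacing between the 5% and
    20% plateau crossings of the least-diluted curve; the stock copy
    number follows by extrapolating the 10% crossing back to t = 0 at
    that rate.
    """
    stock = max(curves, key=lambda c: c.dilution_factor)
    y = stock.fluorescence
    t = stock.times

    def crossing(frac: float) -> float:
        idx = np.flatnonzero(y >= frac)
        if idx.size == 0 or idx[0] == 0:
            return float(t[0])
        i = idx[0]
        y0, y1 = y[i - 1], y[i]
        w = (frac - y0) / (y1 - y0) if y1 > y0 else 0.0
        return float(t[i - 1] + w * (t[i] - t[i - 1]))

    t05, t20 = crossing(0.05), crossing(0.20)
    T_hat = max((t20 - t05) / 2.0, 0.06)  # 2 doublings between 5% and 20%
    T_theta0 = min(max(0.85 * T_hat, DEFAULT_BOUNDS["T_theta"][0]), DEFAULT_BOUNDS["T_theta"][1])
    K_A0 = (S_a / S_p) if S_p else 5.0
    nu0 = 1.2
    thr_copies = micromolar_to_copies(0.1 * c_p0)
    t10 = crossing(0.10)
    N0m0 = thr_copies * 2.0 ** (-t10 / T_hat) / stock.dilution_factor
    N0m0 = min(max(N0m0, DEFAULT_BOUNDS["N_0m"][0] * 10), DEFAULT_BOUNDS["N_0m"][1] / 10)
    return T_theta0, K_A0, nu0, N0m0


def fit_amplification_curves(
    curves: Sequence[AmplificationCurve],
    shared_dilutions: bool = True,
    init: Optional[dict] = None,
    bounds: Optional[dict] = None,
    n_starts: int = 8,
    seed: int = 0,
    dt: float = 0.01,
    S_p: Optional[float] = None,
    normalize: bool = True,
) -> FitResult:
    """Jointly fit the kinetic model to a family of curves.

    Parameters
    ----------
    curves:
        Curves sharing ``S_a`` and ``c_p0``.  With
        ``shared_dilutions=True`` a single stock copy number ``N_0m`` is
        fitted and each curve's initial copies are
        ``N_0m * dilution_factor``.
    n_starts:
        Multi-start count for the bounded least-squares optimizer; the
        first start uses data-driven initial values, the rest are seeded
        random draws within bounds.  Iteration stops early once the fit
        is numerically perfect (MSE < 1e-12).
    normalize:
        Apply :func:`normalize_fluorescence` first (negative wells are
        excluded and reported in ``FitResult.excluded``).  Pass False if
        the curves are already on the 0-1 plateau scale.
    """
    if len(curves) == 0:
        raise ValueError("need at least one curve")
    S_a_set = {c.S_a for c in curves}
    c_p0_set = {c.c_p0 for c in curves}
    if len(S_a_set) != 1 or len(c_p0_set) != 1:
        raise ValueError("all curves in a joint fit must share S_a and c_p0")
    S_a = S_a_set.pop()
    c_p0 = c_p0_set.pop()

    excluded: List[str] = []
    used: List[AmplificationCurve] = []
    for c in curves:
        if normalize:
            try:
                used.append(normalize_fluorescence(c))
            except NegativeCurveError:
                excluded.append(c.sample_id)
        else:
            used.append(c)
    if not used:
        raise NegativeCurveError("no positive curves to fit")
    for c in used:
        if int(np.sum(c.fluorescence > 0.05)) < 4:
            raise ValueError(
                f"curve {c.sample_id!r}: insufficient exponential phase "
                "(fewer than 4 informative points above threshold)"
            )

    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)

    T0, K0, nu0, N0m0 = _estimate_initials(used, c_p0, S_a, S_p)
    if init:
        T0 = init.get("T_theta", T0)
        K0 = init.get("K_A", K0)
        nu0 = init.get("nu", nu0)
        N0m0 = init.get("N_0m", N0m0)

    dil = np.array([c.dilution_factor for c in used])
    t_end = max(float(c.times[-1]) for c in used)
    obs = [c.fluorescence for c in used]
    n_points = int(sum(o.size for o in obs))

    lo = np.array(
        [bnds["T_theta"][0], math.log10(bnds["K_A"][0]), bnds["nu"][0], math.log10(bnds["N_0m"][0])]
    )
    hi = np.array(
        [bnds["T_theta"][1], math.log10(bnds["K_A"][1]), bnds["nu"][1], math.log10(bnds["N_0m"][1])]
    )

    def residuals(x: np.ndarray) -> np.ndarray:
        T_theta, lKA, nu, lN0m = x
        p = KineticParameters(
            T_theta=T_theta, K_A=10.0**lKA, nu=nu, c_p0=c_p0, S_a=S_a
        )
        step = min(dt, T_theta / 10.0)
        n_steps = int(math.ceil(t_end / step))
        c0 = copies_to_micromolar(10.0**lN0m) * dil
        grid = integrate_concentrations(c0, p, step, n_steps)
        t_grid = np.arange(n_steps + 1) * step
        res = []
        for j, c in enumerate(used):
            model = np.interp(c.times, t_grid, grid[:, j])
            if normalize:
                # the same empirical baseline/plateau map applied to the
                # data, so model and observation are compared like for
                # like even when the plateau is not fully reached
                b = np.median(model[:5])
                P = np.median(model[-5:])
                model = (model - b) / max(P - b, 1e-12)
            else:
                model = model / (c0[j] + c_p0)
            res.append(model - obs[j])
        return np.concatenate(res)

    rng = np.random.default_rng(seed)
    x0_main = np.clip(
        np.array([T0, math.log10(K0), nu0, math.log10(N0m0)]), lo + 1e-9, hi - 1e-9
    )
    best = None
    best_cost = np.inf
    starts_run = 0
    for k in range(max(1, n_starts)):
        if k == 0:
            x0 = x0_main
        else:
            # jitter around the data-driven start, falling back to uniform
            if k < n_starts // 2:
                x0 = np.clip(
                    x0_main + rng.normal(scale=[0.15 * x0_main[0], 0.3, 0.4, 0.5]),
                    lo + 1e-9,
                    hi - 1e-9,
                )
            else:
                x0 = lo + (hi - lo) * rng.uniform(0.05, 0.95, size=4)
        sol = least_squares(
            residuals,
            x0,
            bounds=(lo, hi),
            x_scale=[0.1, 0.5, 0.5, 1.0],
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        starts_run += 1
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
        if 2.0 * best.cost / n_points < 1e-12:
            break

    if best is None or not best.success:
        warnings.warn("optimizer did not report convergence", stacklevel=2)

    x = best.x
    fitted = KineticParameters(
        T_theta=float(x[0]), K_A=float(10.0 ** x[1]), nu=float(x[2]), c_p0=c_p0, S_a=S_a, S_p=S_p
    )
    fit_mse = float(np.mean(best.fun**2))
    names = ["T_theta", "K_A", "nu", "N_0m"]
    hit = [
        names[i]
        for i in range(4)
        if x[i] - lo[i] < 1e-6 * (hi[i] - lo[i]) or hi[i] - x[i] < 1e-6 * (hi[i] - lo[i])
    ]
    return FitResult(
        params=fitted,
        N_0m=float(10.0 ** x[3]),
        mse=fit_mse,
        n_points=n_points,
        converged=bool(best.success),
        bounds_hit=hit,
        excluded=excluded,
        seed=seed,
        n_starts=starts_run,
    )
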