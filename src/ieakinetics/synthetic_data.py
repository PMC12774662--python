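"""Synthetic real-time fluorescence experiments.

Emulates the output of a plate-based real-time instrument running an
isothermal amplification assay: readings every 20 s, sigmoidal curves
produced by the kinetic model, Gaussian read noise, serial 10-fold
dilutions in triplicate, and an optional start-up delay that shifts a
curve rightward (mimicking hot-start activation / seed-structure
formation, the main feature of real reactions the deterministic model
does not capture).

Every generated experiment carries a *truth record* with all generator
parameters so that recovery pipelines can be tested end to end without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .curve_fit import AmplificationCurve
from .model_core import KineticParameters, copies_to_micromolar
from .simulator import integrate_concentrations

__all__ = [
    "NoiseModel",
    "generate_curve",
    "generate_dilution_experiment",
    "PRESETS",
]

#: Named parameter presets for three LAMP primer sets targeting
#: SARS-CoV-2 gene fragments (N, N1, S), as characterized at 63-67 C
#: under full enzyme concentration in a published study.  Keys read
#: <target>_<temperature>_E.  c_p0 = 1.6 uM is the standard inner-primer
#: (FIP/BIP) concentration of the assay.
PRESETS: Dict[str, KineticParameters] = {
    "N_63C_E": KineticParameters(T_theta=0.339, K_A=5.962, nu=1.398, c_p0=1.6, S_a=145),
    "N_65C_E": KineticParameters(T_theta=0.294, K_A=7.040, nu=1.579, c_p0=1.6, S_a=145),
    "N_67C_E": KineticParameters(T_theta=0.270, K_A=5.463, nu=1.812, c_p0=1.6, S_a=145),
    "N1_65C_E": KineticParameters(T_theta=0.445, K_A=2.955, nu=0.755, c_p0=1.6, S_a=175),
    "S_63C_E": KineticParameters(T_theta=0.298, K_A=5.668, nu=1.227, c_p0=1.6, S_a=151),
    "S_65C_E": KineticParameters(T_theta=0.385, K_A=4.617, nu=1.561, c_p0=1.6, S_a=151),
}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement model of the virtual instrument.

    sigma_frac:
        Gaussian read-noise SD as a fraction of the plateau amplitude
        (default 1%, a typical plate-reader level on normalized scale).
    baseline / amplitude:
        Affine fluorescence calibration, arbitrary units.
    t_start:
        Deterministic start-up delay applied to every curve, minutes.
    t_start_jitter:
        Half-width of an additional uniform per-curve delay jitter, min.
    seed:
        Seed of the generator; identical seeds give identical curves.
    """

    sigma_frac: float = 0.01
    baseline: float = 0.2
    amplitude: float = 3.0
    t_start: float = 0.0
    t_start_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_frac < 0:
            raise ValueError(f"sigma_frac must be nonnegative, got {self.sigma_frac}")
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if self.t_start < 0 or self.t_start_jitter < 0:
            raise ValueError("start-up delays must be nonnegative")


NOISELESS = NoiseModel(sigma_frac=0.0)


def _render(
    params: KineticParameters,
    N_0: float,
    noise: NoiseModel,
    t_end: float,
    sampling_interval: float,
    rng: np.random.Generator,
    delay: float,
) -> AmplificationCurve:
    c0 = copies_to_micromolar(N_0)
    dt = 0.01
    n_steps = int(np.ceil(t_end / dt))
    grid = integrate_concentrations(np.array([c0]), params, dt, n_steps)[:, 0]
    t_grid = np.arange(n_steps + 1) * dt
    times = np.arange(0.0, t_end + 1e-9, sampling_interval)
    # a start-up delay shifts the trajectory rightward; before the
    # reaction starts the signal sits at the initial concentration
    shifted = np.clip(times - delay, 0.0, None)
    c = np.interp(shifted, t_grid, grid)
    frac = c / (c0 + params.c_p0)
    F = noise.baseline + noise.amplitude * frac
    if noise.sigma_frac > 0:
        F = F + rng.normal(0.0, noise.sigma_frac * noise.amplitude, size=F.size)
    return AmplificationCurve(times=times, fluorescence=F, S_a=params.S_a, c_p0=params.c_p0)


def generate_curve(
    params: KineticParameters,
    N_0: float,
    noise: NoiseModel = NOISELESS,
    t_end: float = 20.0,
    sampling_interval: float = 1.0 / 3.0,
) -> AmplificationCurve:
    """Render one amplification curve as seen by the instrument.

    ``F(t) = baseline + amplitude * c(t - delay)/(c_0 + c_p0) + eps``
    with ``eps ~ N(0, sigma_frac * amplitude)`` and
    ``delay = t_start + U(-jitter, +jitter)``; deterministic for a
    fixed ``noise.seed``.
    """
    if not sampling_interval > 0:
        raise ValueError(f"sampling_interval must be positive, got {sampling_interval}")
    rng = np.random.default_rng(noise.seed)
    delay = noise.t_start
    if noise.t_start_jitter > 0:
        delay = max(0.0, delay + rng.uniform(-noise.t_start_jitter, noise.t_start_jitter))
    return _render(params, N_0, noise, t_end, sampling_interval, rng, delay)


def generate_dilution_experiment(
    params: KineticParameters,
    stock_N0: float = 1e6,
    n_dilutions: int = 5,
    fold: float = 10.0,
    replicates: int = 3,
    noise: NoiseModel = NOISELESS,
    t_end: float = 20.0,
    sampling_interval: float = 1.0 / 3.0,
    target: str = "target",
) -> Tuple[List[AmplificationCurve], dict]:
    """Serial ``fold``-dilution series of one target, with replicates.

    Defaults mirror a routine quantification run: stock at 1e6
    copies/ul, five 10-fold dilutions, triplicates, one reading every
    20 s for 20 min.  Returns the curves and a truth record (all
    generator parameters) for recovery tests.
    """
    if not fold > 1:
        raise ValueError(f"fold must exceed 1, got {fold}")
    if n_dilutions < 4:
        raise ValueError(f"need >= 4 dilutions for a standard curve, got {n_dilutions}")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    rng = np.random.default_rng(noise.seed)
    curves: List[AmplificationCurve] = []
    for k in range(n_dilutions):
        dilution = fold ** (-k)
        N_0 = stock_N0 * dilution
        for r in range(replicates):
            delay = noise.t_start
            if noise.t_start_jitter > 0:
                delay = max(
                    0.0, delay + rng.uniform(-noise.t_start_jitter, noise.t_start_jitter)
                )
            curve = _render(params, N_0, noise, t_end, sampling_interval, rng, delay)
            curve.sample_id = f"{target}_d{k}_r{r}"
            curve.target = target
            curve.dilution_factor = dilution
            curve.replicate = r
            curves.append(curve)
    truth = {
        "target": target,
        "T_theta": params.T_theta,
        "K_A": params.K_A,
        "nu": params.nu,
        "S_a": params.S_a,
        "c_p0": params.c_p0,
        "stock_N0": stock_N0,
        "n_dilutions": n_dilutions,
        "fold": fold,
        "replicates": replicates,
        "t_end": t_end,
        "sampling_interval": sampling_interval,
        "noise": asdict(noise),
    }
    return curves, truth
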