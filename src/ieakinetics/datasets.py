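"""Bundled reference measurements.

Published characterization of three LAMP primer sets targeting
SARS-CoV-2 gene fragments (N, 145 bp repeat unit; N1, 175 bp; S,
151 bp), assayed across temperature (63/65/67 C), enzyme concentration
(full [E] vs halved [E]/2) and sewage-matrix inhibition (spiked into
sewage viral nucleic-acid extract, SVNA, and its 5-fold dilution,
dSVNA).  Two tables are shipped:

* :func:`doubling_times` — apparent doubling times ``T`` (min) read off
  standard-curve slopes, per gene and condition;
* :func:`fitted_parameters` — kinetic parameters ``(T_theta, N_0m, K_A,
  nu)`` and normalized fit MSE obtained by fitting the model to the raw
  amplification curves.

These printed values serve as worked-example inputs for the
quantification helpers (doubling-time ratios, apparent extension rates,
condition effects); the raw fluorescence traces behind them are not
redistributed here.
"""

from __future__ import annotations

from typing import Dict, Tuple

import pandas as pd

__all__ = [
    "AMPLICON_SIZES",
    "doubling_times",
    "fitted_parameters",
    "doubling_time_table",
]

#: Apparent amplicon (repeat-unit) sizes, bp.
AMPLICON_SIZES: Dict[str, float] = {"N": 145.0, "N1": 175.0, "S": 151.0}

# (temperature C, condition) -> (T_N, T_N1, T_S) in minutes
_DOUBLING_TIMES = [
    (63, "E", 0.279, 0.433, 0.307),
    (63, "E/2", 0.342, 0.561, 0.353),
    (65, "E", 0.253, 0.408, 0.384),
    (65, "E/2", 0.320, 0.462, 0.457),
    (65, "SVNA", 0.354, 0.585, 0.542),
    (65, "dSVNA", 0.246, 0.377, 0.385),
    (67, "E", 0.256, 0.400, 0.541),
    (67, "E/2", 0.334, 0.508, 0.674),
]

# (temperature, condition, gene) -> (T_theta min, N_0m copies/ul, K_A, nu, MSE x 1e4)
_FITTED = [
    (63, "E", "N", 0.339, 5.47e5, 5.962, 1.398, 6.732),
    (63, "E", "N1", 0.459, 2.99e6, 3.120, 0.630, 7.371),
    (63, "E", "S", 0.298, 2.45e5, 5.668, 1.227, 4.435),
    (63, "E/2", "N", 0.394, 1.15e5, 6.419, 1.296, 5.326),
    (63, "E/2", "N1", 0.591, 2.58e6, 3.429, 0.595, 1.787),
    (63, "E/2", "S", 0.338, 1.48e5, 6.219, 1.171, 2.269),
    (65, "E", "N", 0.294, 2.64e5, 7.040, 1.579, 14.00),
    (65, "E", "N1", 0.445, 4.53e6, 2.955, 0.755, 52.00),
    (65, "E", "S", 0.385, 2.33e6, 4.617, 1.561, 3.944),
    (65, "E/2", "N", 0.358, 2.48e5, 8.365, 2.072, 3.921),
    (65, "E/2", "N1", 0.538, 2.97e6, 3.238, 1.025, 4.934),
    (65, "E/2", "S", 0.432, 9.87e5, 6.009, 1.580, 4.781),
    (65, "SVNA", "N", 0.410, 1.72e6, 6.331, 1.792, 7.100),
    (65, "SVNA", "N1", 0.681, 3.31e6, 2.435, 0.693, 6.934),
    (65, "SVNA", "S", 0.612, 3.65e6, 3.304, 1.638, 5.199),
    (65, "dSVNA", "N", 0.274, 5.39e4, 6.077, 1.854, 8.060),
    (65, "dSVNA", "N1", 0.421, 8.03e5, 2.499, 1.079, 65.00),
    (65, "dSVNA", "S", 0.396, 8.29e5, 3.810, 1.513, 4.770),
    (67, "E", "N", 0.270, 4.64e5, 5.463, 1.812, 3.533),
    (67, "E", "N1", 0.448, 1.09e7, 2.593, 1.077, 5.251),
    (67, "E", "S", 0.512, 3.38e6, 3.240, 1.281, 1.996),
    (67, "E/2", "N", 0.310, 4.16e4, 7.821, 1.647, 3.315),
    (67, "E/2", "N1", 0.534, 3.21e6, 3.561, 1.077, 3.260),
    (67, "E/2", "S", 0.678, 5.21e6, 3.910, 1.292, 2.440),
]


def doubling_times() -> pd.DataFrame:
    """Apparent doubling times (min) in long format.

    Columns: temperature_C, condition, gene, T_min.
    """
    rows = []
    for temp, cond, T_N, T_N1, T_S in _DOUBLING_TIMES:
        for gene, T in (("N", T_N), ("N1", T_N1), ("S", T_S)):
            rows.append((temp, cond, gene, T))
    return pd.DataFrame(rows, columns=["temperature_C", "condition", "gene", "T_min"])


def doubling_time_table(condition_filter=None) -> Dict[Tuple[int, str], float]:
    """Doubling times as a ``(temperature, gene) -> T`` mapping.

    ``condition_filter`` selects one condition label (e.g. ``"E"``);
    convenient input for :func:`ieakinetics.quantification.condition_effect`.
    """
    df = doubling_times()
    if condition_filter is not None:
        df = df[df["condition"] == condition_filter]
    return {
        (int(r.temperature_C), r.gene): float(r.T_min) for r in df.itertuples()
    }


def fitted_parameters() -> pd.DataFrame:
    """Model parameters from fitting the raw amplification curves.

    Columns: temperature_C, condition, gene, T_theta_min, N_0m, K_A, nu,
    mse_x1e4.
    """
    return pd.DataFrame(
        _FITTED,
        columns=[
            "temperature_C",
            "condition",
            "gene",
            "T_theta_min",
            "N_0m",
            "K_A",
            "nu",
            "mse_x1e4",
        ],
    )
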