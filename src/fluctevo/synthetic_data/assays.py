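"""Constant-temperature growth-assay generator.

Growth characterisation of evolved clones is done outside the fluctuation
regimes: replicate cultures of each strain are grown at a single test
temperature and their OD830 recorded on the instrument's 4-minute grid.
This module generates such replicate curves from known Gompertz parameters
so the growth-rate estimators can be tested against planted truth.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from fluctevo.synthetic_data.trajectories import (
    SAMPLE_INTERVAL_MIN,
    StrainParams,
    _gompertz_y,
)

__all__ = ["gompertz_log_od", "gompertz_od", "simulate_growth_assay"]


def gompertz_log_od(t, A: float, mu_max: float, lag: float):
    """Zwietering modified Gompertz curve in log-OD.

    Returns log(OD(t)/OD(0-)) = A * exp(-exp(mu_max*e/A * (lag - t) + 1)),
    where ``A`` is the asymptotic log fold-increase (nat log), ``mu_max``
    the maximum specific growth rate (1/min, the maximum slope of log-OD)
    and ``lag`` the lag time (min).
    """
    if A <= 0 or mu_max <= 0:
        raise ValueError("A and mu_max must be positive")
    return _gompertz_y(np.asarray(t, dtype=float), A, mu_max, lag)


def gompertz_od(t, od0: float, capacity: float, mu_max: float, lag: float):
    """OD830 along a Gompertz curve from inoculum ``od0`` toward ``capacity``."""
    A = math.log(capacity / od0)
    return od0 * np.exp(gompertz_log_od(t, A, mu_max, lag))


def simulate_growth_assay(
    strains: dict[str, StrainParams],
    temperature: int,
    n_replicates: int = 3,
    seed: int | np.random.Generator = 0,
    *,
    duration_min: float = 2500.0,
    sample_interval: float = SAMPLE_INTERVAL_MIN,
    inoculum_od: float = 0.0025,
    od_floor: float = 1e-4,
) -> pd.DataFrame:
    """Generate replicate growth curves for each strain at one temperature.

    Returns a tidy frame with columns ``strain_id, replicate, time_min,
    od830, temperature_C``.  Replicates differ only by measurement noise
    (``od_noise_sd`` of each strain).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + 1e-9, sample_interval)
    frames = []
    for sid, strain in strains.items():
        phase = strain.phase(temperature)
        od_true = gompertz_od(t, inoculum_od, phase.capacity, phase.mu_max, phase.lag)
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, strain.od_noise_sd, size=t.shape) if strain.od_noise_sd else 0.0
            frames.append(
                pd.DataFrame(
                    {
                        "strain_id": sid,
                        "replicate": rep,
                        "time_min": t,
                        "od830": np.maximum(od_true + noise, od_floor),
                        "temperature_C": temperature,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
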