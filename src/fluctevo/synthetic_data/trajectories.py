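"""Serial-passage batch-culture simulator under fluctuating temperatures.

The simulator emulates a bioreactor experiment in which *E. coli* cultures
grow in batch while the incubation temperature alternates between 15 and
43 degC according to one of three regimes:

``slow``
    one switch per cycle, triggered when the culture density crosses
    OD830 = 0.25;
``fast``
    three switches per cycle, at OD830 = 0.15, 0.30 and 0.45;
``random``
    switches after a uniformly drawn residence time, 3-5 h at 43 degC and
    5-15 h at 15 degC, independent of density.

Within a temperature segment the culture follows a Zwietering-form modified
Gompertz law in log-OD, so that ``mu_max`` is the maximum derivative of
log(OD) (a specific growth rate in 1/min).  At each temperature switch the
curve is re-anchored: the culture continues along the new temperature's
Gompertz curve from its current density, so OD is continuous.  A cycle ends
"just before stationary phase", operationalised as the noiseless OD reaching
a fixed fraction (default 95%) of the active temperature's carrying
capacity, at which point the culture is diluted into fresh medium
(100 uL into 20 mL, a factor of 201) and a new cycle begins at the
temperature the previous cycle ended at.

Samples are taken on a fixed 4-minute grid with additive Gaussian
measurement noise; switch and transfer events are recorded at the exact
(continuous) trigger times of the noiseless curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TemperaturePhase",
    "StrainParams",
    "TemperatureRegime",
    "Segment",
    "ODTrajectory",
    "GenerationLedger",
    "SLOW",
    "FAST",
    "RANDOM",
    "simulate_cycle",
    "simulate_experiment",
    "count_generations",
    "transmittance_to_od",
    "default_strain",
    "default_design",
    "DILUTION_FACTOR",
]

#: culture-volume dilution at transfer: 100 uL into 20 mL -> (20 + 0.1) / 0.1
DILUTION_FACTOR = 201.0

SAMPLE_INTERVAL_MIN = 4.0


class ConfigurationError(ValueError):
    """Raised when strain/regime parameters cannot produce a valid cycle."""


@dataclass(frozen=True)
class TemperaturePhase:
    """Gompertz growth parameters of one strain at one temperature."""

    mu_max: float  # maximum specific growth rate, 1/min
    lag: float  # lag time, min
    capacity: float  # asymptotic OD830

    def __post_init__(self) -> None:
        if not (self.mu_max > 0 and math.isfinite(self.mu_max)):
            raise ConfigurationError(f"mu_max must be positive, got {self.mu_max}")
        if self.lag < 0:
            raise ConfigurationError(f"lag must be >= 0, got {self.lag}")
        if not (self.capacity > 0):
            raise ConfigurationError(f"capacity must be positive, got {self.capacity}")


@dataclass(frozen=True)
class StrainParams:
    """Per-temperature growth parameters of a strain.

    ``carryover_modifier`` optionally rescales ``mu_max`` at a temperature
    conditional on the temperature of the *previous* segment, e.g.
    ``{(15, 15): 0.6}`` models a strain whose growth at 15 degC is impaired
    unless the preceding segment was spent at 43 degC (an "internalised"
    fluctuation regime).
    """

    strain_id: str
    phases: dict[int, TemperaturePhase]
    od_noise_sd: float = 0.0
    carryover_modifier: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.od_noise_sd < 0:
            raise ConfigurationError("od_noise_sd must be >= 0")
        for key, factor in self.carryover_modifier.items():
            if factor <= 0:
                raise ConfigurationError(f"carryover modifier {key} must be > 0")

    def phase(self, temperature: int) -> TemperaturePhase:
        try:
            return self.phases[int(temperature)]
        except KeyError:
            raise ConfigurationError(
                f"strain {self.strain_id} has no parameters at {temperature} degC"
            ) from None

    def effective_mu(self, temperature: int, previous_temperature: int | None) -> float:
        mu = self.phase(temperature).mu_max
        if previous_temperature is not None:
            mu *= self.carryover_modifier.get((int(temperature), int(previous_temperature)), 1.0)
        return mu


@dataclass(frozen=True)
class TemperatureRegime:
    """A temperature switching rule.

    ``switch_ods`` drives the density-triggered (periodic) regimes;
    ``random_durations`` maps temperature to uniform residence-time bounds
    in minutes for the random regime.
    """

    kind: str  # "slow" | "fast" | "random"
    switch_ods: tuple[float, ...] = ()
    random_durations: dict[int, tuple[float, float]] = field(default_factory=dict)
    start_temp_alternation: bool = True
    temperatures: tuple[int, int] = (15, 43)

    def __post_init__(self) -> None:
        if self.kind not in {"slow", "fast", "random"}:
            raise ConfigurationError(f"unknown regime kind {self.kind!r}")
        if self.switch_ods:
            ods = np.asarray(self.switch_ods, dtype=float)
            if not np.all(np.diff(ods) > 0):
                raise ConfigurationError("switch_ods must be strictly increasing")
            if np.any(ods <= 0):
                raise ConfigurationError("switch_ods must be positive")
        for temp, (lo, hi) in self.random_durations.items():
            if not (0 < lo < hi):
                raise ConfigurationError(
                    f"random duration bounds at {temp} degC must satisfy 0 < lower < upper"
                )

    def other_temperature(self, temperature: int) -> int:
        a, b = self.temperatures
        return b if int(temperature) == a else a


#: slow periodic regime: one switch per cycle at OD830 = 0.25
SLOW = TemperatureRegime(kind="slow", switch_ods=(0.25,))
#: fast periodic regime: three switches per cycle at OD830 = 0.15, 0.30, 0.45
FAST = TemperatureRegime(kind="fast", switch_ods=(0.15, 0.30, 0.45))
#: random regime: uniform residence times, 3-5 h at 43 degC and 5-15 h at 15 degC
RANDOM = TemperatureRegime(
    kind="random",
    random_durations={43: (3 * 60.0, 5 * 60.0), 15: (5 * 60.0, 15 * 60.0)},
)


@dataclass(frozen=True)
class Segment:
    """One constant-temperature stretch of a cycle (noiseless book-keeping)."""

    cycle: int
    temperature: int
    t_start: float
    t_end: float
    od_start: float
    od_end: float


@dataclass
class ODTrajectory:
    """Time-stamped OD830 trace of one culture with its event history."""

    culture_id: str
    time_min: np.ndarray
    od830: np.ndarray
    od_true: np.ndarray
    temperature_C: np.ndarray
    cycle: np.ndarray
    switch_events: list[float]
    transfer_events: list[float]
    segments: list[Segment]
    dilution_factor: float = DILUTION_FACTOR

    def __post_init__(self) -> None:
        if len(self.time_min) and np.any(np.diff(self.time_min) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(np.asarray(self.od830) <= 0):
            raise ValueError("od830 must be positive")

    @property
    def end_od(self) -> float:
        return self.segments[-1].od_end

    @property
    def end_temperature(self) -> int:
        return self.segments[-1].temperature

    @classmethod
    def concatenate(cls, parts: list["ODTrajectory"]) -> "ODTrajectory":
        if not parts:
            raise ValueError("nothing to concatenate")
        return cls(
            culture_id=parts[0].culture_id,
            time_min=np.concatenate([p.time_min for p in parts]),
            od830=np.concatenate([p.od830 for p in parts]),
            od_true=np.concatenate([p.od_true for p in parts]),
            temperature_C=np.concatenate([p.temperature_C for p in parts]),
            cycle=np.concatenate([p.cycle for p in parts]),
            switch_events=[t for p in parts for t in p.switch_events],
            transfer_events=[t for p in parts for t in p.transfer_events],
            segments=[s for p in parts for s in p.segments],
            dilution_factor=parts[0].dilution_factor,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table of the trajectory."""
        df = pd.DataFrame(
            {
                "culture_id": self.culture_id,
                "cycle": self.cycle,
                "time_min": self.time_min,
                "od830": self.od830,
                "temperature_C": self.temperature_C,
                "event": "",
            }
        )
        return df


# ---------------------------------------------------------------------------
# Gompertz growth law (Zwietering parameterisation, in log-OD)
# ---------------------------------------------------------------------------

_E = math.e


def _gompertz_y(u: np.ndarray | float, A: float, mu: float, lag: float):
    """log(OD/OD_ref) at curve time ``u`` for asymptote ``A`` (nat-log units)."""
    z = mu * _E / A * (lag - np.asarray(u, dtype=float)) + 1.0
    # exp overflow guard: z large -> y ~ 0
    return A * np.exp(-np.exp(np.minimum(z, 700.0)))


def _gompertz_y_inv(y: float, A: float, mu: float, lag: float) -> float:
    """Curve time at which log(OD/OD_ref) equals ``y`` (0 < y < A)."""
    if not (0.0 < y < A):
        raise ValueError(f"target log-growth {y} outside (0, {A})")
    return lag - (A / (mu * _E)) * (math.log(-math.log(y / A)) - 1.0)


# ---------------------------------------------------------------------------
# cycle simulation
# ---------------------------------------------------------------------------


def simulate_cycle(
    strain: StrainParams,
    regime: TemperatureRegime,
    start_temp: int,
    seed: int | np.random.Generator | None = 0,
    *,
    inoculum_od: float = 0.0025,
    previous_temperature: int | None = None,
    t_origin: float = 0.0,
    cycle_index: int = 0,
    stationary_fraction: float = 0.95,
    secondary_lag: float = 0.0,
    sample_interval: float = SAMPLE_INTERVAL_MIN,
    od_floor: float = 1e-4,
    dilution_factor: float = DILUTION_FACTOR,
    culture_id: str = "culture",
) -> ODTrajectory:
    """Simulate one transfer-to-transfer cycle.

    The cycle starts at ``inoculum_od`` and ``start_temp`` and ends when the
    noiseless OD reaches ``stationary_fraction`` of the active temperature's
    capacity (the transfer trigger).  Raises :class:`ConfigurationError` if
    the strain's capacity cannot reach the regime's switch thresholds before
    the transfer trigger.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if inoculum_od <= 0:
        raise ConfigurationError("inoculum OD must be positive")
    if regime.switch_ods:
        max_thr = max(regime.switch_ods)
        for temp in regime.temperatures:
            cap = strain.phase(temp).capacity
            if stationary_fraction * cap <= max_thr:
                raise ConfigurationError(
                    f"capacity {cap} at {temp} degC cannot exceed the top switch "
                    f"threshold {max_thr} before the transfer trigger "
                    f"({stationary_fraction:.0%} of capacity)"
                )
        if inoculum_od >= min(regime.switch_ods):
            raise ConfigurationError("inoculum OD is already above the first switch threshold")

    od_ref = inoculum_od  # reference OD for log-growth within the cycle
    temp = int(start_temp)
    prev_temp = previous_temperature
    thresholds = list(regime.switch_ods)
    thr_idx = 0

    t_seg = 0.0  # cycle-relative segment start
    y_cur = 0.0  # log(OD/od_ref) at segment start
    first_segment = True

    times: list[np.ndarray] = []
    ods: list[np.ndarray] = []
    temps: list[np.ndarray] = []
    switch_events: list[float] = []
    segments: list[Segment] = []
    next_sample = 0.0

    max_segments = 100_000
    for _ in range(max_segments):
        phase = strain.phase(temp)
        mu = strain.effective_mu(temp, prev_temp)
        A = math.log(phase.capacity / od_ref)
        y_stat = math.log(stationary_fraction * phase.capacity / od_ref)
        lag_here = phase.lag if first_segment else secondary_lag

        if y_cur >= min(y_stat, A - 1e-12):
            # already at/past stationary for this temperature: transfer now
            t_event, event = t_seg, "transfer"
            u_star = None
        else:
            if first_segment:
                u_star = 0.0
                curve_lag = phase.lag
            else:
                # re-anchor: continue along this temperature's curve from y_cur
                curve_lag = 0.0
                u_star = _gompertz_y_inv(max(y_cur, 1e-12), A, mu, 0.0)

            hold = 0.0 if first_segment else lag_here  # flat secondary-lag hold

            def curve(t_rel: np.ndarray):
                """log-growth at cycle time t_rel (within this segment)."""
                u = u_star + np.maximum(np.asarray(t_rel, dtype=float) - t_seg - hold, 0.0)
                return _gompertz_y(u, A, mu, curve_lag)

            def time_at(y_target: float) -> float:
                u = _gompertz_y_inv(y_target, A, mu, curve_lag)
                return t_seg + hold + (u - u_star)

            t_stat = time_at(y_stat)
            candidates: list[tuple[float, str]] = [(t_stat, "transfer")]
            if regime.kind in {"slow", "fast"} and thr_idx < len(thresholds):
                y_thr = math.log(thresholds[thr_idx] / od_ref)
                if y_thr > y_cur:
                    candidates.append((time_at(y_thr), "switch"))
                else:  # threshold already crossed during a previous segment
                    candidates.append((t_seg, "switch"))
            elif regime.kind == "random":
                lo, hi = regime.random_durations[temp]
                candidates.append((t_seg + rng.uniform(lo, hi), "switch"))
            t_event, event = min(candidates, key=lambda c: c[0])

        # sample the 4-min grid within [t_seg, t_event)
        seg_sample_times = []
        while next_sample < t_event - 1e-9:
            seg_sample_times.append(next_sample)
            next_sample += sample_interval
        seg_sample_times = np.asarray(seg_sample_times, dtype=float)
        if u_star is None:
            y_samples = np.full(seg_sample_times.shape, y_cur)
        else:
            y_samples = curve(seg_sample_times)
        times.append(seg_sample_times)
        ods.append(od_ref * np.exp(y_samples))
        temps.append(np.full(seg_sample_times.shape, temp))

        y_end = y_cur if u_star is None else float(curve(np.asarray([t_event]))[0])
        segments.append(
            Segment(
                cycle=cycle_index,
                temperature=temp,
                t_start=t_origin + t_seg,
                t_end=t_origin + t_event,
                od_start=od_ref * math.exp(y_cur),
                od_end=od_ref * math.exp(y_end),
            )
        )
        if event == "transfer":
            transfer_time = t_origin + t_event
            break
        switch_events.append(t_origin + t_event)
        if regime.kind in {"slow", "fast"}:
            thr_idx += 1
        prev_temp = temp
        temp = regime.other_temperature(temp)
        t_seg = t_event
        y_cur = y_end
        first_segment = False
    else:  # pragma: no cover
        raise RuntimeError("cycle did not reach the transfer trigger")

    time_min = np.concatenate(times) + t_origin
    od_true = np.concatenate(ods)
    temperature = np.concatenate(temps).astype(int)
    noise = rng.normal(0.0, strain.od_noise_sd, size=od_true.shape) if strain.od_noise_sd else 0.0
    od_noisy = np.maximum(od_true + noise, od_floor)

    return ODTrajectory(
        culture_id=culture_id,
        time_min=time_min,
        od830=od_noisy,
        od_true=od_true,
        temperature_C=temperature,
        cycle=np.full(time_min.shape, cycle_index, dtype=int),
        switch_events=switch_events,
        transfer_events=[transfer_time],
        segments=segments,
        dilution_factor=dilution_factor,
    )


# ---------------------------------------------------------------------------
# experiment-level simulation
# ---------------------------------------------------------------------------

REGIMES: dict[str, TemperatureRegime] = {"slow": SLOW, "fast": FAST, "random": RANDOM}
_REGIME_LETTER = {"slow": "S", "fast": "F", "random": "R"}


def default_strain(strain_id: str = "606P", od_noise_sd: float = 0.002) -> StrainParams:
    """A realistic ancestor parameter set for glucose minimal medium.

    Doubling times of roughly 50 min at 37 degC, 70 min at 43 degC and
    6 h at 15 degC, with a longer lag and slightly lower capacity in the cold.
    """
    return StrainParams(
        strain_id=strain_id,
        phases={
            15: TemperaturePhase(mu_max=0.0019, lag=300.0, capacity=0.52),
            37: TemperaturePhase(mu_max=0.0140, lag=90.0, capacity=0.58),
            43: TemperaturePhase(mu_max=0.0100, lag=120.0, capacity=0.55),
        },
        od_noise_sd=od_noise_sd,
    )


def default_design() -> dict:
    """The experiment's design block: 2 lineages x 3 regimes x 4 replicates."""
    return {
        "lineages": ["606", "607"],
        "regimes": ["slow", "fast", "random"],
        "replicates": 4,
    }


def population_id(lineage: str, regime: str, replicate: int) -> str:
    return f"{_REGIME_LETTER[regime]}{lineage}-{replicate}"


def simulate_experiment(
    design: dict | None = None,
    n_cycles: int = 3,
    seed: int = 0,
    *,
    strains: dict[str, StrainParams] | None = None,
    regimes: dict[str, TemperatureRegime] | None = None,
    initial_temperature: int = 15,
    inoculum_od: float = 0.0025,
    **cycle_kwargs,
) -> tuple[dict[str, ODTrajectory], "GenerationLedger"]:
    """Simulate the full serial-passage design.

    Returns one multi-cycle trajectory per population (``{}`` for
    ``n_cycles=0``) together with the aggregated generation ledger.  Each
    population draws from its own child random stream of ``seed``, so the
    output is deterministic and insensitive to the order in which
    populations are listed.
    """
    design = dict(default_design() if design is None else design)
    lineages = list(design["lineages"])
    regime_names = list(design["regimes"])
    replicates = int(design["replicates"])
    if not lineages or not regime_names or replicates < 1:
        raise ConfigurationError("design must contain >= 1 lineage, regime and replicate")
    regimes = dict(REGIMES if regimes is None else regimes)
    strains = strains or {lin: default_strain(f"{lin}P") for lin in lineages}

    root = np.random.SeedSequence(seed)
    pop_keys = [
        (lin, reg, rep)
        for lin in lineages
        for reg in regime_names
        for rep in range(1, replicates + 1)
    ]
    children = root.spawn(len(pop_keys))

    trajectories: dict[str, ODTrajectory] = {}
    all_segments: list[tuple[str, Segment]] = []
    n_transfers: dict[str, int] = {}
    for (lin, reg_name, rep), child in zip(pop_keys, children):
        pid = population_id(lin, reg_name, rep)
        regime = regimes[reg_name]
        rng = np.random.default_rng(child)
        parts: list[ODTrajectory] = []
        start_temp = initial_temperature
        prev_temp: int | None = None
        od0 = inoculum_od
        t_origin = 0.0
        for c in range(n_cycles):
            part = simulate_cycle(
                strains[lin],
                regime,
                start_temp,
                rng,
                inoculum_od=od0,
                previous_temperature=prev_temp,
                t_origin=t_origin,
                cycle_index=c,
                culture_id=pid,
                **cycle_kwargs,
            )
            parts.append(part)
            prev_temp = part.end_temperature
            if regime.start_temp_alternation:
                start_temp = part.end_temperature
            od0 = part.end_od / part.dilution_factor
            t_origin = part.transfer_events[-1]
        n_transfers[pid] = n_cycles
        if parts:
            traj = ODTrajectory.concatenate(parts)
            trajectories[pid] = traj
            all_segments.extend((pid, s) for s in traj.segments)

    ledger = GenerationLedger.from_segments(
        all_segments,
        dilution_factor=cycle_kwargs.get("dilution_factor", DILUTION_FACTOR),
        n_transfers=n_transfers,
    )
    return trajectories, ledger


# ---------------------------------------------------------------------------
# generation accounting
# ---------------------------------------------------------------------------


@dataclass
class GenerationLedger:
    """Doubling counts per culture, cycle and temperature segment.

    Two accountings are reported: ``od`` counts doublings from the observed
    density increase of each segment, g = log2(od_end / od_start); and
    ``dilution`` counts log2(dilution factor) per completed transfer
    (full regrowth to the pre-dilution density).  The experiment never
    states which was used, so both are carried.
    """

    segments: pd.DataFrame  # culture_id, cycle, temperature, t_start, t_end, od_start, od_end, generations
    dilution_factor: float = DILUTION_FACTOR
    n_transfers: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_segments(
        cls,
        tagged_segments: list[tuple[str, Segment]],
        dilution_factor: float = DILUTION_FACTOR,
        n_transfers: dict[str, int] | None = None,
    ) -> "GenerationLedger":
        rows = []
        for culture_id, seg in tagged_segments:
            if seg.od_start <= 0 or seg.od_end <= 0:
                raise ValueError("segment ODs must be positive")
            g = max(math.log2(seg.od_end / seg.od_start), 0.0)
            rows.append(
                {
                    "culture_id": culture_id,
                    "cycle": seg.cycle,
                    "temperature_C": seg.temperature,
                    "t_start": seg.t_start,
                    "t_end": seg.t_end,
                    "od_start": seg.od_start,
                    "od_end": seg.od_end,
                    "generations": g,
                }
            )
        cols = [
            "culture_id",
            "cycle",
            "temperature_C",
            "t_start",
            "t_end",
            "od_start",
            "od_end",
            "generations",
        ]
        df = pd.DataFrame(rows, columns=cols)
        return cls(df, dilution_factor=dilution_factor, n_transfers=dict(n_transfers or {}))

    def totals_by_temperature(self) -> pd.DataFrame:
        """Total OD-based generations per culture and temperature."""
        if self.segments.empty:
            return pd.DataFrame(columns=["culture_id", "temperature_C", "generations"])
        return (
            self.segments.groupby(["culture_id", "temperature_C"], as_index=False)["generations"]
            .sum()
        )

    def totals(self, method: str = "od") -> pd.DataFrame:
        """Total generations per culture, by OD or by dilution accounting."""
        if method == "od":
            if self.segments.empty:
                return pd.DataFrame(columns=["culture_id", "generations"])
            return self.segments.groupby("culture_id", as_index=False)["generations"].sum()
        if method == "dilution":
            g = math.log2(self.dilution_factor)
            return pd.DataFrame(
                {
                    "culture_id": list(self.n_transfers),
                    "generations": [g * n for n in self.n_transfers.values()],
                }
            )
        raise ValueError(f"unknown method {method!r}")

    @property
    def total_generations(self) -> float:
        return float(self.segments["generations"].sum())


def count_generations(trajectory: ODTrajectory) -> GenerationLedger:
    """Build a generation ledger from one culture's segment book-keeping."""
    return GenerationLedger.from_segments(
        [(trajectory.culture_id, s) for s in trajectory.segments],
        dilution_factor=trajectory.dilution_factor,
        n_transfers={trajectory.culture_id: len(trajectory.transfer_events)},
    )


# ---------------------------------------------------------------------------
# plate-reader arithmetic
# ---------------------------------------------------------------------------


def transmittance_to_od(transmittance: float):
    """Convert fractional transmittance T in (0, 1] to optical density.

    OD = -log10(T); e.g. the 95% transmittance used to standardise Biolog
    inocula corresponds to OD ~ 0.0223.
    """
    t = np.asarray(transmittance, dtype=float)
    if np.any(t <= 0) or np.any(t > 1):
        raise ValueError("transmittance must lie in (0, 1]")
    out = -np.log10(t)
    return float(out) if np.isscalar(transmittance) or out.ndim == 0 else out
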