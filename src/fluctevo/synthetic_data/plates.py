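"""Synthetic Biolog GEN III plate sets with planted restoration categories.

The generator emulates the phenotype-array arm of the experiment: every
evolved clone is assayed in technical triplicate at 15, 37 and 43 degC and
each ancestor in six technical replicates, 252 plates in all for the full
24-strain design.

Ground truth is planted in the 92-dimensional normalised feature space and
mapped back to raw wells.  Two orthonormal directions are drawn (orthogonal
to the control wells' noise, so that projected replicate noise has exactly
the per-well SD):

* ``u1`` carries the ancestral thermal plasticity: the ancestor mean at a
  stress temperature sits at ``A_s = base +/- 2 * effect * sd`` along u1
  (negative for 15 degC, positive for 43 degC), the 37 degC optimum at the
  base point;
* ``u2`` carries "novel" movement, where the ancestor shows no plasticity.

Planted categories place the evolved strain's mean along u1 relative to
A_o (the base) and A_s: restored at A_o, partially restored halfway,
over-restored half a step beyond A_o, reinforced half a step beyond A_s,
unrestored at A_s, and novel at A_s plus a plasticity-scale displacement
along u2.  Every pairwise distance the classifier must resolve is at least
``effect`` replicate-noise SDs, so recovery is governed by a single knob.

Measurement noise is added per feature well; the control and dye wells are
noiseless by default (``control_noise_sd``).  A shared control-well error
is a plate-level nuisance offset, not part of the replicate noise the
planted effect sizes are calibrated against, and keeping it out makes the
feature-space noise isotropic with exactly ``well_noise_sd`` per
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fluctevo.biolog import DEFAULT_LAYOUT, PlateLayout

__all__ = [
    "PLANTABLE_CATEGORIES",
    "SyntheticBiologConfig",
    "BiologPlateSet",
    "generate_biolog_plates",
    "default_biolog_config",
]

PLANTABLE_CATEGORIES = (
    "restored",
    "partially_restored",
    "over_restored",
    "reinforced",
    "unrestored",
    "novel",
)

#: evolved-mean offset along u1 in units of the half-displacement e, keyed by
#: category; the ancestor stressed state sits at offset 2.
_U1_OFFSET = {
    "restored": 0.0,
    "partially_restored": 1.0,
    "over_restored": -1.0,
    "reinforced": 3.0,
    "unrestored": 2.0,
    "novel": 2.0,
}


@dataclass
class SyntheticBiologConfig:
    """Design of a synthetic plate set.

    ``planted`` maps (strain_id, stress_temperature) to one of
    :data:`PLANTABLE_CATEGORIES`; strains/temperature pairs left out behave
    like ``unrestored`` (they track the ancestor's stressed state).
    ``effect_size`` is the planted half-displacement in replicate-noise SD
    units; 0 makes all plates of a temperature statistically identical.
    """

    evolved_strains: list[str]
    ancestor_strains: list[str] = field(default_factory=lambda: ["606P", "607P"])
    lineage_of: dict[str, str] = field(default_factory=dict)
    planted: dict[tuple[str, int], str] = field(default_factory=dict)
    effect_size: float = 5.0
    n_evolved_replicates: int = 3
    n_ancestor_replicates: int = 6
    well_noise_sd: float = 0.02
    control_noise_sd: float = 0.0
    temperatures: tuple[int, ...] = (15, 37, 43)
    stress_temperatures: tuple[int, ...] = (15, 43)
    optimum_temperature: int = 37
    layout: PlateLayout = field(default_factory=lambda: DEFAULT_LAYOUT)
    nc_value: float = 0.15
    pc_value: float = 1.20
    dye_value: float = 2.00
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_evolved_replicates < 2 or self.n_ancestor_replicates < 2:
            raise ValueError("replicate counts must be >= 2 (downstream tests need variance)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.well_noise_sd < 0:
            raise ValueError("well_noise_sd must be >= 0")
        for key, cat in self.planted.items():
            if cat not in PLANTABLE_CATEGORIES:
                raise ValueError(f"unknown planted category {cat!r} for {key}")
            if key[1] not in self.stress_temperatures:
                raise ValueError(f"planted key {key} is not at a stress temperature")


@dataclass
class BiologPlateSet:
    """A generated plate set: raw wells, metadata and planted ground truth."""

    plates: pd.DataFrame  # index plate_id, columns well_1..well_96
    metadata: pd.DataFrame  # index plate_id: strain_id, temperature_C, replicate, role, lineage
    truth: dict

    @property
    def n_plates(self) -> int:
        return len(self.plates)


def _signal_directions(rng: np.random.Generator, layout: PlateLayout) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal 92-dim directions with zero sum within the metabolic
    and chemical feature blocks (so control-well noise does not project)."""
    n_met = len(layout.metabolic)
    p = n_met + len(layout.chemical)
    vecs = []
    for _ in range(2):
        v = rng.standard_normal(p)
        v[:n_met] -= v[:n_met].mean()
        v[n_met:] -= v[n_met:].mean()
        for u in vecs:
            v -= (v @ u) * u
        v /= np.linalg.norm(v)
        vecs.append(v)
    return vecs[0], vecs[1]


def _features_to_wells(features: np.ndarray, cfg: SyntheticBiologConfig) -> np.ndarray:
    """Invert plate normalisation: embed a 92-feature vector into 96 wells."""
    layout = cfg.layout
    wells = np.empty(96)
    wells[layout.negative_control - 1] = cfg.nc_value
    wells[layout.positive_control - 1] = cfg.pc_value
    for w in layout.dye_wells:
        wells[w - 1] = cfg.dye_value
    n_met = len(layout.metabolic)
    wells[[w - 1 for w in layout.metabolic]] = features[:n_met] + cfg.nc_value
    wells[[w - 1 for w in layout.chemical]] = cfg.pc_value - features[n_met:]
    return wells


def generate_biolog_plates(config: SyntheticBiologConfig, seed: int | None = None) -> BiologPlateSet:
    """Generate the full synthetic plate set for a configuration.

    Reproducible under the config's (or override) seed; the returned truth
    dict records the planted categories, the signal directions and the
    noiseless feature-space means so that classifier recovery can be scored
    exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    layout = config.layout
    p = len(layout.feature_names)
    u1, u2 = _signal_directions(rng, layout)
    n_met = len(layout.metabolic)
    base = np.concatenate(
        [
            np.clip(rng.normal(0.45, 0.12, n_met), 0.05, None),
            np.clip(rng.normal(0.55, 0.12, p - n_met), 0.05, None),
        ]
    )
    e = config.effect_size * config.well_noise_sd  # planted half-displacement

    def stress_sign(temp: int) -> float:
        return -1.0 if temp < config.optimum_temperature else 1.0

    ancestor_means: dict[int, np.ndarray] = {config.optimum_temperature: base}
    for temp in config.stress_temperatures:
        ancestor_means[temp] = base + stress_sign(temp) * 2.0 * e * u1

    def evolved_mean(strain: str, temp: int) -> np.ndarray:
        if temp == config.optimum_temperature:
            return base
        cat = config.planted.get((strain, temp), "unrestored")
        s = stress_sign(temp)
        mean = base + s * _U1_OFFSET[cat] * e * u1
        if cat == "novel":
            # plasticity-scale displacement where the ancestor shows none;
            # the sign alternates across strains so the u1 and u2 sample
            # scores stay uncorrelated and PCA does not rotate the basis
            sign = 1.0 if (sum(map(ord, strain)) + temp) % 2 == 0 else -1.0
            mean = mean + sign * 2.0 * e * u2
        return mean

    plate_rows, meta_rows = [], []

    noise_sd_by_well = np.full(96, config.control_noise_sd)
    noise_sd_by_well[[w - 1 for w in layout.feature_wells]] = config.well_noise_sd

    def emit(strain: str, role: str, temp: int, n_reps: int, mean: np.ndarray) -> None:
        for rep in range(1, n_reps + 1):
            wells = _features_to_wells(mean, config)
            noisy = wells + rng.normal(0.0, 1.0, size=96) * noise_sd_by_well
            pid = f"{strain}_{temp}C_r{rep}"
            plate_rows.append(pd.Series(noisy, index=[f"well_{w}" for w in range(1, 97)], name=pid))
            meta_rows.append(
                {
                    "plate_id": pid,
                    "strain_id": strain,
                    "temperature_C": temp,
                    "replicate": rep,
                    "role": role,
                    "lineage": config.lineage_of.get(strain, strain[:3].lstrip("SFR")),
                }
            )

    for strain in config.ancestor_strains:
        for temp in config.temperatures:
            emit(strain, "ancestor", temp, config.n_ancestor_replicates, ancestor_means[temp])
    for strain in config.evolved_strains:
        for temp in config.temperatures:
            emit(strain, "evolved", temp, config.n_evolved_replicates, evolved_mean(strain, temp))

    plates = pd.DataFrame(plate_rows)
    plates.index.name = "plate_id"
    metadata = pd.DataFrame(meta_rows).set_index("plate_id")
    truth = {
        "planted": dict(config.planted),
        "u1": u1,
        "u2": u2,
        "base_features": base,
        "ancestor_means": ancestor_means,
        "half_displacement": e,
        "feature_names": list(layout.feature_names),
    }
    return BiologPlateSet(plates=plates, metadata=metadata, truth=truth)


def default_biolog_config(seed: int = 0, effect_size: float = 5.0) -> SyntheticBiologConfig:
    """The experiment's full design: 24 evolved strains in triplicate and two
    ancestors in six replicates at three temperatures (252 plates), with the
    six plantable categories cycled over strain x stress-temperature slots."""
    letters = {"slow": "S", "fast": "F", "random": "R"}
    evolved = [
        f"{letters[reg]}{lin}-{rep}"
        for lin in ("606", "607")
        for reg in ("slow", "fast", "random")
        for rep in range(1, 5)
    ]
    lineage_of = {s: ("606" if "606" in s else "607") for s in evolved}
    lineage_of.update({"606P": "606", "607P": "607"})
    planted = {}
    slot = 0
    for strain in evolved:
        for temp in (15, 43):
            planted[(strain, temp)] = PLANTABLE_CATEGORIES[slot % len(PLANTABLE_CATEGORIES)]
            slot += 1
    return SyntheticBiologConfig(
        evolved_strains=evolved,
        lineage_of=lineage_of,
        planted=planted,
        effect_size=effect_size,
        seed=seed,
    )
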