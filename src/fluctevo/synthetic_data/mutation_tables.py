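"""Synthetic mutation-call tables with planted group effects.

Emulates the structure of population/clone resequencing calls from an
evolution experiment: one record per mutation with the strain it was seen
in, the gene hit, a mutation class, and (for population samples) the
frequency of the allele in the final population.  Per-gene hit
probabilities can differ between strain groups (lineage, regime, or
lineage x regime), so that the downstream enrichment statistics can be
validated against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MUTATION_CLASSES = (
    "nonsynonymous",
    "synonymous",
    "small_indel",
    "large_deletion",
    "amplification",
    "IS_insertion",
    "intergenic",
    "nonsense",
)

PERIODIC_REGIMES = {"slow", "fast"}

__all__ = [
    "MUTATION_CLASSES",
    "SyntheticMutationConfig",
    "generate_mutation_table",
    "default_mutation_config",
]


@dataclass
class SyntheticMutationConfig:
    """Configuration of the mutation-table generator.

    ``gene_probabilities`` maps gene -> {group_key: probability}; for each
    strain the most specific matching key wins, searched in the order
    ``"lineage:regime"``, ``"lineage"``, ``"regime"``,
    ``"periodic"``/``"random"``, ``"*"``.
    ``strains`` is a frame with columns ``strain_id, lineage, regime``.
    """

    strains: pd.DataFrame
    gene_probabilities: dict[str, dict[str, float]]
    class_distribution: dict[str, float] = field(
        default_factory=lambda: {
            "nonsynonymous": 0.40,
            "synonymous": 0.05,
            "small_indel": 0.20,
            "large_deletion": 0.10,
            "amplification": 0.07,
            "IS_insertion": 0.08,
            "intergenic": 0.08,
            "nonsense": 0.02,
        }
    )
    frequency_range: tuple[float, float] = (0.10, 1.0)
    sample_kind: str = "population"
    multi_hit_rate: dict[str, float] = field(default_factory=dict)  # gene -> Poisson extra hits
    genome_size: int = 4_629_812
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gene_probabilities:
            raise ValueError("gene list must not be empty")
        for gene, rules in self.gene_probabilities.items():
            for key, p in rules.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"probability for {gene}/{key} outside [0, 1]: {p}")
        total = sum(self.class_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class distribution must sum to 1, got {total}")
        unknown = set(self.class_distribution) - set(MUTATION_CLASSES)
        if unknown:
            raise ValueError(f"unknown mutation classes: {sorted(unknown)}")
        if self.sample_kind not in {"population", "clone"}:
            raise ValueError("sample_kind must be 'population' or 'clone'")
        lo, hi = self.frequency_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("frequency_range must lie within (0, 1]")

    def probability(self, gene: str, lineage: str, regime: str) -> float:
        rules = self.gene_probabilities[gene]
        periodicity = "periodic" if regime in PERIODIC_REGIMES else "random"
        for key in (f"{lineage}:{regime}", lineage, regime, periodicity, "*"):
            if key in rules:
                return rules[key]
        return 0.0


def generate_mutation_table(
    config: SyntheticMutationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Draw a mutation-call table from the configured group probabilities.

    Returns a frame with columns ``strain_id, sample_kind, gene,
    anchor_gene, mutation_class, frequency, position``; clone samples carry
    frequency 1.  Reproducible under the config's (or the override) seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    classes = list(config.class_distribution)
    class_p = np.array([config.class_distribution[c] for c in classes])
    lo, hi = config.frequency_range
    rows = []
    for strain in config.strains.itertuples(index=False):
        for gene in config.gene_probabilities:
            p = config.probability(gene, strain.lineage, strain.regime)
            if rng.random() >= p:
                continue
            n_hits = 1 + rng.poisson(config.multi_hit_rate.get(gene, 0.0))
            for _ in range(n_hits):
                if config.sample_kind == "clone":
                    freq = 1.0
                else:
                    freq = float(rng.uniform(lo, hi))
                rows.append(
                    {
                        "strain_id": strain.strain_id,
                        "sample_kind": config.sample_kind,
                        "gene": gene,
                        "anchor_gene": gene,
                        "mutation_class": classes[int(rng.choice(len(classes), p=class_p))],
                        "frequency": freq,
                        "position": int(rng.integers(1, config.genome_size)),
                    }
                )
    columns = [
        "strain_id",
        "sample_kind",
        "gene",
        "anchor_gene",
        "mutation_class",
        "frequency",
        "position",
    ]
    return pd.DataFrame(rows, columns=columns)


def default_strain_frame() -> pd.DataFrame:
    """The 24-population design frame (2 lineages x 3 regimes x 4 replicates)."""
    letters = {"slow": "S", "fast": "F", "random": "R"}
    rows = [
        {
            "strain_id": f"{letters[reg]}{lin}-{rep}",
            "lineage": lin,
            "regime": reg,
        }
        for lin in ("606", "607")
        for reg in ("slow", "fast", "random")
        for rep in range(1, 5)
    ]
    return pd.DataFrame(rows)


def default_mutation_config(seed: int = 0) -> SyntheticMutationConfig:
    """A default gene panel whose planted group effects mirror the kind of
    lineage- and regime-specific parallelism seen in thermal-fluctuation
    evolution experiments (a termination-factor gene private to one lineage,
    a protease gene enriched in one lineage's periodic populations, a
    cold-shock helicase enriched in the random regime, plus background
    genes hit uniformly)."""
    gene_probabilities = {
        "rho": {"607": 0.92, "606": 0.0},
        "nadR": {"607": 0.75, "606": 0.2},
        "lon": {"606:slow": 1.0, "606:fast": 1.0, "606": 0.6, "607": 0.5},
        "deaD": {"random": 0.6, "periodic": 0.08},
        "rpsE": {"periodic": 0.5, "random": 0.1},
        "groEL-ES": {"periodic": 0.25, "random": 0.0},
        "mrdA": {"random": 0.5, "periodic": 0.15},
        "ycjW": {"periodic": 0.3, "random": 0.1},
        "nusA": {"607": 0.3, "606": 0.0},
        "thiC": {"*": 0.2},
        "spoT": {"*": 0.2},
        "cspA": {"607": 0.2, "606": 0.05},
    }
    return SyntheticMutationConfig(
        strains=default_strain_frame(),
        gene_probabilities=gene_probabilities,
        multi_hit_rate={"lon": 0.5},
        seed=seed,
    )
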