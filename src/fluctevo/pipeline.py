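"""End-to-end orchestration: simulate -> growth -> mutations -> biolog.

The pipeline runs the four analysis stages in dependency order on synthetic
data with known ground truth (or on user tables where supplied), manages
one top-level seed fanned out to reproducible per-stage streams, and emits
a consolidated report: per-stage TSV tables plus a JSON/plain-text summary
recording every statistical decision taken (test, sidedness, correction,
alpha) so a run is self-documenting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fluctevo import biolog as bl
from fluctevo import growth as gr
from fluctevo import io as fio
from fluctevo import mutations as mu
from fluctevo import synthetic_data as syn

__all__ = [
    "PipelineConfig",
    "RunReport",
    "PipelineStageError",
    "run_pipeline",
    "validate_inputs",
    "stage_seed",
]

STAGES = ("simulate", "growth", "mutations", "biolog")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (stage-name CRC folded into the
    top-level seed), kept below 2**31."""
    return (int(seed) ^ (zlib.crc32(stage.encode()) & 0x7FFFFFFF)) % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    alpha: float = 0.05
    out_dir: str | Path | None = None
    lineages: tuple[str, ...] = ("606", "607")
    regimes: tuple[str, ...] = ("slow", "fast", "random")
    replicates: int = 4
    n_cycles: int = 2
    growth_replicates: int = 3
    biolog_effect_size: float = 5.0
    n_components: int | str = 3
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir) if self.out_dir else None
        return d


@dataclass
class RunReport:
    config: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    decisions: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def content_hash(self) -> str:
        digest = hashlib.sha256()
        digest.update(json.dumps(self.config, sort_keys=True).encode())
        for name in sorted(self.tables):
            digest.update(name.encode())
            digest.update(self.tables[name].to_csv(index=False).encode())
        return digest.hexdigest()

    def summary(self) -> dict:
        out = {
            "config": self.config,
            "content_hash": self.content_hash,
            "decisions": self.decisions,
            "warnings": self.warnings,
            "tables": {k: len(v) for k, v in self.tables.items()},
        }
        if "strategy_calls" in self.tables:
            out["strategy_counts"] = (
                self.tables["strategy_calls"]["category"].value_counts().to_dict()
            )
        if "restoration_headline" in self.tables:
            out["restoration_counts"] = (
                self.tables["restoration_headline"]["headline"].value_counts().to_dict()
            )
        return out

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            fio.write_tsv(table, out / f"{name}.tsv")
        (out / "report.json").write_text(json.dumps(self.summary(), indent=2, default=str))
        lines = ["fluctevo run report", "===================", ""]
        lines += [f"seed: {self.config['seed']}", f"content hash: {self.content_hash}", ""]
        lines += ["statistical decisions:"] + [f"  - {d}" for d in self.decisions]
        if self.warnings:
            lines += ["", "warnings:"] + [f"  - {w}" for w in self.warnings]
        (out / "report.txt").write_text("\n".join(lines) + "\n")
        return out


# ---------------------------------------------------------------------------
# synthetic strain effects for the growth stage
# ---------------------------------------------------------------------------

#: relative growth-rate multipliers (15 degC, 43 degC) drawn per regime;
#: periodic regimes lean generalist, the random regime leans 43-specialist
_REGIME_EFFECTS = {
    "slow": {"p_generalist": 0.7, "gain_15": (1.15, 1.35), "gain_43": (1.30, 1.50)},
    "fast": {"p_generalist": 0.7, "gain_15": (1.15, 1.35), "gain_43": (1.30, 1.50)},
    "random": {"p_generalist": 0.1, "gain_15": (0.95, 1.05), "gain_43": (1.30, 1.50)},
}


def _evolved_strains(config: PipelineConfig, rng: np.random.Generator):
    """Evolved strain parameter sets with ground-truth effect multipliers."""
    strains = {}
    truth = {}
    for lin in config.lineages:
        base = syn.default_strain(f"{lin}P")
        for reg in config.regimes:
            eff = _REGIME_EFFECTS[reg]
            for rep in range(1, config.replicates + 1):
                sid = syn.trajectories.population_id(lin, reg, rep)
                generalist = rng.random() < eff["p_generalist"]
                adapted = rng.random() < 0.85  # a few strains stay unadapted
                g15 = rng.uniform(*eff["gain_15"]) if (generalist and adapted) else 1.0
                g43 = rng.uniform(*eff["gain_43"]) if adapted else 1.0
                phases = {
                    t: syn.TemperaturePhase(
                        mu_max=p.mu_max * (g15 if t == 15 else g43 if t == 43 else 1.0),
                        lag=p.lag,
                        capacity=p.capacity,
                    )
                    for t, p in base.phases.items()
                }
                strains[sid] = syn.StrainParams(sid, phases, od_noise_sd=base.od_noise_sd)
                truth[sid] = {"gain_15": g15, "gain_43": g43}
    return strains, truth


def _growth_stage(config: PipelineConfig, report: RunReport) -> pd.DataFrame:
    rng = np.random.default_rng(stage_seed(config.seed, "growth"))
    ancestors = {f"{lin}P": syn.default_strain(f"{lin}P") for lin in config.lineages}
    evolved, truth = _evolved_strains(config, rng)
    calls = []
    rate_frames = []
    per_temp_rates: dict[int, pd.DataFrame] = {}
    for temp in (15, 43):
        assay = syn.simulate_growth_assay(
            {**ancestors, **evolved}, temp, n_replicates=config.growth_replicates, seed=rng
        )
        rates = gr.estimate_replicate_rates(assay)
        per_temp_rates[temp] = rates
        rate_frames.append(rates)
    results: dict[str, dict[int, gr.RelativeGrowthResult]] = {}
    for temp, rates in per_temp_rates.items():
        pool = [g["mu_max"].to_numpy() for _, g in rates.groupby("strain_id")]
        for lin in config.lineages:
            anc = rates.loc[rates.strain_id == f"{lin}P", "mu_max"].to_numpy()
            for sid in evolved:
                if not sid[1:].startswith(lin):
                    continue
                evo = rates.loc[rates.strain_id == sid, "mu_max"].to_numpy()
                res = gr.relative_growth_test(
                    evo, anc, pool, strain_id=sid, temperature_C=temp
                )
                results.setdefault(sid, {})[temp] = res
    for sid, by_temp in results.items():
        calls.append(gr.classify_strategy(by_temp[15], by_temp[43], alpha=config.alpha))
    table = gr.strategy_table(calls)
    table["regime"] = [
        {"S": "slow", "F": "fast", "R": "random"}[s[0]] for s in table["strain_id"]
    ]
    table["lineage"] = [s[1:4] for s in table["strain_id"]]
    table["true_gain_15"] = [truth[s]["gain_15"] for s in table["strain_id"]]
    table["true_gain_43"] = [truth[s]["gain_43"] for s in table["strain_id"]]
    report.tables["growth_rates"] = pd.concat(rate_frames, ignore_index=True)
    report.decisions.append(
        f"growth: spline mu_max (CV-selected smoothing), two-sided pooled t across all "
        f"strain groups per temperature, alpha={config.alpha}; generalist requires "
        f"significant increase at both 15 and 43 degC"
    )
    # regime-level contrasts on the classification
    periodic = table["regime"].isin(["slow", "fast"])
    contingency = [
        [int((table.loc[periodic, "category"] == "generalist").sum()),
         int((table.loc[periodic, "category"] != "generalist").sum())],
        [int((table.loc[~periodic, "category"] == "generalist").sum()),
         int((table.loc[~periodic, "category"] != "generalist").sum())],
    ]
    enrichment_p = gr.fisher_strategy_enrichment(contingency)
    f_p = {}
    for temp, col in ((15, "ratio_15"), (43, "ratio_43")):
        f_stat, p = gr.variance_ratio_test(
            table.loc[periodic, col], table.loc[~periodic, col]
        )
        f_p[temp] = {"F": f_stat, "p": p}
    report.tables["strategy_group_tests"] = pd.DataFrame(
        [
            {"test": "fisher_generalist_periodic_vs_random", "statistic": np.nan, "p_value": enrichment_p},
            {"test": "variance_ratio_15C_periodic_vs_random", "statistic": f_p[15]["F"], "p_value": f_p[15]["p"]},
            {"test": "variance_ratio_43C_periodic_vs_random", "statistic": f_p[43]["F"], "p_value": f_p[43]["p"]},
        ]
    )
    report.decisions.append(
        "growth: generalist enrichment periodic-vs-random by two-sided Fisher exact; "
        "relative-growth variance by two-sided F test"
    )
    return table


def _mutations_stage(config: PipelineConfig, report: RunReport, strategy: pd.DataFrame | None):
    cfg = syn.default_mutation_config(seed=stage_seed(config.seed, "mutations"))
    records = syn.generate_mutation_table(cfg)
    records = mu.filter_by_frequency(records, 0.05)
    meta = cfg.strains.set_index("strain_id")
    meta["periodicity"] = np.where(meta["regime"].isin(["slow", "fast"]), "periodic", "random")
    if strategy is not None:
        meta = meta.join(strategy.set_index("strain_id")["category"].rename("strategy"))
    matrix = mu.collapse_to_gene(records, strain_meta=meta)
    report.tables["mutation_calls"] = records
    report.tables["incidence"] = matrix.incidence.reset_index()
    enr_lineage = mu.z_enrichment(matrix, meta["lineage"])
    enr_lineage.insert(0, "grouping", "lineage")
    enr_regime = mu.z_enrichment(matrix, meta["periodicity"])
    enr_regime.insert(0, "grouping", "periodicity")
    report.tables["enrichment"] = pd.concat([enr_lineage, enr_regime], ignore_index=True)
    report.decisions.append(
        "mutations: 5% population-frequency filter; gene-level collapse (anchor gene for "
        "multi-gene events); two-sided pooled two-proportion z for genes mutated in >= 3 "
        "strains, BH FDR across tested genes"
    )
    class_counts = mu.counts_by_class(records, strains=meta.index)
    rows = []
    for mclass, grouping, alt in (
        ("large_deletion", "lineage", "greater"),
        ("small_indel", "periodicity", "greater"),
    ):
        res = mu.class_count_compare(class_counts[mclass], meta[grouping], alternative=alt)
        rows.append(
            {
                "mutation_class": mclass,
                "grouping": grouping,
                "alternative": alt,
                "U": res.U,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    if strategy is not None and "strategy" in meta:
        gen = (meta["strategy"] == "generalist").map({True: "generalist", False: "other"})
        if gen.nunique() == 2 and gen.value_counts().min() >= 3:
            res = mu.class_count_compare(class_counts["small_indel"], gen, alternative="greater")
            rows.append(
                {
                    "mutation_class": "small_indel",
                    "grouping": "strategy",
                    "alternative": "greater",
                    "U": res.U,
                    "p_value": res.p_value,
                    "method": res.method,
                }
            )
    else:
        report.warnings.append(
            "mutations: strategy-grouped comparisons skipped (growth stage disabled)"
        )
    report.tables["class_comparisons"] = pd.DataFrame(rows)
    report.decisions.append(
        "mutations: per-class strain counts compared by one-sided Mann-Whitney U "
        "(exact enumeration at combined n <= 20)"
    )
    return matrix


def _biolog_stage(config: PipelineConfig, report: RunReport, strategy: pd.DataFrame | None):
    cfg = syn.default_biolog_config(
        seed=stage_seed(config.seed, "biolog"), effect_size=config.biolog_effect_size
    )
    plates = syn.generate_biolog_plates(cfg)
    feats = bl.normalize_plates(plates.plates)
    model = bl.fit_pca(feats, n_components=config.n_components)
    meta = plates.metadata
    anc_idx = meta.index[meta["role"] == "ancestor"]
    evo_idx = meta.index[meta["role"] == "evolved"]
    centroids = bl.ancestor_centroids(
        model, model.scores.loc[anc_idx], meta.loc[anc_idx], group_col="lineage"
    )
    group_of = pd.Series(
        {s: cfg.lineage_of.get(s, "606") for s in meta["strain_id"].unique()}
    )
    calls = bl.classify_restoration(
        model.scores.loc[evo_idx],
        meta.loc[evo_idx],
        centroids,
        alpha=config.alpha,
        group_of=group_of,
    )
    headline = bl.headline_calls(calls)
    clustering = bl.cluster_samples(feats)
    report.tables["pca_scores"] = model.scores.reset_index(names="plate_id")
    report.tables["restoration_calls"] = calls
    report.tables["restoration_headline"] = headline
    grouping = None
    if strategy is not None:
        s = strategy.set_index("strain_id")["category"]
        grouping = (s == "generalist").map({True: "generalist", False: "other"})
    group_tests = bl.restoration_group_tests(calls, grouping)
    report.tables["restoration_group_tests"] = group_tests
    report.tables["dendrogram"] = pd.DataFrame({"newick": [clustering.newick]})
    report.decisions.append(
        f"biolog: plate normalisation vs controls, wells 86/94 dropped (92 features); "
        f"PCA with n_components={config.n_components!r}; restoration via pooled t-tests "
        f"with Holm FWER per strain x temperature across components, alpha={config.alpha}; "
        f"Fisher presence tests 15 vs 43 degC and one-sided Mann-Whitney group tests"
    )
    return calls


def run_pipeline(config: PipelineConfig | None = None) -> RunReport:
    """Execute the configured stages in dependency order.

    Any stage failure raises :class:`PipelineStageError` naming the stage;
    tables produced by earlier stages remain on the report (and on disk,
    with a failure marker file, when ``out_dir`` is set).
    """
    config = config or PipelineConfig()
    report = RunReport(config=config.to_dict())
    strategy: pd.DataFrame | None = None
    try:
        stage = "simulate"
        if "simulate" in config.stages:
            trajectories, ledger = syn.simulate_experiment(
                design={
                    "lineages": list(config.lineages),
                    "regimes": list(config.regimes),
                    "replicates": config.replicates,
                },
                n_cycles=config.n_cycles,
                seed=stage_seed(config.seed, "simulate"),
            )
            report.tables["trajectories"] = fio.trajectories_to_frame(trajectories)
            report.tables["events"] = fio.events_to_frame(trajectories)
            report.tables["generation_ledger"] = ledger.segments
            report.tables["generations_by_temperature"] = ledger.totals_by_temperature()
            report.decisions.append(
                "simulate: Gompertz growth in log-OD, 4-min sampling, transfer at 95% of "
                "capacity, dilution 1:201, start-temperature alternation across cycles"
            )
        stage = "growth"
        if "growth" in config.stages:
            strategy = _growth_stage(config, report)
            report.tables["strategy_calls"] = strategy
        stage = "mutations"
        if "mutations" in config.stages:
            _mutations_stage(config, report, strategy)
        stage = "biolog"
        if "biolog" in config.stages:
            _biolog_stage(config, report, strategy)
    except Exception as exc:  # noqa: BLE001 - stage contract: name the stage
        if config.out_dir:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            RunReport(config=config.to_dict(), tables=report.tables).write(out)
            (out / f"FAILED_{stage}").write_text(str(exc))
        raise PipelineStageError(stage, exc) from exc
    if config.out_dir:
        report.write(config.out_dir)
    return report


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

SCHEMAS = {
    "mutation_calls": {
        "required": ["strain_id", "sample_kind", "gene", "mutation_class", "frequency"],
        "ranges": {"frequency": (0.0, 1.0)},
    },
    "growth_assay": {
        "required": ["strain_id", "replicate", "time_min", "od830"],
        "ranges": {"od830": (0.0, np.inf)},
    },
    "plate_metadata": {
        "required": ["strain_id", "temperature_C", "replicate", "role"],
        "ranges": {},
    },
}


def validate_inputs(paths: dict[str, str | Path], schemas: dict | None = None) -> pd.DataFrame:
    """Schema-check input tables; returns all violations at once.

    ``paths`` maps a schema name (see :data:`SCHEMAS`) to a TSV/CSV path.
    The result has one row per violation (missing column, out-of-range
    value, unreadable file); an empty frame means the inputs are valid.
    """
    schemas = schemas or SCHEMAS
    issues = []
    for name, path in paths.items():
        schema = schemas.get(name)
        if schema is None:
            issues.append({"input": name, "kind": "unknown_schema", "detail": name})
            continue
        try:
            sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
            df = pd.read_csv(path, sep=sep)
        except Exception as exc:  # noqa: BLE001
            issues.append({"input": name, "kind": "unreadable", "detail": str(exc)})
            continue
        for col in schema["required"]:
            if col not in df.columns:
                issues.append({"input": name, "kind": "missing_column", "detail": col})
        for col, (lo, hi) in schema["ranges"].items():
            if col not in df.columns:
                continue
            values = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[(values < lo) | (values > hi) | values.isna()]
            for i in bad:
                issues.append(
                    {
                        "input": name,
                        "kind": "range_violation",
                        "detail": f"{col}={df[col].iloc[i]!r} at row {i} outside [{lo}, {hi}]",
                    }
                )
    return pd.DataFrame(issues, columns=["input", "kind", "detail"])
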