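"""Mutation filtering, gene collapse, enrichment and count comparisons."""

import numpy as np
import pandas as pd
import pytest

from fluctevo.mutations import (
    class_count_compare,
    collapse_to_gene,
    compare_rates,
    counts_by_category,
    counts_by_class,
    filter_by_frequency,
    per_generation_rate,
    read_genomediff,
    z_enrichment,
)
from fluctevo.synthetic_data import (
    SyntheticMutationConfig,
    default_mutation_config,
    generate_mutation_table,
)
from fluctevo.synthetic_data.mutation_tables import default_strain_frame


def records_from(rows):
    defaults = {
        "sample_kind": "population",
        "anchor_gene": None,
        "mutation_class": "nonsynonymous",
        "frequency": 1.0,
        "position": 1,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestFrequencyFilter:
    def test_boundary_kept(self):
        recs = records_from(
            [
                {"strain_id": "a", "gene": "g", "frequency": f}
                for f in (0.04, 0.05, 0.9)
            ]
        )
        out = filter_by_frequency(recs)
        assert sorted(out["frequency"]) == [0.05, 0.9]

    def test_clone_records_unaffected(self):
        recs = records_from(
            [
                {"strain_id": "a", "gene": "g", "sample_kind": "clone", "frequency": 1.0},
                {"strain_id": "a", "gene": "h", "frequency": 0.01},
            ]
        )
        out = filter_by_frequency(recs)
        assert list(out["gene"]) == ["g"]

    def test_empty_input(self):
        assert filter_by_frequency(records_from([])).empty

    def test_threshold_one_keeps_only_fixed(self):
        recs = records_from(
            [{"strain_id": "a", "gene": g, "frequency": f} for g, f in [("x", 0.99), ("y", 1.0)]]
        )
        assert list(filter_by_frequency(recs, 1.0)["gene"]) == ["y"]

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_threshold_domain(self, bad):
        with pytest.raises(ValueError):
            filter_by_frequency(records_from([]), bad)


class TestGeneCollapse:
    def test_multiple_hits_collapse_to_one_incidence_but_keep_counts(self):
        recs = records_from(
            [
                {"strain_id": "P1", "gene": "lon", "position": 10},
                {"strain_id": "P1", "gene": "lon", "position": 99},
            ]
        )
        m = collapse_to_gene(recs)
        assert m.incidence.loc["lon", "P1"] == 1
        assert m.counts.loc["lon", "P1"] == 2

    def test_multi_gene_deletion_anchored(self):
        recs = records_from(
            [
                {
                    "strain_id": "P1",
                    "gene": "cybB;hokB;mokB;ydcA;ydcI;ydcJ;trg;ydcG",
                    "anchor_gene": "cybB",
                    "mutation_class": "large_deletion",
                }
            ]
        )
        m = collapse_to_gene(recs)
        assert list(m.incidence.index) == ["cybB"]
        assert m.incidence.loc["cybB", "P1"] == 1

    def test_multi_gene_event_without_anchor_raises(self):
        recs = records_from([{"strain_id": "P1", "gene": "a;b", "anchor_gene": None}])
        with pytest.raises(ValueError, match="anchor"):
            collapse_to_gene(recs)

    def test_empty_records_with_declared_universe(self):
        m = collapse_to_gene(
            records_from([]),
            gene_universe=["rho", "lon"],
            strain_meta=pd.DataFrame(index=pd.Index(["P1"], name="strain_id")),
        )
        assert m.incidence.shape == (2, 1)
        assert (m.incidence.to_numpy() == 0).all()

    def test_invariant_to_record_order_and_duplication(self):
        rows = [
            {"strain_id": "P1", "gene": "rho"},
            {"strain_id": "P2", "gene": "lon"},
            {"strain_id": "P2", "gene": "rho"},
        ]
        a = collapse_to_gene(records_from(rows))
        b = collapse_to_gene(records_from(rows[::-1] + rows[:1]))
        assert a.incidence.equals(b.incidence)

    def test_metadata_must_cover_strains(self):
        recs = records_from([{"strain_id": "P1", "gene": "rho"}])
        meta = pd.DataFrame(index=pd.Index(["P2"], name="strain_id"))
        m = collapse_to_gene(recs, strain_meta=meta)
        # P1 not declared -> dropped from columns rather than silently added
        assert list(m.incidence.columns) == ["P2"]


class TestPerGenerationRates:
    def test_rate_arithmetic(self):
        rates = per_generation_rate(
            pd.Series({"a": 12}), pd.Series({"a": 600.0})
        )
        assert rates["a"] == pytest.approx(0.02)

    def test_equal_groups_give_null_t(self):
        rates = pd.Series({"a": 0.02, "b": 0.02, "c": 0.02, "d": 0.02})
        groups = pd.Series({"a": "x", "b": "x", "c": "y", "d": "y"})
        t, p = compare_rates(rates, groups)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_zero_generations_error(self):
        with pytest.raises(ValueError):
            per_generation_rate(pd.Series({"a": 3}), pd.Series({"a": 0.0}))

    def test_power_against_doubled_poisson_rate(self, rng):
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.poisson(10, 12) / 600.0
            b = rng.poisson(20, 12) / 600.0
            rates = pd.Series(np.concatenate([a, b]), index=[f"s{i}" for i in range(24)])
            groups = pd.Series(["x"] * 12 + ["y"] * 12, index=rates.index)
            _, p = compare_rates(rates, groups)
            rejections += p < 0.05
        assert rejections / n_sim > 0.90


class TestZEnrichment:
    @staticmethod
    def matrix_with(gene_hits):
        strains = [f"A{i}" for i in range(12)] + [f"B{i}" for i in range(12)]
        rows = []
        for gene, (k1, k2) in gene_hits.items():
            rows += [{"strain_id": f"A{i}", "gene": gene} for i in range(k1)]
            rows += [{"strain_id": f"B{i}", "gene": gene} for i in range(k2)]
        meta = pd.DataFrame(
            {"group": ["A"] * 12 + ["B"] * 12}, index=pd.Index(strains, name="strain_id")
        )
        return collapse_to_gene(records_from(rows), strain_meta=meta), meta

    def test_strong_enrichment_magnitude(self):
        m, meta = self.matrix_with({"rho": (9, 0)})
        res = z_enrichment(m, meta["group"])
        assert res.loc[0, "z_stat"] == pytest.approx(3.79, abs=0.01)
        assert res.loc[0, "p_value"] == pytest.approx(1.5e-4, rel=0.05)

    def test_equal_proportions_null(self):
        m, meta = self.matrix_with({"g": (6, 6)})
        res = z_enrichment(m, meta["group"])
        assert res.loc[0, "z_stat"] == 0.0
        assert res.loc[0, "p_value"] == 1.0

    def test_rare_genes_excluded(self):
        m, meta = self.matrix_with({"rare": (1, 1), "common": (5, 5)})
        res = z_enrichment(m, meta["group"], min_strains=3)
        assert list(res["gene"]) == ["common"]

    def test_q_not_below_p(self):
        m, meta = self.matrix_with({"a": (9, 0), "b": (5, 4), "c": (3, 3)})
        res = z_enrichment(m, meta["group"])
        assert (res["fdr_q"] >= res["p_value"] - 1e-12).all()

    def test_planted_gene_attains_smallest_q(self):
        """A gene present at 0.8 vs 0 probability should win the ranking."""
        strains = default_strain_frame()
        wins = 0
        n_seeds = 300
        for seed in range(n_seeds):
            cfg = SyntheticMutationConfig(
                strains=strains,
                gene_probabilities={
                    "planted": {"606": 0.8, "607": 0.0},
                    "bg1": {"*": 0.3},
                    "bg2": {"*": 0.3},
                    "bg3": {"*": 0.4},
                },
                seed=seed,
            )
            table = generate_mutation_table(cfg)
            meta = strains.set_index("strain_id")
            m = collapse_to_gene(table, strain_meta=meta)
            res = z_enrichment(m, meta["lineage"])
            if len(res) and res.sort_values("fdr_q").iloc[0]["gene"] == "planted":
                wins += 1
        assert wins / n_seeds >= 0.99

    def test_null_calibration_not_anticonservative(self, rng):
        """Rejection at alpha under label permutation stays at/below alpha
        (the discrete z-test is conservative, never inflated)."""
        strains = [f"s{i}" for i in range(24)]
        meta = pd.DataFrame(index=pd.Index(strains, name="strain_id"))
        rejections, tests = 0, 0
        for _ in range(400):
            hits = rng.random(24) < 0.4
            rows = [{"strain_id": s, "gene": "g"} for s, h in zip(strains, hits) if h]
            if sum(hits) < 3:
                continue
            m = collapse_to_gene(records_from(rows), strain_meta=meta)
            labels = pd.Series(rng.permutation(["x"] * 12 + ["y"] * 12), index=strains)
            res = z_enrichment(m, labels)
            rejections += int((res["p_value"] < 0.05).sum())
            tests += len(res)
        assert rejections / tests < 0.07


class TestClassCounts:
    def test_exact_small_comparison(self):
        counts = pd.Series([1, 2, 3, 4, 5, 6], index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.index)
        res = class_count_compare(counts, groups, alternative="less")
        assert res.p_value == pytest.approx(0.05)
        assert res.method == "exact"

    def test_identical_groups(self):
        counts = pd.Series([2, 2, 2, 2, 2, 2], index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.index)
        res = class_count_compare(counts, groups)
        assert res.degenerate and res.p_value == 1.0

    def test_counts_by_class_covers_zero_strains(self):
        recs = records_from([{"strain_id": "a", "gene": "g", "mutation_class": "small_indel"}])
        table = counts_by_class(recs, strains=["a", "b"])
        assert table.loc["a", "small_indel"] == 1
        assert table.loc["b"].sum() == 0

    def test_counts_by_category_multilabel(self):
        recs = records_from(
            [{"strain_id": "a", "gene": "groEL-ES", "anchor_gene": "groEL-ES"}]
        )
        cats = {"groEL-ES": {"heat_shock", "cold_shock"}}
        table = counts_by_category(recs, cats, strains=["a"])
        assert table.loc["a", "heat_shock"] == 1
        assert table.loc["a", "cold_shock"] == 1


class TestGenerator:
    def test_deterministic_under_seed(self):
        cfg = default_mutation_config(seed=3)
        assert generate_mutation_table(cfg).equals(generate_mutation_table(cfg))

    def test_certain_and_impossible_genes(self):
        strains = default_strain_frame()
        cfg = SyntheticMutationConfig(
            strains=strains,
            gene_probabilities={"g": {"606": 1.0, "607": 0.0}},
            seed=0,
        )
        table = generate_mutation_table(cfg)
        hit_strains = set(table["strain_id"])
        assert all(s.startswith(("S606", "F606", "R606")) or "606" in s for s in hit_strains)
        assert len(hit_strains) == 12

    def test_all_zero_probabilities_give_empty_table(self):
        cfg = SyntheticMutationConfig(
            strains=default_strain_frame(),
            gene_probabilities={"g": {"*": 0.0}},
            seed=0,
        )
        assert generate_mutation_table(cfg).empty

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            SyntheticMutationConfig(strains=default_strain_frame(), gene_probabilities={})

    def test_class_distribution_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SyntheticMutationConfig(
                strains=default_strain_frame(),
                gene_probabilities={"g": {"*": 0.5}},
                class_distribution={"nonsynonymous": 0.5},
            )


GD_SAMPLE = """#=GENOME_DIFF	1.0
SNP	1	10	NC_012967	100	T	gene_name=rho	snp_type=nonsynonymous	frequency=0.45
SNP	2	11	NC_012967	200	G	gene_name=yaaA	snp_type=synonymous	frequency=1.0
DEL	3	12	NC_012967	300	120	gene_name=cybB	frequency=0.8
DEL	4	13	NC_012967	400	2	gene_name=nadR	frequency=0.6
MOB	5	14	NC_012967	500	IS186	gene_name=lon	frequency=0.9
AMP	6	15	NC_012967	600	2	gene_name=groEL	frequency=0.3
RA	7	.	NC_012967	700	0	A	G
"""


class TestGenomeDiff:
    def test_mapping(self, tmp_path):
        path = tmp_path / "sample.gd"
        path.write_text(GD_SAMPLE)
        recs = read_genomediff(path, strain_id="P1")
        assert len(recs) == 6  # RA evidence line ignored
        by_gene = recs.set_index("gene")["mutation_class"]
        assert by_gene["rho"] == "nonsynonymous"
        assert by_gene["yaaA"] == "synonymous"
        assert by_gene["cybB"] == "large_deletion"
        assert by_gene["nadR"] == "small_indel"
        assert by_gene["lon"] == "IS_insertion"
        assert by_gene["groEL"] == "amplification"
        assert recs.set_index("gene").loc["rho", "frequency"] == pytest.approx(0.45)
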