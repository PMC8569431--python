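"""Plate normalisation, PCA, restoration classification and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from fluctevo.biolog import (
    COLLAPSED_MAP,
    DEFAULT_LAYOUT,
    PlateLayout,
    ancestor_centroids,
    assemble_and_center,
    broken_stick,
    classify_component,
    classify_restoration,
    cluster_samples,
    fit_pca,
    headline_calls,
    normalize_plate,
    normalize_plates,
    qc_impute,
    restoration_group_tests,
)
from fluctevo.stats import fisher_exact_2x2
from fluctevo.synthetic_data import (
    SyntheticBiologConfig,
    default_biolog_config,
    generate_biolog_plates,
)


class TestLayout:
    def test_default_partitions_96_wells(self):
        layout = DEFAULT_LAYOUT
        assert len(layout.metabolic) == 70
        assert len(layout.chemical) == 22
        assert set(layout.dye_wells) == {86, 94}
        assert len(layout.feature_names) == 92

    def test_overlapping_roles_rejected(self):
        with pytest.raises(ValueError):
            PlateLayout(negative_control=2)  # collides with metabolic wells


class TestNormalisation:
    def test_metabolic_wells_equal_to_nc_give_zero_features(self):
        wells = np.full(96, 0.2)
        wells[DEFAULT_LAYOUT.positive_control - 1] = 1.0
        vec = normalize_plate(wells)
        metabolic = vec[[n for n in vec.index if n.startswith("M")]]
        assert np.allclose(metabolic, 0.0)

    def test_any_plate_yields_92_features(self, rng):
        vec = normalize_plate(rng.uniform(0, 2, 96))
        assert vec.shape == (92,)

    def test_constant_shift_invariance(self, rng):
        wells = rng.uniform(0, 2, 96)
        assert np.allclose(normalize_plate(wells), normalize_plate(wells + 0.37))

    def test_missing_well_rejected(self):
        with pytest.raises(ValueError):
            normalize_plate(np.ones(95))
        bad = np.ones(96)
        bad[5] = np.nan
        with pytest.raises(ValueError):
            normalize_plate(bad)

    def test_wide_table_matches_single_plate(self, rng):
        wells = rng.uniform(0, 2, 96)
        wide = pd.DataFrame([wells], columns=[f"well_{w}" for w in range(1, 97)], index=["p1"])
        assert np.allclose(normalize_plates(wide).iloc[0], normalize_plate(wells))


class TestQcImpute:
    def make_replicates(self, rng, n=3):
        base = rng.uniform(0.2, 1.0, 96)
        return pd.DataFrame(
            [base + rng.normal(0, 0.01, 96) for _ in range(n)],
            index=[f"r{i}" for i in range(n)],
        )

    def test_gross_outlier_replaced_by_remaining_mean(self, rng):
        reps = self.make_replicates(rng)
        reps.iloc[0, 10] = 10 * reps.iloc[1, 10]
        corrected, flags = qc_impute(reps)
        assert flags.iloc[0, 10]
        assert corrected.iloc[0, 10] == pytest.approx(reps.iloc[1:, 10].mean())

    def test_clean_replicates_untouched(self, rng):
        reps = self.make_replicates(rng)
        corrected, flags = qc_impute(reps)
        assert not flags.to_numpy().any()
        assert np.allclose(corrected, reps)

    def test_two_replicates_impute_from_the_other(self, rng):
        reps = self.make_replicates(rng, n=2)
        reps.iloc[0, 5] = reps.iloc[1, 5] + 5.0
        corrected, flags = qc_impute(reps)
        assert flags.iloc[0, 5]
        assert corrected.iloc[0, 5] == reps.iloc[1, 5]

    def test_single_replicate_rejected(self, rng):
        with pytest.raises(ValueError):
            qc_impute(self.make_replicates(rng, n=1))


class TestCentering:
    def test_column_means_zero_and_idempotent(self, rng):
        mat = pd.DataFrame(rng.normal(1, 2, (8, 5)))
        centred, means = assemble_and_center(mat)
        assert np.allclose(centred.mean(axis=0), 0.0, atol=1e-12)
        again, _ = assemble_and_center(centred)
        assert np.allclose(again, centred)

    def test_single_sample_becomes_zero(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0]])
        centred, _ = assemble_and_center(mat)
        assert np.allclose(centred, 0.0)


class TestPCA:
    def test_broken_stick_three_parts(self):
        assert broken_stick(3) == pytest.approx([0.6111, 0.2778, 0.1111], abs=5e-5)

    def test_broken_stick_sums_to_one(self):
        assert broken_stick(92).sum() == pytest.approx(1.0)

    def test_variance_proportions_sum_to_one(self, rng):
        model = fit_pca(pd.DataFrame(rng.normal(size=(30, 8))))
        assert model.proportions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(model.eigenvalues) <= 1e-9)

    def test_auto_retains_three_planted_directions(self, rng):
        # 3 strong orthogonal directions (SNR 10) + isotropic noise in 92 dims
        basis, _ = np.linalg.qr(rng.normal(size=(92, 3)))
        scores = rng.normal(0, 10, (120, 3))
        data = scores @ basis.T + rng.normal(0, 1, (120, 92))
        model = fit_pca(pd.DataFrame(data), n_components="auto")
        assert model.n_retained == 3

    def test_requested_components_bounded_by_rank(self, rng):
        mat = pd.DataFrame(rng.normal(size=(4, 10)))  # rank 3 after centring
        with pytest.raises(ValueError):
            fit_pca(mat, n_components=5)

    def test_transform_reproduces_training_scores(self, rng):
        mat = pd.DataFrame(rng.normal(size=(20, 6)))
        model = fit_pca(mat, n_components=2)
        assert np.allclose(model.transform(mat), model.scores, atol=1e-9)


class TestCentroids:
    @staticmethod
    def model_of(rng, scores):
        frame = pd.DataFrame(scores, columns=["PC1", "PC2"])
        frame.index = [f"p{i}" for i in range(len(frame))]
        return frame

    def test_centroid_is_mean(self, rng):
        scores = self.model_of(rng, [[0.0, 0.0], [2.0, 2.0]])
        meta = pd.DataFrame({"temperature_C": [15, 15]}, index=scores.index)
        cents = ancestor_centroids(None, scores, meta, group_col=None)
        assert cents.get("pooled", 15).to_numpy() == pytest.approx([1.0, 1.0])

    def test_kmeans_k1_equals_arithmetic_mean(self, rng):
        pts = rng.normal(size=(7, 2))
        km = KMeans(n_clusters=1, n_init=1, random_state=0).fit(pts)
        assert km.cluster_centers_[0] == pytest.approx(pts.mean(axis=0))

    def test_order_invariance(self, rng):
        pts = rng.normal(size=(6, 2))
        a = self.model_of(rng, pts)
        b = self.model_of(rng, pts[::-1])
        meta = pd.DataFrame({"temperature_C": [37] * 6}, index=a.index)
        ca = ancestor_centroids(None, a, meta, group_col=None)
        cb = ancestor_centroids(None, b, meta, group_col=None)
        assert np.allclose(ca.get("pooled", 37), cb.get("pooled", 37))

    def test_single_replicate_rejected(self, rng):
        scores = self.model_of(rng, [[1.0, 1.0]])
        meta = pd.DataFrame({"temperature_C": [15]}, index=scores.index)
        with pytest.raises(ValueError):
            ancestor_centroids(None, scores, meta, group_col=None)


class TestCategoryRule:
    def test_exhaustive_and_exclusive_over_all_patterns(self):
        """Every significance pattern x geometry yields exactly one category."""
        a_s, a_o = 5.0, 0.0
        positions = {
            "between": 2.5,
            "beyond_opt": -2.0,
            "beyond_stress": 7.0,
        }
        seen = set()
        for sig_a, sig_s, sig_o in itertools.product([False, True], repeat=3):
            for _, e in positions.items():
                cat = classify_component(sig_a, sig_s, sig_o, e, a_s, a_o)
                assert cat in COLLAPSED_MAP
                seen.add(cat)
        assert seen == set(COLLAPSED_MAP)  # all seven categories reachable

    def test_named_geometries(self):
        # full significance: position decides
        assert classify_component(True, True, True, 2.5, 5.0, 0.0) == "partially_restored"
        assert classify_component(True, True, True, -1.0, 5.0, 0.0) == "over_restored"
        assert classify_component(True, True, True, 7.0, 5.0, 0.0) == "reinforced"
        # ancestor moved, strain followed to the optimum
        assert classify_component(True, True, False, 0.1, 5.0, 0.0) == "restored"
        assert classify_component(True, False, False, 5.0, 5.0, 0.0) == "unrestored"
        assert classify_component(False, True, True, 3.0, 0.1, 0.0) == "novel"
        assert classify_component(False, False, False, 0.0, 0.1, 0.0) == "uninformative"

    def test_mirror_symmetry(self):
        # flipping the sign of the component must not change the category
        for sig in itertools.product([False, True], repeat=3):
            for e in (-2.0, 2.5, 7.0):
                cat = classify_component(*sig, e, 5.0, 0.0)
                flipped = classify_component(*sig, -e, -5.0, 0.0)
                assert cat == flipped


from fluctevo.benchmarks import restoration_chain as chain
from fluctevo.benchmarks import restoration_recovered_fraction as recovered_fraction


class TestRestorationRecovery:
    def test_planted_categories_recovered_at_strong_effect(self):
        fractions = [recovered_fraction(*chain(seed)) for seed in range(12)]
        assert np.mean(fractions) >= 0.95

    def test_zero_effect_collapses_to_null_pattern(self):
        ps, model, calls = chain(seed=0, effect_size=0.0)
        assert set(calls["category"]) <= {"uninformative", "novel", "unrestored"}
        # with no planted signal almost everything is uninformative
        assert (calls["category"] == "uninformative").mean() > 0.8

    def test_recovery_degrades_toward_zero_effect(self):
        strong = np.mean([recovered_fraction(*chain(s, 5.0)) for s in range(4)])
        weak = np.mean([recovered_fraction(*chain(s, 1.0)) for s in range(4)])
        assert weak < strong

    def test_sign_flip_equivariance(self):
        ps, model, calls = chain(seed=3)
        flipped_scores = model.scores * -1.0
        meta = ps.metadata
        anc = meta.index[meta.role == "ancestor"]
        evo = meta.index[meta.role == "evolved"]
        cents = ancestor_centroids(
            model, flipped_scores.loc[anc], meta.loc[anc], group_col="lineage"
        )
        cfg_lineage = pd.Series(
            {s: ("606" if "606" in s else "607") for s in meta.strain_id.unique()}
        )
        flipped = classify_restoration(
            flipped_scores.loc[evo], meta.loc[evo], cents, group_of=cfg_lineage
        )
        key = ["strain_id", "temperature_C", "component"]
        merged = calls.merge(flipped, on=key, suffixes=("_a", "_b"))
        assert (merged["category_a"] == merged["category_b"]).all()

    def test_pca_component_one_separates_temperatures(self):
        for seed in range(5):
            ps, model, _ = chain(seed)
            pc1 = model.scores["PC1"]
            meta = ps.metadata.loc[pc1.index]
            means = pc1.groupby(meta["temperature_C"]).mean().sort_values()
            # the three temperatures order along PC1 with 37 in the middle
            assert list(means.index)[1] == 37
            # gaps are large relative to replicate noise (within strain x temp)
            rep_sd = pc1.groupby([meta["strain_id"], meta["temperature_C"]]).std().median()
            gaps = np.diff(means.to_numpy())
            assert (gaps > 3 * rep_sd).all()

    def test_headline_majority_aggregation(self):
        calls = pd.DataFrame(
            {
                "strain_id": ["s"] * 3,
                "temperature_C": [15] * 3,
                "component": ["PC1", "PC2", "PC3"],
                "category": ["restored", "partially_restored", "uninformative"],
                "collapsed": ["restorative", "restorative", "uninformative"],
            }
        )
        assert headline_calls(calls)["headline"].iloc[0] == "restorative"
        # a tie breaks toward the less restorative side
        calls.loc[1, ["category", "collapsed"]] = ["unrestored", "unrestored"]
        assert headline_calls(calls)["headline"].iloc[0] == "unrestored"


class TestGeneratorContracts:
    def test_default_design_is_252_plates(self):
        ps = generate_biolog_plates(default_biolog_config(seed=0))
        assert ps.n_plates == 252
        roles = ps.metadata["role"].value_counts()
        assert roles["evolved"] == 216 and roles["ancestor"] == 36

    def test_effect_zero_means_noise_only_differences(self):
        cfg = default_biolog_config(seed=1, effect_size=0.0)
        ps = generate_biolog_plates(cfg)
        feats = normalize_plates(ps.plates)
        meta = ps.metadata
        spread = feats.groupby(meta["temperature_C"]).mean().std(axis=0)
        within = feats.std(axis=0)
        assert (spread < within.max()).all()

    def test_zero_noise_zero_effect_plates_identical_per_temperature(self):
        cfg = default_biolog_config(seed=2, effect_size=0.0)
        cfg.well_noise_sd = 0.0
        ps = generate_biolog_plates(cfg)
        feats = normalize_plates(ps.plates)
        for _, idx in ps.metadata.groupby(["strain_id", "temperature_C"]).groups.items():
            block = feats.loc[idx]
            assert np.allclose(block, block.iloc[0])

    def test_replicate_counts_validated(self):
        with pytest.raises(ValueError):
            SyntheticBiologConfig(evolved_strains=["a"], n_evolved_replicates=1)

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            SyntheticBiologConfig(evolved_strains=["a"], effect_size=-1.0)


class TestClustering:
    def test_two_blobs_recovered_exactly(self, rng):
        a = rng.normal(0, 1, (10, 5))
        b = rng.normal(10, 1, (12, 5))
        mat = pd.DataFrame(np.vstack([a, b]), index=[f"s{i}" for i in range(22)])
        result = cluster_samples(mat)
        labels = result.cut(2)
        truth = [0] * 10 + [1] * 12
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_merge_heights_invariant_to_order(self, rng):
        mat = pd.DataFrame(rng.normal(size=(12, 4)), index=[f"s{i}" for i in range(12)])
        h1 = np.sort(cluster_samples(mat).linkage[:, 2])
        h2 = np.sort(cluster_samples(mat.iloc[::-1]).linkage[:, 2])
        assert np.allclose(h1, h2)

    def test_first_split_isolates_most_distant_group(self, rng):
        # mirrors the hot-temperature branch splitting off first
        cold = rng.normal(0, 1, (8, 6))
        opt = rng.normal(3, 1, (8, 6))
        hot = rng.normal(20, 1, (8, 6))
        mat = pd.DataFrame(
            np.vstack([cold, opt, hot]),
            index=[f"c{i}" for i in range(8)] + [f"o{i}" for i in range(8)] + [f"h{i}" for i in range(8)],
        )
        labels = cluster_samples(mat).cut(2)
        hot_labels = set(labels[[f"h{i}" for i in range(8)]])
        rest_labels = set(labels[[f"c{i}" for i in range(8)] + [f"o{i}" for i in range(8)]])
        assert len(hot_labels) == 1 and hot_labels.isdisjoint(rest_labels)

    def test_newick_is_parseable_and_complete(self, rng):
        mat = pd.DataFrame(rng.normal(size=(6, 3)), index=[f"s{i}" for i in range(6)])
        newick = cluster_samples(mat).newick
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(newick), "newick")
        assert sorted(leaf.name for leaf in tree.get_terminals()) == sorted(mat.index)

    def test_duplicate_ids_rejected(self, rng):
        mat = pd.DataFrame(rng.normal(size=(3, 3)), index=["a", "a", "b"])
        with pytest.raises(ValueError):
            cluster_samples(mat)


class TestGroupTests:
    def test_identical_distributions_give_large_one_sided_p(self):
        calls = pd.DataFrame(
            {
                "strain_id": [f"s{i}" for i in range(8)] * 2,
                "temperature_C": [15] * 8 + [43] * 8,
                "component": ["PC1"] * 16,
                "category": ["restored"] * 16,
                "collapsed": ["restorative"] * 16,
            }
        )
        grouping = pd.Series(
            ["g"] * 4 + ["o"] * 4, index=[f"s{i}" for i in range(8)]
        )
        table = restoration_group_tests(calls, grouping)
        mw = table[table["test"].str.startswith("mannwhitney")]
        assert (mw["p_value"] >= 0.5).all()

    def test_planted_generalist_excess_detected(self, rng):
        """Strains labelled generalist receive twice the restorative calls."""
        detections = 0
        n_seeds = 60
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            rows = []
            for i in range(24):
                generalist = i < 7
                n_restorative = r.binomial(6, 0.6 if generalist else 0.3)
                for c in range(6):
                    cat = "restored" if c < n_restorative else "unrestored"
                    rows.append(
                        {
                            "strain_id": f"s{i}",
                            "temperature_C": 15 if c % 2 else 43,
                            "component": f"PC{c}",
                            "category": cat,
                            "collapsed": COLLAPSED_MAP[cat],
                        }
                    )
            calls = pd.DataFrame(rows)
            grouping = pd.Series(
                ["generalist"] * 7 + ["other"] * 17, index=[f"s{i}" for i in range(24)]
            )
            table = restoration_group_tests(calls, grouping)
            p = table.loc[
                (table["category"] == "restorative")
                & table["test"].str.startswith("mannwhitney"),
                "p_value",
            ].iloc[0]
            detections += p < 0.05
        assert detections / n_seeds >= 0.80

    def test_fisher_kernel_shared_with_growth_module(self):
        from fluctevo.growth import fisher_strategy_enrichment

        table = [[3, 5], [6, 2]]
        assert fisher_strategy_enrichment(table) == fisher_exact_2x2(table)

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            restoration_group_tests(pd.DataFrame())
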