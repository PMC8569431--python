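"""Phenotype-microarray (Biolog GEN III) restoration analysis.

A GEN III plate holds 96 endpoint OD590 readings: 70 metabolic wells with a
negative-control well, 22 chemical-sensitivity wells with a positive-control
well, and two tetrazolium-dye wells (86 and 94) that are dropped.  Each
plate is normalised (metabolic well minus negative control; positive
control minus chemical well) into a 92-feature phenotype vector.  Vectors
are centred, embedded by PCA (components retained by the broken-stick
rule, with the talus drop as a cross-check), and each evolved strain's
position at a stressful temperature (15 or 43 degC) is classified per
retained component relative to two ancestral reference states: the
ancestor at the same stress temperature (A_s) and the ancestor at the
37 degC optimum (A_o).

Three FWER-corrected t-tests decide the classification: the ancestral
plasticity D_a (A_s vs A_o replicates), the evolved movement from the
stressed state D_s (evolved vs ancestor-at-stress), and the distance from
the optimum D_o (evolved vs ancestor-at-37).  The seven mutually exclusive
outcomes:

===============  =====  =====  =====  ===========================================
category         D_a    D_s    D_o    geometry of the evolved mean E
===============  =====  =====  =====  ===========================================
uninformative     ns     ns     --    (no ancestral plasticity, no movement)
novel             ns     sig    --    movement where the ancestor had none
unrestored        sig    ns     --    stayed at the stressed state
restored          sig    sig    ns    moved to the optimum state
partially_rest.   sig    sig    sig   strictly between A_s and A_o
over_restored     sig    sig    sig   beyond A_o, away from A_s
reinforced        sig    sig    sig   beyond A_s, away from A_o
===============  =====  =====  =====  ===========================================

restored / partially_restored / over_restored collapse to "restorative".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from fluctevo.stats import fisher_exact_2x2, holm_adjust, mann_whitney

__all__ = [
    "PlateLayout",
    "DEFAULT_LAYOUT",
    "normalize_plate",
    "normalize_plates",
    "qc_impute",
    "assemble_and_center",
    "broken_stick",
    "PCAModel",
    "fit_pca",
    "CentroidSet",
    "ancestor_centroids",
    "RESTORATION_CATEGORIES",
    "COLLAPSED_MAP",
    "classify_restoration",
    "classify_component",
    "headline_calls",
    "ClusteringResult",
    "cluster_samples",
    "restoration_group_tests",
]

N_WELLS = 96


@dataclass(frozen=True)
class PlateLayout:
    """Role of every well on a 96-well plate (1-based, row-major A1=1).

    The default GEN III layout places the negative control at well 1, the
    70 metabolic assays at wells 2-71, the positive control at well 72, the
    22 chemical-sensitivity assays at wells 73-96 except the two
    tetrazolium-dye wells 86 and 94.  Only the well numbers are fixed by
    the instrument report, so the layout is explicit and overridable.
    """

    negative_control: int = 1
    positive_control: int = 72
    dye_wells: tuple[int, ...] = (86, 94)
    metabolic: tuple[int, ...] = tuple(range(2, 72))
    chemical: tuple[int, ...] = tuple(w for w in range(73, 97) if w not in (86, 94))

    def __post_init__(self) -> None:
        roles = (
            [self.negative_control, self.positive_control]
            + list(self.dye_wells)
            + list(self.metabolic)
            + list(self.chemical)
        )
        if sorted(roles) != list(range(1, N_WELLS + 1)):
            raise ValueError("layout roles must partition wells 1..96")
        if len(self.metabolic) != 70 or len(self.chemical) != 22 or len(self.dye_wells) != 2:
            raise ValueError("expected 70 metabolic, 22 chemical and 2 dye wells")

    @property
    def feature_wells(self) -> tuple[int, ...]:
        return tuple(self.metabolic) + tuple(self.chemical)

    @property
    def feature_names(self) -> list[str]:
        return [f"M{w:02d}" for w in self.metabolic] + [f"C{w:02d}" for w in self.chemical]

    @classmethod
    def from_dict(cls, mapping: dict) -> "PlateLayout":
        return cls(
            negative_control=int(mapping["negative_control"]),
            positive_control=int(mapping["positive_control"]),
            dye_wells=tuple(mapping["dye_wells"]),
            metabolic=tuple(mapping["metabolic"]),
            chemical=tuple(mapping["chemical"]),
        )


DEFAULT_LAYOUT = PlateLayout()


def _well_values(plate) -> np.ndarray:
    values = np.asarray(plate, dtype=float)
    if values.shape != (N_WELLS,):
        raise ValueError(f"expected 96 well values, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("plate contains non-finite well values")
    return values


def normalize_plate(plate, layout: PlateLayout = DEFAULT_LAYOUT) -> pd.Series:
    """Normalise one plate into its 92-feature phenotype vector.

    Metabolic feature = well - negative control; chemical feature =
    positive control - well.  Controls and dye wells are dropped.  Both
    normalisations are differences, so adding a constant to every well
    leaves all 92 features unchanged.
    """
    values = _well_values(plate)
    nc = values[layout.negative_control - 1]
    pc = values[layout.positive_control - 1]
    metabolic = values[[w - 1 for w in layout.metabolic]] - nc
    chemical = pc - values[[w - 1 for w in layout.chemical]]
    return pd.Series(np.concatenate([metabolic, chemical]), index=layout.feature_names)


def normalize_plates(wide: pd.DataFrame, layout: PlateLayout = DEFAULT_LAYOUT) -> pd.DataFrame:
    """Normalise a wide plate table (rows = plates, columns well_1..well_96)."""
    cols = [f"well_{w}" for w in range(1, N_WELLS + 1)]
    missing = [c for c in cols if c not in wide.columns]
    if missing:
        raise ValueError(f"missing well columns: {missing[:3]}...")
    arr = wide[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("plates contain non-finite well values")
    nc = arr[:, layout.negative_control - 1][:, None]
    pc = arr[:, layout.positive_control - 1][:, None]
    metabolic = arr[:, [w - 1 for w in layout.metabolic]] - nc
    chemical = pc - arr[:, [w - 1 for w in layout.chemical]]
    return pd.DataFrame(
        np.hstack([metabolic, chemical]), index=wide.index, columns=layout.feature_names
    )


def qc_impute(
    replicates: pd.DataFrame,
    *,
    threshold: float = 4.0,
    sd_floor: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag and impute inconsistent well values among technical replicates.

    ``replicates`` holds the raw well values of one (strain, temperature)
    replicate set (rows = replicates, columns = wells).  A well of one
    replicate is flagged when it deviates from the mean of the *remaining*
    replicates by more than ``threshold`` times their standard deviation
    (floored at ``sd_floor`` OD units so that two nearly identical
    remaining replicates do not trigger on noise).  Flagged wells are
    replaced by the mean of the remaining replicates.

    With exactly two replicates a disagreement flags both symmetrically;
    the tie is broken by the within-replicate robust z-score (the replicate
    in which the well is also an outlier against its *own* plate loses).
    Three or more replicates all flagging one well is unresolvable and
    raises.  Returns the corrected frame and a boolean flag frame.
    """
    if len(replicates) < 2:
        raise ValueError("imputation needs >= 2 replicates")
    values = replicates.to_numpy(dtype=float)
    n = values.shape[0]
    flags = np.zeros_like(values, dtype=bool)
    for i in range(n):
        others = np.delete(values, i, axis=0)
        mean_others = others.mean(axis=0)
        sd_others = others.std(axis=0, ddof=1) if n > 2 else np.zeros(values.shape[1])
        scale = np.maximum(sd_others, sd_floor)
        flags[i] = np.abs(values[i] - mean_others) > threshold * scale
    fully_flagged = np.nonzero(flags.all(axis=0))[0]
    if fully_flagged.size:
        if n > 2:
            wells = list(replicates.columns[fully_flagged])
            raise ValueError(
                f"all replicates flagged for wells {wells}: nothing to impute from"
            )
        med = np.median(values, axis=1, keepdims=True)
        mad = np.median(np.abs(values - med), axis=1, keepdims=True)
        row_z = np.abs(values - med) / np.maximum(1.4826 * mad, 1e-9)
        for w in fully_flagged:
            keep = int(np.argmin(row_z[:, w]))
            flags[keep, w] = False
    corrected = values.copy()
    for w in range(values.shape[1]):
        good = ~flags[:, w]
        if not good.all():
            corrected[~good, w] = values[good, w].mean()
    return (
        pd.DataFrame(corrected, index=replicates.index, columns=replicates.columns),
        pd.DataFrame(flags, index=replicates.index, columns=replicates.columns),
    )


def assemble_and_center(vectors: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Column-centre a feature matrix; returns (centred, stored means)."""
    if vectors.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    means = vectors.mean(axis=0)
    return vectors - means, means


# ---------------------------------------------------------------------------
# PCA and component retention
# ---------------------------------------------------------------------------


def broken_stick(p: int) -> np.ndarray:
    """Broken-stick expected variance shares b_k = (1/p) * sum_{i=k..p} 1/i."""
    if p < 1:
        raise ValueError("p must be >= 1")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def _talus_drop(eigenvalues: np.ndarray) -> int:
    """Heuristic count of informative components from the log-eigenvalue
    "talus": the largest drop between consecutive log-eigenvalues marks the
    edge of the informative set."""
    ev = eigenvalues[eigenvalues > 1e-12]
    if ev.size < 2:
        return max(ev.size, 1)
    drops = np.diff(np.log(ev))
    return int(np.argmin(drops)) + 1  # most negative difference


@dataclass
class PCAModel:
    loadings: pd.DataFrame  # features x retained components
    scores: pd.DataFrame  # samples x retained components
    eigenvalues: np.ndarray  # full spectrum
    proportions: np.ndarray  # variance proportions, full spectrum
    broken_stick_values: np.ndarray
    n_retained: int
    talus_suggestion: int
    feature_means: pd.Series

    def transform(self, vectors: pd.DataFrame) -> pd.DataFrame:
        """Project (already plate-normalised) feature vectors onto the
        retained components using the training centring."""
        centred = vectors[self.loadings.index] - self.feature_means
        return pd.DataFrame(
            centred.to_numpy() @ self.loadings.to_numpy(),
            index=vectors.index,
            columns=self.loadings.columns,
        )


def fit_pca(matrix: pd.DataFrame, n_components: int | str = "auto") -> PCAModel:
    """PCA of the centred (unscaled) feature matrix.

    ``n_components="auto"`` retains the leading components whose variance
    proportion exceeds the broken-stick reference; when that rule and the
    talus drop heuristic disagree, the retained count defaults to 3 (capped
    by rank).  At least one component is always retained.
    """
    if len(matrix) < 3:
        raise ValueError("PCA needs at least 3 samples")
    centred, means = assemble_and_center(matrix)
    pca = PCA(n_components=None)
    scores_full = pca.fit_transform(centred.to_numpy())
    eigenvalues = pca.explained_variance_
    proportions = pca.explained_variance_ratio_
    rank = int(np.sum(eigenvalues > 1e-12))
    bstick = broken_stick(proportions.size)
    above = proportions > bstick
    k_bs = 0
    for flag in above:  # leading run only
        if not flag:
            break
        k_bs += 1
    k_bs = max(k_bs, 1)
    k_talus = _talus_drop(eigenvalues)
    if isinstance(n_components, str):
        if n_components != "auto":
            raise ValueError("n_components must be an int or 'auto'")
        k = k_bs if k_bs == k_talus else min(3, rank)
        k = max(min(k, rank), 1)
    else:
        k = int(n_components)
        if k < 1 or k > rank:
            raise ValueError(f"n_components must be in [1, rank={rank}]")
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAModel(
        loadings=pd.DataFrame(pca.components_[:k].T, index=matrix.columns, columns=comp_names),
        scores=pd.DataFrame(scores_full[:, :k], index=matrix.index, columns=comp_names),
        eigenvalues=eigenvalues,
        proportions=proportions,
        broken_stick_values=bstick,
        n_retained=k,
        talus_suggestion=k_talus,
        feature_means=means,
    )


# ---------------------------------------------------------------------------
# ancestral centroids
# ---------------------------------------------------------------------------


@dataclass
class CentroidSet:
    """Ancestor reference states on the retained components.

    ``centroids`` maps (group, temperature) -> component-coordinate Series;
    ``replicate_scores`` keeps the per-replicate scores behind each
    centroid (needed by the classification t-tests); ``dispersions`` the
    per-component replicate SDs.  With k-means at k = 1 the centroid is the
    arithmetic mean of the replicate scores.
    """

    centroids: dict[tuple[str, int], pd.Series]
    replicate_scores: dict[tuple[str, int], pd.DataFrame]
    dispersions: dict[tuple[str, int], pd.Series]

    def get(self, group: str, temperature: int) -> pd.Series:
        key = (group, int(temperature))
        if key not in self.centroids:
            raise KeyError(f"no ancestor centroid for group {group!r} at {temperature} degC")
        return self.centroids[key]

    def scores_of(self, group: str, temperature: int) -> pd.DataFrame:
        return self.replicate_scores[(group, int(temperature))]


def ancestor_centroids(
    model: PCAModel,
    ancestor_scores: pd.DataFrame,
    meta: pd.DataFrame,
    *,
    group_col: str | None = "lineage",
) -> CentroidSet:
    """Centroids of the ancestor replicate clouds per (group, temperature).

    ``ancestor_scores`` are retained-component scores of ancestor plates
    (index = plate ids), ``meta`` the matching metadata with a
    ``temperature_C`` column and optionally ``group_col`` (``None`` pools
    all ancestors).  Each centroid is the k-means (k = 1) centre, i.e. the
    arithmetic mean; single-replicate groups raise (no dispersion).
    """
    meta = meta.loc[ancestor_scores.index]
    groups = meta[group_col].astype(str) if group_col else pd.Series("pooled", index=meta.index)
    centroids, reps, disp = {}, {}, {}
    for (group, temp), idx in ancestor_scores.groupby([groups, meta["temperature_C"]]).groups.items():
        sub = ancestor_scores.loc[idx]
        if len(sub) < 2:
            raise ValueError(f"ancestor group {group!r} at {temp} degC has a single replicate")
        key = (str(group), int(temp))
        centroids[key] = sub.mean(axis=0)
        reps[key] = sub
        disp[key] = sub.std(axis=0, ddof=1)
    return CentroidSet(centroids=centroids, replicate_scores=reps, dispersions=disp)


# ---------------------------------------------------------------------------
# restoration classification
# ---------------------------------------------------------------------------

RESTORATION_CATEGORIES = (
    "restored",
    "partially_restored",
    "over_restored",
    "reinforced",
    "unrestored",
    "novel",
    "uninformative",
)

COLLAPSED_MAP = {
    "restored": "restorative",
    "partially_restored": "restorative",
    "over_restored": "restorative",
    "reinforced": "reinforced",
    "unrestored": "unrestored",
    "novel": "novel",
    "uninformative": "uninformative",
}

# tie-break order for headline aggregation: lower = "less restorative"
_CONSERVATISM_RANK = {
    "uninformative": 0,
    "unrestored": 1,
    "novel": 2,
    "reinforced": 3,
    "restorative": 4,
}


def classify_component(
    sig_a: bool,
    sig_s: bool,
    sig_o: bool,
    e_value: float,
    a_stress: float,
    a_opt: float,
) -> str:
    """Apply the seven-way decision rule on one component.

    Exactly one category fires for every significance pattern combined with
    the position of the evolved mean relative to the two ancestral states.
    """
    if not sig_a:
        return "novel" if sig_s else "uninformative"
    if not sig_s:
        return "unrestored"
    if not sig_o:
        return "restored"
    lo, hi = min(a_stress, a_opt), max(a_stress, a_opt)
    if lo < e_value < hi:
        return "partially_restored"
    towards_opt = a_opt - a_stress  # direction of restoration
    if (e_value - a_opt) * towards_opt > 0:
        return "over_restored"
    if (e_value - a_stress) * towards_opt < 0:
        return "reinforced"
    # E coincides with a centroid while both distance tests reject: the
    # tests' contracts make this impossible on real data
    raise RuntimeError(
        "inconsistent classification state: evolved mean equals an ancestral "
        "centroid but both distance tests are significant"
    )


def classify_restoration(
    evolved_scores: pd.DataFrame,
    evolved_meta: pd.DataFrame,
    centroids: CentroidSet,
    *,
    alpha: float = 0.05,
    fwer: str = "holm",
    optimum_temperature: int = 37,
    group_of: pd.Series | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Classify every evolved strain x stress temperature x component.

    ``evolved_scores`` are retained-component scores of evolved plates with
    ``evolved_meta`` providing ``strain_id`` and ``temperature_C`` per
    plate; ``group_of`` maps strain_id to the ancestor group whose
    centroids serve as reference (defaults to the single available group).
    FWER correction (Holm by default) is applied per strain x temperature
    family across the retained components' D_s and D_o tests, and per
    temperature across components for the ancestral plasticity D_a.
    Pooled-variance t-tests by default (technical replicates share the
    measurement-noise variance); ``welch=True`` drops that assumption.
    Returns one row per (strain, temperature, component).
    """
    meta = evolved_meta.loc[evolved_scores.index]
    components = list(evolved_scores.columns)
    groups_available = sorted({g for g, _ in centroids.centroids})

    def group_for(strain: str) -> str:
        if group_of is not None:
            return str(group_of[strain])
        if len(groups_available) == 1:
            return groups_available[0]
        raise ValueError("multiple ancestor groups present: provide group_of")

    # ancestral plasticity tests, FWER-corrected across components
    plasticity: dict[tuple[str, int], dict[str, bool]] = {}
    for group in groups_available:
        for temp in sorted({t for _, t in centroids.centroids if t != optimum_temperature}):
            a_s = centroids.scores_of(group, temp)
            a_o = centroids.scores_of(group, optimum_temperature)
            pvals = [
                sps.ttest_ind(a_s[c], a_o[c], equal_var=not welch).pvalue for c in components
            ]
            adj = holm_adjust(pvals, method=fwer)
            plasticity[(group, temp)] = {c: bool(q < alpha) for c, q in zip(components, adj)}

    rows = []
    for (strain, temp), idx in evolved_scores.groupby(
        [meta["strain_id"], meta["temperature_C"]]
    ).groups.items():
        temp = int(temp)
        if temp == optimum_temperature:
            continue
        sub = evolved_scores.loc[idx]
        if len(sub) < 2:
            raise ValueError(f"strain {strain} at {temp} degC has fewer than 2 replicates")
        group = group_for(str(strain))
        a_s_scores = centroids.scores_of(group, temp)
        a_o_scores = centroids.scores_of(group, optimum_temperature)
        a_s = centroids.get(group, temp)
        a_o = centroids.get(group, optimum_temperature)
        p_s = [sps.ttest_ind(sub[c], a_s_scores[c], equal_var=not welch).pvalue for c in components]
        p_o = [sps.ttest_ind(sub[c], a_o_scores[c], equal_var=not welch).pvalue for c in components]
        adj = holm_adjust(np.concatenate([p_s, p_o]), method=fwer)
        adj_s, adj_o = adj[: len(components)], adj[len(components):]
        for c, q_s, q_o in zip(components, adj_s, adj_o):
            sig_a = plasticity[(group, temp)][c]
            e_val = float(sub[c].mean())
            category = classify_component(
                sig_a, bool(q_s < alpha), bool(q_o < alpha), e_val, float(a_s[c]), float(a_o[c])
            )
            rows.append(
                {
                    "strain_id": strain,
                    "temperature_C": temp,
                    "component": c,
                    "category": category,
                    "collapsed": COLLAPSED_MAP[category],
                    "evolved_mean": e_val,
                    "ancestor_stress": float(a_s[c]),
                    "ancestor_optimum": float(a_o[c]),
                    "p_plasticity": float("nan"),
                    "p_stress_adj": float(q_s),
                    "p_optimum_adj": float(q_o),
                    "plasticity_significant": sig_a,
                }
            )
    return pd.DataFrame(rows)


def headline_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """One collapsed category per strain x temperature.

    The headline is the collapsed category of the majority of informative
    components (uninformative excluded); ties break toward the less
    restorative category.  All-uninformative strains stay uninformative.
    """
    rows = []
    for (strain, temp), grp in calls.groupby(["strain_id", "temperature_C"]):
        informative = grp.loc[grp["collapsed"] != "uninformative", "collapsed"]
        if informative.empty:
            headline = "uninformative"
        else:
            freq = informative.value_counts()
            best = freq[freq == freq.max()].index
            headline = min(best, key=lambda c: _CONSERVATISM_RANK[c])
        rows.append({"strain_id": strain, "temperature_C": int(temp), "headline": headline})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusteringResult:
    linkage: np.ndarray
    ids: list[str]
    newick: str

    def cut(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.ids, name="cluster")


def _linkage_to_newick(Z: np.ndarray, ids: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return ids[node.id]
        left, right = node.get_left(), node.get_right()
        return (
            f"({walk(left)}:{node.dist - left.dist:g},"
            f"{walk(right)}:{node.dist - right.dist:g})"
        )

    return walk(tree) + ";"


def cluster_samples(matrix: pd.DataFrame) -> ClusteringResult:
    """Ward hierarchical clustering (Euclidean) of the centred feature matrix.

    Returns the linkage, the sample order and a Newick serialisation of the
    dendrogram (branch lengths from the Ward merge heights).
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs >= 2 samples")
    if matrix.index.duplicated().any():
        dupes = list(matrix.index[matrix.index.duplicated()].unique())
        raise ValueError(f"duplicate sample ids: {dupes}")
    Z = hierarchy.linkage(matrix.to_numpy(dtype=float), method="ward", metric="euclidean")
    ids = [str(i) for i in matrix.index]
    return ClusteringResult(linkage=Z, ids=ids, newick=_linkage_to_newick(Z, ids))


# ---------------------------------------------------------------------------
# group-level restoration comparisons
# ---------------------------------------------------------------------------


def restoration_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Component-call counts per strain x temperature x collapsed category."""
    counts = (
        calls.groupby(["strain_id", "temperature_C", "collapsed"]).size().rename("count").reset_index()
    )
    cats = sorted(set(COLLAPSED_MAP.values()))
    wide = counts.pivot_table(
        index=["strain_id", "temperature_C"], columns="collapsed", values="count", fill_value=0
    ).reindex(columns=cats, fill_value=0)
    return wide.astype(int)


def restoration_group_tests(
    calls: pd.DataFrame,
    grouping: pd.Series | None = None,
    *,
    alternative: str = "greater",
    temperatures: tuple[int, int] = (15, 43),
) -> pd.DataFrame:
    """Group-level comparisons of restoration outcomes.

    For every collapsed category: a Fisher exact test of category presence
    (any component call) against the temperature the plates were grown at,
    and - when ``grouping`` maps strains to two groups - a one-sided
    Mann-Whitney U on per-strain category counts (temperatures combined).
    Returns a tidy table of tests and p-values.
    """
    if calls.empty:
        raise ValueError("no restoration calls to compare")
    counts = restoration_counts(calls)
    cats = list(counts.columns)
    rows = []
    t_lo, t_hi = temperatures
    for cat in cats:
        present = counts[cat] > 0
        by_temp = present.groupby(level="temperature_C")
        table = [
            [int(by_temp.sum().get(t, 0)), int(by_temp.count().get(t, 0) - by_temp.sum().get(t, 0))]
            for t in (t_lo, t_hi)
        ]
        rows.append(
            {
                "category": cat,
                "test": f"fisher_presence_{t_lo}C_vs_{t_hi}C",
                "statistic": float("nan"),
                "p_value": fisher_exact_2x2(table),
            }
        )
    if grouping is not None:
        per_strain = counts.groupby(level="strain_id").sum()
        groups = grouping.loc[per_strain.index]
        labels = sorted(pd.unique(groups))
        if len(labels) != 2:
            raise ValueError(f"grouping must define exactly two groups, got {labels}")
        if (groups == labels[0]).sum() == 0 or (groups == labels[1]).sum() == 0:
            raise ValueError("both groups must be non-empty")
        for cat in cats:
            a = per_strain.loc[groups == labels[0], cat].to_numpy(dtype=float)
            b = per_strain.loc[groups == labels[1], cat].to_numpy(dtype=float)
            res = mann_whitney(a, b, alternative=alternative)
            rows.append(
                {
                    "category": cat,
                    "test": f"mannwhitney_{labels[0]}_vs_{labels[1]}_{alternative}",
                    "statistic": res.U,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)
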