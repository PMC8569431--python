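"""Gene-level mutation parallelism and enrichment statistics.

Mutation-call tables (one row per predicted mutation in a sequenced
population or clone) are filtered at 5% population frequency, collapsed to
a binary gene-by-strain incidence matrix (multi-gene deletions and
amplifications count once, attributed to a designated anchor gene), and
compared across strain groups:

* per-gene two-proportion z-tests between groups, restricted to genes
  mutated in three or more strains, with Benjamini-Hochberg FDR across the
  tested genes;
* mutation counts per generation compared by two-sample t-test;
* per-class / per-functional-category mutation counts compared by one-sided
  Mann-Whitney U (exact by enumeration at the experiment's sample sizes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from fluctevo.stats import MannWhitneyResult, bh_fdr, mann_whitney, two_proportion_z

__all__ = [
    "MUTATION_CLASSES",
    "FUNCTIONAL_CATEGORIES",
    "IncidenceMatrix",
    "filter_by_frequency",
    "collapse_to_gene",
    "per_generation_rate",
    "compare_rates",
    "z_enrichment",
    "counts_by_class",
    "counts_by_category",
    "class_count_compare",
    "bh_fdr",
    "read_genomediff",
]

from fluctevo.synthetic_data.mutation_tables import MUTATION_CLASSES

FUNCTIONAL_CATEGORIES = (
    "heat_shock",
    "cold_shock",
    "heat_and_cold_shock",
    "regulatory",
    "membrane_cell_wall",
    "metabolic",
    "transporter",
    "other",
)

_MULTI_GENE_SEP = re.compile(r"[;,/]| - |–")


def filter_by_frequency(records: pd.DataFrame, min_frequency: float = 0.05) -> pd.DataFrame:
    """Drop population calls below the frequency threshold (boundary kept).

    Clone calls (frequency identically 1) pass through untouched.  The
    default 5% threshold reflects the detection floor of deep population
    sequencing.
    """
    if not (0.0 < min_frequency <= 1.0):
        raise ValueError("min_frequency must lie in (0, 1]")
    if records.empty:
        return records.copy()
    keep = (records["sample_kind"] == "clone") | (records["frequency"] >= min_frequency)
    return records.loc[keep].reset_index(drop=True)


@dataclass
class IncidenceMatrix:
    """Binary gene-by-strain incidence with per-strain hit counts.

    ``incidence`` is 0/1 (any qualifying hit in the gene), ``counts``
    preserves multiplicity (e.g. several distinct hits to one gene in one
    population).  ``strain_meta`` is indexed by strain_id and must cover
    every strain column.
    """

    incidence: pd.DataFrame
    counts: pd.DataFrame
    strain_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    categories: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.incidence.columns.equals(self.counts.columns) or not self.incidence.index.equals(
            self.counts.index
        ):
            raise ValueError("incidence and counts must share genes and strains")
        if not self.strain_meta.empty:
            missing = set(self.incidence.columns) - set(self.strain_meta.index)
            if missing:
                raise ValueError(f"strain metadata missing for: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def strains(self) -> list[str]:
        return list(self.incidence.columns)

    def category_of(self, gene: str) -> set[str]:
        return self.categories.get(gene, {"other"})


def collapse_to_gene(
    records: pd.DataFrame,
    *,
    strain_meta: pd.DataFrame | None = None,
    gene_universe=None,
    categories: dict[str, set[str]] | None = None,
) -> IncidenceMatrix:
    """Collapse mutation calls to a binary gene-by-strain incidence matrix.

    Multi-gene events (a ``gene`` field naming several genes) contribute a
    single entry attributed to their ``anchor_gene``; events without a
    resolvable anchor raise, listing the offending rows.  Repeated hits to
    one gene in one strain give incidence 1 but are preserved in ``counts``.
    ``gene_universe`` declares genes that must appear as (possibly all-zero)
    rows; ``strain_meta`` likewise declares the strain columns.
    """
    records = records.copy()
    if not records.empty:
        anchor = records.get("anchor_gene")
        if anchor is None:
            anchor = pd.Series(np.nan, index=records.index)
        anchor = anchor.where(anchor.notna() & (anchor.astype(str).str.len() > 0))
        multi = records["gene"].astype(str).str.contains(_MULTI_GENE_SEP)
        unresolved = records.loc[multi & anchor.isna()]
        if len(unresolved):
            events = unresolved[["strain_id", "gene"]].to_dict("records")
            raise ValueError(f"multi-gene events without an anchor gene: {events}")
        records["collapsed_gene"] = anchor.fillna(records["gene"])

    strains = (
        list(strain_meta.index)
        if strain_meta is not None
        else sorted(records["strain_id"].unique()) if not records.empty else []
    )
    genes = sorted(
        set(gene_universe or [])
        | (set(records["collapsed_gene"]) if not records.empty else set())
    )
    counts = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=pd.Index(strains, name="strain_id"))
    if not records.empty:
        tab = records.groupby(["collapsed_gene", "strain_id"]).size()
        for (gene, sid), n in tab.items():
            if gene in counts.index and sid in counts.columns:
                counts.loc[gene, sid] = int(n)
    incidence = (counts > 0).astype(int)
    return IncidenceMatrix(
        incidence=incidence,
        counts=counts,
        strain_meta=strain_meta if strain_meta is not None else pd.DataFrame(index=pd.Index(strains, name="strain_id")),
        categories=dict(categories or {}),
    )


def per_generation_rate(counts_per_strain: pd.Series, generations_per_strain: pd.Series) -> pd.Series:
    """Mutations per generation for each strain."""
    counts, gens = counts_per_strain.align(generations_per_strain, join="inner")
    if (gens <= 0).any():
        bad = list(gens.index[gens <= 0])
        raise ValueError(f"non-positive generation totals for: {bad}")
    return (counts / gens).rename("mutations_per_generation")


def compare_rates(rates: pd.Series, grouping: pd.Series, *, welch: bool = False):
    """Two-sample t-test of per-generation rates between two strain groups.

    Pooled-variance by default (``welch=True`` for unequal variances);
    returns ``(t, p)``.
    """
    groups = grouping.loc[rates.index]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"grouping must define exactly two groups, got {labels}")
    a = rates[groups == labels[0]].to_numpy(dtype=float)
    b = rates[groups == labels[1]].to_numpy(dtype=float)
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0  # identical degenerate groups: no evidence either way
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def z_enrichment(
    matrix: IncidenceMatrix,
    grouping: pd.Series,
    min_strains: int = 3,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-gene two-proportion z-tests between two strain groups.

    Only genes mutated in at least ``min_strains`` strains (across both
    groups) are tested; Benjamini-Hochberg q-values are computed across the
    tested genes.  Returns a frame sorted by p with columns
    ``gene, k1, n1, k2, n2, z, p_value, fdr_q``.
    """
    grouping = grouping.loc[[s for s in matrix.strains if s in grouping.index]]
    labels = sorted(pd.unique(grouping))
    if len(labels) != 2:
        raise ValueError(f"grouping must define exactly two groups, got {labels}")
    g1 = [s for s in matrix.strains if grouping.get(s) == labels[0]]
    g2 = [s for s in matrix.strains if grouping.get(s) == labels[1]]
    if not g1 or not g2:
        raise ValueError("both groups must contain at least one strain")
    rows = []
    for gene in matrix.genes:
        inc = matrix.incidence.loc[gene]
        if int(inc[g1 + g2].sum()) < min_strains:
            continue
        k1, k2 = int(inc[g1].sum()), int(inc[g2].sum())
        z, p = two_proportion_z(k1, len(g1), k2, len(g2), alternative=alternative)
        rows.append(
            {
                "gene": gene,
                "k1": k1,
                "n1": len(g1),
                "k2": k2,
                "n2": len(g2),
                "z_stat": z,
                "p_value": p,
            }
        )
    result = pd.DataFrame(rows, columns=["gene", "k1", "n1", "k2", "n2", "z_stat", "p_value"])
    if len(result):
        result["fdr_q"] = bh_fdr(result["p_value"].to_numpy())
        result = result.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        result["fdr_q"] = pd.Series(dtype=float)
    return result


def counts_by_class(records: pd.DataFrame, strains=None) -> pd.DataFrame:
    """Mutation counts per strain (rows) and mutation class (columns)."""
    strains = list(strains) if strains is not None else sorted(records["strain_id"].unique())
    table = (
        records.groupby(["strain_id", "mutation_class"]).size().unstack(fill_value=0)
        if not records.empty
        else pd.DataFrame()
    )
    table = table.reindex(index=strains, columns=list(MUTATION_CLASSES), fill_value=0)
    return table.fillna(0).astype(int)


def counts_by_category(
    records: pd.DataFrame,
    categories: dict[str, set[str]],
    strains=None,
) -> pd.DataFrame:
    """Mutation counts per strain and functional category (multi-label genes
    count toward every category they carry; unknown genes count as other)."""
    strains = list(strains) if strains is not None else sorted(records["strain_id"].unique())
    out = pd.DataFrame(0, index=pd.Index(strains, name="strain_id"), columns=list(FUNCTIONAL_CATEGORIES))
    for row in records.itertuples(index=False):
        gene = getattr(row, "anchor_gene", None) or row.gene
        for cat in categories.get(gene, categories.get(row.gene, {"other"})):
            if row.strain_id in out.index:
                out.loc[row.strain_id, cat] += 1
    return out


def class_count_compare(
    counts: pd.Series,
    grouping: pd.Series,
    alternative: str = "greater",
) -> MannWhitneyResult:
    """One-sided Mann-Whitney U comparison of per-strain mutation counts.

    ``counts`` is one column of :func:`counts_by_class` /
    :func:`counts_by_category`; ``grouping`` maps each strain to one of two
    groups (sorted label order: ``alternative="greater"`` means the first
    group tends to have more).  Exact when the combined n is at most 20.
    All-tied inputs return p = 1 with the degeneracy flag set.
    """
    groups = grouping.loc[counts.index]
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"grouping must define exactly two groups, got {labels}")
    a = counts[groups == labels[0]].to_numpy(dtype=float)
    b = counts[groups == labels[1]].to_numpy(dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 strains")
    return mann_whitney(a, b, alternative=alternative)


# ---------------------------------------------------------------------------
# GenomeDiff input dialect
# ---------------------------------------------------------------------------

_GD_CLASSES = {"SNP", "INS", "DEL", "MOB", "AMP"}
_LARGE_DELETION_MIN_BP = 50


def read_genomediff(path, strain_id: str | None = None, sample_kind: str = "population") -> pd.DataFrame:
    """Read mutation lines of a GenomeDiff (GD) file into a call table.

    Only SNP/INS/DEL/MOB/AMP entries are mapped.  SNPs take their class
    from the ``snp_type`` annotation when present; deletions of 50 bp or
    more become ``large_deletion``; MOB becomes ``IS_insertion`` and AMP
    ``amplification``.  The ``gene_name`` annotation supplies the gene and
    ``frequency`` defaults to 1 (clone-like calls).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            kind = parts[0]
            if kind not in _GD_CLASSES:
                continue
            position = int(parts[4]) if len(parts) > 4 and parts[4].isdigit() else None
            kv = {}
            for item in parts:
                if "=" in item:
                    key, _, value = item.partition("=")
                    kv[key] = value
            gene = kv.get("gene_name", kv.get("gene", "unknown"))
            freq = float(kv.get("frequency", 1.0))
            if kind == "SNP":
                mclass = {
                    "nonsynonymous": "nonsynonymous",
                    "synonymous": "synonymous",
                    "nonsense": "nonsense",
                    "intergenic": "intergenic",
                }.get(kv.get("snp_type", ""), "nonsynonymous")
            elif kind == "INS":
                mclass = "small_indel"
            elif kind == "DEL":
                size = int(parts[5]) if len(parts) > 5 and parts[5].isdigit() else 1
                mclass = "large_deletion" if size >= _LARGE_DELETION_MIN_BP else "small_indel"
            elif kind == "MOB":
                mclass = "IS_insertion"
            else:  # AMP
                mclass = "amplification"
            rows.append(
                {
                    "strain_id": strain_id or kv.get("strain", "unknown"),
                    "sample_kind": sample_kind,
                    "gene": gene,
                    "anchor_gene": gene,
                    "mutation_class": mclass,
                    "frequency": freq,
                    "position": position,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["strain_id", "sample_kind", "gene", "anchor_gene", "mutation_class", "frequency", "position"],
    )
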