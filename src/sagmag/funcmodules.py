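"""Six-step KEGG-module gene-content comparison between genome collections.

1. module completeness per genome (fraction of the module's KOs present);
2. presence call at >= 75% completeness;
3. retention of modules present in a KEGG reference genome or in >= 5% of
   the pooled SAG+MAG genomes;
4. merging of modules sharing >= 65% of their KOs (relative to the smaller
   module) into single representative categories;
5. per-genome gene counts per category, standardised by the median count in
   cultured isolate genomes;
6. per-category Games-Howell comparison of the standardised counts between
   collections (significant at p < 1e-3).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import stats_core

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ModuleDefinition:
    """A KEGG module: an identifier plus its nonempty set of KOs."""

    module_id: str
    ko_set: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ko_set:
            raise ValueError(f"module {self.module_id!r} has an empty KO set")


@dataclasses.dataclass(frozen=True)
class MergedCategory:
    """A representative category produced by overlap merging."""

    category_id: str
    member_modules: frozenset[str]
    ko_union: frozenset[str]


def modules_from_table(table: pd.DataFrame) -> list[ModuleDefinition]:
    """Build ModuleDefinitions from a (module_id, ko_id) pair table."""
    return [
        ModuleDefinition(module_id=str(mid), ko_set=frozenset(group["ko_id"]))
        for mid, group in table.groupby("module_id", sort=True)
    ]


def genome_ko_sets(annotations: pd.DataFrame) -> dict[str, frozenset[str]]:
    """genome_id -> set of assigned KOs."""
    return {
        str(gid): frozenset(group["ko_id"])
        for gid, group in annotations.groupby("genome_id", sort=True)
    }


def module_completeness(genome_kos: Iterable[str],
                        module: ModuleDefinition) -> float:
    """Fraction of the module's KOs found in the genome."""
    return len(module.ko_set & frozenset(genome_kos)) / len(module.ko_set)


def call_presence(completeness: float, threshold: float = 0.75) -> bool:
    """A module is present when it covers at least *threshold* of its KOs."""
    if not 0 <= completeness <= 1:
        raise ValueError("completeness must be in [0, 1]")
    return completeness >= threshold


def presence_matrix(
    annotations: pd.DataFrame,
    modules: Sequence[ModuleDefinition],
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Genome x module presence flags at the completeness threshold."""
    kos = genome_ko_sets(annotations)
    data = {
        m.module_id: [
            call_presence(module_completeness(kos.get(g, frozenset()), m),
                          threshold)
            for g in sorted(kos)
        ]
        for m in modules
    }
    return pd.DataFrame(data, index=sorted(kos))


def retain_modules(
    presence: pd.DataFrame,
    kegg_reference_presence: Mapping[str, bool],
    collections: Mapping[str, str],
    min_prevalence: float = 0.05,
) -> set[str]:
    """Modules kept for comparison.

    Kept iff present in at least one fully annotated KEGG reference genome,
    OR present in at least *min_prevalence* (inclusive) of the pooled
    SAG+MAG genomes.
    """
    pooled = [g for g in presence.index
              if collections.get(g) in ("SAG", "MAG")]
    if not pooled:
        raise ValueError("no SAG or MAG genomes in the presence matrix")
    frac = presence.loc[pooled].mean(axis=0)
    retained = set()
    for module_id in presence.columns:
        if kegg_reference_presence.get(module_id, False):
            retained.add(module_id)
        elif frac[module_id] >= min_prevalence:
            retained.add(module_id)
    return retained


def merge_overlapping(
    modules: Sequence[ModuleDefinition],
    overlap_threshold: float = 0.65,
    overlap: str = "min",
) -> list[MergedCategory]:
    """Merge modules sharing a large fraction of KOs into categories.

    Overlap between two modules is |A & B| / min(|A|, |B|) by default (a
    nested submodule counts as full overlap; ``overlap="jaccard"`` uses
    |A & B| / |A | B| instead).  Modules whose overlap reaches the
    threshold are connected; categories are the connected components, each
    represented by its largest-KO-set member (ties: lexicographically
    smallest module_id).
    """
    if not modules:
        raise ValueError("no modules to merge")
    if overlap not in ("min", "jaccard"):
        raise ValueError("overlap must be 'min' or 'jaccard'")
    graph = nx.Graph()
    graph.add_nodes_from(m.module_id for m in modules)
    by_id = {m.module_id: m for m in modules}
    mods = list(modules)
    for i in range(len(mods)):
        for j in range(i + 1, len(mods)):
            inter = len(mods[i].ko_set & mods[j].ko_set)
            if overlap == "min":
                denom = min(len(mods[i].ko_set), len(mods[j].ko_set))
            else:
                denom = len(mods[i].ko_set | mods[j].ko_set)
            if denom and inter / denom >= overlap_threshold:
                graph.add_edge(mods[i].module_id, mods[j].module_id)
    categories = []
    for component in nx.connected_components(graph):
        members = frozenset(component)
        representative = min(
            members, key=lambda mid: (-len(by_id[mid].ko_set), mid))
        ko_union = frozenset().union(*(by_id[m].ko_set for m in members))
        categories.append(MergedCategory(
            category_id=representative, member_modules=members,
            ko_union=ko_union))
    return sorted(categories, key=lambda c: c.category_id)


def standardized_counts(
    annotations: pd.DataFrame,
    categories: Sequence[MergedCategory],
    isolate_annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Per-genome gene counts per category, standardised by isolates.

    The raw count is the number of genes whose KO falls in the category's
    KO union (a gene counts once even when several member modules claim its
    KO).  Each count is divided by the median raw count over the isolate
    genomes; a zero isolate median falls back to the median over the
    compared genomes, and categories whose fallback median is also zero are
    dropped with a logged notice.
    """
    if isolate_annotations.empty:
        raise ValueError("no isolate genomes supplied")

    def raw_counts(ann: pd.DataFrame, cat: MergedCategory) -> pd.Series:
        hit = ann[ann["ko_id"].isin(cat.ko_union)]
        return (hit.groupby("genome_id")["gene_id"].nunique()
                .reindex(sorted(ann["genome_id"].unique()), fill_value=0))

    rows = []
    for cat in categories:
        compared = raw_counts(annotations, cat)
        isolates = raw_counts(isolate_annotations, cat)
        median = float(np.median(isolates.to_numpy()))
        if median == 0:
            median = float(np.median(compared.to_numpy()))
            if median == 0:
                logger.info("category %s dropped: zero median in isolates "
                            "and in compared genomes", cat.category_id)
                continue
            logger.info("category %s: isolate median 0, falling back to "
                        "all-genome median %.3g", cat.category_id, median)
        for genome_id, raw in compared.items():
            rows.append({
                "genome_id": genome_id,
                "category_id": cat.category_id,
                "raw_gene_count": int(raw),
                "standardized_count": float(raw) / median,
                "isolate_median": median,
            })
    return pd.DataFrame(rows)


def compare_categories(
    counts: pd.DataFrame,
    collections: Mapping[str, str],
    p_cutoff: float = 1e-3,
    conf_level: float = 0.95,
    compute_ci: bool = True,
) -> pd.DataFrame:
    """Games-Howell (k = 2) on standardised counts per category.

    Positive estimated differences mean SAG enrichment (difference is
    SAG mean minus MAG mean).  Categories with zero variance in either
    collection are reported with ``tested = False`` and never flagged.
    """
    rows = []
    for category_id, group in counts.groupby("category_id", sort=True):
        values = {"SAG": [], "MAG": []}
        for _, row in group.iterrows():
            coll = collections.get(row["genome_id"])
            if coll in values:
                values[coll].append(row["standardized_count"])
        sag = np.asarray(values["SAG"], dtype=float)
        mag = np.asarray(values["MAG"], dtype=float)
        base = {"category_id": category_id,
                "n_sag": sag.size, "n_mag": mag.size}
        if (sag.size < 2 or mag.size < 2
                or np.var(sag, ddof=1) == 0 or np.var(mag, ddof=1) == 0):
            rows.append({**base, "tested": False, "estimated_difference":
                         float(sag.mean() - mag.mean()) if sag.size and
                         mag.size else np.nan,
                         "p_value": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "significant": False})
            continue
        res = stats_core.games_howell({"SAG": sag, "MAG": mag},
                                      conf_level=conf_level,
                                      compute_ci=compute_ci)[0]
        rows.append({**base, "tested": True,
                     "estimated_difference": res.estimated_difference,
                     "p_value": res.p_value,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "significant": bool(res.p_value < p_cutoff)})
    return pd.DataFrame(rows)
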