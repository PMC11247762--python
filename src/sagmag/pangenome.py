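"""Taxonomic richness and pangenome accumulation.

Richness counts distinct gene clusters (unigenes or protein families), not
genes: a genome contributes a cluster once however many of its genes fall
in it.  The permutation accumulation curve follows the classical
species-accumulation recipe (random genome orderings, cumulative distinct
clusters); its analytic twin is the hypergeometric expectation

    E[richness at depth g] = sum_c [ 1 - C(N - n_c, g) / C(N, g) ],

with N genomes in the subset and n_c genomes carrying cluster c.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_model import RANKS, RankedTaxonomy


def richness_by_rank(
    sag_taxa: Iterable[RankedTaxonomy],
    mag_taxa: Iterable[RankedTaxonomy],
    rank: str,
) -> tuple[int, int, int]:
    """Counts of (shared, SAG-only, MAG-only) distinct labels at *rank*.

    Empty labels (unassigned) are ignored; the three counts disjointly
    partition the union of observed labels.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    sag = {t.label(rank) for t in sag_taxa} - {""}
    mag = {t.label(rank) for t in mag_taxa} - {""}
    return len(sag & mag), len(sag - mag), len(mag - sag)


def venn_counts(
    assignment: pd.DataFrame,
    collection_of: Mapping[str, str],
    member_genome: Mapping[str, str] | None = None,
) -> tuple[int, int, int]:
    """(shared, SAG-exclusive, MAG-exclusive) cluster counts.

    A cluster is shared when it holds members from both collections.
    *collection_of* maps genome_id -> collection; *member_genome* maps
    member_id -> genome_id (identity when members are genomes themselves,
    e.g. ANI dereplication clusters).
    """
    shared = sag_only = mag_only = 0
    for _, group in assignment.groupby("cluster_id", sort=False):
        colls = set()
        for member in group["member_id"]:
            genome = member_genome[member] if member_genome else member
            if genome not in collection_of:
                raise KeyError(f"member {member!r}: unknown genome {genome!r}")
            colls.add(collection_of[genome])
        has_sag = "SAG" in colls
        has_mag = "MAG" in colls
        if has_sag and has_mag:
            shared += 1
        elif has_sag:
            sag_only += 1
        elif has_mag:
            mag_only += 1
        else:
            raise ValueError("cluster without SAG or MAG members")
    return shared, sag_only, mag_only


@dataclasses.dataclass(frozen=True)
class IncidenceMatrix:
    """Cluster-by-genome presence flags plus genome collection labels."""

    presence: np.ndarray          # bool (n_clusters, n_genomes)
    cluster_ids: tuple[str, ...]
    genome_ids: tuple[str, ...]
    collection_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.presence.shape != (len(self.cluster_ids), len(self.genome_ids)):
            raise ValueError("presence shape mismatch")
        if not self.presence.any(axis=1).all():
            raise ValueError("every cluster must occur in >= 1 genome")

    @classmethod
    def from_assignment(
        cls,
        assignment: pd.DataFrame,
        member_genome: Mapping[str, str],
        collection_of: Mapping[str, str],
    ) -> "IncidenceMatrix":
        genomes = sorted({member_genome[m] for m in assignment["member_id"]})
        clusters = sorted(assignment["cluster_id"].unique())
        gidx = {g: i for i, g in enumerate(genomes)}
        cidx = {c: i for i, c in enumerate(clusters)}
        presence = np.zeros((len(clusters), len(genomes)), dtype=bool)
        for member, cluster in zip(assignment["member_id"],
                                   assignment["cluster_id"]):
            presence[cidx[cluster], gidx[member_genome[member]]] = True
        return cls(presence=presence, cluster_ids=tuple(clusters),
                   genome_ids=tuple(genomes), collection_of=collection_of)

    def subset_columns(self, subset: str) -> np.ndarray:
        if subset == "all":
            cols = np.arange(len(self.genome_ids))
        else:
            cols = np.array([i for i, g in enumerate(self.genome_ids)
                             if self.collection_of[g] == subset], dtype=int)
        if cols.size == 0:
            raise ValueError(f"no genomes in subset {subset!r}")
        return cols


@dataclasses.dataclass(frozen=True)
class AccumulationCurve:
    """Mean/sd distinct-cluster richness per sampling depth 1..N."""

    depths: np.ndarray
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    n_perm: int
    seed: int | None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "depth": self.depths,
            "mean_richness": self.mean_richness,
            "sd_richness": self.sd_richness,
        })


def accumulation_curve_perm(
    inc: IncidenceMatrix,
    subset: str = "all",
    n_perm: int = 1000,
    seed: int = 0,
) -> AccumulationCurve:
    """Permutation estimate of the accumulation curve (vegan-style).

    Genomes of the subset are randomly reordered *n_perm* times; mean and
    n-1 standard deviation of the cumulative distinct-cluster count are
    reported per depth.
    """
    cols = inc.subset_columns(subset)
    mat = inc.presence[:, cols]
    keep = mat.any(axis=1)
    mat = mat[keep]
    n = cols.size
    rng = np.random.default_rng(seed)
    richness = np.empty((n_perm, n), dtype=np.int64)
    for p in range(n_perm):
        order = rng.permutation(n)
        seen = np.logical_or.accumulate(mat[:, order], axis=1)
        richness[p] = seen.sum(axis=0)
    return AccumulationCurve(
        depths=np.arange(1, n + 1),
        mean_richness=richness.mean(axis=0),
        sd_richness=richness.std(axis=0, ddof=1) if n_perm > 1
        else np.zeros(n),
        n_perm=n_perm,
        seed=seed,
    )


def accumulation_curve_exact(
    inc: IncidenceMatrix,
    subset: str = "all",
) -> AccumulationCurve:
    """Closed-form expected accumulation curve.

    Uses log-gamma evaluation of the hypergeometric absence probability
    ``C(N - n_c, g) / C(N, g)`` (relative error well below 1e-10).
    """
    cols = inc.subset_columns(subset)
    mat = inc.presence[:, cols]
    counts = mat.sum(axis=1)
    counts = counts[counts > 0]
    n = cols.size
    g = np.arange(1, n + 1)

    def log_comb(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    # P(cluster absent at depth g) = C(N - n_c, g) / C(N, g), zero when
    # g > N - n_c
    nc = counts[:, None].astype(float)
    gg = g[None, :].astype(float)
    with np.errstate(invalid="ignore"):
        log_absent = log_comb(n - nc, gg) - log_comb(float(n), gg)
    absent = np.where(gg > n - nc, 0.0, np.exp(log_absent))
    mean = (1.0 - absent).sum(axis=0)
    return AccumulationCurve(
        depths=g, mean_richness=mean,
        sd_richness=np.zeros(n), n_perm=0, seed=None,
    )
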