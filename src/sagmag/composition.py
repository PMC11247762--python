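"""Taxonomic composition profiles and compositional differential abundance.

The differential-abundance procedure follows the ALDEx2-style recipe:
prevalence-filter lineages, draw Dirichlet Monte-Carlo instances of each
sample's composition (prior mass 0.5 per count cell), centre-log-ratio
transform every instance, run the Games-Howell post-hoc test across
observation methods per lineage and Monte-Carlo instance, and average the
per-instance estimated differences and p-values.  A lineage is called
significantly different for a method pair when the expected difference
exceeds 2 CLR units in magnitude and the expected p-value is below 1e-3
(both strict).
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import stats_core

DEFAULT_EXCLUDE = frozenset({"chloroplast", "mitochondria", "eukaryote",
                             "unclassified"})


def _rank_table(table: pd.DataFrame, rank: str) -> pd.DataFrame:
    sub = table[table["rank"] == rank]
    if sub.empty:
        raise ValueError(f"no counts at rank {rank!r}")
    return sub


def build_profile(
    table: pd.DataFrame,
    rank: str,
    exclude_lineages: Iterable[str] = DEFAULT_EXCLUDE,
) -> pd.DataFrame:
    """Mean per-sample proportion of each lineage, per observation method.

    Excluded lineages (organellar, eukaryotic, unclassified reads) are
    removed before proportions are computed.  Within a method, a lineage's
    mean proportion is the unweighted average of its per-sample proportions,
    counting 0 for samples that lack it; per method the means sum to 1.
    """
    sub = _rank_table(table, rank)
    excluded = frozenset(exclude_lineages)
    sub = sub[~sub["lineage"].isin(excluded)]
    if sub.empty:
        raise ValueError("no lineages left after exclusions")
    totals = sub.groupby(["method", "sample_id"])["count"].sum()
    if (totals == 0).any():
        bad = totals[totals == 0].index[0]
        raise ValueError(f"sample {bad} has zero total count after exclusions")
    rows = []
    for method, mgroup in sub.groupby("method", sort=True):
        pivot = (mgroup.pivot_table(index="sample_id", columns="lineage",
                                    values="count", aggfunc="sum",
                                    fill_value=0.0)
                 .astype(float))
        props = pivot.div(pivot.sum(axis=1), axis=0)
        means = props.mean(axis=0)
        for lineage, mean_prop in means.items():
            rows.append({"method": method, "rank": rank, "lineage": lineage,
                         "mean_proportion": float(mean_prop),
                         "n_samples": int(props.shape[0])})
    return pd.DataFrame(rows)


def lump_rare(
    profile: pd.DataFrame,
    reference_methods: Iterable[str],
    min_fraction: float,
    other_label: str = "Others",
) -> pd.DataFrame:
    """Merge lineages below *min_fraction* in every reference method.

    A lineage is kept if it reaches the cutoff in at least one reference
    method (figure convention: "constituting >= 2% ... using either
    reference"); the lumped mass is reported as one explicit bucket so the
    per-method proportions still sum to 1.
    """
    refs = sorted(set(reference_methods))
    present = set(profile["method"])
    missing = [m for m in refs if m not in present]
    if missing:
        raise ValueError(f"profile lacks reference methods {missing}")
    ref_max = (profile[profile["method"].isin(refs)]
               .groupby("lineage")["mean_proportion"].max())
    keep = set(ref_max[ref_max >= min_fraction].index)
    rows = []
    for (method, rank), group in profile.groupby(["method", "rank"], sort=True):
        kept = group[group["lineage"].isin(keep)]
        lumped = group[~group["lineage"].isin(keep)]
        rows.extend(kept.to_dict("records"))
        if not lumped.empty:
            rows.append({"method": method, "rank": rank,
                         "lineage": other_label,
                         "mean_proportion": float(
                             lumped["mean_proportion"].sum()),
                         "n_samples": int(group["n_samples"].iloc[0])})
    return pd.DataFrame(rows).reset_index(drop=True)


def prevalence_filter(
    table: pd.DataFrame,
    rank: str,
    min_prevalence: float = 0.9,
    methods: Sequence[str] = ("SAG", "MAG", "AMPLICON", "SHOTGUN"),
) -> set[str]:
    """Lineages present in strictly more than *min_prevalence* of the
    samples of every method.

    Presence means count > 0; the comparison is strict ("found in > 90%"),
    so 9 of 10 samples at the 0.9 default is not enough.
    """
    sub = _rank_table(table, rank)
    lineages: set[str] | None = None
    for method in methods:
        mgroup = sub[sub["method"] == method]
        samples = mgroup["sample_id"].unique()
        if samples.size == 0:
            raise ValueError(f"method {method!r} has no samples")
        positive = mgroup[mgroup["count"] > 0]
        prevalence = (positive.groupby("lineage")["sample_id"].nunique()
                      / samples.size)
        passing = set(prevalence[prevalence > min_prevalence].index)
        lineages = passing if lineages is None else lineages & passing
    return lineages or set()


def _per_sample_counts(
    table: pd.DataFrame, rank: str, lineages: Sequence[str],
    methods: Sequence[str],
) -> dict[str, np.ndarray]:
    """method -> integer count matrix (n_samples, n_lineages)."""
    sub = _rank_table(table, rank)
    sub = sub[sub["lineage"].isin(set(lineages))]
    out = {}
    for method in methods:
        mgroup = sub[sub["method"] == method]
        pivot = (mgroup.pivot_table(index="sample_id", columns="lineage",
                                    values="count", aggfunc="sum",
                                    fill_value=0)
                 .reindex(columns=list(lineages), fill_value=0)
                 .sort_index())
        if pivot.shape[0] < 2:
            raise ValueError(f"method {method!r} needs >= 2 samples")
        out[method] = pivot.to_numpy(dtype=float)
    return out


def differential_abundance(
    table: pd.DataFrame,
    rank: str,
    n_mc: int = 1000,
    prior_mass: float = 0.5,
    diff_cutoff: float = 2.0,
    p_cutoff: float = 1e-3,
    seed: int = 0,
    methods: Sequence[str] = ("SAG", "MAG", "AMPLICON", "SHOTGUN"),
    aggregate: str = "mean",
    lineages: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Dirichlet-MC + CLR + Games-Howell differential abundance.

    *table* should already be restricted to prevalence-filtered lineages
    (or pass *lineages* to restrict here).  For every Monte-Carlo index a
    Games-Howell test is run across methods on each lineage's per-sample
    CLR values; the per-instance estimated differences and p-values are
    then aggregated (arithmetic mean by default, ``aggregate="median"``
    optional) into one expected difference and expected p per lineage and
    method pair.  Significance uses the dual cutoff
    ``|difference| > diff_cutoff and p < p_cutoff`` (both strict).
    """
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    sub = _rank_table(table, rank)
    if lineages is None:
        lineage_list = sorted(sub["lineage"].unique())
    else:
        lineage_list = sorted(lineages)
    if len(lineage_list) < 2:
        raise ValueError("need >= 2 lineages for CLR analysis")
    counts = _per_sample_counts(table, rank, lineage_list, methods)

    rng = np.random.default_rng(seed)
    clr_by_method: dict[str, np.ndarray] = {}
    for method in methods:  # fixed draw order keeps the run reproducible
        mat = counts[method]
        n_samples = mat.shape[0]
        draws = np.empty((n_mc, len(lineage_list), n_samples))
        for s in range(n_samples):
            inst = rng.dirichlet(mat[s] + prior_mass, size=n_mc)
            tiny = np.finfo(float).tiny
            np.clip(inst, tiny, None, out=inst)
            draws[:, :, s] = stats_core.clr_transform(inst, axis=1)
        clr_by_method[method] = draws  # (n_mc, D, n_samples)

    k = len(methods)
    means = np.stack([clr_by_method[m].mean(axis=2) for m in methods], axis=-1)
    variances = np.stack([clr_by_method[m].var(axis=2, ddof=1)
                          for m in methods], axis=-1)
    ns = np.array([counts[m].shape[0] for m in methods], dtype=float)
    if np.any(variances == 0):
        idx = np.argwhere(variances == 0)[0]
        raise ValueError(
            f"zero variance: lineage {lineage_list[idx[1]]!r}, "
            f"method {methods[idx[2]]!r} (MC instance {idx[0]})")
    pairs = list(itertools.combinations(range(k), 2))
    d, _, t, wdf = stats_core.welch_pairwise_stats(means, variances, ns, pairs)
    p = stats_core.studentized_range_sf(np.abs(t) * np.sqrt(2.0), k, wdf,
                                        fast=True)
    agg = np.mean if aggregate == "mean" else np.median
    exp_d = agg(d, axis=0)   # (D, P)
    exp_p = agg(p, axis=0)

    rows = []
    for li, lineage in enumerate(lineage_list):
        for pi, (i, j) in enumerate(pairs):
            diff = float(exp_d[li, pi])
            pval = float(exp_p[li, pi])
            rows.append({
                "lineage": lineage,
                "method_pair": f"{methods[i]}_vs_{methods[j]}",
                "expected_difference": diff,
                "expected_p": pval,
                "significant": bool(abs(diff) > diff_cutoff
                                    and pval < p_cutoff),
            })
    return pd.DataFrame(rows)
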