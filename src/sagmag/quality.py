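"""Assembly-quality rules: completeness/contamination prefilters, GUNC
default chimera calls, GUNC-vs-MDMcleaner incongruence, the stringent
consensus chimera caller, and 16S-vs-genome taxonomy conflict auditing.

The consensus caller requires, at a single taxonomic rank strictly above
genus, a clade separation score (CSS) of at least 0.85 together with a
reference representation score (RRS) of at least 0.5, plus an MDMcleaner
contamination fraction of at least 10%; this is deliberately stricter than
the default single-threshold call (CSS > 0.45 at any rank).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_model import (RANKS, RANKS_ABOVE_GENUS, RankedTaxonomy,
                       normalize_rank)


@dataclasses.dataclass(frozen=True)
class RankScores:
    css: float
    rrs: float
    contamination_portion: float


@dataclasses.dataclass(frozen=True)
class ChimeraEvidence:
    """Per-genome contamination metrics from several estimators."""

    genome_id: str
    per_rank: Mapping[str, RankScores]   # rank -> scores (>= 1 rank)
    mdm_contamination: float
    checkm_completeness: float = float("nan")
    checkm_contamination: float = float("nan")

    def __post_init__(self) -> None:
        if not self.per_rank:
            raise ValueError(f"{self.genome_id}: no per-rank scores")
        for rank, scores in self.per_rank.items():
            if rank not in RANKS:
                raise ValueError(f"{self.genome_id}: unknown rank {rank!r}")
            for value in (scores.css, scores.rrs,
                          scores.contamination_portion):
                if not 0 <= value <= 1:
                    raise ValueError(
                        f"{self.genome_id}: score {value} outside [0, 1]")
        if not 0 <= self.mdm_contamination <= 1:
            raise ValueError(f"{self.genome_id}: MDM fraction outside [0, 1]")


@dataclasses.dataclass(frozen=True)
class ChimeraCall:
    genome_id: str
    default_call: bool
    consensus_call: bool
    evidence_rank: str | None
    reasons: tuple[str, ...]


def evidence_from_tables(
    gunc: pd.DataFrame,
    mdm: pd.DataFrame,
    genomes: pd.DataFrame | None = None,
) -> list[ChimeraEvidence]:
    """Assemble per-genome evidence from gunc/mdm (and genome) tables.

    GUNC's "kingdom" rank is mapped onto the domain slot.  Every genome in
    the GUNC table must carry an MDM row.
    """
    mdm_of = dict(zip(mdm["genome_id"], mdm["contamination_fraction"]))
    checkm: dict[str, tuple[float, float]] = {}
    if genomes is not None:
        checkm = {
            row.genome_id: (row.completeness, row.contamination)
            for row in genomes.itertuples(index=False)
        }
    out = []
    for genome_id, group in gunc.groupby("genome_id", sort=True):
        if genome_id not in mdm_of:
            raise ValueError(f"genome {genome_id!r} missing from MDM table")
        per_rank = {
            normalize_rank(row.rank): RankScores(
                css=row.css, rrs=row.rrs,
                contamination_portion=row.contamination_portion)
            for row in group.itertuples(index=False)
        }
        comp, cont = checkm.get(genome_id, (float("nan"), float("nan")))
        out.append(ChimeraEvidence(
            genome_id=str(genome_id), per_rank=per_rank,
            mdm_contamination=float(mdm_of[genome_id]),
            checkm_completeness=comp, checkm_contamination=cont))
    return out


def checkm_prefilter(
    genomes: pd.DataFrame,
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
    whitelist: Sequence[str] = (),
) -> pd.DataFrame:
    """Retain genomes passing the CheckM quality gate.

    Keeps completeness >= *min_completeness* and contamination <=
    *max_contamination* (boundaries inclusive), plus whitelisted genomes
    regardless of their metrics (manual-review overrides).
    """
    allowed = frozenset(whitelist)
    keep = (
        ((genomes["completeness"] >= min_completeness)
         & (genomes["contamination"] <= max_contamination))
        | genomes["genome_id"].isin(allowed)
    )
    return genomes.loc[keep].reset_index(drop=True)


def gunc_default_call(
    ev: ChimeraEvidence,
    css_cutoff: float = 0.45,
    require_rrs: float | None = None,
) -> bool:
    """Default GUNC chimera call: CSS strictly above the cutoff at any rank.

    With *require_rrs* set, only ranks whose RRS exceeds it are eligible
    (the "well represented in the reference database" restricted view).
    """
    for scores in ev.per_rank.values():
        if require_rrs is not None and not scores.rrs > require_rrs:
            continue
        if scores.css > css_cutoff:
            return True
    return False


def consensus_chimera_call(
    ev: ChimeraEvidence,
    rrs_min: float = 0.5,
    css_min: float = 0.85,
    mdm_min: float = 0.10,
) -> ChimeraCall:
    """Stringent consensus chimera call.

    True iff some rank strictly above genus has CSS >= *css_min* and
    RRS >= *rrs_min*, and the MDMcleaner contamination fraction is at
    least *mdm_min*.  The evidence rank is the qualifying rank with the
    highest CSS; the reasons list records each condition's outcome.
    """
    qualifying = [
        (rank, scores) for rank, scores in ev.per_rank.items()
        if rank in RANKS_ABOVE_GENUS
        and scores.css >= css_min and scores.rrs >= rrs_min
    ]
    rank_ok = bool(qualifying)
    mdm_ok = ev.mdm_contamination >= mdm_min
    reasons = (
        ("css_rrs_above_genus:" + ("pass" if rank_ok else "fail")),
        ("mdm_min:" + ("pass" if mdm_ok else "fail")),
    )
    evidence_rank = None
    if rank_ok:
        evidence_rank = max(qualifying, key=lambda rs: rs[1].css)[0]
    return ChimeraCall(
        genome_id=ev.genome_id,
        default_call=gunc_default_call(ev),
        consensus_call=rank_ok and mdm_ok,
        evidence_rank=evidence_rank if (rank_ok and mdm_ok) else None,
        reasons=reasons,
    )


def contamination_incongruence(
    evs: Sequence[ChimeraEvidence],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-genome GUNC vs MDMcleaner contamination and an OLS fit.

    The GUNC fraction is the contamination portion at the genome's
    maximum-CSS rank.  Returns the per-genome table (gunc_fraction,
    mdm_fraction, difference = gunc - mdm) and the ordinary least squares
    regression of the MDM fraction on the GUNC fraction (slope, intercept,
    r-squared, two-sided slope p).
    """
    if len(evs) < 3:
        raise ValueError("need >= 3 genomes for the regression")
    rows = []
    for ev in evs:
        best_rank = max(ev.per_rank, key=lambda r: ev.per_rank[r].css)
        gunc_fraction = ev.per_rank[best_rank].contamination_portion
        rows.append({
            "genome_id": ev.genome_id,
            "gunc_fraction": gunc_fraction,
            "mdm_fraction": ev.mdm_contamination,
            "difference": gunc_fraction - ev.mdm_contamination,
        })
    table = pd.DataFrame(rows)
    x = table["gunc_fraction"].to_numpy()
    y = table["mdm_fraction"].to_numpy()
    if np.allclose(x, x[0]):
        fit = {"slope": 0.0, "intercept": float(y.mean()),
               "r_squared": 0.0, "p_value": float("nan")}
    else:
        res = sps.linregress(x, y)
        fit = {"slope": float(res.slope),
               "intercept": float(res.intercept),
               "r_squared": float(res.rvalue ** 2),
               "p_value": float(res.pvalue)}
    return table, fit


def conflict_16s(
    genome_taxa: Mapping[str, RankedTaxonomy],
    rrna: pd.DataFrame,
    collections: Mapping[str, str],
    ranks: Sequence[str] = ("domain", "phylum", "class"),
) -> dict[str, object]:
    """Audit 16S assignments against genome taxonomy.

    A genome mismatches at a rank when both its genome taxonomy and at
    least one of its 16S assignments are assigned there and disagree.  A
    multi-copy conflict is two 16S copies of one genome that are assigned
    and mutually different at a rank.  Also reports, per collection, the
    fraction of genomes with at least one recovered 16S sequence.
    """
    orphans = sorted(set(rrna["genome_id"]) - set(genome_taxa))
    if orphans:
        raise ValueError(f"rrna rows reference unknown genomes: {orphans}")
    assignments: dict[str, list[RankedTaxonomy]] = {}
    for row in rrna.itertuples(index=False):
        tax = RankedTaxonomy.from_string(row.taxonomy)
        assignments.setdefault(str(row.genome_id), []).append(tax)

    mismatch_counts = {
        coll: {rank: 0 for rank in ranks}
        for coll in sorted(set(collections.values()))
    }
    mismatched: dict[str, list[tuple[str, str]]] = {r: [] for r in ranks}
    multi_conflicts: dict[str, list[str]] = {r: [] for r in ranks}
    for genome_id, taxa in assignments.items():
        coll = collections.get(genome_id, "?")
        genome_tax = genome_taxa[genome_id]
        for rank in ranks:
            rank = normalize_rank(rank)
            if any(genome_tax.agrees_at(t, rank) is False for t in taxa):
                if coll in mismatch_counts:
                    mismatch_counts[coll][rank] += 1
                mismatched[rank].append((genome_id, coll))
            labels = [t.label(rank) for t in taxa if t.label(rank)]
            if len(set(labels)) > 1:
                multi_conflicts[rank].append(genome_id)

    recovery = {}
    for coll in sorted(set(collections.values())):
        members = [g for g, c in collections.items() if c == coll]
        with_16s = sum(1 for g in members if g in assignments)
        recovery[coll] = with_16s / len(members) if members else float("nan")
    return {
        "mismatch_counts": mismatch_counts,
        "mismatched_genomes": mismatched,
        "multi_copy_conflicts": {r: sorted(v)
                                 for r, v in multi_conflicts.items()},
        "recovery_fraction": recovery,
    }
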