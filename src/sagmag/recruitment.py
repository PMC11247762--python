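"""Fragment-recruitment comparison between reference genome sets.

For each metagenomic sample and reference set, the recruited fraction is
the share of the sample's reads whose best alignment reaches an identity
threshold with an alignment length of at least 100 bp.  SAG and MAG
reference sets are compared across samples, per threshold, with the exact
paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .stats_core import wilcoxon_signed_rank_paired

#: Identity grid used in the recruitment figures.
DEFAULT_THRESHOLDS: tuple[float, ...] = (1.00, 0.98, 0.95, 0.90, 0.85, 0.80)


def recruitment_fraction(
    aln: pd.DataFrame,
    identity_threshold: float,
    min_aln_length: int = 100,
) -> pd.DataFrame:
    """Per-sample, per-reference-set recruited read fraction.

    ``fraction = |reads with best_identity >= threshold and aln_length >=
    min_aln_length| / sample_total_reads``.  The declared total must be
    consistent within each (sample, reference set).
    """
    totals = aln.groupby(["sample_id", "reference_set"])["sample_total_reads"]
    if (totals.nunique() > 1).any():
        bad = totals.nunique()
        key = bad[bad > 1].index[0]
        raise ValueError(f"inconsistent sample_total_reads for {key}")
    rows = []
    for (sample_id, ref), group in aln.groupby(
            ["sample_id", "reference_set"], sort=True):
        total = int(group["sample_total_reads"].iloc[0])
        recruited = int(((group["best_identity"] >= identity_threshold)
                         & (group["aln_length"] >= min_aln_length)).sum())
        rows.append({"sample_id": sample_id, "reference_set": ref,
                     "identity_threshold": identity_threshold,
                     "fraction": recruited / total})
    return pd.DataFrame(rows)


def compare_recruitment(
    aln: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    min_aln_length: int = 100,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recruited fractions plus a paired SAG-vs-MAG test per threshold.

    Every sample must carry both reference sets.  Returns the long
    fractions table and a per-threshold table with the signed-rank W,
    two-sided p, and an "ns" label when p >= *alpha*.
    """
    frames = [recruitment_fraction(aln, thr, min_aln_length)
              for thr in thresholds]
    fractions = pd.concat(frames, ignore_index=True)
    tests = []
    for thr in thresholds:
        sub = fractions[fractions["identity_threshold"] == thr]
        wide = sub.pivot(index="sample_id", columns="reference_set",
                         values="fraction")
        if wide.isna().any().any() or not {"SAG", "MAG"} <= set(wide.columns):
            raise ValueError(f"missing SAG/MAG pair at threshold {thr}")
        w, p = wilcoxon_signed_rank_paired(wide["SAG"].to_numpy(),
                                           wide["MAG"].to_numpy())
        tests.append({"identity_threshold": thr, "n_samples": wide.shape[0],
                      "W": w, "p_value": p,
                      "label": "ns" if p >= alpha else f"p={p:.3g}"})
    return fractions, pd.DataFrame(tests)
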