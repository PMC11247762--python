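"""Greedy identity-threshold clustering and pairwise sequence identity.

The same greedy incremental rule serves three purposes: species-like genome
dereplication on an ANI matrix (95% threshold), nucleotide "unigene"
clustering (95% identity, 90% shorter-sequence coverage), and protein-family
clustering at a stated amino-acid identity.

Pairwise identity comes from a global Gotoh affine-gap alignment.  Terminal
gap runs are charged the same affine penalty as interior gaps but excluded
from the identity bookkeeping: the core of the alignment runs from the
first to the last match/mismatch column, identity is matches divided by
core columns, and each sequence's coverage is the fraction of its residues
inside the core.  Among co-optimal alignments the one with the most matches
(then the fewest core columns) is chosen, deterministically.  Wildcard
residues (N for nucleotides, X for proteins) occupy columns but never count
as matches.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

NUCLEOTIDE_ALPHABET = "ACGT"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_WILDCARD = {"nucleotide": "N", "protein": "X"}
_NEG = -1.0e30


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """A gene (or genome fragment) sequence tied to its source genome."""

    seq_id: str
    genome_id: str
    alphabet: str  # "nucleotide" | "protein"
    residues: str

    def __post_init__(self) -> None:
        if self.alphabet not in _WILDCARD:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if not self.residues:
            raise ValueError(f"{self.seq_id}: empty sequence")
        allowed = set(
            (NUCLEOTIDE_ALPHABET if self.alphabet == "nucleotide"
             else PROTEIN_ALPHABET) + _WILDCARD[self.alphabet])
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"{self.seq_id}: residues {sorted(bad)} outside the "
                f"{self.alphabet} alphabet")


@dataclasses.dataclass(frozen=True)
class ClusterParams:
    """Identity/coverage thresholds for greedy clustering.

    ``coverage_mode`` selects which coverage must clear the threshold:
    the shorter sequence's (CD-HIT ``-aS`` semantics), the query's, or both.
    """

    identity_threshold: float
    coverage_threshold: float = 0.0
    coverage_mode: str = "shorter"

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")
        if not 0 <= self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in [0, 1]")
        if self.coverage_mode not in ("shorter", "query", "bidirectional"):
            raise ValueError(f"unknown coverage_mode {self.coverage_mode!r}")


def _encode(record: SequenceRecord) -> np.ndarray:
    table = (NUCLEOTIDE_ALPHABET if record.alphabet == "nucleotide"
             else PROTEIN_ALPHABET)
    mapping = {ch: i + 1 for i, ch in enumerate(table)}
    mapping[_WILDCARD[record.alphabet]] = 0  # wildcard: never a match
    return np.array([mapping[ch] for ch in record.residues], dtype=np.int8)


# the lexicographic objective (score, matches, -columns) is packed into one
# int64 key: 4*score in the top bits (scoring parameters are rounded to
# multiples of 0.25), matches in 13 bits, 16383 - columns in the low 14 bits;
# additions never carry between fields, so ordinary max() is an exact
# lexicographic comparison
_KEY_NEG = np.int64(-(1 << 62))
_MATCH_SHIFT = 14
_SCORE_SHIFT = 27
_COL_BASE = np.int64((1 << 14) - 1)
_MAX_LEN = 8000  # keeps matches/columns inside their bit fields


@njit(cache=True)
def _gotoh_core(a, b, d_match, d_mismatch, d_open, d_extend):  # pragma: no cover
    """Global affine-gap alignment; lexicographic (score, matches, -cols).

    States: M = a_i over b_j; X = a_i over gap; Y = gap over b_j.  Any
    global alignment decomposes into a leading terminal-gap run (in exactly
    one sequence), a core from the first to the last match/mismatch column,
    and a trailing terminal-gap run; terminal runs are charged the same
    affine penalty as interior gaps but stay outside the match/column
    bookkeeping, so an M state may start fresh when i == 1 or j == 1 (with
    the leading penalty) and the answer is read from M cells on the last
    row or column (plus the trailing penalty).  The d_* arguments are
    packed int64 deltas (score and column increments; the match increment
    is added separately).  Returns (key, matches, columns, a_span, b_span).
    """
    n, m = a.shape[0], b.shape[0]
    # terminal gap run of length L costs open + (L-1)*extend, packed into
    # the score field only
    open4 = (d_open + 1) >> 27   # recover 4*gap_open from the packed delta
    ext4 = (d_extend + 1) >> 27
    ms = np.full((n + 1, m + 1), _KEY_NEG)
    xs = np.full((n + 1, m + 1), _KEY_NEG)
    ys = np.full((n + 1, m + 1), _KEY_NEG)
    mi = np.zeros((n + 1, m + 1), np.int32)  # core start coordinates
    mj = np.zeros((n + 1, m + 1), np.int32)
    xi = np.zeros((n + 1, m + 1), np.int32)
    xj = np.zeros((n + 1, m + 1), np.int32)
    yi = np.zeros((n + 1, m + 1), np.int32)
    yj = np.zeros((n + 1, m + 1), np.int32)
    start_key = np.int64(_COL_BASE)  # score 0, matches 0, columns 0
    match_inc = np.int64(1) << _MATCH_SHIFT

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            wild = ai == 0 or b[j - 1] == 0
            is_match = (not wild) and ai == b[j - 1]
            delta = (d_match + match_inc) if is_match else d_mismatch

            # --- M state: best predecessor at (i-1, j-1) or fresh start ---
            best = _KEY_NEG
            bi = bj = 0
            if i == 1 or j == 1:
                lead = (i - 1) + (j - 1)
                pen4 = np.int64(0) if lead == 0 else open4 + (lead - 1) * ext4
                best = start_key + (pen4 << _SCORE_SHIFT)
                bi, bj = i, j
            p = ms[i - 1, j - 1]
            if p > best:
                best = p
                bi, bj = mi[i - 1, j - 1], mj[i - 1, j - 1]
            p = xs[i - 1, j - 1]
            if p > best:
                best = p
                bi, bj = xi[i - 1, j - 1], xj[i - 1, j - 1]
            p = ys[i - 1, j - 1]
            if p > best:
                best = p
                bi, bj = yi[i - 1, j - 1], yj[i - 1, j - 1]
            if best > _KEY_NEG // 2:
                ms[i, j] = best + delta
                mi[i, j], mj[i, j] = bi, bj
            else:
                ms[i, j] = _KEY_NEG

            # --- X state: a_i over a gap (interior) ---
            best = ms[i - 1, j] + d_open
            bi, bj = mi[i - 1, j], mj[i - 1, j]
            p = xs[i - 1, j] + d_extend
            if p > best:
                best = p
                bi, bj = xi[i - 1, j], xj[i - 1, j]
            p = ys[i - 1, j] + d_open
            if p > best:
                best = p
                bi, bj = yi[i - 1, j], yj[i - 1, j]
            if best > _KEY_NEG // 2:
                xs[i, j] = best
                xi[i, j], xj[i, j] = bi, bj
            else:
                xs[i, j] = _KEY_NEG

            # --- Y state: gap over b_j (interior) ---
            best = ms[i, j - 1] + d_open
            bi, bj = mi[i, j - 1], mj[i, j - 1]
            p = xs[i, j - 1] + d_open
            if p > best:
                best = p
                bi, bj = xi[i, j - 1], xj[i, j - 1]
            p = ys[i, j - 1] + d_extend
            if p > best:
                best = p
                bi, bj = yi[i, j - 1], yj[i, j - 1]
            if best > _KEY_NEG // 2:
                ys[i, j] = best
                yi[i, j], yj[i, j] = bi, bj
            else:
                ys[i, j] = _KEY_NEG

    # best M cell on the last row or last column, charging the trailing
    # terminal-gap run (in exactly one sequence)
    best = _KEY_NEG
    bi0 = bj0 = bi1 = bj1 = 0
    for j in range(1, m + 1):
        trail = m - j
        pen4 = np.int64(0) if trail == 0 else open4 + (trail - 1) * ext4
        cand = ms[n, j] + (pen4 << _SCORE_SHIFT)
        if ms[n, j] > _KEY_NEG // 2 and cand > best:
            best = cand
            bi0, bj0, bi1, bj1 = mi[n, j], mj[n, j], n, j
    for i in range(1, n + 1):
        trail = n - i
        pen4 = np.int64(0) if trail == 0 else open4 + (trail - 1) * ext4
        cand = ms[i, m] + (pen4 << _SCORE_SHIFT)
        if ms[i, m] > _KEY_NEG // 2 and cand > best:
            best = cand
            bi0, bj0, bi1, bj1 = mi[i, m], mj[i, m], i, m
    if best <= _KEY_NEG // 2:  # unreachable for nonempty sequences
        return np.int64(0), 0, 0, 0, 0
    matches = int((best >> _MATCH_SHIFT) & np.int64((1 << 13) - 1))
    columns = int(_COL_BASE - (best & _COL_BASE))
    return best, matches, columns, bi1 - bi0 + 1, bj1 - bj0 + 1


def _pack_deltas(match: float, mismatch: float, gap_open: float,
                 gap_extend: float) -> tuple[np.int64, np.int64, np.int64,
                                             np.int64]:
    """Pack scoring parameters into int64 key deltas (one core column each)."""
    deltas = []
    for value in (match, mismatch, gap_open, gap_extend):
        scaled = round(4.0 * value)
        if abs(scaled - 4.0 * value) > 1e-9:
            raise ValueError("scoring parameters must be multiples of 0.25")
        # score delta in the top field, column +1 lowers the low field by 1
        deltas.append(np.int64((scaled << _SCORE_SHIFT) - 1))
    return tuple(deltas)


def _align_codes(codes_a: np.ndarray, codes_b: np.ndarray, len_a: int,
                 len_b: int, deltas) -> tuple[float, float, float]:
    if len_a + len_b > _MAX_LEN * 2 or max(len_a, len_b) > _MAX_LEN:
        raise ValueError(f"sequences longer than {_MAX_LEN} are unsupported")
    _, matches, columns, a_span, b_span = _gotoh_core(
        codes_a, codes_b, *deltas)
    if columns == 0:
        return 0.0, 0.0, 0.0
    return matches / columns, a_span / len_a, b_span / len_b


def _align(a: SequenceRecord, b: SequenceRecord, gap_open: float,
           gap_extend: float, match: float,
           mismatch: float) -> tuple[float, float, float]:
    """(identity, coverage of a, coverage of b)."""
    if a.alphabet != b.alphabet:
        raise ValueError("alphabet mismatch")
    deltas = _pack_deltas(match, mismatch, gap_open, gap_extend)
    return _align_codes(_encode(a), _encode(b), len(a.residues),
                        len(b.residues), deltas)


def pairwise_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    match: float = 2.0,
    mismatch: float = -3.0,
) -> tuple[float, float, float]:
    """Alignment identity and coverages for two sequences.

    Returns ``(identity, coverage_shorter, coverage_query)`` where *a* is
    the query.  Integral scoring parameters keep tie detection exact.
    """
    identity, cov_a, cov_b = _align(a, b, gap_open, gap_extend, match, mismatch)
    cov_shorter = cov_a if len(a.residues) <= len(b.residues) else cov_b
    return identity, cov_shorter, cov_a


def greedy_cluster(
    seqs: Sequence[SequenceRecord],
    params: ClusterParams,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    match: float = 2.0,
    mismatch: float = -3.0,
) -> pd.DataFrame:
    """Greedy incremental clustering (CD-HIT/MMseqs2-style stand-in).

    Sequences are processed in order of decreasing length (ties broken by
    seq_id).  Each sequence joins the existing representative with the
    highest identity among those meeting both thresholds (ties favour the
    earliest-created cluster); otherwise it founds a new cluster.  Returns
    a clusters table (member_id, cluster_id, is_representative) whose
    cluster_id is the representative's seq_id.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    ids = [s.seq_id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate seq_ids")
    ordered = sorted(seqs, key=lambda s: (-len(s.residues), s.seq_id))
    deltas = _pack_deltas(match, mismatch, gap_open, gap_extend)
    codes = {s.seq_id: _encode(s) for s in ordered}
    reps: list[SequenceRecord] = []
    assignment: dict[str, str] = {}
    for seq in ordered:
        best_identity = -1.0
        best_rep: SequenceRecord | None = None
        for rep in reps:  # creation order
            if seq.alphabet != rep.alphabet:
                raise ValueError("alphabet mismatch")
            identity, cov_query, cov_rep = _align_codes(
                codes[seq.seq_id], codes[rep.seq_id], len(seq.residues),
                len(rep.residues), deltas)
            if params.coverage_mode == "shorter":
                cov = (cov_query if len(seq.residues) <= len(rep.residues)
                       else cov_rep)
            elif params.coverage_mode == "query":
                cov = cov_query
            else:  # bidirectional
                cov = min(cov_query, cov_rep)
            if (identity >= params.identity_threshold
                    and cov >= params.coverage_threshold
                    and identity > best_identity):
                best_identity = identity
                best_rep = rep
        if best_rep is None:
            reps.append(seq)
            assignment[seq.seq_id] = seq.seq_id
        else:
            assignment[seq.seq_id] = best_rep.seq_id
    rows = [
        {"member_id": member, "cluster_id": rep_id,
         "is_representative": member == rep_id}
        for member, rep_id in assignment.items()
    ]
    return (pd.DataFrame(rows)
            .sort_values(["cluster_id", "member_id"])
            .reset_index(drop=True))


def ani_dereplicate(
    genomes: pd.DataFrame,
    ani: pd.DataFrame,
    threshold: float = 95.0,
) -> pd.DataFrame:
    """Greedy species-level dereplication on a percent-ANI matrix.

    Genomes are ranked by completeness (descending; ties by genome_id) and
    each joins the first existing representative with ANI >= *threshold*,
    else founds its own cluster.  *ani* is a square DataFrame indexed and
    columned by genome_id, symmetric within 1e-9, with diagonal 100.
    """
    ids = list(genomes["genome_id"])
    if set(ids) - set(ani.index) or set(ids) - set(ani.columns):
        raise ValueError("ANI matrix is missing genomes")
    sub = ani.loc[ids, ids].to_numpy(dtype=float)
    if not np.allclose(sub, sub.T, atol=1e-9):
        raise ValueError("ANI matrix is not symmetric")
    if not np.allclose(np.diag(sub), 100.0, atol=1e-9):
        raise ValueError("ANI diagonal must be 100")
    if sub.min() < 0 or sub.max() > 100 + 1e-9:
        raise ValueError("ANI values must lie in [0, 100]")
    order = (genomes[["genome_id", "completeness"]]
             .sort_values(["completeness", "genome_id"],
                          ascending=[False, True])["genome_id"].tolist())
    pos = {g: i for i, g in enumerate(ids)}
    reps: list[str] = []
    assignment: dict[str, str] = {}
    for g in order:
        for rep in reps:
            if sub[pos[g], pos[rep]] >= threshold:
                assignment[g] = rep
                break
        else:
            reps.append(g)
            assignment[g] = g
    rows = [
        {"member_id": g, "cluster_id": rep, "is_representative": g == rep}
        for g, rep in assignment.items()
    ]
    return (pd.DataFrame(rows)
            .sort_values(["cluster_id", "member_id"])
            .reset_index(drop=True))


def records_from_fasta(
    fasta_records: Iterable[tuple[str, str, str]],
    alphabet: str,
    genome_of: Mapping[str, str] | None = None,
) -> list[SequenceRecord]:
    """Build SequenceRecords from (seq_id, description, residues) triples.

    The source genome is taken from a ``genome=<id>`` token in the FASTA
    description, or from *genome_of* when provided.
    """
    out = []
    for seq_id, description, residues in fasta_records:
        genome_id = ""
        if genome_of is not None and seq_id in genome_of:
            genome_id = genome_of[seq_id]
        else:
            for token in description.split():
                if token.startswith("genome="):
                    genome_id = token[len("genome="):]
        out.append(SequenceRecord(seq_id=seq_id, genome_id=genome_id,
                                  alphabet=alphabet, residues=residues))
    return out
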