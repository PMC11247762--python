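"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: alignments are
enumerated path by path, signed-rank distributions by explicit sign
vectors, the studentized range by Monte Carlo, graph components by label
propagation, and least squares by the normal equations.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_alignment(a: str, b: str, match: float = 2.0,
                        mismatch: float = -3.0, gap_open: float = -5.0,
                        gap_extend: float = -2.0,
                        wildcard: str = "N") -> tuple | None:
    """Best (score, matches, -columns) over all global alignments.

    Paths run from (0,0) to (len(a), len(b)); terminal gap runs must sit
    within a single sequence and are charged the affine penalty, while
    matches/columns count only the core (first to last match/mismatch
    column); interior gaps are affine and a switch between gap directions
    reopens.  Returns None when no alignment has a match/mismatch column.
    """
    n, m = len(a), len(b)
    best = None

    def walk(i: int, j: int, path: list) -> None:
        nonlocal best
        if i == n and j == m:
            idx = [t for t, (op, _, _) in enumerate(path) if op == "M"]
            if not idx:
                return
            prefix = [op for op, _, _ in path[:idx[0]]]
            suffix = [op for op, _, _ in path[idx[-1] + 1:]]
            if len(set(prefix)) > 1 or len(set(suffix)) > 1:
                return
            score, matches, prev = 0.0, 0, None
            for run in (prefix, suffix):
                if run:
                    score += gap_open + (len(run) - 1) * gap_extend
            core = path[idx[0]:idx[-1] + 1]
            for op, x, y in core:
                if op == "M":
                    wild = x == wildcard or y == wildcard
                    if (not wild) and x == y:
                        score += match
                        matches += 1
                    else:
                        score += mismatch
                else:
                    score += gap_extend if prev == op else gap_open
                prev = op
            cand = (score, matches, -len(core))
            if best is None or cand > best:
                best = cand
            return
        if i < n:
            walk(i + 1, j, path + [("X", a[i], "-")])
        if j < m:
            walk(i, j + 1, path + [("Y", "-", b[j])])
        if i < n and j < m:
            walk(i + 1, j + 1, path + [("M", a[i], b[j])])

    walk(0, 0, [])
    return best


def replay_greedy(seqs, params, identity_fn):
    """Re-implementation of the greedy clustering rule.

    *identity_fn(seq, rep)* must return (identity, coverage) for the
    configured coverage mode.  Returns member -> representative mapping.
    """
    ordered = sorted(seqs, key=lambda s: (-len(s.residues), s.seq_id))
    reps, assignment = [], {}
    for seq in ordered:
        best = None
        for rep in reps:
            identity, cov = identity_fn(seq, rep)
            if identity >= params.identity_threshold and \
                    cov >= params.coverage_threshold:
                if best is None or identity > best[0]:
                    best = (identity, rep)
        if best is None:
            reps.append(seq)
            assignment[seq.seq_id] = seq.seq_id
        else:
            assignment[seq.seq_id] = best[1].seq_id
    return assignment


def signed_rank_enumeration(diff: np.ndarray) -> tuple[float, float]:
    """Exact two-sided paired signed-rank (W, p) over all sign vectors."""
    from scipy.stats import rankdata

    diff = np.asarray(diff, dtype=float)
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(diff))
    w_obs = float(ranks[diff > 0].sum())
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws, dtype=float)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return w_obs, float(min(1.0, 2.0 * min(p_le, p_ge)))


def studentized_range_mc(q_grid: np.ndarray, k: int, df: float,
                         n_draws: int, seed: int) -> tuple[np.ndarray,
                                                           np.ndarray]:
    """Monte-Carlo tail of the studentized range; returns (sf, se)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, k))
    rng_range = z.max(axis=1) - z.min(axis=1)
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    q_draws = rng_range / s
    sf = np.array([(q_draws >= q).mean() for q in q_grid])
    se = np.sqrt(np.maximum(sf * (1 - sf), 1e-12) / n_draws)
    return sf, se


def connected_components(nodes, edges) -> list[frozenset]:
    """Label-propagation components (no graph library)."""
    label = {n: n for n in nodes}

    def find(x):
        while label[x] != x:
            label[x] = label[label[x]]
            x = label[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            label[ru] = rv
    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return [frozenset(g) for g in groups.values()]


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float,
                                                                float]:
    """(slope, intercept, r^2) by the closed-form normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_res = ((y - intercept - slope * x) ** 2).sum()
    ss_tot = ((y - ybar) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def expected_richness_by_permutation(presence: np.ndarray, n_perm: int,
                                     seed: int) -> np.ndarray:
    """Mean accumulation curve by explicit permutation (oracle twin)."""
    rng = np.random.default_rng(seed)
    n = presence.shape[1]
    acc = np.zeros(n)
    for _ in range(n_perm):
        order = rng.permutation(n)
        seen = np.logical_or.accumulate(presence[:, order], axis=1)
        acc += seen.sum(axis=0)
    return acc / n_perm
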