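"""Independent reference implementations used only as test oracles.

Each function here recomputes a quantity by the most direct route available
(explicit loops, enumeration, closed forms), deliberately sharing no code
with the package implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

BASE_ORDER = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# MATCH scoring, direct formula evaluation
# ---------------------------------------------------------------------------

def pwm_frequencies(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    f = counts / counts.sum(axis=1, keepdims=True)
    f = f + pseudocount
    return f / f.sum(axis=1, keepdims=True)


def information_vector(freqs: np.ndarray) -> np.ndarray:
    out = np.zeros(len(freqs))
    for i, row in enumerate(freqs):
        out[i] = sum(p * math.log(4 * p) for p in row if p > 0)
    return out


def direct_mss(counts: np.ndarray, pseudocount: float, window: str,
               positions: list[int] | None = None) -> float:
    """(raw - Min) / (Max - Min) over the given positions (all by default)."""
    f = pwm_frequencies(counts, pseudocount)
    info = information_vector(f)
    if positions is None:
        positions = list(range(len(f)))
    # window is already sliced to the given positions
    raw = lo = hi = 0.0
    for k, i in enumerate(positions):
        raw += info[i] * f[i][BASE_ORDER.index(window[k])]
        lo += info[i] * min(f[i])
        hi += info[i] * max(f[i])
    if hi - lo <= 0:
        return 1.0
    return (raw - lo) / (hi - lo)


def core_positions(counts: np.ndarray, pseudocount: float,
                   core_len: int = 5) -> list[int]:
    f = pwm_frequencies(counts, pseudocount)
    info = information_vector(f)
    k = min(core_len, len(info))
    sums = [sum(info[s:s + k]) for s in range(len(info) - k + 1)]
    start = sums.index(max(sums))
    return list(range(start, start + k))


def _mss_from_tables(f, info, window: str, positions) -> float:
    """direct_mss on precomputed frequency/information tables."""
    raw = lo = hi = 0.0
    for k, i in enumerate(positions):
        raw += info[i] * f[i][BASE_ORDER.index(window[k])]
        lo += info[i] * min(f[i])
        hi += info[i] * max(f[i])
    if hi - lo <= 0:
        return 1.0
    return (raw - lo) / (hi - lo)


def naive_scan(promoters, pwms, mss_cut: float, css_cut: float):
    """Exhaustive reference scanner: every window, every strand, explicit
    per-position loops (frequency and information tables computed once per
    PWM). Returns a set of (gene, pwm, start, strand, round(mss,10),
    round(css,10)) tuples."""
    out = set()
    for pwm in pwms:
        L = len(pwm.counts)
        f = pwm_frequencies(pwm.counts, pwm.pseudocount)
        info = information_vector(f)
        core = core_positions(pwm.counts, pwm.pseudocount, pwm.core_length)
        all_pos = list(range(L))
        for prom in promoters:
            for start in range(len(prom.sequence) - L + 1):
                fwd = prom.sequence[start:start + L]
                for strand, window in (("+", fwd), ("-", revcomp(fwd))):
                    if any(c not in BASE_ORDER for c in window):
                        continue
                    mss = _mss_from_tables(f, info, window, all_pos)
                    css = _mss_from_tables(
                        f, info, "".join(window[i] for i in core), core)
                    if mss >= mss_cut and css >= css_cut:
                        out.add((prom.gene_id, pwm.name, start, strand,
                                 round(mss, 10), round(css, 10)))
    return out


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def bh_stepup(p_values) -> list[float]:
    """Brute-force BH: adj_(i) = min_{j >= i} m * p_(j) / j, capped at 1."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)
        ]
        adj[i] = min(min(candidates), 1.0)
    return adj


def hypergeom_tail(yes_hit: int, yes_total: int, no_hit: int,
                   no_total: int) -> float:
    """One-sided Fisher p: P(X >= yes_hit) under the hypergeometric law
    with margins fixed, computed as an explicit tail sum of binomial
    coefficients."""
    n = yes_total + no_total
    k = yes_hit + no_hit  # total hits
    denom = math.comb(n, k)
    p = 0.0
    for x in range(yes_hit, min(yes_total, k) + 1):
        if k - x > no_total:
            continue
        p += math.comb(yes_total, x) * math.comb(no_total, k - x) / denom
    return p


def exact_ranksum_greater(yes, no) -> float:
    """Exact one-sided rank-sum p (Yes tends larger) by enumerating every
    subset assignment of the pooled midranks."""
    pooled = list(yes) + list(no)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = mid
        i = j + 1
    n_yes = len(yes)
    observed = sum(ranks[:n_yes])
    count = total = 0
    for comb in combinations(range(len(pooled)), n_yes):
        w = sum(ranks[i] for i in comb)
        if w >= observed - 1e-9:
            count += 1
        total += 1
    return count / total


def median_of_ratios(mat: np.ndarray) -> np.ndarray:
    """Brute-force size factors: per-sample median of count/geomean ratios
    over all-positive genes, rescaled to geometric mean one."""
    keep = [g for g in range(mat.shape[0]) if all(mat[g] > 0)]
    geo = [math.exp(np.mean([math.log(v) for v in mat[g]])) for g in keep]
    factors = []
    for s in range(mat.shape[1]):
        ratios = sorted(mat[g, s] / geo[i] for i, g in enumerate(keep))
        m = len(ratios)
        med = (ratios[m // 2] if m % 2 else
               (ratios[m // 2 - 1] + ratios[m // 2]) / 2)
        factors.append(med)
    gm = math.exp(np.mean([math.log(f) for f in factors]))
    return np.array([f / gm for f in factors])


def module_score_bruteforce(hits_by_pwm: dict, members, width: int,
                            promoter_length: int) -> float:
    """Evaluate every integer window start."""
    best = 0.0
    for s in range(0, promoter_length - width + 1):
        total = 0.0
        for name, weight, cap in members:
            starts = hits_by_pwm.get(name, [])
            n = sum(1 for x in starts if s <= x < s + width)
            total += weight * min(n, cap)
        best = max(best, total)
    return best
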