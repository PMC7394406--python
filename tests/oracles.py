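"""Independent reference implementations used only to check the package.

These deliberately share no code with skipfeat: brute-force enumeration and
naive scans against which the real implementations are compared.
"""

from itertools import combinations

import numpy as np


def mw_exact_two_sided_p(a, b) -> float:
    """Two-sided Mann-Whitney p by full enumeration of rank assignments.

    Pools the data, enumerates every way the n ranks of sample a could fall
    among the n+m ranks, and counts assignments at least as extreme (in
    either tail of the U distribution) as the observed one. Assumes no ties.
    """
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - n * (n + 1) / 2
    total = 0
    extreme = 0
    hi = max(u_obs, n * m - u_obs)
    lo = min(u_obs, n * m - u_obs)
    for combo in combinations(range(1, n + m + 1), n):
        u = sum(combo) - n * (n + 1) / 2
        total += 1
        if u >= hi or u <= lo:
            extreme += 1
    return extreme / total


def exhaustive_branch_scan(intron: str, weights, search_min: int, search_max: int):
    """Naive branch-point search: score every eligible adenosine heptamer.

    ``weights`` is a (7, 4) array over A,C,G,T with the branch A at heptamer
    index 5. Returns (distance_from_3ss, score) for the best candidate with
    ties to the smallest distance, or None.
    """
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(intron)
    candidates = []
    for i, base in enumerate(intron.upper()):
        if base != "A":
            continue
        d = L - i
        if not (search_min <= d <= search_max):
            continue
        if i - 5 < 0 or i + 1 >= L:
            continue
        hept = intron[i - 5 : i + 2].upper()
        if any(ch not in base_idx for ch in hept):
            continue
        score = sum(weights[k][base_idx[ch]] for k, ch in enumerate(hept))
        candidates.append((score, -d))
    if not candidates:
        return None
    score, neg_d = max(candidates)
    return (-neg_d, score)


def brute_force_internal_pool(exons_5to3, strand, event_spans):
    """Valid internal-control windows by direct interval arithmetic.

    ``exons_5to3`` are genomic (start, end) pairs in transcript order;
    returns the list of window indices k whose full genomic span (from the
    leftmost to the rightmost coordinate of exons k..k+2) overlaps no event
    span.
    """
    valid = []
    for k in range(len(exons_5to3) - 2):
        trio = exons_5to3[k : k + 3]
        lo = min(s for s, _ in trio)
        hi = max(e for _, e in trio)
        if all(not (lo < ev_hi and ev_lo < hi) for ev_lo, ev_hi in event_spans):
            valid.append(k)
    return valid


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def random_exon_chain(rng, n_exons, exon_len=(30, 150), intron_len=(30, 400)):
    """Non-overlapping genomic exon intervals separated by introns >= 1."""
    exons = []
    pos = int(rng.integers(0, 500))
    for _ in range(n_exons):
        length = int(rng.integers(*exon_len))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(*intron_len))
    return exons
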