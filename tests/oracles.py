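"""Independent reference implementations used to cross-check the library.

Everything here is written directly from the definitions — plain loops,
exhaustive enumeration, brute force — and deliberately shares no code
with the package.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}
SEED = range(2, 14)  # miRNA positions 2..13


def seed_w(i: int) -> float:
    return 2.0 if i in SEED else 1.0


def pair_penalty(m: str, t: str) -> float:
    if (m, t) in WC:
        return 0.0
    if (m, t) in WOBBLE:
        return 0.5
    return 1.0


def brute_force_expectation(
    mirna: str, site: str, bulge: Optional[Tuple[str, int]]
) -> float:
    """Penalty sum computed position by position from the definitions.

    `bulge` is None, ("target", anchor) or ("mirna", pos).  Site is the
    mRNA 5'->3'; miRNA position i pairs site position L-i+1 when
    ungapped, shifted around the bulge otherwise.
    """
    L = len(mirna)
    M = len(site)
    total = 0.0
    if bulge is None:
        assert M == L
        for i in range(1, L + 1):
            total += seed_w(i) * pair_penalty(mirna[i - 1], site[L - i])
    elif bulge[0] == "target":
        a = bulge[1]
        assert M == L + 1
        total += seed_w(a) * 2.0
        for i in range(1, L + 1):
            j = (M - i + 1) if i <= a else (M - i)
            total += seed_w(i) * pair_penalty(mirna[i - 1], site[j - 1])
    else:
        b = bulge[1]
        assert M == L - 1
        total += seed_w(b) * 2.0
        for i in range(1, L + 1):
            if i == b:
                continue
            j = (M - i + 1) if i < b else (M - i + 2)
            total += seed_w(i) * pair_penalty(mirna[i - 1], site[j - 1])
    return total


# ---------------------------------------------------------------------------
# nested-structure enumeration for the accessibility proxy
# ---------------------------------------------------------------------------

PAIR_W = {("G", "C"): 3.0, ("C", "G"): 3.0, ("A", "U"): 2.0,
          ("U", "A"): 2.0, ("G", "U"): 1.0, ("U", "G"): 1.0}


def enumerate_structures(seq: str, min_loop: int = 3) -> List[frozenset]:
    """All nested structures (sets of (i, j) 0-based pairs, loop >= 3)."""

    def rec(positions: tuple) -> List[frozenset]:
        if not positions:
            return [frozenset()]
        first, rest = positions[0], positions[1:]
        out = list(rec(rest))  # first unpaired
        for idx, j in enumerate(rest):
            if j - first <= min_loop:
                continue
            if (seq[first], seq[j]) not in PAIR_W:
                continue
            inside = tuple(p for p in rest[:idx])
            outside = tuple(p for p in rest[idx + 1:])
            for si in rec(inside):
                for so in rec(outside):
                    out.append(si | so | {(first, j)})
        return out

    return rec(tuple(range(len(seq))))


def best_structures(seq: str, min_loop: int = 3):
    """(max total weight, list of optimal structures)."""
    best_w = -1.0
    best: List[frozenset] = []
    for s in enumerate_structures(seq, min_loop):
        w = sum(PAIR_W[(seq[i], seq[j])] for i, j in s)
        if w > best_w + 1e-12:
            best_w, best = w, [s]
        elif abs(w - best_w) <= 1e-12:
            best.append(s)
    return best_w, best


# ---------------------------------------------------------------------------
# genome scanning / interval overlap
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def naive_occurrences(query: str, genome: Dict[str, str],
                      max_mm: int) -> List[tuple]:
    """(chrom, 1-based start, strand, mismatches) by sliding comparison."""
    hits = []
    rc = query.translate(_COMP)[::-1]
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        L = len(query)
        for s in range(len(seq) - L + 1):
            win = seq[s:s + L]
            for strand, q in (("+", query), ("-", rc)):
                mm = sum(1 for a, b in zip(win, q) if a != b)
                if mm <= max_mm:
                    hits.append((chrom, s + 1, strand, mm))
    hits.sort(key=lambda h: (h[0], h[1], h[2] == "-"))
    return hits


def brute_force_overlaps(variants, locations) -> set:
    """{(variant key, site id)} by checking every pair and every base."""
    out = set()
    for v in variants:
        span = range(v.pos, v.pos + len(v.ref))
        for loc in locations:
            if loc.chrom != v.chrom:
                continue
            for g in span:
                if any(lo <= g <= hi for lo, hi in loc.blocks):
                    out.add((v.key, loc.site_id))
                    break
    return out


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def exact_rank_sum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided exact Mann-Whitney P by full enumeration of labelings."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "tie-free samples only"
    na = len(a)
    ranks = {v: r for r, v in enumerate(pooled, start=1)}
    u_obs = sum(ranks[v] for v in a) - na * (na + 1) / 2
    n = len(pooled)
    us = []
    for combo in itertools.combinations(range(n), na):
        ra = sum(c + 1 for c in combo)
        us.append(ra - na * (na + 1) / 2)
    mu = na * (n - na) / 2
    dev = abs(u_obs - mu)
    count = sum(1 for u in us if abs(u - mu) >= dev - 1e-12)
    return count / len(us)


def ols_fit(g: Sequence[float], y: Sequence[float]):
    """(slope, r2) from the textbook normal equations."""
    n = len(g)
    gm = sum(g) / n
    ym = sum(y) / n
    sxx = sum((x - gm) ** 2 for x in g)
    syy = sum((v - ym) ** 2 for v in y)
    sxy = sum((x - gm) * (v - ym) for x, v in zip(g, y))
    slope = sxy / sxx
    r2 = sxy * sxy / (sxx * syy)
    return slope, r2
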