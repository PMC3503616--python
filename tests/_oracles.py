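"""Independent brute-force oracles used by the test suite.

These are deliberately naive (nested loops, Fractions, dict-of-dict
distance matrices) and share no code with the package implementation.
"""

from __future__ import annotations

from fractions import Fraction


def primitive(motif: str) -> bool:
    n = len(motif)
    return not any(n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n))


def brute_mnr(seq: str, min_len: int = 6) -> set[tuple[int, int, str]]:
    out = set()
    n = len(seq)
    s = 0
    while s < n:
        e = s
        while e < n and seq[e] == seq[s]:
            e += 1
        if e - s >= min_len and seq[s] != "N":
            out.add((s, e, seq[s]))
        s = e
    return out


def brute_perfect(seq: str, min_motif: int = 3, max_motif: int = 500,
                  min_copies: int = 3) -> set[tuple[int, int, int]]:
    """All maximal perfect tandem arrays as (start, end, period)."""
    n = len(seq)
    out = set()
    for p in range(min_motif, min(max_motif, n // min_copies) + 1):
        for s in range(n):
            # must be leftmost: not extendable left
            if s - 1 >= 0 and s - 1 + p < n and seq[s - 1] == seq[s - 1 + p] \
                    and seq[s - 1] != "N":
                continue
            e = s + p
            if e > n:
                break
            while e < n and seq[e] == seq[e - p] and seq[e] != "N" and seq[e - p] != "N":
                e += 1
            if "N" in seq[s:e]:
                continue
            if (e - s) // p < min_copies:
                continue
            if not primitive(seq[s : s + p]):
                continue
            out.add((s, e, p))
    return out


def _np_valid(seq: str, s: int, p: int, c: int, sim: Fraction):
    """Validity + (consensus, purity fractions) of a candidate, or None."""
    wins = [seq[s + k * p : s + (k + 1) * p] for k in range(c)]
    if any("N" in w for w in wins):
        return None
    cons = ""
    for col in range(p):
        counts = {}
        for w in wins:
            counts[w[col]] = counts.get(w[col], 0) + 1
        cons += max(sorted(counts), key=lambda b: counts[b])
    idents = [Fraction(sum(x == y for x, y in zip(w, cons)), p) for w in wins]
    if any(i <= sim for i in idents):  # strictly-more-than threshold
        return None
    return cons, idents


def brute_nonperfect(seq: str, min_motif: int = 3, sim: Fraction = Fraction(7, 10),
                     min_copies: int = 3, max_motif: int = 500,
                     include_perfect: bool = False) -> set[tuple[int, int, int, float]]:
    """Maximal valid NP arrays as (start, end, period, purity)."""
    n = len(seq)
    valid_by_p: dict[int, set[tuple[int, int]]] = {}
    for p in range(min_motif, min(max_motif, n // min_copies) + 1):
        vs = set()
        for s in range(n - min_copies * p + 1):
            for c in range(min_copies, (n - s) // p + 1):
                if _np_valid(seq, s, p, c, sim) is not None:
                    vs.add((s, s + c * p))
        valid_by_p[p] = vs
    out = set()
    for p, vs in valid_by_p.items():
        for (a, b) in vs:
            if any(x <= a and b <= y and (x, y) != (a, b) for x, y in vs):
                continue
            cons, idents = _np_valid(seq, a, p, (b - a) // p, sim)
            if not include_perfect and all(i == 1 for i in idents):
                continue
            if not primitive(cons):
                continue
            purity = float(sum(idents) / len(idents))
            out.add((a, b, p, purity))
    return out


def naive_upgma_cophenetic(ids: list[str], d: dict[str, dict[str, float]]):
    """UPGMA by textbook recursion on a dict matrix; returns the cophenetic
    distance dict and the sorted merge heights."""
    clusters = {i: [x] for i, x in enumerate(ids)}
    dist = {(i, j): d[ids[i]][ids[j]] for i in range(len(ids)) for j in range(len(ids)) if i < j}
    coph = {}
    heights = []
    next_id = len(ids)
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1:]:
                key = (min(a, b), max(a, b))
                if best is None or dist[key] < dist[best]:
                    best = key
        a, b = best
        h = dist[best] / 2
        heights.append(h)
        for x in clusters[a]:
            for y in clusters[b]:
                coph[(x, y)] = coph[(y, x)] = 2 * h
        merged = clusters[a] + clusters[b]
        na, nb = len(clusters[a]), len(clusters[b])
        for c in clusters:
            if c in (a, b):
                continue
            ka = (min(a, c), max(a, c))
            kb = (min(b, c), max(b, c))
            dist[(min(next_id, c), max(next_id, c))] = (na * dist[ka] + nb * dist[kb]) / (na + nb)
        del clusters[a], clusters[b]
        clusters[next_id] = merged
        next_id += 1
    return coph, sorted(heights)
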