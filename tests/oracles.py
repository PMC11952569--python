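"""Independent brute-force oracles used to validate the fast implementations.

Each oracle restates the operation's definition in the most literal way
possible (exhaustive enumeration, naive dynamic programming, pairwise loops)
without sharing code with the package.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# zinc fingers


def brute_force_fingers(seq: str):
    """Leftmost, smallest-spacer C2H2 matches by exhaustive position scan.

    Returns a list of (c1, c2, h1, h2) tuples, non-overlapping, N to C.
    """
    hits = []
    i = 0
    n = len(seq)
    while i < n:
        found = None
        for g1 in (2, 3, 4):
            for g2 in (3, 4, 5):
                c1 = i
                c2 = c1 + 1 + g1
                h1 = c2 + 13
                h2 = h1 + 1 + g2
                if h2 >= n:
                    continue
                if (seq[c1] == "C" and seq[c2] == "C" and seq[h1] == "H"
                        and seq[h2] == "H"):
                    found = (c1, c2, h1, h2)
                    break
            if found:
                break
        if found:
            hits.append(found)
            i = found[3] + 1
        else:
            i += 1
    return hits


def brute_force_fingerprint(seq: str, h1: int) -> str:
    """Fingerprint by explicit offset enumeration from the first histidine."""
    offsets = {-1: -7, 2: -5, 3: -4, 6: -1}
    return "".join(seq[h1 + offsets[k]] for k in (-1, 2, 3, 6))


# ---------------------------------------------------------------------------
# repeated label substrings (gene blocks)


def brute_force_blocks(labels, min_len=3, min_occurrences=2):
    """Exhaustive repeated-substring enumeration with reversal awareness.

    Returns a set of (labels_tuple, occurrences_tuple) in the same orientation
    convention as the implementation (leftmost occurrence defines orientation).
    """
    labels = tuple(labels)
    n = len(labels)

    def occ(pattern):
        rev = pattern[::-1]
        L = len(pattern)
        raw = []
        for j in range(n - L + 1):
            w = labels[j : j + L]
            if w == pattern:
                raw.append((j, "forward"))
            elif w == rev:
                raw.append((j, "reversed"))
        chosen, last = [], -1
        for j, o in raw:
            if j >= last:
                chosen.append((j, o))
                last = j + L
        return chosen

    def canon(p):
        return min(p, p[::-1])

    qualifying = {}
    for L in range(min_len, n + 1):
        for j in range(n - L + 1):
            p = canon(labels[j : j + L])
            if p in qualifying:
                continue
            o = occ(p)
            if len(o) >= min_occurrences:
                qualifying[p] = o

    alphabet = sorted(set(labels))
    out = set()
    spans_by_len = {}
    for L in sorted({len(p) for p in qualifying}, reverse=True):
        for p, o in sorted(qualifying.items()):
            if len(p) != L:
                continue
            maximal = True
            for x in alphabet:
                for q in ((x,) + p, p + (x,)):
                    if len(occ(canon(q))) >= len(o):
                        maximal = False
            if not maximal:
                continue
            longer_spans = [
                s for LL, spans in spans_by_len.items() if LL > L for s in spans
            ]
            if longer_spans and all(
                any(s <= j and j + L <= e for s, e in longer_spans)
                for j, _ in o
            ):
                continue
            j0, o0 = o[0]
            seq = p if o0 == "forward" else p[::-1]
            occs = tuple(
                (j, oo if o0 == "forward" else
                 ("forward" if oo == "reversed" else "reversed"))
                for j, oo in o
            )
            out.add((seq, occs))
            spans_by_len.setdefault(L, []).append(None)  # placeholder
            spans_by_len[L] = [
                sp for sp in spans_by_len[L] if sp is not None
            ] + [(j, j + L) for j, _ in occs]
    return out


# ---------------------------------------------------------------------------
# global affine alignment (Gotoh) matching the package's scoring convention


def gotoh_score(a: str, b: str, match=1.0, mismatch=-1.0, gap_open=-2.0,
                gap_extend=-0.5) -> float:
    """Optimal global alignment score; first gap residue costs gap_open,
    each later residue gap_extend (end gaps penalized)."""
    NEG = -1e18
    la, lb = len(a), len(b)
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in b (a aligned to gap)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return float(max(M[la, lb], X[la, lb], Y[la, lb]))


# ---------------------------------------------------------------------------
# contig filtering


def brute_force_contig_filter(records, known_chroms):
    """Literal restatement of the three filtering criteria.

    Returns {contig: (kept, chrom_or_None, flip, reason)}.
    """
    known = set(known_chroms)
    contigs = []
    for r in records:
        if r.query not in contigs:
            contigs.append(r.query)
    info = {}
    for c in contigs:
        recs = [r for r in records if r.query == c and r.target in known]
        if not recs:
            info[c] = None
            continue
        bp = {}
        for r in recs:
            bp[r.target] = bp.get(r.target, 0) + r.aln_len
        best = sorted(bp.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        on = [r for r in recs if r.target == best]
        fp = (min(r.target_start for r in on), max(r.target_end for r in on))
        minus = sum(r.aln_len for r in on if r.strand == "-")
        plus = sum(r.aln_len for r in on if r.strand == "+")
        info[c] = {"chrom": best, "fp": fp, "bp": bp[best], "flip": minus > plus}

    out = {}
    for c in contigs:
        if info[c] is None:
            out[c] = (False, None, False, "unplaced")
    # iterate to fixpoint: drop any contig nested in a kept, higher-priority one
    placed = [c for c in contigs if info[c] is not None]
    prio = sorted(placed, key=lambda c: (-info[c]["bp"], c))
    kept = []
    for c in prio:
        s, e = info[c]["fp"]
        nested = any(
            info[k]["chrom"] == info[c]["chrom"]
            and info[k]["fp"][0] <= s and e <= info[k]["fp"][1]
            for k in kept
        )
        if nested:
            out[c] = (False, info[c]["chrom"], info[c]["flip"], "nested")
        else:
            kept.append(c)
            out[c] = (True, info[c]["chrom"], info[c]["flip"], "kept")
    return out


# ---------------------------------------------------------------------------
# 1-D tie chaining


def brute_force_tie_groups(values, epsilon, min_size):
    """O(n^2) pairwise chaining: connect i~j when |v_i - v_j| <= epsilon and
    no value lies strictly between them; groups = connected components."""
    n = len(values)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            lo, hi = sorted((values[i], values[j]))
            if hi - lo <= epsilon:
                between = any(
                    k not in (i, j) and lo < values[k] < hi for k in range(n)
                )
                # direct link allowed even with values between: chaining will
                # connect through them anyway
                adj[i][j] = True
    seen = [False] * n
    groups = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            x = stack.pop()
            comp.append(x)
            for y in range(n):
                if adj[x][y] and not seen[y]:
                    seen[y] = True
                    stack.append(y)
        if len(comp) >= min_size:
            groups.append(sorted(comp))
    tied = sum(len(g) for g in groups)
    return groups, (tied / n if n else 0.0)
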