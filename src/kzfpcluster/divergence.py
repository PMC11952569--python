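"""Divergence-distribution statistics and duplicated gene-block detection.

Two signatures of segmental duplication are quantified here.

*Tie groups*: TE copies created by duplication inherit the accumulated
divergence of their template, so a locus expanded by duplication shows groups
of copies with nearly identical percent divergence, against the genome-wide
continuum produced by independent insertions.  ``tie_groups`` finds such
groups by 1-D single linkage and ``tie_group_test`` compares the locus
tied-fraction to draws from the genome-wide values.

*Gene blocks*: runs of adjacent genes whose paralog labels (from 3'-exon
sequence identity) recur elsewhere in the cluster, in the same or inverted
order, evidence duplication of multi-gene segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .enrichment import _midpoint_in
from .io import GenomicInterval, RepeatCopy


@dataclass
class DivergenceProfile:
    family: str
    locus_values: list
    genome_values: list
    absent: bool = False


@dataclass
class TieGroupResult:
    groups: list  # of (center percent, member indices into the values list)
    tied_fraction: float
    n_values: int
    epsilon: float
    min_size: int
    p_resample: float | None = None
    n_resample: int = 0


@dataclass
class GeneBlock:
    labels: tuple
    occurrences: list  # of (start gene index, orientation 'forward'|'reversed')

    @property
    def length(self) -> int:
        return len(self.labels)


def divergence_profiles(repeats: list[RepeatCopy], locus: GenomicInterval,
                        families: list[str]) -> list[DivergenceProfile]:
    """Per family: divergence values of locus copies (midpoint rule) and of
    all genome copies."""
    if not families:
        raise ValueError("families must be nonempty")
    out = []
    for family in families:
        fam = [rc for rc in repeats if rc.family == family]
        genome_vals = [rc.pct_divergence for rc in fam]
        locus_vals = [
            rc.pct_divergence for rc in fam if _midpoint_in(rc.interval, locus)
        ]
        out.append(
            DivergenceProfile(family, locus_vals, genome_vals, absent=not fam)
        )
    return out


def tie_groups(values, epsilon: float = 0.2, min_size: int = 3) -> TieGroupResult:
    """1-D single-linkage groups of near-identical divergence values.

    Values are sorted and chained while consecutive gaps are <= epsilon;
    chains with >= min_size members become groups.  tied_fraction is the
    fraction of input values belonging to any group.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    values = list(values)
    n = len(values)
    if n < min_size:
        return TieGroupResult([], 0.0, n, epsilon, min_size)
    order = sorted(range(n), key=lambda i: values[i])
    groups = []
    chain = [order[0]]
    for prev, cur in zip(order, order[1:]):
        if values[cur] - values[prev] <= epsilon:
            chain.append(cur)
        else:
            if len(chain) >= min_size:
                groups.append(chain)
            chain = [cur]
    if len(chain) >= min_size:
        groups.append(chain)
    tied = sum(len(g) for g in groups)
    result_groups = [
        (float(np.mean([values[i] for i in g])), sorted(g)) for g in groups
    ]
    return TieGroupResult(result_groups, tied / n, n, epsilon, min_size)


def tie_group_test(profile: DivergenceProfile, epsilon: float = 0.2,
                   min_size: int = 3, n_resample: int = 1000,
                   seed: int = 0) -> TieGroupResult:
    """Resampling test of locus tie structure against the genome continuum.

    The null draws |locus| values without replacement from the genome-wide
    values (locus copies are themselves genome copies, preserving the finite
    population) and recomputes the tied fraction; the +1-corrected p-value is
    (1 + #{null >= observed}) / (n_resample + 1).
    """
    loc = np.asarray(profile.locus_values, dtype=float)
    gen = np.asarray(profile.genome_values, dtype=float)
    if len(loc) < min_size:
        raise ValueError("need at least min_size locus values")
    if len(gen) < len(loc):
        raise ValueError("genome values fewer than locus values")
    obs_res = tie_groups(loc, epsilon, min_size)
    rng = np.random.default_rng(seed)
    null = np.empty(n_resample)
    for k in range(n_resample):
        draw = rng.choice(gen, size=len(loc), replace=False)
        null[k] = _tied_fraction_sorted(np.sort(draw), epsilon, min_size)
    p = (1.0 + float(np.sum(null >= obs_res.tied_fraction))) / (n_resample + 1.0)
    obs_res.p_resample = p
    obs_res.n_resample = n_resample
    return obs_res


def _tied_fraction_sorted(sv: np.ndarray, epsilon: float, min_size: int) -> float:
    """Tied fraction of an already-sorted value array (fast inner loop)."""
    n = len(sv)
    if n < min_size:
        return 0.0
    gaps = np.diff(sv) <= epsilon
    tied = 0
    run = 1
    for g in gaps:
        if g:
            run += 1
        else:
            if run >= min_size:
                tied += run
            run = 1
    if run >= min_size:
        tied += run
    return tied / n


# ---------------------------------------------------------------------------
# 3'-exon identity, paralog clustering, gene blocks

#: global pairwise alignment scoring used for 3'-exon identity (the first
#: residue of a gap costs the open score; subsequent residues the extend score)
ALN_MATCH = 1.0
ALN_MISMATCH = -1.0
ALN_GAP_OPEN = -2.0
ALN_GAP_EXTEND = -0.5


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = ALN_MATCH
    aligner.mismatch_score = ALN_MISMATCH
    aligner.open_gap_score = ALN_GAP_OPEN
    aligner.extend_gap_score = ALN_GAP_EXTEND
    return aligner


def align_score(a: str, b: str) -> float:
    """Optimal global affine-gap alignment score of two DNA sequences."""
    if not a or not b:
        raise ValueError("empty sequence")
    return float(_make_aligner().score(a, b))


def exon3_identity(seqs: list[str]) -> np.ndarray:
    """Pairwise global-alignment identity matrix.

    identity(i, j) = matched columns / total alignment columns of one optimal
    global alignment; the matrix is symmetric with unit diagonal.
    """
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences")
    if any(not s for s in seqs):
        raise ValueError("empty sequence")
    aligner = _make_aligner()
    n = len(seqs)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(seqs[i], seqs[j])[0]
            counts = aln.counts()
            ident = counts.identities / aln.length
            mat[i, j] = mat[j, i] = ident
    return mat


def cluster_paralogs(matrix: np.ndarray, threshold: float = 0.95) -> list[str]:
    """Single-linkage paralog labels from an identity matrix.

    Genes are connected when identity >= threshold; connected components get
    labels 'A', 'B', ... in order of first occurrence along the input
    (i.e. locus coordinate) order.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    mat = np.asarray(matrix)
    n = mat.shape[0]
    if mat.shape != (n, n):
        raise ValueError("matrix must be square")
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] >= threshold:
                parent[find(i)] = find(j)
    label_of_root: dict[int, str] = {}
    labels = []
    for i in range(n):
        r = find(i)
        if r not in label_of_root:
            label_of_root[r] = _alpha_label(len(label_of_root))
        labels.append(label_of_root[r])
    return labels


def _alpha_label(k: int) -> str:
    out = ""
    k += 1
    while k:
        k, rem = divmod(k - 1, 26)
        out = chr(ord("A") + rem) + out
    return out


def find_blocks(labels, min_len: int = 3, min_occurrences: int = 2
                ) -> list[GeneBlock]:
    """Maximal repeated label substrings (duplicated gene blocks).

    A block is a label sequence of length >= min_len occurring >=
    min_occurrences times in the ordered label string, counting reversed-order
    occurrences (inverted duplications).  Occurrences are selected greedily
    left-to-right without overlap.  A block must be maximal: every one-label
    extension has strictly fewer occurrences.  Shorter blocks nested in
    longer reported blocks are reported only if at least one occurrence falls
    outside all longer-block occurrences (partial duplications).
    """
    labels = tuple(labels)
    if not labels:
        raise ValueError("labels must be nonempty")
    n = len(labels)
    occ_count_cache: dict[tuple, list] = {}

    def occurrences(pattern: tuple) -> list:
        """Greedy non-overlapping occurrences of pattern or its reverse."""
        if pattern in occ_count_cache:
            return occ_count_cache[pattern]
        rev = pattern[::-1]
        L = len(pattern)
        hits = []
        for j in range(n - L + 1):
            window = labels[j : j + L]
            if window == pattern:
                hits.append((j, "forward"))
            elif window == rev:
                hits.append((j, "reversed"))
        chosen = []
        last_end = -1
        for j, ori in hits:
            if j >= last_end:
                chosen.append((j, ori))
                last_end = j + L
        occ_count_cache[pattern] = chosen
        return chosen

    def canon(pattern: tuple) -> tuple:
        return min(pattern, pattern[::-1])

    # collect qualifying canonical patterns per length
    qualifying: dict[int, dict[tuple, list]] = {}
    for L in range(min_len, n + 1):
        seen = set()
        for j in range(n - L + 1):
            pat = canon(labels[j : j + L])
            if pat in seen:
                continue
            seen.add(pat)
            occ = occurrences(pat)
            if len(occ) >= min_occurrences:
                qualifying.setdefault(L, {})[pat] = occ

    blocks: list[GeneBlock] = []
    reported_spans: list[tuple[int, int]] = []  # (start, end) of longer blocks
    alphabet = sorted(set(labels))
    for L in sorted(qualifying, reverse=True):
        for pat, occ in sorted(qualifying[L].items()):
            # maximality: every one-label extension loses an occurrence
            maximal = True
            for ext in _extensions(pat, alphabet):
                if len(occurrences(canon(ext))) >= len(occ):
                    maximal = False
                    break
            if not maximal:
                continue
            # partial-duplication gate against longer reported blocks
            if reported_spans:
                outside = any(
                    not any(s <= j and j + L <= e for s, e in reported_spans)
                    for j, _ in occ
                )
                if not outside:
                    continue
            # orient the reported label sequence by its leftmost occurrence
            j0, ori0 = occ[0]
            seq = pat if ori0 == "forward" else pat[::-1]
            occs = [
                (j, ori if ori0 == "forward" else
                 ("forward" if ori == "reversed" else "reversed"))
                for j, ori in occ
            ]
            blocks.append(GeneBlock(seq, occs))
        reported_spans.extend(
            (j, j + b.length) for b in blocks if b.length == L for j, _ in b.occurrences
        )
    blocks.sort(key=lambda b: (b.occurrences[0][0], -b.length))
    return blocks


def _extensions(pattern: tuple, alphabet):
    for x in alphabet:
        yield (x,) + pattern
        yield pattern + (x,)
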