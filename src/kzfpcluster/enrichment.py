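"""TE enrichment statistics, permutation tests and peak filtering.

The central quantity is the bp-ratio enrichment of a TE family at a locus:

    ratio = (bp of family in locus / locus length)
          / (bp of family genome-wide / genome length)

with bp counted on the union of the family's copy intervals (RepeatMasker
tables routinely contain fragmented or nested hits).  Significance is
assessed by a permutation test that uniformly re-places either the locus
(single-region TE enrichment) or the query interval set (peak-vs-TE tests)
within an allowed placement space, with the +1-corrected empirical p-value
p = (1 + #{null >= obs}) / (n_perm + 1) and the normal-deviate Z-score
against the permutation null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .intervals import MergedSet, clip_to, union_bp
from .io import GenomicInterval, Peak, RepeatCopy


@dataclass
class EnrichmentResult:
    family: str
    bp_in_locus: int
    locus_len: int
    bp_genome: int
    genome_len: int
    ratio: float | None
    log2_ratio: float | None
    undefined: bool = False
    p_perm: float | None = None
    z_score: float | None = None
    n_perm: int = 0


@dataclass
class PermConfig:
    n_perm: int = 1000
    mode: str = "randomize_locus"  # or "randomize_query"
    seed: int = 0
    allowed_space: list | None = None  # of GenomicInterval

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.mode not in {"randomize_locus", "randomize_query"}:
            raise ValueError(f"unknown permutation mode {self.mode!r}")


@dataclass
class PermResult:
    observed: float
    p_perm: float
    z_score: float | None
    null_mean: float
    null_sd: float
    n_perm: int


def locus_genome_percent(locus_bp: float, genome_bp: float) -> float:
    """Percent of the genome occupied by a locus (e.g. 5.4 Mb of 2.53 Gb)."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    return 100.0 * locus_bp / genome_bp


def composition(repeats: list[RepeatCopy], space: GenomicInterval) -> dict:
    """Per-class union bp and fraction of the queried space.

    Classes absent from ``repeats`` simply do not appear; classes present but
    with no overlap report 0.
    """
    if len(space) <= 0:
        raise ValueError("zero-length space")
    out: dict[str, dict] = {}
    for te_class in sorted({rc.te_class for rc in repeats}):
        ivs = [rc.interval for rc in repeats if rc.te_class == te_class]
        bp = union_bp(clip_to(ivs, space))
        out[te_class] = {"bp": bp, "fraction": bp / len(space)}
    return out


def enrichment(repeats: list[RepeatCopy], family: str, locus: GenomicInterval,
               genome_len: int) -> EnrichmentResult:
    """bp-ratio enrichment of one family at one locus (no permutation)."""
    locus_len = len(locus)
    if not (genome_len >= locus_len > 0):
        raise ValueError("require genome_len >= locus length > 0")
    fam_ivs = [rc.interval for rc in repeats if rc.family == family]
    bp_genome = union_bp(fam_ivs)
    bp_locus = union_bp(clip_to(fam_ivs, locus))
    if bp_genome == 0:
        return EnrichmentResult(family, 0, locus_len, 0, genome_len,
                                None, None, undefined=True)
    ratio = (bp_locus / locus_len) / (bp_genome / genome_len)
    log2 = math.log2(ratio) if ratio > 0 else float("-inf")
    return EnrichmentResult(family, bp_locus, locus_len, bp_genome,
                            genome_len, ratio, log2)


def _placement_arrays(allowed_space, lengths: np.ndarray, rng: np.random.Generator,
                      n_perm: int, seq_constraint: list | None = None):
    """Uniformly re-place intervals of the given lengths within allowed_space.

    Returns (seq_ids, starts[n_perm, n], ends[n_perm, n]).  Each interval is
    placed uniformly over all valid start positions across the allowed
    intervals (optionally restricted to its own sequence), independently per
    permutation.
    """
    n = len(lengths)
    seq_out = [None] * n
    starts = np.empty((n_perm, n), dtype=np.int64)
    for j in range(n):
        L = int(lengths[j])
        cand = [
            iv for iv in allowed_space
            if len(iv) >= L and (seq_constraint is None or iv.seq_id == seq_constraint[j])
        ]
        if not cand:
            raise ValueError(
                f"allowed_space has no interval able to host a {L} bp span"
            )
        weights = np.array([len(iv) - L + 1 for iv in cand], dtype=float)
        probs = weights / weights.sum()
        choice = rng.choice(len(cand), size=n_perm, p=probs)
        offs = rng.random(n_perm)
        for k, iv in enumerate(cand):
            sel = choice == k
            span = len(iv) - L + 1
            starts[sel, j] = iv.start + (offs[sel] * span).astype(np.int64)
        # a single query sequence per column keeps the statistic well defined
        seq_out[j] = cand[0].seq_id if len({iv.seq_id for iv in cand}) == 1 else None
        if seq_out[j] is None:
            # mixed sequences: remember per-permutation assignment
            seq_out[j] = [cand[k].seq_id for k in choice]
    return seq_out, starts


def permutation_test(query: list[GenomicInterval], reference: list[GenomicInterval],
                     config: PermConfig) -> PermResult:
    """Permutation test of query/reference overlap.

    ``randomize_locus``: statistic is the union-overlap bp between query and
    reference; the query set is uniformly re-placed within ``allowed_space``
    preserving lengths.  ``randomize_query``: statistic is the number of query
    intervals overlapping the reference by >= 1 bp; re-placement additionally
    preserves each interval's sequence assignment.
    """
    if not query or not reference:
        raise ValueError("query and reference must be nonempty")
    allowed = config.allowed_space
    if not allowed:
        raise ValueError("allowed_space must be nonempty")
    rng = np.random.default_rng(config.seed)
    ref = MergedSet(reference)
    lengths = np.array([len(iv) for iv in query], dtype=np.int64)

    count_mode = config.mode == "randomize_query"
    seq_constraint = [iv.seq_id for iv in query] if count_mode else None

    # observed statistic
    obs = 0.0
    for iv in query:
        qs = np.array([iv.start])
        qe = np.array([iv.end])
        if count_mode:
            obs += float(ref.hits(iv.seq_id, qs, qe)[0])
        else:
            obs += float(ref.overlap_bp(iv.seq_id, qs, qe)[0])

    seq_ids, starts = _placement_arrays(
        allowed, lengths, rng, config.n_perm, seq_constraint
    )
    null = np.zeros(config.n_perm)
    for j in range(len(query)):
        qs = starts[:, j]
        qe = qs + lengths[j]
        sj = seq_ids[j]
        if isinstance(sj, list):
            vals = np.zeros(config.n_perm)
            for seq in set(sj):
                mask = np.array([s == seq for s in sj])
                fn = ref.hits if count_mode else ref.overlap_bp
                vals[mask] = fn(seq, qs[mask], qe[mask]).astype(float)
        else:
            fn = ref.hits if count_mode else ref.overlap_bp
            vals = fn(sj, qs, qe).astype(float)
        null += vals

    p = (1.0 + float(np.sum(null >= obs))) / (config.n_perm + 1.0)
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    z = (obs - mean) / sd if sd > 0 else None
    return PermResult(obs, p, z, mean, sd, config.n_perm)


def family_fraction(repeats: list[RepeatCopy], family: str,
                    locus: GenomicInterval, unit: str = "count") -> float:
    """Percent of a family's annotations falling within the locus.

    ``unit='count'`` (default) counts annotation records whose midpoint lies
    in the locus; ``unit='bp'`` is the union-bp analogue.
    """
    fam = [rc for rc in repeats if rc.family == family]
    if not fam:
        raise ValueError(f"family {family!r} has no genome-wide copies")
    if unit == "count":
        n_in = sum(1 for rc in fam if _midpoint_in(rc.interval, locus))
        return 100.0 * n_in / len(fam)
    elif unit == "bp":
        ivs = [rc.interval for rc in fam]
        total = union_bp(ivs)
        return 100.0 * union_bp(clip_to(ivs, locus)) / total
    raise ValueError(f"unknown unit {unit!r}")


def _midpoint_in(iv: GenomicInterval, locus: GenomicInterval) -> bool:
    if iv.seq_id != locus.seq_id:
        return False
    mid = (iv.start + iv.end) // 2
    return locus.start <= mid < locus.end


def select_families(repeats: list[RepeatCopy], locus: GenomicInterval,
                    min_frac: float = 2.0, min_copies: int = 10) -> list[str]:
    """Families with > min_frac percent of their annotations in the locus AND
    > min_copies annotation records in the locus, sorted by fraction
    descending (family name breaks ties deterministically)."""
    selected = []
    for family in sorted({rc.family for rc in repeats}):
        fam = [rc for rc in repeats if rc.family == family]
        n_in = sum(1 for rc in fam if _midpoint_in(rc.interval, locus))
        frac = 100.0 * n_in / len(fam)
        if frac > min_frac and n_in > min_copies:
            selected.append((frac, family))
    selected.sort(key=lambda t: (-t[0], t[1]))
    return [family for _, family in selected]


def filter_peaks(peaks: list[Peak], control_peaks: list[Peak],
                 q_max: float = 0.01, fe_primary: float = 10.0,
                 fe_fallback: float = 5.0, min_peaks: int = 20) -> list[Peak]:
    """Control-overlap removal followed by q/fold-enrichment thresholding.

    Any peak overlapping any control peak by >= 1 bp is removed first.  Peaks
    are then kept at q <= q_max and fold enrichment >= fe_primary; if fewer
    than min_peaks survive, the fold-enrichment cutoff falls back to
    fe_fallback.
    """
    if control_peaks:
        ctrl = MergedSet([p.interval for p in control_peaks])
        free = [
            p for p in peaks
            if not ctrl.hits(
                p.interval.seq_id,
                np.array([p.interval.start]),
                np.array([p.interval.end]),
            )[0]
        ]
    else:
        free = list(peaks)
    primary = [p for p in free if p.q_value <= q_max and p.fold_enrichment >= fe_primary]
    if len(primary) < min_peaks:
        return [p for p in free if p.q_value <= q_max and p.fold_enrichment >= fe_fallback]
    return primary
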