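"""Generative model of KZFP gene-cluster expansion by ERV-anchored NAHR.

The model evolves a single linear genome containing one repeat-rich gene
cluster through discrete generations.  Each generation applies three steps:

1. *Insertion*: each TE family gains Poisson(rate) new copies genome-wide;
   each new copy lands inside the cluster with probability ``cluster_bias``
   (else uniformly in the cluster's complement), never interrupting a gene.
2. *NAHR*: pairs of same-family, same-orientation TE copies that are close
   (<= ``max_pair_dist``) and still similar enough to provide microhomology
   (divergences within ``microhomology_tol`` of each other and each below
   ``max_anchor_div``) may trigger a non-allelic homologous recombination
   event.  With probability ``p_dup_given_nahr`` the span between the two
   anchor starts is duplicated in tandem — carrying every contained gene and
   TE copy with its *current* divergence and sequences — otherwise it is
   deleted (the right anchor survives as the hybrid copy).  At most one event
   is applied per generation (the first triggered pair in coordinate order).
3. *Mutation*: every TE copy's percent divergence grows by a Gamma(shape=2,
   mean=mu) increment; gene 3'-exon DNA and finger-array protein sequences
   mutate per site with probability ``exon_mu``.

TE copies are annotation objects (family, strand, length, divergence), not
nucleotide sequences; gene 3'-exons and finger arrays are explicit sequences
so the fingerprint and paralog analyses can run on simulator output.  An
event log records every change with enough detail that replaying it from the
initial state reproduces the final genome exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import fingerprints as fp
from .io import (
    GenomicInterval,
    RepeatCopy,
    write_bed,
    write_repeatmasker_out,
)

SEQ_ID = "chr4"

DNA = "ACGT"
#: residues used for random fingerprint positions; C and H are excluded so
#: that generated arrays never gain spurious zinc-coordinating residues
FP_ALPHABET = "ADEGIKLMNQRSTV"

#: 21-residue canonical C2H2 finger with placeholders for the fingerprint
#: residues at helix -1, +2, +3, +6 (indices 9, 11, 12, 15); the structural
#: residues -3 F (index 7) and +4 L (index 13) are fixed
_FINGER_TEMPLATE = "CPECGKAFS{0}S{1}{2}L R{3}HIRTH".replace(" ", "")
#: inter-finger linker; the Y at its index 5 provides the -12 F/Y position
LINKER = "TGEKPYA"
N_TERM = "MYA"


@dataclass(frozen=True)
class TeFamily:
    name: str
    te_class: str
    consensus_len: int
    insertion_rate: float  # expected new copies per generation, genome-wide
    cluster_bias: float    # probability that a new copy lands in the cluster


def _default_families():
    # ERV families the cluster is enriched for, plus a background LINE;
    # rates are desk-scale free parameters, not estimates of mouse rates
    return [
        TeFamily("MLTR18A_MM", "LTR", 600, 0.020, 0.15),
        TeFamily("MMTV-int", "LTR", 900, 0.014, 0.15),
        TeFamily("RLTR13D3", "LTR", 450, 0.010, 0.15),
        TeFamily("L1Md_T", "LINE", 5000, 0.010, 0.1),
    ]


@dataclass
class SimulationConfig:
    genome_len: int = 10_000_000
    cluster: GenomicInterval = field(
        default_factory=lambda: GenomicInterval(SEQ_ID, 4_900_000, 5_100_000)
    )
    n_init_genes: int = 8
    init_line_density: float = 25.0  # copies per Mb inside the cluster
    te_families: list = field(default_factory=_default_families)
    p_nahr: float = 4e-4
    p_dup_given_nahr: float = 0.8
    mu: float = 0.005        # percentage points of divergence per generation
    exon_mu: float = 1e-5    # substitutions per site per generation
    generations: int = 3000
    seed: int = 0
    max_pair_dist: int = 25_000
    microhomology_tol: float = 5.0  # max |divergence difference| of anchors
    max_anchor_div: float = 20.0    # anchors older than this never recombine
    gene_len: int = 4000
    exon3_len: int = 600
    fingers_min: int = 3
    fingers_max: int = 8
    dup_mode: str = "tandem"  # or "scatter"
    #: mutation ticks are bulky (one per generation); disable their logging
    #: for long exploratory runs where replay is not needed
    log_mutations: bool = True

    def __post_init__(self):
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        for p in (self.p_nahr, self.p_dup_given_nahr):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        if self.mu < 0 or self.exon_mu < 0:
            raise ValueError("mutation rates must be >= 0")
        if not (0 <= self.cluster.start and self.cluster.end <= self.genome_len):
            raise ValueError("cluster must lie within the genome")
        for fam in self.te_families:
            if fam.insertion_rate < 0 or not (0 <= fam.cluster_bias <= 1):
                raise ValueError(f"invalid rates for family {fam.name}")


@dataclass
class Segment:
    kind: str              # gene | te | neutral
    length: int
    copy_id: int
    in_cluster: bool
    strand: str = "+"
    family: str = ""       # te: family name; gene: gene_id
    te_class: str = ""
    birth_gen: int = 0
    pct_divergence: float = 0.0
    origin: str = "ancestral"  # ancestral | insertion | duplication
    exon3_seq: str = ""
    finger_seq: str = ""


@dataclass
class Event:
    generation: int
    type: str  # insert | duplicate | delete | mutate_tick
    params: dict


@dataclass
class EvolvedGenome:
    config: SimulationConfig
    segments: list
    log: list = field(default_factory=list)
    next_id: int = 0
    dup_counter: int = 0
    #: derived per-family TE arrays; rebuilt lazily after structural events
    _te_cache: dict | None = field(default=None, repr=False, compare=False)

    # -- bookkeeping -------------------------------------------------------

    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    def te_cache(self) -> dict:
        if self._te_cache is None:
            self._te_cache = _build_te_cache(self)
        return self._te_cache

    def sync_divergences(self) -> None:
        """Write cached divergence arrays back onto the Segment objects."""
        if self._te_cache is None:
            return
        for grp in self._te_cache["groups"].values():
            for sg, d in zip(grp["segs"], grp["div"]):
                sg.pct_divergence = float(d)

    def invalidate_cache(self) -> None:
        self.sync_divergences()
        self._te_cache = None

    def starts(self) -> np.ndarray:
        lens = np.fromiter((s.length for s in self.segments), dtype=np.int64,
                           count=len(self.segments))
        return np.concatenate([[0], np.cumsum(lens)])[:-1]

    def cluster_span(self) -> GenomicInterval | None:
        starts = self.starts()
        lo, hi = None, None
        for st, seg in zip(starts, self.segments):
            if seg.in_cluster:
                lo = int(st) if lo is None else lo
                hi = int(st + seg.length)
        if lo is None:
            return None
        return GenomicInterval(SEQ_ID, lo, hi)

    def by_id(self, copy_id: int) -> Segment:
        for seg in self.segments:
            if seg.copy_id == copy_id:
                return seg
        raise KeyError(copy_id)

    def repeat_copies(self) -> list[RepeatCopy]:
        self.sync_divergences()
        out = []
        starts = self.starts()
        for st, seg in zip(starts, self.segments):
            if seg.kind == "te":
                out.append(
                    RepeatCopy(
                        GenomicInterval(SEQ_ID, int(st), int(st + seg.length),
                                        seg.strand),
                        family=seg.family,
                        te_class=seg.te_class,
                        pct_divergence=min(seg.pct_divergence, 100.0),
                    )
                )
        return out

    def genes(self) -> list[tuple[GenomicInterval, Segment]]:
        out = []
        starts = self.starts()
        for st, seg in zip(starts, self.segments):
            if seg.kind == "gene":
                out.append(
                    (GenomicInterval(SEQ_ID, int(st), int(st + seg.length),
                                     seg.strand), seg)
                )
        return out

    def expected_length_from_log(self) -> int:
        """Length-conservation identity assertable from the event log."""
        total = self.config.genome_len
        for ev in self.log:
            if ev.type == "insert":
                total += ev.params["length"]
            elif ev.type == "duplicate":
                total += ev.params["span"]
            elif ev.type == "delete":
                total -= ev.params["span"]
        return total

    def new_copy_id(self) -> int:
        cid = self.next_id
        self.next_id += 1
        return cid


# ---------------------------------------------------------------------------
# initialisation


def init_genome(config: SimulationConfig, rng: np.random.Generator | None = None
                ) -> EvolvedGenome:
    """Seed the genome: genes and LINE copies inside the cluster, neutral
    sequence elsewhere; all divergences zero."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    g = EvolvedGenome(config, [])
    clen = len(config.cluster)
    n_lines = int(round(config.init_line_density * clen / 1e6))
    line_family = next(
        (f for f in config.te_families if f.te_class == "LINE"),
        TeFamily("L1_sim", "LINE", 5000, 0.0, 0.0),
    )
    items = []
    for i in range(config.n_init_genes):
        items.append(("gene", i))
    for i in range(n_lines):
        items.append(("line", i))
    occupied = (
        config.n_init_genes * config.gene_len + n_lines * line_family.consensus_len
    )
    if occupied > clen:
        raise ValueError(
            f"cluster ({clen} bp) too small for {config.n_init_genes} genes "
            f"and {n_lines} LINE copies ({occupied} bp)"
        )
    if not items:
        g.segments.append(
            Segment("neutral", config.genome_len, g.new_copy_id(), False)
        )
        return g

    order = rng.permutation(len(items))
    slack = clen - occupied
    gaps = rng.multinomial(slack, [1.0 / (len(items) + 1)] * (len(items) + 1))

    if config.cluster.start > 0:
        g.segments.append(
            Segment("neutral", config.cluster.start, g.new_copy_id(), False)
        )
    for k, idx in enumerate(order):
        if gaps[k] > 0:
            g.segments.append(
                Segment("neutral", int(gaps[k]), g.new_copy_id(), True)
            )
        kind, i = items[idx]
        if kind == "gene":
            gene_id = f"g{i:03d}"
            exon3 = "".join(
                DNA[b] for b in rng.integers(0, 4, size=config.exon3_len)
            )
            nf = int(rng.integers(config.fingers_min, config.fingers_max + 1))
            finger_seq = _random_finger_array(rng, nf)
            g.segments.append(
                Segment("gene", config.gene_len, g.new_copy_id(), True,
                        strand="+", family=gene_id, exon3_seq=exon3,
                        finger_seq=finger_seq)
            )
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            g.segments.append(
                Segment("te", line_family.consensus_len, g.new_copy_id(), True,
                        strand=strand, family=line_family.name,
                        te_class=line_family.te_class)
            )
    if gaps[len(items)] > 0:
        g.segments.append(
            Segment("neutral", int(gaps[len(items)]), g.new_copy_id(), True)
        )
    if config.cluster.end < config.genome_len:
        g.segments.append(
            Segment("neutral", config.genome_len - config.cluster.end,
                    g.new_copy_id(), False)
        )
    return g


def _random_finger_array(rng: np.random.Generator, n_fingers: int) -> str:
    parts = [N_TERM]
    for k in range(n_fingers):
        if k > 0:
            parts.append(LINKER)
        res = [FP_ALPHABET[j] for j in rng.integers(0, len(FP_ALPHABET), size=4)]
        parts.append(_FINGER_TEMPLATE.format(*res))
    return "".join(parts)


# ---------------------------------------------------------------------------
# event application (shared by the simulation steps and by replay)


def _find_segment_at(genome: EvolvedGenome, position: int) -> int:
    starts = genome.starts()
    idx = int(np.searchsorted(starts, position, side="right")) - 1
    if idx < 0 or position >= genome.total_length():
        raise ValueError(f"position {position} outside genome")
    return idx


def _build_te_cache(genome: EvolvedGenome) -> dict:
    """Per-(family, strand) TE coordinate/divergence arrays plus the
    distance-eligible anchor-pair structure, in global coordinate order.

    Only the divergence values change between structural events, so this is
    rebuilt on insert/duplicate/delete and merely updated by mutation.
    """
    cfg = genome.config
    starts = genome.starts()
    grouped: dict[tuple, list] = {}
    for i, seg in enumerate(genome.segments):
        if seg.kind == "te":
            grouped.setdefault((seg.family, seg.strand), []).append(i)
    keys_sorted = sorted(grouped)
    n_te = sum(len(v) for v in grouped.values())
    divcat = np.empty(n_te)  # shared buffer; group 'div' entries are views
    groups = {}
    pair_ls, pair_rs, pair_key, pair_gl, pair_gr = [], [], [], [], []
    off = 0
    for key in keys_sorted:
        idxs = grouped[key]
        segs = [genome.segments[i] for i in idxs]
        m = len(idxs)
        s = np.array([int(starts[i]) for i in idxs], dtype=np.int64)
        e = s + np.array([sg.length for sg in segs], dtype=np.int64)
        divcat[off : off + m] = [sg.pct_divergence for sg in segs]
        groups[key] = {"segs": segs, "start": s, "div": divcat[off : off + m]}
        if m >= 2:
            hi = np.searchsorted(s, e + cfg.max_pair_dist, side="right")
            counts = np.maximum(hi - np.arange(m) - 1, 0)
            if counts.sum() > 0:
                left = np.repeat(np.arange(m), counts)
                offs = np.concatenate(
                    [np.arange(1, c + 1) for c in counts if c > 0]
                )
                right = left + offs
                pair_ls.append(s[left])
                pair_rs.append(s[right])
                pair_key.extend([key] * len(left))
                pair_gl.append(left + off)
                pair_gr.append(right + off)
        off += m
    if pair_ls:
        ls = np.concatenate(pair_ls)
        rs = np.concatenate(pair_rs)
        gl = np.concatenate(pair_gl)
        gr = np.concatenate(pair_gr)
        order = np.lexsort((rs, ls))
        keys = [pair_key[i] for i in order]
        pairs = {"ls": ls[order], "rs": rs[order], "gl": gl[order],
                 "gr": gr[order], "keys": keys}
    else:
        pairs = None
    return {"groups": groups, "pairs": pairs, "divcat": divcat}


def _apply_insert(genome: EvolvedGenome, params: dict) -> None:
    genome.invalidate_cache()
    pos = params["position"]
    idx = _find_segment_at(genome, pos)
    host = genome.segments[idx]
    if host.kind == "gene":
        raise ValueError("insertion position inside a gene")
    starts = genome.starts()
    offset = pos - int(starts[idx])
    new_te = Segment(
        "te", params["length"], genome.new_copy_id(), params["in_cluster"],
        strand=params["strand"], family=params["family"],
        te_class=params["te_class"], birth_gen=params["generation"],
        origin="insertion",
    )
    if offset == 0:
        genome.segments.insert(idx, new_te)
    else:
        right = replace(host, length=host.length - offset,
                        copy_id=genome.new_copy_id())
        host.length = offset
        genome.segments[idx + 1 : idx + 1] = [new_te, right]


def _span_indices(genome: EvolvedGenome, left_start: int, right_start: int
                  ) -> tuple[int, int]:
    starts = genome.starts()
    li = int(np.searchsorted(starts, left_start))
    ri = int(np.searchsorted(starts, right_start))
    if starts[li] != left_start or starts[ri] != right_start:
        raise ValueError("NAHR span boundaries must be segment starts")
    return li, ri


def _apply_duplicate(genome: EvolvedGenome, params: dict) -> None:
    genome.invalidate_cache()
    li, ri = _span_indices(genome, params["left_start"], params["right_start"])
    copies = []
    copied_te_families = set()
    for seg in genome.segments[li:ri]:
        c = replace(seg, copy_id=genome.new_copy_id(),
                    birth_gen=params["generation"], origin="duplication")
        if c.kind == "gene":
            genome.dup_counter += 1
            c.family = f"{seg.family}_d{genome.dup_counter}"
        elif c.kind == "te":
            copied_te_families.add(c.family)
        copies.append(c)
    genome.segments[ri:ri] = copies
    params["copied_te_families"] = sorted(copied_te_families)
    params["n_copied_genes"] = sum(1 for c in copies if c.kind == "gene")


def _apply_delete(genome: EvolvedGenome, params: dict) -> None:
    genome.invalidate_cache()
    li, ri = _span_indices(genome, params["left_start"], params["right_start"])
    del genome.segments[li:ri]


def _apply_gene_muts(genome: EvolvedGenome, gene_muts: list) -> None:
    lookup = {s.copy_id: s for s in genome.segments if s.kind == "gene"}
    for cid, which, pos, new_char in gene_muts:
        seg = lookup[cid]
        attr = "exon3_seq" if which == "exon3" else "finger_seq"
        s = getattr(seg, attr)
        setattr(seg, attr, s[:pos] + new_char + s[pos + 1 :])


def _apply_mutation(genome: EvolvedGenome, params: dict) -> None:
    """Replay path: apply a logged mutation tick to the Segment objects."""
    if params["te_ids"]:
        lookup = {s.copy_id: s for s in genome.segments if s.kind == "te"}
        for cid, delta in zip(params["te_ids"], params["te_deltas"]):
            lookup[cid].pct_divergence += delta
    if params["gene_muts"]:
        _apply_gene_muts(genome, params["gene_muts"])


# ---------------------------------------------------------------------------
# per-generation steps


def step_insertion(genome: EvolvedGenome, rng: np.random.Generator,
                   generation: int = 0) -> None:
    """Poisson insertions for every TE family (in configuration order)."""
    cfg = genome.config
    for fam in cfg.te_families:
        if fam.insertion_rate <= 0:
            continue
        n_new = int(rng.poisson(fam.insertion_rate))
        for _ in range(n_new):
            params = _draw_insertion(genome, fam, rng, generation)
            if params is None:
                continue
            _apply_insert(genome, params)
            genome.log.append(Event(generation, "insert", params))


def _draw_insertion(genome: EvolvedGenome, fam: TeFamily,
                    rng: np.random.Generator, generation: int):
    cluster = genome.cluster_span()
    total = genome.total_length()
    in_cluster = cluster is not None and rng.random() < fam.cluster_bias
    for _ in range(1000):
        if in_cluster:
            pos = int(rng.integers(cluster.start, cluster.end))
        elif cluster is None:
            pos = int(rng.integers(0, total))
        else:
            outside = total - len(cluster)
            if outside <= 0:
                return None
            pos = int(rng.integers(0, outside))
            if pos >= cluster.start:
                pos += len(cluster)
        idx = _find_segment_at(genome, pos)
        if genome.segments[idx].kind != "gene":
            strand = "+" if rng.random() < 0.5 else "-"
            flag = cluster is not None and cluster.start <= pos < cluster.end
            return {
                "generation": generation,
                "position": pos,
                "length": fam.consensus_len,
                "strand": strand,
                "family": fam.name,
                "te_class": fam.te_class,
                "in_cluster": flag,
            }
    return None  # genome saturated with genes; skip this insertion


def step_nahr(genome: EvolvedGenome, rng: np.random.Generator,
              generation: int = 0) -> None:
    """Trigger at most one NAHR duplication/deletion per generation.

    A pair is eligible when both copies share family and strand, the gap
    between them is <= max_pair_dist, their divergences differ by at most
    the microhomology tolerance and neither exceeds max_anchor_div.  Each
    eligible pair triggers independently with p_nahr; the first triggered
    pair in left-to-right coordinate order is applied.
    """
    cfg = genome.config
    if cfg.p_nahr <= 0:
        return
    cache = genome.te_cache()
    pairs = cache["pairs"]
    if pairs is None:
        return
    # divergence eligibility per pair, against the live shared buffer
    dl = cache["divcat"][pairs["gl"]]
    dr = cache["divcat"][pairs["gr"]]
    ok = (
        (np.abs(dl - dr) <= cfg.microhomology_tol)
        & (dl <= cfg.max_anchor_div)
        & (dr <= cfg.max_anchor_div)
    )
    n_ok = int(ok.sum())
    if n_ok == 0:
        return
    draws = rng.random(n_ok)
    hit = np.nonzero(draws < cfg.p_nahr)[0]
    if len(hit) == 0:
        return
    pair_idx = np.nonzero(ok)[0][int(hit[0])]
    family = pairs["keys"][pair_idx][0]
    left_start = int(pairs["ls"][pair_idx])
    right_start = int(pairs["rs"][pair_idx])
    duplicate = rng.random() < cfg.p_dup_given_nahr
    params = {
        "generation": generation,
        "left_start": left_start,
        "right_start": right_start,
        "family": family,
        "span": right_start - left_start,
    }
    if duplicate:
        _apply_duplicate(genome, params)
        genome.log.append(Event(generation, "duplicate", params))
    else:
        _apply_delete(genome, params)
        genome.log.append(Event(generation, "delete", params))


def step_mutation(genome: EvolvedGenome, rng: np.random.Generator,
                  generation: int = 0) -> None:
    """Divergence gain for every TE copy; per-site gene sequence mutation.

    Divergence increments are applied to the cached per-family arrays; the
    Segment objects are kept in sync per generation when mutation logging is
    on, and lazily (at the next structural event or read-out) when it is off.
    """
    cfg = genome.config
    te_ids, te_deltas = [], []
    if cfg.mu > 0:
        cache = genome.te_cache()
        for key in sorted(cache["groups"]):
            grp = cache["groups"][key]
            m = len(grp["div"])
            if m == 0:
                continue
            deltas = rng.gamma(2.0, cfg.mu / 2.0, size=m)
            grp["div"] += deltas
            if cfg.log_mutations:
                for sg, d in zip(grp["segs"], deltas):
                    sg.pct_divergence += float(d)
                te_ids.extend(sg.copy_id for sg in grp["segs"])
                te_deltas.extend(float(d) for d in deltas)
    gene_muts = []
    if cfg.exon_mu > 0:
        gene_segs = [s for s in genome.segments if s.kind == "gene"]
        if gene_segs:
            lens = np.array(
                [len(s.exon3_seq) for s in gene_segs]
                + [len(s.finger_seq) for s in gene_segs]
            )
            hits = rng.binomial(lens, cfg.exon_mu)
            for pos_in_list in np.nonzero(hits)[0]:
                seg = gene_segs[pos_in_list % len(gene_segs)]
                which = "exon3" if pos_in_list < len(gene_segs) else "finger"
                s = seg.exon3_seq if which == "exon3" else seg.finger_seq
                k = int(hits[pos_in_list])
                positions = rng.choice(len(s), size=k, replace=False)
                for pos in sorted(int(p) for p in positions):
                    if which == "exon3":
                        choices = [c for c in DNA if c != s[pos]]
                    else:
                        choices = [
                            c for c in sorted(fp.AMINO_ACIDS) if c != s[pos]
                        ]
                    new_char = choices[int(rng.integers(0, len(choices)))]
                    gene_muts.append((seg.copy_id, which, pos, new_char))
    if gene_muts:
        _apply_gene_muts(genome, gene_muts)
    if cfg.log_mutations and (te_ids or gene_muts):
        params = {
            "generation": generation,
            "te_ids": te_ids,
            "te_deltas": te_deltas,
            "gene_muts": gene_muts,
        }
        genome.log.append(Event(generation, "mutate_tick", params))


# ---------------------------------------------------------------------------
# top level


def simulate(config: SimulationConfig) -> EvolvedGenome:
    """Initialise then run ``generations`` rounds of insertion, NAHR and
    mutation; fully deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genome = init_genome(config, rng)
    for gen in range(1, config.generations + 1):
        step_insertion(genome, rng, gen)
        step_nahr(genome, rng, gen)
        step_mutation(genome, rng, gen)
    genome.sync_divergences()
    return genome


def replay(config: SimulationConfig, log: list) -> EvolvedGenome:
    """Rebuild the final genome by re-applying the event log to the initial
    state; no randomness is consumed beyond initialisation."""
    genome = init_genome(config)
    for ev in log:
        if ev.type == "insert":
            _apply_insert(genome, ev.params)
        elif ev.type == "duplicate":
            _apply_duplicate(genome, ev.params)
        elif ev.type == "delete":
            _apply_delete(genome, ev.params)
        elif ev.type == "mutate_tick":
            _apply_mutation(genome, ev.params)
        else:
            raise ValueError(f"unknown event type {ev.type}")
        genome.log.append(ev)
    return genome


def genomes_equal(a: EvolvedGenome, b: EvolvedGenome) -> bool:
    if len(a.segments) != len(b.segments):
        return False
    return all(sa == sb for sa, sb in zip(a.segments, b.segments))


# ---------------------------------------------------------------------------
# export


def export(genome: EvolvedGenome, out_dir) -> dict:
    """Write the analysis-stage inputs: repeats.out, genes.bed, exon3.fasta,
    fingers.fasta, locus.bed.  Returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "repeats": out_dir / "repeats.out",
        "genes": out_dir / "genes.bed",
        "exon3": out_dir / "exon3.fasta",
        "fingers": out_dir / "fingers.fasta",
        "locus": out_dir / "locus.bed",
    }
    write_repeatmasker_out(
        genome.repeat_copies(), paths["repeats"], seq_len=genome.total_length()
    )
    gene_rows = genome.genes()
    write_bed([iv for iv, _ in gene_rows], paths["genes"],
              names=[seg.family for _, seg in gene_rows])
    with open(paths["exon3"], "w") as fh:
        for _, seg in gene_rows:
            fh.write(f">{seg.family}\n{seg.exon3_seq}\n")
    with open(paths["fingers"], "w") as fh:
        for _, seg in gene_rows:
            fh.write(f">{seg.family}\n{seg.finger_seq}\n")
    span = genome.cluster_span()
    with open(paths["locus"], "w") as fh:
        if span is not None:
            fh.write(f"{span.seq_id}\t{span.start}\t{span.end}\tcluster\t0\t+\n")
    return paths
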