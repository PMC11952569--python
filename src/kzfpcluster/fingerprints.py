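"""C2H2 zinc-finger detection, fingerprint extraction and repertoire comparison.

A C2H2 zinc finger is matched as ``C-x(2,4)-C-x(12)-H-x(3,5)-H``.  The four
*fingerprint* residues sit on the recognition helix at positions -1, +2, +3
and +6 (helical nomenclature), i.e. at offsets -7, -5, -4 and -1 from the
first histidine of the H..H pair.  The exact, ordered concatenation of all
fingerprints in a protein (its *fingerprint array*) is the identity key used
to compare KZFP repertoires between assemblies.

Fingers are additionally classified by the conservation of the structural
residues: a finger missing one of the two zinc-coordinating C or H residues
is a ``chz_mutant`` ("red"); one with an intact C2H2 scaffold but a mutation
at -12 (F/Y), -3 (F) or +4 (L) is a ``structural_mutant`` ("yellow").
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: canonical finger period (21-residue finger + 7-residue linker)
FINGER_PERIOD = 28

STATUS_INTACT = "intact"
STATUS_CHZ = "chz_mutant"
STATUS_STRUCT = "structural_mutant"


@dataclass
class ZincFinger:
    """One detected (or rescued) finger within a protein sequence."""

    protein_id: str
    start: int            # index of the first C (or its expected position)
    c1: int
    c2: int
    first_his: int
    h2: int
    residues: str         # sequence slice start..h2 inclusive
    status: str = STATUS_INTACT
    rescued: bool = False
    truncated: bool = False

    @property
    def end(self) -> int:
        """Exclusive end index in the protein."""
        return self.h2 + 1


@dataclass
class FingerprintArray:
    protein_id: str
    fingers: list  # of (fingerprint: str, status: str)
    is_kzfp: bool = True

    @property
    def signature(self) -> str:
        return "|".join(fp for fp, _ in self.fingers)

    def signature_intact_only(self) -> str:
        return "|".join(fp for fp, st in self.fingers if st == STATUS_INTACT)


@dataclass
class RepertoireComparison:
    """Venn-style partition of fingerprint-array signatures over assemblies."""

    assemblies: list
    # mapping frozenset(assembly names) -> list of (signature, {assembly: count})
    cells: dict = field(default_factory=dict)

    def shared_signatures(self) -> list:
        full = frozenset(self.assemblies)
        return [sig for sig, _ in self.cells.get(full, [])]

    def unique_signatures(self, assembly: str) -> list:
        return [sig for sig, _ in self.cells.get(frozenset([assembly]), [])]


def _check_sequence(seq: str) -> None:
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")


def detect_fingers(protein_seq: str, protein_id: str = "", rescue: bool = True
                   ) -> list[ZincFinger]:
    """Locate C2H2 fingers, N to C, non-overlapping.

    The primary scan walks left to right; at each C it tries the C-x(2,4)-C-
    x(12)-H-x(3,5)-H geometry with the smallest spacer lengths first, accepts
    the first fit and resumes after its last histidine.  A rescue pass (on by
    default) then looks for degenerate fingers in gaps between, before or
    after canonical fingers whose size matches the canonical ~28-residue
    stride, relaxing the C/H requirement; rescued fingers are classified by
    :func:`classify_finger` (typically chz_mutant).
    """
    _check_sequence(protein_seq)
    fingers: list[ZincFinger] = []
    i = 0
    n = len(protein_seq)
    while i < n:
        hit = _match_at(protein_seq, i)
        if hit is None:
            i += 1
            continue
        c1, c2, h1, h2 = hit
        zf = ZincFinger(
            protein_id, c1, c1, c2, h1, h2,
            residues=protein_seq[c1 : h2 + 1],
        )
        classify_finger(zf, protein_seq)
        fingers.append(zf)
        i = h2 + 1
    if rescue and fingers:
        fingers = _rescue_pass(protein_seq, protein_id, fingers)
    return fingers


def _match_at(seq: str, i: int):
    """Try a canonical finger anchored at position i; smallest spacers win."""
    if seq[i] != "C":
        return None
    for g1 in (2, 3, 4):
        c2 = i + 1 + g1
        if c2 >= len(seq) or seq[c2] != "C":
            continue
        h1 = c2 + 13
        if h1 >= len(seq) or seq[h1] != "H":
            continue
        for g2 in (3, 4, 5):
            h2 = h1 + 1 + g2
            if h2 < len(seq) and seq[h2] == "H":
                return (i, c2, h1, h2)
    return None


def _rescue_pass(seq: str, protein_id: str, canonical: list[ZincFinger]
                 ) -> list[ZincFinger]:
    """Fill stride-sized gaps between/flanking canonical fingers.

    A candidate is attempted when the unoccupied stretch is consistent with
    exactly one missing finger at the canonical period (+/-3 residues).  The
    candidate copies the internal C/C/H/H spacing of its nearest canonical
    neighbour; residues at those positions may be anything (the point of the
    rescue) and the finger is classified accordingly.
    """
    rescued: list[ZincFinger] = []

    def attempt(c1: int, template: ZincFinger):
        off_c2 = template.c2 - template.c1
        off_h1 = template.first_his - template.c1
        off_h2 = template.h2 - template.c1
        h2 = c1 + off_h2
        if c1 < 0 or h2 >= len(seq):
            return
        for zf in canonical + rescued:
            if not (h2 < zf.c1 or c1 > zf.h2):  # overlap
                return
        zf = ZincFinger(
            protein_id, c1, c1, c1 + off_c2, c1 + off_h1, h2,
            residues=seq[c1 : h2 + 1], rescued=True,
        )
        classify_finger(zf, seq)
        rescued.append(zf)

    # gaps between consecutive canonical fingers: one extra period missing
    for prev, nxt in zip(canonical, canonical[1:]):
        stride = nxt.start - prev.start
        if abs(stride - 2 * FINGER_PERIOD) <= 3:
            attempt(prev.start + round(stride / 2), prev)
    # N-terminal flank
    first = canonical[0]
    if FINGER_PERIOD - 3 <= first.start <= FINGER_PERIOD + 10:
        attempt(first.start - FINGER_PERIOD, first)
    # C-terminal flank
    last = canonical[-1]
    tail = len(seq) - last.end
    if FINGER_PERIOD - 3 <= tail <= FINGER_PERIOD + 10:
        attempt(last.start + FINGER_PERIOD, last)

    return sorted(canonical + rescued, key=lambda z: z.start)


def extract_fingerprint(finger: ZincFinger) -> str:
    """The 4 fingerprint residues (-1, +2, +3, +6) of one finger.

    Helix position -1 is 7 residues before the first histidine, +2 is 5
    before, +3 is 4 before and +6 is 1 before.
    """
    base = finger.first_his - finger.start
    if base - 7 < 0:
        raise ValueError("malformed finger: helix start precedes finger start")
    r = finger.residues
    return r[base - 7] + r[base - 5] + r[base - 4] + r[base - 1]


def classify_finger(finger: ZincFinger, protein_seq: str) -> str:
    """Assign intact / chz_mutant / structural_mutant status (in place).

    chz_mutant: any of the two C or two H positions lacks the expected
    residue (takes precedence).  structural_mutant: -12 not in {F, Y}, or
    -3 != F, or +4 != L (offsets -18, -9, -3 from the first histidine).
    Fingers whose -12 position falls before the start of the protein cannot
    be certified and are classified as degenerate (chz_mutant) with the
    ``truncated`` flag set.
    """
    h = finger.first_his
    s = protein_seq
    if (
        s[finger.c1] != "C"
        or s[finger.c2] != "C"
        or s[h] != "H"
        or s[finger.h2] != "H"
    ):
        finger.status = STATUS_CHZ
        return finger.status
    if h - 18 < 0:
        finger.truncated = True
        finger.status = STATUS_CHZ
        return finger.status
    if s[h - 18] not in "FY" or s[h - 9] != "F" or s[h - 3] != "L":
        finger.status = STATUS_STRUCT
        return finger.status
    finger.status = STATUS_INTACT
    return finger.status


def build_array(protein_id: str, protein_seq: str, rescue: bool = True
                ) -> FingerprintArray:
    """Detect, extract and classify all fingers of one protein."""
    fingers = detect_fingers(protein_seq, protein_id, rescue=rescue)
    entries = [(extract_fingerprint(zf), zf.status) for zf in fingers]
    return FingerprintArray(protein_id, entries, is_kzfp=bool(entries))


def compare_repertoires(assemblies: dict[str, list[FingerprintArray]],
                        intact_only: bool = False) -> RepertoireComparison:
    """Partition fingerprint-array signatures by the assemblies carrying them.

    Signatures are compared by exact string equality; each partition cell
    records per-assembly copy counts (arrays from the same assembly with the
    same signature are multiple gene copies).  Proteins with zero fingers
    (non-KZFPs) are excluded.
    """
    names = list(assemblies)
    if len(names) < 2:
        raise ValueError("compare_repertoires needs >= 2 assemblies")
    if len(set(names)) != len(names):
        raise ValueError("duplicate assembly names")
    counters = {}
    for name, arrays in assemblies.items():
        sigs = []
        for arr in arrays:
            if not arr.is_kzfp:
                continue
            sig = arr.signature_intact_only() if intact_only else arr.signature
            if sig:
                sigs.append(sig)
        counters[name] = Counter(sigs)
    cells: dict = {}
    all_sigs = set().union(*(set(c) for c in counters.values())) if counters else set()
    for sig in sorted(all_sigs):
        members = frozenset(n for n in names if counters[n][sig] > 0)
        counts = {n: counters[n][sig] for n in members}
        cells.setdefault(members, []).append((sig, counts))
    return RepertoireComparison(names, cells)
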