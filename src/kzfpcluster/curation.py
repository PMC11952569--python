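"""Reference-guided contig curation and the KZFP-unit conservation census.

Contig filtering follows three rules applied to contig-to-reference PAF
alignments: (i) contigs with no alignment to a known chromosome are dropped;
(ii) a contig aligning to several chromosomes is assigned to the one with the
largest total aligned bp; (iii) a contig whose reference footprint is fully
contained in a larger kept contig's footprint on the same chromosome is
dropped as nested.  Contigs whose aligned bp are mostly on the minus strand
are flagged for strand flipping.

The census partitions every (species, unit) pair into four conservation
categories: unique to the species; shared only within the focal clade;
shared with other mammals but absent outside mammals; or shared beyond
mammals.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .io import PafRecord, UnitsRow


@dataclass
class ContigDecision:
    contig: str
    kept: bool
    assigned_chrom: str | None
    flip: bool
    reason: str  # unplaced | nested | kept


@dataclass
class CensusResult:
    mode: str  # units | copies
    focal_clade: str
    # species -> {category: count}
    counts: dict

    CATEGORIES = (
        "unique_to_species",
        "clade_shared",
        "mammal_shared",
        "beyond_mammals",
    )


def filter_contigs(paf_records: list[PafRecord], known_chroms: list[str],
                   exclude_contigs: list[str] | None = None
                   ) -> list[ContigDecision]:
    """Apply the three filtering criteria plus strand-flip calls.

    ``exclude_contigs`` supports dataset-specific removals (e.g. fragmented
    sex-chromosome contigs) without changing the rules.
    """
    if not known_chroms:
        raise ValueError("known_chroms must be nonempty")
    known = set(known_chroms)
    exclude = set(exclude_contigs or [])

    by_contig: dict[str, list[PafRecord]] = defaultdict(list)
    for rec in paf_records:
        by_contig[rec.query].append(rec)

    decisions: dict[str, ContigDecision] = {}
    assigned: dict[str, dict] = {}
    for contig, recs in by_contig.items():
        if contig in exclude:
            decisions[contig] = ContigDecision(contig, False, None, False, "unplaced")
            continue
        placed = [r for r in recs if r.target in known]
        if not placed:
            decisions[contig] = ContigDecision(contig, False, None, False, "unplaced")
            continue
        bp_per_chrom: dict[str, int] = defaultdict(int)
        for r in placed:
            bp_per_chrom[r.target] += r.aln_len
        # largest total aligned bp wins; name order breaks ties
        chrom = min(bp_per_chrom, key=lambda c: (-bp_per_chrom[c], c))
        on_chrom = [r for r in placed if r.target == chrom]
        footprint = (
            min(r.target_start for r in on_chrom),
            max(r.target_end for r in on_chrom),
        )
        minus_bp = sum(r.aln_len for r in on_chrom if r.strand == "-")
        plus_bp = sum(r.aln_len for r in on_chrom if r.strand == "+")
        assigned[contig] = {
            "chrom": chrom,
            "footprint": footprint,
            "aligned_bp": bp_per_chrom[chrom],
            "flip": minus_bp > plus_bp,
        }

    # nested removal per chromosome: larger aligned bp has priority; a contig
    # contained in an already-kept footprint is dropped
    by_chrom: dict[str, list[str]] = defaultdict(list)
    for contig, info in assigned.items():
        by_chrom[info["chrom"]].append(contig)
    for chrom, contigs in by_chrom.items():
        order = sorted(contigs, key=lambda c: (-assigned[c]["aligned_bp"], c))
        kept_footprints: list[tuple[int, int]] = []
        for contig in order:
            s, e = assigned[contig]["footprint"]
            nested = any(ks <= s and e <= ke for ks, ke in kept_footprints)
            info = assigned[contig]
            if nested:
                decisions[contig] = ContigDecision(
                    contig, False, chrom, info["flip"], "nested"
                )
            else:
                kept_footprints.append((s, e))
                decisions[contig] = ContigDecision(
                    contig, True, chrom, info["flip"], "kept"
                )
    # stable output order: input first-appearance order
    seen = []
    for rec in paf_records:
        if rec.query not in seen:
            seen.append(rec.query)
    return [decisions[c] for c in seen]


def census(units: list[UnitsRow], clade_map: dict[str, dict],
           focal_clade: str, mode: str = "units") -> CensusResult:
    """Assign each (species, unit) pair to a conservation category.

    ``clade_map`` maps species -> {'clade': str, 'is_mammal': bool}.  For a
    species s carrying unit u with carrier set C:

    - unique_to_species: C == {s}
    - clade_shared: another focal-clade species carries u and no carrier is
      outside the focal clade
    - mammal_shared: a mammal outside the focal clade carries u and no
      carrier is a non-mammal
    - beyond_mammals: otherwise (some carrier is a non-mammal)

    ``mode='units'`` counts each (species, unit) once; ``mode='copies'``
    weights by the species' copy_count for that unit.
    """
    if mode not in {"units", "copies"}:
        raise ValueError(f"unknown census mode {mode!r}")
    for row in units:
        if row.species not in clade_map:
            raise ValueError(f"species {row.species!r} missing from clade_map")

    carriers: dict[str, set] = defaultdict(set)
    for row in units:
        carriers[row.unit_id].add(row.species)

    counts: dict[str, dict] = {}
    for row in sorted(units, key=lambda r: (r.species, r.unit_id)):
        s = row.species
        crs = carriers[row.unit_id]
        others = crs - {s}
        info = {sp: clade_map[sp] for sp in crs}
        outside_clade = [sp for sp in crs if info[sp]["clade"] != focal_clade]
        non_mammal = [sp for sp in crs if not info[sp]["is_mammal"]]
        if not others:
            cat = "unique_to_species"
        elif not outside_clade and any(
            info[sp]["clade"] == focal_clade for sp in others
        ):
            cat = "clade_shared"
        elif not non_mammal:
            cat = "mammal_shared"
        else:
            cat = "beyond_mammals"
        weight = row.copy_count if mode == "copies" else 1
        per = counts.setdefault(
            s, {c: 0 for c in CensusResult.CATEGORIES}
        )
        per[cat] += weight
    return CensusResult(mode, focal_clade, counts)
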