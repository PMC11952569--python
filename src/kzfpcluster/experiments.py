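"""Reproducible simulation experiments over the cluster-expansion model.

These drivers tie the simulator to the statistics modules: power and
type-I-error experiments for the divergence tie-group test, calibration of
the interval permutation test, and enrichment summaries on simulated
clusters.  They are used both by the test suite and by the reproduction
script.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass

import numpy as np

from . import divergence as dvg
from . import enrichment as enr
from .io import GenomicInterval
from .simulate import SimulationConfig, simulate


@dataclass
class TieRunResult:
    seed: int
    family: str | None
    n_dup_events: int
    n_locus: int = 0
    n_genome: int = 0
    tied_fraction: float | None = None
    p_resample: float | None = None


def _qualifying_ltr_family(genome, min_events: int = 3, min_outside: int = 10):
    """The LTR family to test in one run, or None.

    A family qualifies when >= min_events logged duplication events copied at
    least one of its copies.  Among qualifying families the one with the most
    locus copies is tested, provided it keeps >= min_outside copies outside
    the locus (the resampling null draws from the genome-wide pool).  LINE
    families are never tested: the initial cluster LINE cohort is born with
    identical divergence and would tie regardless of any duplication history.
    """
    cls = {f.name: f.te_class for f in genome.config.te_families}
    counts = Counter()
    for ev in genome.log:
        if ev.type != "duplicate":
            continue
        for fam in ev.params.get("copied_te_families", []):
            if cls.get(fam) == "LTR":
                counts[fam] += 1
    reps = genome.repeat_copies()
    locus = genome.cluster_span()
    best, best_n = None, -1
    for fam, n in counts.items():
        if n < min_events:
            continue
        prof = dvg.divergence_profiles(reps, locus, [fam])[0]
        nl, ng = len(prof.locus_values), len(prof.genome_values)
        if nl >= 3 and ng - nl >= min_outside and nl > best_n:
            best, best_n = fam, nl
    return best


def tie_group_experiment(n_seeds: int = 50, base_seed: int = 0,
                         p_nahr: float | None = None,
                         n_resample: int = 500,
                         config: SimulationConfig | None = None
                         ) -> list[TieRunResult]:
    """Run the tie-group test over seeded simulations.

    With the default (duplication-active) configuration this measures the
    power of the test on runs whose event log shows >= 3 duplications copying
    a single LTR family; with ``p_nahr=0`` it measures the type-I error under
    the retrotransposition-only null (every run with enough locus copies of
    the most cluster-active LTR family is evaluated).
    """
    base = config if config is not None else SimulationConfig()
    results = []
    for k in range(n_seeds):
        seed = base_seed + k
        overrides = {"seed": seed, "log_mutations": False}
        if p_nahr is not None:
            overrides["p_nahr"] = p_nahr
        cfg = dataclasses.replace(base, **overrides)
        genome = simulate(cfg)
        n_dups = sum(1 for e in genome.log if e.type == "duplicate")
        if cfg.p_nahr > 0:
            fam = _qualifying_ltr_family(genome)
        else:
            fam = next(f.name for f in cfg.te_families if f.te_class == "LTR")
        if fam is None:
            results.append(TieRunResult(seed, None, n_dups))
            continue
        prof = dvg.divergence_profiles(
            genome.repeat_copies(), genome.cluster_span(), [fam]
        )[0]
        nl, ng = len(prof.locus_values), len(prof.genome_values)
        if nl < 3 or ng <= nl:
            results.append(TieRunResult(seed, None, n_dups))
            continue
        res = dvg.tie_group_test(prof, n_resample=n_resample, seed=seed)
        results.append(
            TieRunResult(seed, fam, n_dups, nl, ng, res.tied_fraction,
                         res.p_resample)
        )
    return results


def significant_fraction(results: list[TieRunResult], alpha: float = 0.05
                         ) -> tuple[int, int]:
    """(number significant, number evaluated) among qualifying runs."""
    evaluated = [r for r in results if r.p_resample is not None]
    sig = sum(1 for r in evaluated if r.p_resample < alpha)
    return sig, len(evaluated)


def permutation_calibration(n_replicates: int = 500, n_perm: int = 200,
                            seed: int = 0, n_query: int = 15,
                            n_reference: int = 30,
                            space_len: int = 1_000_000) -> float:
    """Empirical P(p <= 0.05) of the permutation test under a uniform null.

    A fixed reference interval set is drawn once; each replicate places the
    query uniformly at random within the allowed space (the same placement
    distribution the permutation null uses, making the null exact) and runs
    the bp-overlap permutation test.
    """
    rng = np.random.default_rng(seed)
    space = GenomicInterval("chrS", 0, space_len)
    ref_starts = rng.integers(0, space_len - 300, size=n_reference)
    reference = [GenomicInterval("chrS", int(s), int(s) + 300)
                 for s in ref_starts]
    hits = 0
    for rep in range(n_replicates):
        lengths = rng.integers(200, 800, size=n_query)
        starts = [int(rng.integers(0, space_len - L)) for L in lengths]
        query = [GenomicInterval("chrS", s, s + int(L))
                 for s, L in zip(starts, lengths)]
        cfg = enr.PermConfig(n_perm=n_perm, mode="randomize_locus",
                             seed=seed + 1000 + rep, allowed_space=[space])
        res = enr.permutation_test(query, reference, cfg)
        hits += res.p_perm <= 0.05
    return hits / n_replicates


def enrichment_summary(genome, families: list[str] | None = None) -> dict:
    """Per-family bp-ratio enrichment and locus fraction on one simulated
    genome, using the evolved cluster span as the locus."""
    reps = genome.repeat_copies()
    locus = genome.cluster_span()
    genome_len = genome.total_length()
    if families is None:
        families = sorted({rc.family for rc in reps})
    out = {}
    for fam in families:
        res = enr.enrichment(reps, fam, locus, genome_len)
        row = {"ratio": res.ratio, "log2_ratio": res.log2_ratio,
               "undefined": res.undefined}
        if not res.undefined:
            row["locus_fraction_pct"] = enr.family_fraction(
                reps, fam, locus, unit="count"
            )
        out[fam] = row
    return out
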