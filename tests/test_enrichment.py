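"""bp-ratio enrichment, permutation machinery and peak filtering."""

import math

import numpy as np
import pytest

from kzfpcluster import enrichment as enr
from kzfpcluster.io import GenomicInterval, Peak, RepeatCopy


def rc(start, end, family="FAM", te_class="LTR", div=1.0, seq="chr4", strand="+"):
    return RepeatCopy(GenomicInterval(seq, start, end, strand), family,
                      te_class, div)


def peak(start, end, q=0.001, fe=12.0, seq="chr4"):
    return Peak(GenomicInterval(seq, start, end), summit=(end - start) // 2,
                q_value=q, fold_enrichment=fe)


class TestComposition:
    def test_fraction_hand_arithmetic(self):
        space = GenomicInterval("chr4", 0, 1000)
        comp = enr.composition([rc(100, 200)], space)
        assert comp["LTR"]["fraction"] == pytest.approx(0.10)

    def test_no_repeats(self):
        assert enr.composition([], GenomicInterval("c", 0, 100)) == {}

    def test_overlapping_copies_counted_once(self):
        space = GenomicInterval("chr4", 0, 1000)
        comp = enr.composition([rc(0, 100), rc(50, 150)], space)
        assert comp["LTR"]["bp"] == 150

    def test_classes_reported_separately(self):
        space = GenomicInterval("chr4", 0, 1000)
        comp = enr.composition(
            [rc(0, 100, te_class="LTR"), rc(500, 550, te_class="LINE")], space
        )
        assert comp["LTR"]["bp"] == 100 and comp["LINE"]["bp"] == 50


class TestEnrichment:
    def test_uniform_density_gives_ratio_one(self):
        # 10% coverage both inside the 1 kb locus and across the 10 kb genome
        repeats = [rc(i * 1000, i * 1000 + 100) for i in range(10)]
        locus = GenomicInterval("chr4", 0, 1000)
        res = enr.enrichment(repeats, "FAM", locus, 10_000)
        assert res.ratio == 1.0 and res.log2_ratio == 0.0

    def test_toy_ratio_five(self):
        # locus 1 kb of a 10 kb genome; 100 bp in locus, 200 bp genome-wide
        repeats = [rc(0, 100), rc(5000, 5100)]
        res = enr.enrichment(repeats, "FAM", GenomicInterval("chr4", 0, 1000),
                             10_000)
        assert res.ratio == pytest.approx(5.0)
        assert res.log2_ratio == pytest.approx(math.log2(5.0), abs=1e-4)

    def test_family_entirely_inside_locus(self):
        repeats = [rc(100, 300)]
        locus = GenomicInterval("chr4", 0, 1000)
        res = enr.enrichment(repeats, "FAM", locus, 50_000)
        assert res.ratio == pytest.approx(50_000 / 1000)

    def test_absent_family_flagged_not_zero(self):
        res = enr.enrichment([rc(0, 10)], "OTHER",
                             GenomicInterval("chr4", 0, 100), 1000)
        assert res.undefined and res.ratio is None

    def test_scale_invariance(self):
        locus = GenomicInterval("chr4", 0, 1000)
        repeats = [rc(0, 100), rc(5000, 5100)]
        r1 = enr.enrichment(repeats, "FAM", locus, 10_000)
        k = 7
        scaled = [rc(0, 100 * k), rc(5000 * k, 5100 * k)]
        r2 = enr.enrichment(scaled, "FAM",
                            GenomicInterval("chr4", 0, 1000 * k), 10_000 * k)
        assert r1.ratio == pytest.approx(r2.ratio)


class TestLocusGenomePercent:
    def test_percent(self):
        assert enr.locus_genome_percent(54, 1000) == pytest.approx(5.4)

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            enr.locus_genome_percent(1, 0)


class TestPermutationTest:
    def test_identical_query_is_maximally_significant(self):
        reference = [GenomicInterval("chr4", i * 10_000, i * 10_000 + 50)
                     for i in range(5)]
        cfg = enr.PermConfig(n_perm=99, seed=1, allowed_space=[
            GenomicInterval("chr4", 0, 1_000_000)
        ])
        res = enr.permutation_test(reference, reference, cfg)
        assert res.p_perm == pytest.approx(1 / 100)

    def test_reference_covering_space_gives_p_one(self):
        space = GenomicInterval("chr4", 0, 10_000)
        reference = [space]
        query = [GenomicInterval("chr4", 100, 200)]
        cfg = enr.PermConfig(n_perm=50, seed=1, allowed_space=[space])
        res = enr.permutation_test(query, reference, cfg)
        assert res.p_perm == 1.0

    def test_oversized_interval_rejected(self):
        cfg = enr.PermConfig(n_perm=10, seed=0, allowed_space=[
            GenomicInterval("chr4", 0, 50)
        ])
        with pytest.raises(ValueError):
            enr.permutation_test([GenomicInterval("chr4", 0, 99)],
                                 [GenomicInterval("chr4", 0, 10)], cfg)

    def test_count_mode_preserves_sequence_assignment(self):
        # reference only on chrA; chrB queries can never hit it
        reference = [GenomicInterval("chrA", 0, 1000)]
        query = [GenomicInterval("chrA", 100, 200),
                 GenomicInterval("chrB", 100, 200)]
        cfg = enr.PermConfig(
            n_perm=200, mode="randomize_query", seed=3,
            allowed_space=[GenomicInterval("chrA", 0, 1000),
                           GenomicInterval("chrB", 0, 1000)],
        )
        res = enr.permutation_test(query, reference, cfg)
        # chrA query always hits (reference covers chrA space), chrB never
        assert res.observed == 1.0
        assert res.null_mean == pytest.approx(1.0)
        assert res.p_perm == 1.0


class TestFamilyFraction:
    def test_count_unit(self):
        locus = GenomicInterval("chr4", 0, 1000)
        repeats = [rc(i * 10, i * 10 + 5) for i in range(4)] + [
            rc(5000 + i * 10, 5000 + i * 10 + 5) for i in range(12)
        ]
        assert enr.family_fraction(repeats, "FAM", locus) == pytest.approx(25.0)

    def test_all_in_locus(self):
        locus = GenomicInterval("chr4", 0, 1000)
        assert enr.family_fraction([rc(0, 10)], "FAM", locus) == 100.0

    def test_straddling_midpoint_rule(self):
        locus = GenomicInterval("chr4", 0, 1000)
        # midpoint at 1100 -> outside
        repeats = [rc(900, 1300), rc(10, 20)]
        assert enr.family_fraction(repeats, "FAM", locus) == pytest.approx(50.0)

    def test_absent_family_rejected(self):
        with pytest.raises(ValueError):
            enr.family_fraction([], "FAM", GenomicInterval("c", 0, 10))


class TestSelectFamilies:
    def _mk(self, n_locus, n_out, family):
        locus_copies = [rc(i * 20, i * 20 + 10, family=family)
                        for i in range(n_locus)]
        out_copies = [rc(100_000 + i * 20, 100_000 + i * 20 + 10, family=family)
                      for i in range(n_out)]
        return locus_copies + out_copies

    def test_conjunction_of_fraction_and_count(self):
        locus = GenomicInterval("chr4", 0, 10_000)
        # 3% fraction but only 8 locus copies -> excluded
        reps = self._mk(8, 259, "LOWCOUNT")
        assert enr.select_families(reps, locus) == []
        # 2.5% fraction with 11 locus copies -> included
        reps = self._mk(11, 429, "OK")
        assert enr.select_families(reps, locus) == ["OK"]

    def test_sorted_by_fraction_descending(self):
        locus = GenomicInterval("chr4", 0, 10_000)
        reps = self._mk(20, 180, "TEN") + self._mk(15, 285, "FIVE")
        assert enr.select_families(reps, locus) == ["TEN", "FIVE"]


class TestFilterPeaks:
    def test_primary_threshold_retains(self):
        peaks = [peak(i * 1000, i * 1000 + 100) for i in range(25)]
        assert len(enr.filter_peaks(peaks, [])) == 25

    def test_fallback_fires_below_min_peaks(self):
        peaks = [peak(i * 1000, i * 1000 + 100, fe=12.0) for i in range(15)]
        peaks += [peak((15 + i) * 1000, (15 + i) * 1000 + 100, fe=7.0)
                  for i in range(13)]
        peaks += [peak(28_000, 28_100, fe=2.0), peak(29_000, 29_100, fe=3.0)]
        kept = enr.filter_peaks(peaks, [])
        assert len(kept) == 28  # 15 with fe>=10 plus 13 with 5<=fe<10

    def test_one_bp_control_overlap_removes(self):
        p = peak(1000, 1100)
        ctrl = peak(1099, 1200)  # exactly 1 bp overlap
        others = [peak(i * 1000, i * 1000 + 100) for i in range(5, 30)]
        kept = enr.filter_peaks([p] + others, [ctrl])
        assert p not in kept and len(kept) == 25

    def test_monotone_in_fold_enrichment(self):
        rng = np.random.default_rng(5)
        peaks = [
            peak(int(i * 1000), int(i * 1000) + 100, q=0.001,
                 fe=float(rng.uniform(0, 20)))
            for i in range(40)
        ]
        strict = {id(p) for p in enr.filter_peaks(peaks, [], min_peaks=0)}
        loose = {id(p) for p in enr.filter_peaks(peaks, [], min_peaks=10**9)}
        assert strict <= loose


class TestEnrichmentOnSimulatedClusters:
    """Unbiased insertion gives enrichment ~1; cluster-biased insertion plus
    duplication drives anchor-family enrichment above 1."""

    @staticmethod
    def _config(seed, bias, p_nahr):
        import kzfpcluster.simulate as sim

        return sim.SimulationConfig(
            genome_len=1_000_000,
            cluster=GenomicInterval("chr4", 400_000, 600_000),
            n_init_genes=2, init_line_density=0.0,
            te_families=[sim.TeFamily("MLTR18A_MM", "LTR", 600, 0.1, bias)],
            p_nahr=p_nahr, p_dup_given_nahr=0.9, mu=0.01, exon_mu=0.0,
            generations=300, max_pair_dist=25_000, seed=seed,
        )

    def test_null_enrichment_near_one(self):
        import kzfpcluster.simulate as sim

        ratios = []
        for seed in range(100):
            # cluster_bias equal to the cluster's genome share = uniform null
            g = sim.simulate(self._config(seed, bias=0.2, p_nahr=0.0))
            res = enr.enrichment(g.repeat_copies(), "MLTR18A_MM",
                                 g.cluster_span(), g.total_length())
            if not res.undefined:
                ratios.append(res.ratio)
        mean = float(np.mean(ratios))
        se = float(np.std(ratios, ddof=1) / np.sqrt(len(ratios)))
        assert abs(mean - 1.0) <= max(3 * se, 0.05), (mean, se)

    def test_duplication_drives_enrichment_above_one(self):
        import kzfpcluster.simulate as sim

        above = 0
        n = 40
        for seed in range(n):
            g = sim.simulate(self._config(seed, bias=0.6, p_nahr=2e-3))
            res = enr.enrichment(g.repeat_copies(), "MLTR18A_MM",
                                 g.cluster_span(), g.total_length())
            above += (not res.undefined) and res.ratio > 1.0
        assert above / n >= 0.9
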