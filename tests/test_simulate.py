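"""Simulator: initialisation, steps, invariants, determinism, export."""

import numpy as np
import pytest

from kzfpcluster import fingerprints as fps
from kzfpcluster import simulate as sim
from kzfpcluster.io import GenomicInterval, read_intervals, read_repeatmasker_out


def small_config(**kw):
    """Desk-scale config for fast unit tests."""
    defaults = dict(
        genome_len=200_000,
        cluster=GenomicInterval("chr4", 80_000, 120_000),
        n_init_genes=4,
        init_line_density=100.0,
        generations=50,
        seed=0,
    )
    defaults.update(kw)
    return sim.SimulationConfig(**defaults)


class TestInitGenome:
    def test_empty_cluster_single_neutral_segment(self):
        cfg = small_config(n_init_genes=0, init_line_density=0.0)
        g = sim.init_genome(cfg)
        assert len(g.segments) == 1
        assert g.segments[0].kind == "neutral"
        assert g.total_length() == cfg.genome_len

    def test_gene_count(self):
        g = sim.init_genome(small_config(n_init_genes=5))
        assert sum(1 for s in g.segments if s.kind == "gene") == 5
        span = g.cluster_span()
        assert span.start >= 80_000 and span.end <= 120_000

    def test_deterministic_given_seed(self):
        g1 = sim.init_genome(small_config(seed=7))
        g2 = sim.init_genome(small_config(seed=7))
        assert sim.genomes_equal(g1, g2)

    def test_cluster_too_small_rejected(self):
        with pytest.raises(ValueError):
            sim.init_genome(small_config(
                cluster=GenomicInterval("chr4", 80_000, 84_000),
                n_init_genes=5,
            ))

    def test_initial_divergences_zero(self):
        g = sim.init_genome(small_config())
        assert all(s.pct_divergence == 0.0 for s in g.segments)

    def test_gene_finger_arrays_are_detectable_kzfps(self):
        g = sim.init_genome(small_config())
        for _, seg in g.genes():
            arr = fps.build_array(seg.family, seg.finger_seq)
            assert arr.is_kzfp
            assert all(st == fps.STATUS_INTACT for _, st in arr.fingers)


class TestStepInsertion:
    def test_zero_rates_leave_genome_unchanged(self):
        cfg = small_config(te_families=[
            sim.TeFamily("X", "LTR", 100, 0.0, 0.5)
        ])
        g = sim.init_genome(cfg)
        before = [s for s in g.segments]
        rng = np.random.default_rng(0)
        sim.step_insertion(g, rng)
        assert g.segments == before

    def test_full_bias_confines_to_cluster(self):
        cfg = small_config(te_families=[
            sim.TeFamily("X", "LTR", 100, 5.0, 1.0)
        ])
        g = sim.init_genome(cfg)
        rng = np.random.default_rng(1)
        for _ in range(10):
            sim.step_insertion(g, rng)
        span = g.cluster_span()
        for rc in g.repeat_copies():
            if rc.family == "X":
                assert span.start <= rc.interval.start < span.end

    def test_poisson_mean_copy_count(self):
        """Expected insertions over G generations = rate * G (within 3 sigma
        of the Poisson total across seeds)."""
        rate, gens, n_seeds = 0.5, 20, 100
        total = 0
        for seed in range(n_seeds):
            cfg = small_config(
                te_families=[sim.TeFamily("X", "LTR", 100, rate, 0.5)],
                init_line_density=0.0, generations=0, seed=seed,
            )
            g = sim.init_genome(cfg)
            rng = np.random.default_rng(seed + 10_000)
            for _ in range(gens):
                sim.step_insertion(g, rng)
            total += sum(1 for e in g.log if e.type == "insert")
        lam = rate * gens * n_seeds
        assert abs(total - lam) <= 3 * np.sqrt(lam)

    def test_genes_never_disrupted(self):
        cfg = small_config(te_families=[
            sim.TeFamily("X", "LTR", 100, 10.0, 1.0)
        ])
        g = sim.init_genome(cfg)
        n_genes = len(g.genes())
        rng = np.random.default_rng(2)
        for _ in range(20):
            sim.step_insertion(g, rng)
        assert len(g.genes()) == n_genes
        assert all(seg.length == cfg.gene_len for _, seg in g.genes())


def toy_nahr_genome(p_dup):
    """Hand-built 5-segment genome with exactly one eligible anchor pair."""
    cfg = small_config(
        n_init_genes=0, init_line_density=0.0, p_nahr=1.0,
        p_dup_given_nahr=p_dup, max_pair_dist=50_000,
    )
    g = sim.init_genome(cfg)
    # replace the single neutral segment by an explicit layout:
    # [neutral 50k][anchor TE 1k][2 genes 4k each + neutral filler][anchor TE 1k][neutral]
    def mk(**kw):
        kw.setdefault("in_cluster", True)
        return sim.Segment(copy_id=g.new_copy_id(), **kw)
    g.segments = [
        mk(kind="neutral", length=50_000, in_cluster=False),
        mk(kind="te", length=1000, strand="+", family="ANC", te_class="LTR"),
        mk(kind="gene", length=4000, family="gA", exon3_seq="ACGT" * 50,
           finger_seq="M"),
        mk(kind="neutral", length=1000),
        mk(kind="gene", length=4000, family="gB", exon3_seq="TTGG" * 50,
           finger_seq="M"),
        mk(kind="te", length=1000, strand="+", family="ANC", te_class="LTR"),
        mk(kind="neutral", length=139_000, in_cluster=False),
    ]
    return g


class TestStepNahr:
    def test_no_shared_family_no_event(self):
        g = toy_nahr_genome(1.0)
        g.segments[1].family = "OTHER"
        before = list(g.segments)
        sim.step_nahr(g, np.random.default_rng(0))
        assert g.segments == before

    def test_duplication_branch(self):
        g = toy_nahr_genome(p_dup=1.0)
        total0 = g.total_length()
        genes0 = len(g.genes())
        sim.step_nahr(g, np.random.default_rng(0), generation=5)
        # span = left anchor start .. right anchor start = 10 kb
        assert g.total_length() == total0 + 10_000
        assert len(g.genes()) == genes0 + 2
        new_tes = [s for s in g.segments
                   if s.kind == "te" and s.origin == "duplication"]
        assert len(new_tes) == 1
        assert new_tes[0].pct_divergence == g.segments[1].pct_divergence

    def test_deletion_branch(self):
        g = toy_nahr_genome(p_dup=0.0)
        total0 = g.total_length()
        sim.step_nahr(g, np.random.default_rng(0), generation=5)
        assert g.total_length() == total0 - 10_000
        anchors = [s for s in g.segments if s.family == "ANC"]
        assert len(anchors) == 1  # right anchor survives

    def test_diverged_anchors_ineligible(self):
        g = toy_nahr_genome(p_dup=1.0)
        g.segments[1].pct_divergence = 30.0  # beyond max_anchor_div
        before = list(g.segments)
        sim.step_nahr(g, np.random.default_rng(0))
        assert g.segments == before


class TestStepMutation:
    def test_zero_rates_unchanged(self):
        cfg = small_config(mu=0.0, exon_mu=0.0)
        g = sim.init_genome(cfg)
        before = list(g.segments)
        sim.step_mutation(g, np.random.default_rng(0))
        assert g.segments == before and g.log == []

    def test_mean_divergence_growth(self):
        """After G generations mean divergence of ancestral copies is close
        to mu*G (law of large numbers across seeds)."""
        mu, gens = 0.05, 30
        divs = []
        for seed in range(60):
            cfg = small_config(mu=mu, generations=0, seed=seed,
                               n_init_genes=0, init_line_density=200.0)
            g = sim.init_genome(cfg)
            rng = np.random.default_rng(seed + 999)
            for gen in range(gens):
                sim.step_mutation(g, rng, gen)
            divs.extend(s.pct_divergence for s in g.segments if s.kind == "te")
        divs = np.array(divs)
        expect = mu * gens
        se = divs.std(ddof=1) / np.sqrt(len(divs))
        assert abs(divs.mean() - expect) <= 3 * se

    def test_duplicated_copies_identical_then_diverge(self):
        g = toy_nahr_genome(p_dup=1.0)
        g.segments[1].pct_divergence = 4.0
        g.segments[5].pct_divergence = 4.0
        sim.step_nahr(g, np.random.default_rng(0), generation=1)
        pair = [s for s in g.segments if s.family == "ANC"
                and s.pct_divergence == 4.0]
        assert len(pair) >= 2
        rng = np.random.default_rng(1)
        for gen in range(5):
            sim.step_mutation(g, rng, gen)
        anc = [s.pct_divergence for s in g.segments if s.family == "ANC"]
        assert len(set(anc)) == len(anc)  # drifted apart independently


class TestSimulateTopLevel:
    def test_zero_generations_is_init(self):
        cfg = small_config(generations=0)
        assert sim.genomes_equal(sim.simulate(cfg), sim.init_genome(cfg))

    def test_determinism(self):
        cfg = small_config(generations=30)
        assert sim.genomes_equal(sim.simulate(cfg), sim.simulate(cfg))

    def test_replay_reproduces_final_genome(self):
        cfg = small_config(generations=40)
        g = sim.simulate(cfg)
        r = sim.replay(cfg, g.log)
        assert sim.genomes_equal(g, r)

    def test_length_conservation_identity(self):
        for seed in range(5):
            cfg = small_config(generations=40, seed=seed, p_nahr=0.01)
            g = sim.simulate(cfg)
            assert g.total_length() == g.expected_length_from_log()

    def test_duplication_only_grows_deletion_only_shrinks(self):
        base = dict(generations=60, p_nahr=0.01)
        for seed in range(3):
            g = sim.simulate(small_config(p_dup_given_nahr=1.0, seed=seed,
                                          **base))
            span = g.cluster_span()
            assert len(span) >= 40_000
            g = sim.simulate(small_config(p_dup_given_nahr=0.0, seed=seed,
                                          **base))
            span = g.cluster_span()
            assert span is None or len(span) <= 40_000

    def test_divergence_monotone_over_time(self):
        cfg = small_config(generations=0, seed=3)
        g = sim.init_genome(cfg)
        rng = np.random.default_rng(33)
        last = {s.copy_id: s.pct_divergence for s in g.segments}
        for gen in range(30):
            sim.step_insertion(g, rng, gen)
            sim.step_nahr(g, rng, gen)
            sim.step_mutation(g, rng, gen)
            for s in g.segments:
                if s.kind != "te":
                    continue
                if s.copy_id in last:
                    assert s.pct_divergence >= last[s.copy_id]
            last = {s.copy_id: s.pct_divergence for s in g.segments}


class TestExport:
    def test_round_trip_files(self, tmp_path):
        cfg = small_config(generations=30)
        g = sim.simulate(cfg)
        paths = sim.export(g, tmp_path)
        copies = read_repeatmasker_out(paths["repeats"])
        assert len(copies) == len(g.repeat_copies())
        got = sorted((rc.family, round(rc.pct_divergence, 1)) for rc in copies)
        want = sorted((rc.family, round(rc.pct_divergence, 1))
                      for rc in g.repeat_copies())
        assert got == want
        locus, _ = read_intervals(paths["locus"], "bed")
        assert len(locus[0]) == len(g.cluster_span())
        genes, attrs = read_intervals(paths["genes"], "bed")
        assert len(genes) == len(g.genes())

    def test_no_event_run_exports_initial_lines(self, tmp_path):
        cfg = small_config(
            generations=0, init_line_density=100.0,
            te_families=[sim.TeFamily("L1Md_T", "LINE", 5000, 0.0, 0.0)],
        )
        g = sim.simulate(cfg)
        paths = sim.export(g, tmp_path)
        copies = read_repeatmasker_out(paths["repeats"])
        assert len(copies) == 4  # 100/Mb in a 40 kb cluster
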