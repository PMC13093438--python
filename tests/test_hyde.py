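import itertools
import math

import numpy as np
import pytest

from phyloconflict.alignment import Alignment
from phyloconflict.hyde import (
    PATTERN_CLASSES,
    HilsResult,
    QuartetAssignment,
    SitePatternCounts,
    count_site_patterns,
    hils_test,
    n_triples,
    node_mode,
    null_hypothesis_filter,
    scan_triples,
)
from phyloconflict.simulate import (
    HybridEvent,
    SpeciesTreeModel,
    SubstitutionModel,
    evolve_sequences,
    simulate_network_gene_tree,
)
from phyloconflict.trees import parse_newick


def quartet(o="O", p1="P1", h="H", p2="P2"):
    return QuartetAssignment([o], [p1], [h], [p2])


class TestCountSitePatterns:
    def test_identical_sequences_all_aaaa(self):
        aln = Alignment({k: "ACGTACGT" for k in ("O", "P1", "H", "P2")})
        counts = count_site_patterns(aln, quartet())
        assert counts.as_dict()["AAAA"] == 8
        assert counts.n_sites_skipped == 0

    def test_hand_built_patterns(self):
        # order (O, P1, H, P2): 2x AABB, 1x ABAB, 1x ABBA, 4x AAAA
        aln = Alignment({
            "O":  "AAAAACGT",
            "P1": "AAGGACGT",
            "H":  "CCGAACGT",
            "P2": "CCAGACGT",
        })
        counts = count_site_patterns(aln, quartet()).as_dict()
        assert counts["AABB"] == 2
        assert counts["ABAB"] == 1
        assert counts["ABBA"] == 1
        assert counts["AAAA"] == 4

    def test_gaps_skipped_and_tallied(self):
        aln = Alignment({"O": "A-CN", "P1": "AACA", "H": "AACA", "P2": "AACA"})
        counts = count_site_patterns(aln, quartet())
        assert counts.n_sites_used == 2
        assert counts.n_sites_skipped == 2

    def test_duplicate_individual_averaging_degenerate(self):
        rows = {
            "O": "ACGTACAC", "P1a": "AAGTACAC", "P1b": "AAGTACAC",
            "H": "ACTTACGC", "P2": "ACGAACGG",
        }
        aln = Alignment(rows)
        single = count_site_patterns(
            aln, QuartetAssignment(["O"], ["P1a"], ["H"], ["P2"])
        )
        double = count_site_patterns(
            aln, QuartetAssignment(["O"], ["P1a", "P1b"], ["H"], ["P2"])
        )
        assert np.allclose(single.counts, double.counts)

    def test_conservation_on_random_alignments(self, rng):
        for _ in range(10):
            n = int(rng.integers(20, 200))
            rows = {
                k: "".join(rng.choice(list("ACGT-N?"), n, p=[0.22] * 4 + [0.04] * 3))
                for k in ("O", "P1", "H", "P2")
            }
            counts = count_site_patterns(Alignment(rows), quartet())
            assert counts.n_sites_used + counts.n_sites_skipped == pytest.approx(n)
            assert (counts.counts >= 0).all()

    def test_missing_individual_rejected(self):
        aln = Alignment({"O": "ACGT", "P1": "ACGT", "H": "ACGT", "P2": "ACGT"})
        with pytest.raises(ValueError, match="absent"):
            count_site_patterns(aln, QuartetAssignment(["O"], ["nope"], ["H"], ["P2"]))

    def test_fifteen_classes(self):
        assert len(PATTERN_CLASSES) == 15
        assert {"AAAA", "AABB", "ABAB", "ABBA", "ABCD"} <= set(PATTERN_CLASSES)


def counts_from(abba, abab, aabb, aaaa=10_000):
    vec = np.zeros(len(PATTERN_CLASSES))
    idx = {c: i for i, c in enumerate(PATTERN_CLASSES)}
    vec[idx["ABBA"]] = abba
    vec[idx["ABAB"]] = abab
    vec[idx["AABB"]] = aabb
    vec[idx["AAAA"]] = aaaa
    total = vec.sum()
    return SitePatternCounts(counts=vec, n_sites_used=total, n_sites_skipped=0)


class TestHilsTest:
    def test_no_signal_not_significant(self):
        r = hils_test(counts_from(100, 100, 600))
        assert not r.significant
        assert abs(r.z_value) < 2

    def test_strong_signal_detected(self):
        r = hils_test(counts_from(400, 100, 400))
        assert r.significant
        assert 0.4 < r.gamma_hat < 0.6

    def test_misarranged_triple_undefined(self):
        # both "minority" patterns exceed the concordance pattern
        r = hils_test(counts_from(500, 600, 100))
        assert not r.defined
        assert r.p_value == 1.0
        assert not r.significant

    def test_bonferroni_correction(self):
        # a ~0.01 raw p-value survives alpha=0.05 alone but not 10 tests
        c = counts_from(136, 100, 600)
        raw = hils_test(c, alpha=0.05, n_tests=1)
        corrected = hils_test(c, alpha=0.05, n_tests=10)
        assert raw.p_value == corrected.p_value
        assert 0.0005 < raw.p_value < 0.05
        assert raw.significant and not corrected.significant

    def test_gamma_swap_symmetry(self, rng):
        for _ in range(20):
            abba, abab, aabb = rng.integers(50, 800, size=3)
            fwd = hils_test(counts_from(abba, abab, aabb))
            rev = hils_test(counts_from(aabb, abab, abba))  # P1 <-> P2 swap
            if fwd.defined and rev.defined:
                assert fwd.gamma_raw + rev.gamma_raw == pytest.approx(1.0, abs=1e-9)

    def test_orientation_gamma_one(self):
        # hybrid fully tracing P1 with deep divergences: gamma_hat -> 1
        species = parse_newick(
            "(((P1:4,P2:4):4,X:8):4,O:12);", units="coalescent"
        )
        model = SpeciesTreeModel(species)
        event = HybridEvent("H", "P1", "P2", 1.0, attach_time1=1.0, attach_time2=1.0)
        rng = np.random.default_rng(6)
        alns = []
        for _ in range(120):
            g = simulate_network_gene_tree(model, event, seed=rng)
            alns.append(evolve_sequences(g, SubstitutionModel(), 120, seed=rng,
                                         coal_to_subst=0.02))
        from phyloconflict.filters import concatenate_alignments

        sup, _ = concatenate_alignments(
            {f"g{i}": a for i, a in enumerate(alns)}, ["O", "P1", "H", "P2", "X"]
        )
        counts = count_site_patterns(sup, quartet())
        r = hils_test(counts)
        # gamma = 1 is tree-consistent, so no significance is expected;
        # the estimate must still orient towards P1
        assert r.defined
        assert r.gamma_hat > 0.9

    def test_empty_counts_rejected(self):
        empty = SitePatternCounts(np.zeros(15), n_sites_used=0, n_sites_skipped=5)
        with pytest.raises(ValueError, match="usable"):
            hils_test(empty)


class TestScanTriples:
    def _alignment(self, taxa, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return Alignment({t: "".join(rng.choice(list("ACGT"), n)) for t in taxa})

    def test_three_ingroup_three_tests(self):
        aln = self._alignment(["O", "a", "b", "c"])
        res = scan_triples(aln, {t: t for t in aln.labels}, "O")
        assert len(res) == 3

    def test_combinatorial_count_k5(self):
        taxa = ["O"] + [f"x{i}" for i in range(5)]
        aln = self._alignment(taxa)
        res = scan_triples(aln, {t: t for t in taxa}, "O")
        enumerated = sum(
            1 for h in taxa[1:] for _ in itertools.combinations(
                [t for t in taxa[1:] if t != h], 2)
        )
        assert len(res) == enumerated == n_triples(5) == 30

    def test_sorted_by_pvalue(self):
        taxa = ["O"] + [f"x{i}" for i in range(4)]
        aln = self._alignment(taxa, n=200, seed=3)
        res = scan_triples(aln, {t: t for t in taxa}, "O")
        ps = [r.p_value for r in res]
        assert ps == sorted(ps)

    def test_missing_outgroup_rejected(self):
        aln = self._alignment(["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="outgroup"):
            scan_triples(aln, {t: t for t in aln.labels}, "O")

    def test_power_monotone_in_gamma_and_sites(self):
        # mean z grows with gamma and with site count
        species = parse_newick("(((P1:4,P2:4):4,X:8):4,O:12);", units="coalescent")
        model = SpeciesTreeModel(species)
        subst = SubstitutionModel()
        mean_z = {}
        for gamma in (0.1, 0.3, 0.5):
            for n_sites, n_genes in ((5_000, 25), (20_000, 100)):
                event = HybridEvent("H", "P1", "P2", gamma,
                                    attach_time1=1.0, attach_time2=1.0)
                rng = np.random.default_rng(int(gamma * 10) * 100 + n_genes)
                zs = []
                for rep in range(3):
                    alns = {}
                    for i in range(n_genes):
                        g = simulate_network_gene_tree(model, event, seed=rng)
                        alns[f"g{i}"] = evolve_sequences(
                            g, subst, n_sites // n_genes, seed=rng, coal_to_subst=0.02
                        )
                    from phyloconflict.filters import concatenate_alignments

                    sup, _ = concatenate_alignments(alns, ["O", "P1", "H", "P2", "X"])
                    r = hils_test(count_site_patterns(sup, quartet()))
                    zs.append(r.z_value)
                mean_z[(gamma, n_sites)] = float(np.mean(zs))
        for n_sites in (5_000, 20_000):
            assert mean_z[(0.1, n_sites)] < mean_z[(0.3, n_sites)] < mean_z[(0.5, n_sites)]
        for gamma in (0.1, 0.3, 0.5):
            assert mean_z[(gamma, 5_000)] < mean_z[(gamma, 20_000)]


def fake_result(p1, h, p2, gamma, significant=True, p=1e-6):
    return HilsResult(
        p1=p1, hybrid=h, p2=p2, outgroup="O", z_value=5.0, p_value=p,
        gamma_raw=gamma, gamma_hat=gamma, n_sites=1000, significant=significant,
    )


SPECIES = parse_newick("(((a,b),(c,(d,e))),O);")


class TestNodeMode:
    def test_single_test_cell(self):
        heat = node_mode([fake_result("a", "d", "b", 0.7)], SPECIES, ["d"])
        assert heat.mean.loc["a", "b"] == pytest.approx(0.7)
        assert heat.mean.loc["b", "a"] == pytest.approx(0.3)
        assert heat.sd.loc["a", "b"] == 0.0
        assert heat.count.loc["a", "b"] == 1

    def test_two_tests_mean(self):
        results = [fake_result("a", "d", "b", 0.5), fake_result("a", "d", "b", 0.7)]
        heat = node_mode(results, SPECIES, ["d"])
        assert heat.mean.loc["a", "b"] == pytest.approx(0.6)

    def test_summary_format(self):
        results = [fake_result("a", "d", "b", 0.5), fake_result("a", "e", "b", 0.682)]
        heat = node_mode(results, SPECIES, ["d", "e"])
        assert heat.parent_summary["a"] == "0.591 ± 0.091"

    def test_insignificant_tests_excluded(self):
        heat = node_mode(
            [fake_result("a", "d", "b", 0.7, significant=False)], SPECIES, ["d"]
        )
        assert heat.empty

    def test_hybrids_outside_clade_excluded(self):
        heat = node_mode([fake_result("a", "c", "b", 0.7)], SPECIES, ["d", "e"])
        assert heat.empty


class TestNullFilter:
    def _setup(self):
        tree = parse_newick("(((P1:0.02,H:0.02):0.02,P2:0.04):0.04,O:0.08);")
        tree.units = "substitutions"
        return tree, SubstitutionModel()

    def test_zero_rejections_retained(self):
        tree, model = self._setup()
        observed = [fake_result("P1", "H", "P2", 0.5)]
        report = null_hypothesis_filter(
            observed, tree, model, {t: t for t in "O P1 H P2".split()},
            n_sites=500, n_replicates=20, seed=1, alpha=0.05, correction_tests=100,
        )
        assert report.rows.loc[0, "verdict"] == "retained"
        assert report.rows.loc[0, "null_rejection_fraction"] == 0.0

    def test_no_significant_input_empty_report(self):
        tree, model = self._setup()
        observed = [fake_result("P1", "H", "P2", 0.5, significant=False)]
        report = null_hypothesis_filter(
            observed, tree, model, {t: t for t in "O P1 H P2".split()},
            n_sites=100, n_replicates=20, seed=1,
        )
        assert report.rows.empty

    def test_minimum_replicates_enforced(self):
        tree, model = self._setup()
        with pytest.raises(ValueError, match="20"):
            null_hypothesis_filter([], tree, model, {}, n_sites=10, n_replicates=5)
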