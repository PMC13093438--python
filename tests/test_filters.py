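import numpy as np
import pandas as pd
import pytest

from phyloconflict.alignment import Alignment
from phyloconflict.filters import (
    GeneTreeRecord,
    OrthogroupTable,
    concatenate_alignments,
    filter_alignment_columns,
    filter_by_abs,
    filter_by_occupancy,
    flag_long_branches,
    partition_by_length,
    screen_organellar,
)
from phyloconflict.trees import parse_newick


def make_table(presence_rows, samples):
    df = pd.DataFrame(presence_rows, columns=samples)
    df.index = [f"g{i}" for i in range(len(presence_rows))]
    return OrthogroupTable(presence=df.astype(bool))


class TestOccupancy:
    def test_printed_cutoff_47_samples(self):
        # floor(0.7 * 47) = 32
        samples = [f"s{i}" for i in range(47)]
        rows = [[1] * 32 + [0] * 15, [1] * 31 + [0] * 16]
        table = make_table(rows, samples)
        kept = filter_by_occupancy(table, 0.70)
        assert kept.genes == ["g0"]

    def test_complete_gene_always_kept(self):
        table = make_table([[1, 1, 1, 1]], list("abcd"))
        assert filter_by_occupancy(table, 1.0).n_genes == 1

    def test_matches_brute_force_row_sums(self, rng):
        samples = [f"s{i}" for i in range(20)]
        rows = rng.integers(0, 2, size=(10, 20))
        table = make_table(rows, samples)
        kept = filter_by_occupancy(table, 0.7)
        threshold = int(np.floor(0.7 * 20))
        expected = [f"g{i}" for i in range(10) if rows[i].sum() >= threshold]
        assert kept.genes == expected

    def test_empty_table_warns(self):
        table = make_table([], list("ab")) if False else OrthogroupTable(
            presence=pd.DataFrame(columns=["a", "b"])
        )
        with pytest.warns(UserWarning, match="empty"):
            out = filter_by_occupancy(table, 0.5)
        assert out.n_genes == 0

    def test_idempotent(self, rng):
        samples = [f"s{i}" for i in range(12)]
        table = make_table(rng.integers(0, 2, size=(15, 12)), samples)
        once = filter_by_occupancy(table, 0.6)
        twice = filter_by_occupancy(once, 0.6)
        assert once.genes == twice.genes

    def test_tsv_round_trip(self, tmp_path, rng):
        samples = [f"s{i}" for i in range(5)]
        table = make_table(rng.integers(0, 2, size=(4, 5)), samples)
        table.write_tsv(tmp_path / "og.tsv")
        back = OrthogroupTable.read_tsv(tmp_path / "og.tsv")
        assert back.presence.equals(table.presence)


class TestOrganellarScreen:
    def test_verbatim_substring_removed(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 500))
        gene = ref[100:200]
        kept, removed, report = screen_organellar({"g": gene}, [ref])
        assert "g" in removed

    def test_random_gene_kept(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 2000))
        gene = "".join(rng.choice(list("ACGT"), 300))
        kept, removed, report = screen_organellar({"g": gene}, [ref])
        assert "g" in kept
        assert report.loc[0, "shared_frac"] < 0.05

    def test_reverse_complement_detected(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 500))
        comp = str.maketrans("ACGT", "TGCA")
        gene = ref[50:150].translate(comp)[::-1]
        kept, removed, _ = screen_organellar({"g": gene}, [ref])
        assert "g" in removed

    def test_chimeric_fraction_matches_brute_force(self, rng):
        k = 21
        ref = "".join(rng.choice(list("ACGT"), 1000))
        gene = ref[0:150] + "".join(rng.choice(list("ACGT"), 150))
        kept, removed, report = screen_organellar({"g": gene}, [ref], k=k)
        ref_rc = ref.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        gene_kmers = {gene[i:i + k] for i in range(len(gene) - k + 1)}
        ref_kmers = {ref[i:i + k] for i in range(len(ref) - k + 1)} | {
            ref_rc[i:i + k] for i in range(len(ref_rc) - k + 1)
        }
        expected = len(gene_kmers & ref_kmers) / len(gene_kmers)
        assert report.loc[0, "shared_frac"] == pytest.approx(expected)
        assert 0.35 < expected < 0.65

    def test_short_gene_kept_with_warning(self):
        with pytest.warns(UserWarning, match="shorter"):
            kept, _, _ = screen_organellar({"g": "ACGT"}, ["ACGT" * 50])
        assert "g" in kept

    def test_small_k_rejected(self):
        with pytest.raises(ValueError, match="k"):
            screen_organellar({"g": "A" * 50}, ["A" * 50], k=5)


class TestColumnFilter:
    def test_strict_inequality_at_threshold(self):
        # 10 rows, exactly 2 gaps = 20% -> kept; 3 gaps -> removed
        rows = {f"s{i}": ("-" if i < 2 else "A") + ("-" if i < 3 else "C") for i in range(10)}
        aln = Alignment(rows)
        out, kept = filter_alignment_columns(aln, 0.2)
        assert kept == [0]
        assert out.n_sites == 1

    def test_all_gap_column_removed(self):
        aln = Alignment({"a": "-A", "b": "-C"})
        out, kept = filter_alignment_columns(aln, 0.2)
        assert kept == [1]

    def test_manual_count_fixture(self, rng):
        cols = []
        gap_counts = [0, 1, 2, 3, 0, 8, 2, 1, 5, 0, 4, 2]
        for g in gap_counts:
            cols.append(["-"] * g + ["A"] * (8 - g))
        rows = {f"s{i}": "".join(c[i] for c in cols) for i in range(8)}
        out, kept = filter_alignment_columns(Alignment(rows), 0.25)
        expected = [i for i, g in enumerate(gap_counts) if g / 8 <= 0.25]
        assert kept == expected

    def test_surviving_columns_verbatim(self, rng):
        rows = {f"s{i}": "".join(rng.choice(list("ACGT-"), 50)) for i in range(6)}
        aln = Alignment(rows)
        out, kept = filter_alignment_columns(aln, 0.3)
        for lbl in rows:
            assert out[lbl] == "".join(rows[lbl][i] for i in kept)

    def test_all_removed_warns(self):
        aln = Alignment({"a": "--", "b": "--"})
        with pytest.warns(UserWarning, match="all columns"):
            out, kept = filter_alignment_columns(aln, 0.5)
        assert kept == []

    def test_idempotent(self, rng):
        rows = {f"s{i}": "".join(rng.choice(list("ACGT-"), 40)) for i in range(5)}
        once, _ = filter_alignment_columns(Alignment(rows), 0.2)
        twice, _ = filter_alignment_columns(once, 0.2)
        assert twice.rows == once.rows


class TestLengthClasses:
    def test_class_membership(self):
        alns = {
            "g1500": Alignment({"a": "A" * 1500}),
            "g2500": Alignment({"a": "A" * 2500}),
            "g500": Alignment({"a": "A" * 500}),
        }
        classes = partition_by_length(alns, [1000, 2000])
        assert set(classes[1000]) == {"g1500", "g2500"}
        assert set(classes[2000]) == {"g2500"}

    def test_threshold_one_includes_all_nonempty(self):
        alns = {"a": Alignment({"x": "ACGT"}), "b": Alignment({"x": "A"})}
        assert set(partition_by_length(alns, [1])[1]) == {"a", "b"}

    def test_matches_brute_force_counts(self, rng):
        lengths = rng.integers(1, 3000, size=30)
        alns = {f"g{i}": Alignment({"x": "A" * int(n)}) for i, n in enumerate(lengths)}
        classes = partition_by_length(alns, [500, 1500])
        assert len(classes[500]) == int((lengths >= 500).sum())
        assert len(classes[1500]) == int((lengths >= 1500).sum())

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            partition_by_length({}, [2000, 1000])


def record_with_abs(value, gene_id="g"):
    tree = parse_newick(f"(((A,B){value},C){value},(D,E){value});")
    return GeneTreeRecord(gene_id=gene_id, tree=tree, abs_support=float(value))


class TestAbsFilter:
    def test_strictly_exceeding(self):
        recs = [record_with_abs(60.0, "a"), record_with_abs(60.01, "b")]
        kept = filter_by_abs(recs, 60)
        assert [r.gene_id for r in kept] == ["b"]

    def test_full_support_always_kept(self):
        assert filter_by_abs([record_with_abs(100)], 100 - 1e-9)

    def test_mixed_fixture_one_survivor(self):
        recs = [record_with_abs(v, str(v)) for v in (55, 61, 60)]
        assert [r.gene_id for r in filter_by_abs(recs, 60)] == ["61"]

    def test_missing_abs_rejected(self):
        rec = record_with_abs(80)
        rec.abs_support = None
        with pytest.raises(ValueError, match="ABS"):
            filter_by_abs([rec], 60)

    def test_commutes_with_length_partition(self, rng):
        # order of ABS filter and length classing does not matter
        recs = []
        for i in range(10):
            r = record_with_abs(int(rng.integers(40, 100)), f"g{i}")
            r.alignment_length = int(rng.integers(100, 3000))
            recs.append(r)
        a = [r.gene_id for r in filter_by_abs(recs, 60) if r.alignment_length >= 1000]
        b = [r.gene_id for r in filter_by_abs(
            [r for r in recs if r.alignment_length >= 1000], 60)]
        assert a == b


class TestLongBranches:
    def test_equal_pendants_nothing_flagged(self):
        tree = parse_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
        rec = GeneTreeRecord("g", tree)
        _, flagged = flag_long_branches(rec, factor=1.5)
        assert flagged == []

    def test_ten_fold_branch_flagged(self):
        tree = parse_newick("((A:1,B:10):0.5,(C:1,D:1):0.5);")
        _, flagged = flag_long_branches(GeneTreeRecord("g", tree), factor=5)
        assert flagged == ["B"]

    def test_prune_leaves_valid_tree(self):
        tree = parse_newick("((A:1,B:10):0.5,((C:1,D:1):0.2,E:1):0.5);")
        rec, flagged = flag_long_branches(GeneTreeRecord("g", tree), factor=5, prune=True)
        assert flagged == ["B"]
        assert sorted(rec.tree.leaf_labels()) == ["A", "C", "D", "E"]

    def test_gene_dropped_below_four_leaves(self):
        tree = parse_newick("((A:1,B:10):0.5,(C:1,D:1):0.5);")
        with pytest.warns(UserWarning, match="dropped"):
            rec, flagged = flag_long_branches(GeneTreeRecord("g", tree), factor=5, prune=True)
        assert rec is None


class TestConcatenate:
    def test_single_gene_identity(self):
        aln = Alignment({"a": "ACG", "b": "TTT"})
        sup, parts = concatenate_alignments({"g1": aln}, ["a", "b"])
        assert sup.rows == aln.rows
        assert parts.values.tolist() == [["g1", 1, 3]]

    def test_partition_coordinates(self):
        a1 = Alignment({"a": "ACG", "b": "TTT"})
        a2 = Alignment({"a": "ACGTT", "b": "TTTAA"})
        _, parts = concatenate_alignments({"g1": a1, "g2": a2}, ["a", "b"])
        assert parts.values.tolist() == [["g1", 1, 3], ["g2", 4, 8]]

    def test_missing_taxon_padded(self):
        a1 = Alignment({"a": "ACG"})
        sup, _ = concatenate_alignments({"g1": a1}, ["a", "b"])
        assert sup["b"] == "???"

    def test_string_join_oracle(self, rng):
        taxa = ["a", "b", "c"]
        alns = {}
        for i in range(5):
            n = int(rng.integers(3, 20))
            present = [t for t in taxa if rng.random() > 0.2] or taxa
            alns[f"g{i}"] = Alignment(
                {t: "".join(rng.choice(list("ACGT"), n)) for t in present}
            )
        sup, _ = concatenate_alignments(alns, taxa)
        for t in taxa:
            expected = "".join(
                alns[g][t] if t in alns[g] else "?" * alns[g].n_sites for g in alns
            )
            assert sup[t] == expected

    def test_duplicate_gene_ids_rejected(self):
        aln = Alignment({"a": "ACG"})
        with pytest.raises(ValueError, match="duplicate"):
            concatenate_alignments([("g", aln), ("g", aln)], ["a"])
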