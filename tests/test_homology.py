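"""Homology filtering, BBH orthology, families, categories, annotation."""

import numpy as np
import pytest

from conftest import brute_bbh, brute_connected_components
from fungicomp.homology import (
    CATEGORIES,
    BbhPair,
    HomologyFilter,
    HomologyHit,
    annotate_by_reference,
    bidirectional_best_hits,
    category_counts,
    classify_categories,
    expand_family_by_linkage,
    filter_homologs,
    read_hit_table,
    single_linkage_families,
)
from fungicomp.synthetic import simulate_hit_table, write_hit_table


def make_hit(qid, sid, qg="A", sg="B", ident=50.0, aln=100, ev=1e-20,
             bits=200.0, qlen=100, slen=100):
    return HomologyHit(qid, sid, qg, sg, ident, aln, ev, bits, qlen, slen)


class TestReadHitTable:
    def test_single_valid_row(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t50.0\t100\t0\t0\t1\t100\t1\t100\t1e-20\t200\t100\t100\n")
        hits = read_hit_table(p, {"q1": "A", "s1": "B"})
        assert len(hits) == 1 and hits[0].query_length == 100

    def test_missing_lengths_errors(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t50.0\t100\t0\t0\t1\t100\t1\t100\t1e-20\t200\n")
        with pytest.raises(ValueError, match="length"):
            read_hit_table(p, {"q1": "A", "s1": "B"})

    def test_separate_length_table_accepted(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t50.0\t100\t0\t0\t1\t100\t1\t100\t1e-20\t200\n")
        hits = read_hit_table(p, {"q1": "A", "s1": "B"}, lengths={"q1": 120, "s1": 110})
        assert hits[0].query_length == 120 and hits[0].subject_length == 110

    def test_id_missing_from_genome_map(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\tsX\t50.0\t100\t0\t0\t1\t100\t1\t100\t1e-20\t200\t100\t100\n")
        with pytest.raises(ValueError, match="sX"):
            read_hit_table(p, {"q1": "A"})

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\tnot_a_number\t100\t0\t0\t1\t100\t1\t100\t1e-20\t200\t100\t100\n")
        with pytest.raises(ValueError, match=":1"):
            read_hit_table(p, {"q1": "A", "s1": "B"})


class TestFilter:
    def test_all_thresholds_passed(self):
        h = make_hit("a", "b", ident=45.0, aln=70, ev=1e-6, qlen=100, slen=100)
        assert HomologyFilter().passes(h)

    def test_identity_boundary(self):
        assert not HomologyFilter().passes(make_hit("a", "b", ident=29.9))
        assert HomologyFilter().passes(make_hit("a", "b", ident=30.0))

    def test_evalue_boundary_inclusive(self):
        assert HomologyFilter().passes(make_hit("a", "b", ev=1e-5))
        assert not HomologyFilter().passes(make_hit("a", "b", ev=1.1e-5))

    def test_coverage_must_hold_for_both_lengths(self):
        # aln 59 on lengths 100/80: 59 < 60 fails the longer protein
        assert not HomologyFilter().passes(make_hit("a", "b", aln=59, qlen=100, slen=80))
        assert HomologyFilter().passes(make_hit("a", "b", aln=60, qlen=100, slen=80))

    def test_self_hits_and_duplicates_collapsed(self):
        hits = [
            make_hit("a", "a"),
            make_hit("a", "b", bits=100.0),
            make_hit("b", "a", qg="B", sg="A", bits=250.0),
        ]
        pairs = filter_homologs(hits)
        assert list(pairs) == [("a", "b")]
        assert pairs[("a", "b")].bitscore == 250.0


class TestBbh:
    def test_mutual_best(self):
        hits = [make_hit("A1", "B1"), make_hit("B1", "A1", qg="B", sg="A")]
        assert bidirectional_best_hits(hits, "A", "B") == {
            BbhPair("A1", "B1", "A", "B")
        }

    def test_reciprocity_fails(self):
        hits = [
            make_hit("A1", "B1", bits=300.0),
            make_hit("B1", "A2", qg="B", sg="A", bits=400.0),
            make_hit("A2", "B1", bits=400.0),
        ]
        # B1's best is A2 (mutual); A1->B1 is not reciprocated
        got = bidirectional_best_hits(hits, "A", "B")
        assert got == {BbhPair("A2", "B1", "A", "B")}

    def test_invariant_to_row_order_and_presentation(self):
        rng = np.random.default_rng(3)
        hits = []
        for i in range(5):
            for j in range(5):
                hits.append(
                    make_hit(f"A{i}", f"B{j}", bits=float(rng.integers(50, 500)))
                )
        base = bidirectional_best_hits(hits, "A", "B")
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert bidirectional_best_hits(shuffled, "A", "B") == base
        flipped = [
            HomologyHit(h.subject_id, h.query_id, h.subject_genome, h.query_genome,
                        h.pct_identity, h.aln_length, h.evalue, h.bitscore,
                        h.subject_length, h.query_length)
            for h in hits
        ]
        assert bidirectional_best_hits(flipped, "A", "B") == base

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        hits = []
        for i in range(5):
            for j in range(5):
                if rng.random() < 0.7:
                    hits.append(
                        make_hit(f"A{i}", f"B{j}", bits=float(rng.integers(50, 500)),
                                 ev=float(10.0 ** -rng.integers(6, 50)))
                    )
        got = {frozenset((p.gene_a, p.gene_b))
               for p in bidirectional_best_hits(hits, "A", "B")}
        assert got == brute_bbh(hits, "A", "B")


class TestFamilies:
    def test_transitive_closure(self):
        fams, _ = single_linkage_families([("A", "B"), ("B", "C")])
        assert [set(f.member_ids) for f in fams] == [{"A", "B", "C"}]

    def test_disjoint_pairs(self):
        fams, _ = single_linkage_families([("A", "B"), ("C", "D")])
        assert sorted(sorted(f.member_ids) for f in fams) == [["A", "B"], ["C", "D"]]

    def test_singletons_reported(self):
        fams, singles = single_linkage_families([("A", "B")], universe=["A", "B", "C"])
        assert singles == {"C"}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_closure(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(int(rng.integers(10, 50)))]
        pairs = [
            tuple(rng.choice(genes, size=2, replace=False))
            for _ in range(int(rng.integers(5, 40)))
        ]
        pairs = [(str(a), str(b)) for a, b in pairs]
        fams, _ = single_linkage_families(pairs)
        got = sorted(sorted(f.member_ids) for f in fams)
        want = sorted(sorted(c) for c in brute_connected_components(pairs))
        assert got == want

    def test_family_ids_stable_under_pair_order(self):
        pairs = [("x", "y"), ("a", "b"), ("b", "c")]
        f1, _ = single_linkage_families(pairs)
        f2, _ = single_linkage_families(list(reversed(pairs)))
        assert [(f.family_id, sorted(f.member_ids)) for f in f1] == [
            (f.family_id, sorted(f.member_ids)) for f in f2
        ]


class TestExpandByLinkage:
    def test_seed_pulls_in_component(self):
        assert expand_family_by_linkage({"A"}, [("A", "B")]) == {"A", "B"}

    def test_singleton_seed(self):
        assert expand_family_by_linkage({"Z"}, [("A", "B")]) == {"Z"}

    def test_unknown_seed_errors(self):
        with pytest.raises(KeyError, match="Z"):
            expand_family_by_linkage({"Z"}, [("A", "B")], universe={"A", "B"})

    def test_multiple_seeds_union_of_components(self):
        pairs = [("A", "B"), ("B", "C"), ("D", "E"), ("F", "G")]
        got = expand_family_by_linkage({"A", "D"}, pairs)
        assert got == {"A", "B", "C", "D", "E"}


class TestCategories:
    def test_definitions(self, five_genome_groups):
        bbh_by = {
            "pat1": {BbhPair("g1", "p1", "ao", "pat1")},
            "pat2": {BbhPair("g1", "p2", "ao", "pat2")},
            "non1": {BbhPair("g2", "n1", "ao", "non1")},
            "non2": set(),
        }
        assignments = classify_categories(
            ["g1", "g2", "g3"], bbh_by, five_genome_groups
        )
        cats = {a.gene_id: a.category for a in assignments}
        assert cats == {
            "g1": "with_pathogen",
            "g2": "with_nonpathogen",
            "g3": "specific",
        }

    def test_counts_partition_proteome(self, five_genome_groups):
        assignments = classify_categories(["g1", "g2"], {}, five_genome_groups)
        counts = category_counts(assignments)
        assert set(counts) == set(CATEGORIES)
        assert sum(counts.values()) == 2

    def test_missing_group_errors(self):
        with pytest.raises(ValueError, match="nonpathogen"):
            classify_categories(["g1"], {}, {"ao": "focal", "p": "pathogen"})

    def test_planted_simulation_recovered_exactly(self, five_genome_groups):
        sim = simulate_hit_table(five_genome_groups, n_focal_genes=40, seed=11)
        filt = HomologyFilter()
        bbh_by = {
            g: bidirectional_best_hits(sim.hits, "ao", g, filt)
            for g in five_genome_groups
            if g != "ao"
        }
        assignments = classify_categories(sim.focal_genes, bbh_by, five_genome_groups)
        assert {a.gene_id: a.category for a in assignments} == sim.true_categories


class TestAnnotateByReference:
    def test_best_reference_hit_kept(self):
        hits = [
            make_hit("g1", "ref1", qg="ao", sg="ref", bits=100.0),
            make_hit("g1", "ref2", qg="ao", sg="ref", bits=300.0),
        ]
        best = annotate_by_reference(hits, "ao", "ref")
        assert best["g1"].subject_id == "ref2"

    def test_failing_hits_excluded(self):
        hits = [make_hit("g1", "ref1", qg="ao", sg="ref", ident=10.0)]
        assert annotate_by_reference(hits, "ao", "ref") == {}

    def test_matches_brute_force_selection(self):
        rng = np.random.default_rng(7)
        hits = []
        for i in range(10):
            for j in range(5):
                if rng.random() < 0.6:
                    hits.append(
                        make_hit(f"g{i}", f"r{j}", qg="ao", sg="ref",
                                 bits=float(rng.integers(50, 500)))
                    )
        filt = HomologyFilter()
        best = annotate_by_reference(hits, "ao", "ref", filt)
        surviving = [h for h in hits if filt.passes(h)]
        for gene in {h.query_id for h in surviving}:
            expected = min(
                (h for h in surviving if h.query_id == gene),
                key=lambda h: (-h.bitscore, h.evalue, -h.pct_identity, h.subject_id),
            )
            assert best[gene].subject_id == expected.subject_id


class TestSimulatedRoundTrip:
    def test_hit_table_file_round_trip(self, tmp_path, five_genome_groups):
        """Writing and re-reading the simulated table preserves every hit."""
        sim = simulate_hit_table(five_genome_groups, seed=2)
        path = tmp_path / "hits.tsv"
        write_hit_table(sim.hits, path)
        back = read_hit_table(path, sim.genome_map)
        assert len(back) == len(sim.hits)
        filt = HomologyFilter()
        for (ga, gb), truth in sim.true_bbh.items():
            assert bidirectional_best_hits(back, ga, gb, filt) == truth
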