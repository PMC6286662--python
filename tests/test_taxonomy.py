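"""Windowed-LCA assignment: taxonomy loading, LCA, demotion, constraints."""

import io

import numpy as np
import pandas as pd
import pytest

from ednabench.taxonomy import (
    Adjustment,
    AssignmentParams,
    HitRecord,
    TaxonomyDB,
    TaxonomyError,
    apply_taxon_adjustments,
    assign_otu,
    constrained_reassign,
    load_taxonomy,
    lowest_common_ancestor,
    read_hit_table,
)


def hsp(taxid, bit, ident, qid="otu1", acc=None):
    return HitRecord(qid, acc or f"acc{taxid}_{bit}", taxid, bit, ident, 300)


class TestLoadTaxonomy:
    def test_toy_three_node_chain(self):
        nodes = io.StringIO("1\t|\t1\t|\troot\t|\n2\t|\t1\t|\tgenus\t|\n3\t|\t2\t|\tspecies\t|\n")
        db = load_taxonomy(nodes)
        assert db.depth(3) == 2
        assert db.root == 1

    def test_merged_id_remaps_transitively(self):
        nodes = io.StringIO("1\t|\t1\t|\troot\t|\n6\t|\t1\t|\tspecies\t|\n")
        merged = io.StringIO("99\t|\t6\t|\n")
        db = load_taxonomy(nodes, merged_source=merged)
        assert db.resolve(99) == 6

    def test_missing_parent_is_structural_error(self):
        nodes = io.StringIO("1\t|\t1\t|\troot\t|\n2\t|\t7\t|\tgenus\t|\n")
        with pytest.raises(TaxonomyError, match="unknown parent"):
            load_taxonomy(nodes)

    def test_cycle_is_structural_error(self):
        with pytest.raises(TaxonomyError):
            TaxonomyDB({1: (1, "root"), 2: (3, "genus"), 3: (2, "genus")})

    def test_two_roots_rejected(self):
        with pytest.raises(TaxonomyError, match="one root"):
            TaxonomyDB({1: (1, "root"), 2: (2, "root")})

    def test_names_source_and_lookup(self):
        nodes = io.StringIO("1\t|\t1\t|\troot\t|\n2\t|\t1\t|\tgenus\t|\n")
        names = io.StringIO("2\t|\tSalmo\t|\t\t|\tscientific name\t|\n")
        db = load_taxonomy(nodes, names)
        assert db.find_by_name("Salmo") == 2


class TestLCA:
    @pytest.mark.parametrize(
        "ids,expected",
        [({6}, 6), ({6, 8}, 4), ({6, 10}, 3), ({6, 8, 10}, 3), ({5, 6}, 5)],
    )
    def test_fish_tree_cases(self, fish_db, ids, expected):
        assert lowest_common_ancestor(ids, fish_db) == expected

    def test_empty_set_errors(self, fish_db):
        with pytest.raises(TaxonomyError):
            lowest_common_ancestor(set(), fish_db)

    def test_unresolvable_id_errors(self, fish_db):
        with pytest.raises(TaxonomyError):
            lowest_common_ancestor({6, 12345}, fish_db)

    def test_matches_bruteforce_on_random_trees(self):
        """LCA equals full root-path intersection on >= 1000 random cases."""
        rng = np.random.default_rng(42)
        n_cases = 0
        while n_cases < 1000:
            n = int(rng.integers(3, 40))
            nodes = {1: (1, "root")}
            for tid in range(2, n + 1):
                nodes[tid] = (int(rng.integers(1, tid)), "clade")
            db = TaxonomyDB(nodes)
            for _ in range(5):
                k = int(rng.integers(1, 5))
                ids = rng.integers(1, n + 1, size=k).tolist()
                # oracle: deepest node present in every full root path
                paths = [db.path_to_root(t) for t in ids]
                common = set(paths[0]).intersection(*map(set, paths[1:]))
                oracle = max(common, key=db.depth)
                assert lowest_common_ancestor(ids, db) == oracle
                n_cases += 1


class TestAssignOtu:
    def test_both_hsps_in_window_lca_at_family(self, fish_db, coi_params):
        a = assign_otu([hsp(6, 300, 99.0), hsp(8, 295, 98.0)], coi_params, fish_db)
        assert (a.taxon_id, a.assigned_rank) == (4, "family")
        assert a.mean_identity == pytest.approx(98.5)
        assert a.n_contributing == 2 and not a.demoted

    def test_window_excludes_second_hsp(self, fish_db, coi_params):
        # cutoff = 0.95 * 300 = 285 > 280: only the best HSP participates
        a = assign_otu([hsp(6, 300, 99.0), hsp(8, 280, 98.0)], coi_params, fish_db)
        assert (a.taxon_id, a.assigned_rank) == (6, "species")
        assert a.mean_identity == pytest.approx(99.0)

    def test_boundary_bitscore_is_retained(self, fish_db, coi_params):
        # exactly at (1 - window) * best: closed interval keeps it
        a = assign_otu([hsp(6, 300, 99.0), hsp(8, 285, 98.0)], coi_params, fish_db)
        assert a.taxon_id == 4

    def test_low_identity_species_demoted_to_genus(self, fish_db, coi_params):
        a = assign_otu([hsp(6, 300, 93.0)], coi_params, fish_db)
        assert (a.taxon_id, a.assigned_rank) == (5, "genus")
        assert a.demoted

    def test_very_low_identity_demoted_to_family(self, fish_db, coi_params):
        a = assign_otu([hsp(6, 300, 88.0)], coi_params, fish_db)
        assert (a.taxon_id, a.assigned_rank) == (4, "family")
        assert a.demoted

    def test_all_below_floor_unassigned(self, fish_db, coi_params):
        a = assign_otu([hsp(6, 240, 99.0), hsp(8, 100, 99.0)], coi_params, fish_db)
        assert not a.assigned

    def test_empty_hsps_unassigned_not_exception(self, fish_db, coi_params):
        assert not assign_otu([], coi_params, fish_db).assigned

    def test_mixed_query_ids_rejected(self, fish_db, coi_params):
        with pytest.raises(ValueError, match="multiple query ids"):
            assign_otu([hsp(6, 300, 99.0, qid="a"), hsp(8, 300, 99.0, qid="b")],
                       coi_params, fish_db)

    def test_best_hsp_per_subject_before_windowing(self, fish_db, coi_params):
        # two HSPs to the same accession: only the better one participates,
        # so the weaker one cannot widen the window pool
        hsps = [hsp(6, 300, 99.0, acc="X"), hsp(6, 260, 80.0, acc="X")]
        a = assign_otu(hsps, coi_params, fish_db)
        assert a.n_contributing == 1 and a.mean_identity == pytest.approx(99.0)

    def test_no_genus_ancestor_walks_to_family(self, coi_params):
        # rank-sparse lineage: species directly under family
        db = TaxonomyDB({1: (1, "root"), 2: (1, "family", "F"),
                         3: (2, "species", "S")})
        a = assign_otu([hsp(3, 300, 93.0)], coi_params, db)
        assert (a.taxon_id, a.assigned_rank) == (2, "family")

    def test_no_ancestor_at_or_below_family_unassigned(self, coi_params):
        # demotion would have to pass family: unassigned instead
        db = TaxonomyDB({1: (1, "root"), 2: (1, "order", "O"),
                         3: (2, "species", "S")})
        a = assign_otu([hsp(3, 300, 93.0)], coi_params, db)
        assert not a.assigned and "family" in a.notes

    def test_shrinking_window_never_more_rootward(self, fish_db):
        """Monotonicity: a smaller LCA window retains a subset of HSPs, so the
        assignment can only stay or move leafward."""
        rng = np.random.default_rng(3)
        leaves = [6, 8, 10]
        for _ in range(200):
            hsps = [hsp(int(rng.choice(leaves)), float(rng.uniform(250, 400)),
                        99.0, acc=f"a{i}") for i in range(int(rng.integers(1, 6)))]
            prev_depth = None
            for window in (0.30, 0.10, 0.02):
                p = AssignmentParams(min_bitscore=250, lca_window=window)
                a = assign_otu(hsps, p, fish_db)
                d = fish_db.depth(a.taxon_id)
                if prev_depth is not None:
                    assert d >= prev_depth
                prev_depth = d

    def test_raising_floor_never_increases_contributors(self, fish_db):
        rng = np.random.default_rng(4)
        for _ in range(100):
            hsps = [hsp(int(rng.choice([6, 8, 10])), float(rng.uniform(100, 500)),
                        99.0, acc=f"a{i}") for i in range(5)]
            prev = None
            for floor in (100.0, 250.0, 400.0):
                p = AssignmentParams(min_bitscore=floor, lca_window=0.3)
                a = assign_otu(hsps, p, fish_db)
                n = a.n_contributing
                if prev is not None:
                    assert n <= prev
                prev = n


class TestConstrainedReassign:
    def test_disallowed_equal_scorer_dropped(self, fish_db, coi_params):
        """A non-expected fish match at equal score is removed and the
        assignment resolves to the expected taxon."""
        hsps = [hsp(6, 300, 99.0), hsp(8, 300, 99.0)]  # 8 plays the outsider
        a = constrained_reassign(hsps, allowed_taxa={5}, constraint_clade=3,
                                 params=coi_params, db=fish_db)
        assert a.taxon_id == 6

    def test_all_disallowed_unassigned_with_note(self, fish_db, coi_params):
        a = constrained_reassign([hsp(6, 300, 99.0)], allowed_taxa={10},
                                 constraint_clade=3, params=coi_params, db=fish_db)
        assert not a.assigned and "constraint" in a.notes

    def test_assignment_outside_clade_unchanged(self, coi_params):
        # bird-like lineage outside the fish clade passes through untouched
        db = TaxonomyDB({1: (1, "root"), 2: (1, "class", "Actinopterygii"),
                         3: (1, "class", "Aves"), 4: (3, "genus", "Gallus"),
                         5: (4, "species", "Gallus gallus"),
                         6: (2, "genus", "Salmo")})
        a0 = assign_otu([hsp(5, 300, 99.0)], coi_params, db)
        a1 = constrained_reassign([hsp(5, 300, 99.0)], allowed_taxa={6},
                                  constraint_clade=2, params=coi_params, db=db)
        assert a1.taxon_id == a0.taxon_id == 5

    def test_allowed_everything_is_identity(self, fish_db, coi_params):
        hsps = [hsp(6, 300, 99.0), hsp(8, 295, 98.0)]
        base = assign_otu(hsps, coi_params, fish_db)
        allow_all = set(range(1, 11))
        a = constrained_reassign(hsps, allow_all, 3, coi_params, fish_db)
        assert a.taxon_id == base.taxon_id

    def test_empty_allowed_list_is_config_error(self, fish_db, coi_params):
        with pytest.raises(ValueError, match="empty"):
            constrained_reassign([hsp(6, 300, 99.0)], set(), 3, coi_params, fish_db)


class TestAdjustments:
    def _assignments(self, fish_db, coi_params):
        return [
            assign_otu([hsp(6, 300, 99.0, qid="o1")], coi_params, fish_db),
            assign_otu([hsp(8, 300, 99.0, qid="o2")], coi_params, fish_db),
            assign_otu([hsp(10, 300, 99.0, qid="o3")], coi_params, fish_db),
        ]

    def test_remove_drops_matching_otus(self, fish_db, coi_params):
        out = apply_taxon_adjustments(
            self._assignments(fish_db, coi_params),
            [Adjustment("Salmo salar", "remove")], fish_db,
        )
        assert [a.query_id for a in out] == ["o2", "o3"]

    def test_merge_into_reassigns_taxon(self, fish_db, coi_params):
        out = apply_taxon_adjustments(
            self._assignments(fish_db, coi_params),
            [Adjustment("Coregonus artedi", "merge_into", "Chrosomus")], fish_db,
        )
        merged = next(a for a in out if a.query_id == "o2")
        assert merged.taxon_name == "Chrosomus" and merged.taxon_id == 10

    def test_empty_adjustments_is_identity(self, fish_db, coi_params):
        src = self._assignments(fish_db, coi_params)
        out = apply_taxon_adjustments(src, [], fish_db)
        assert [a.taxon_id for a in out] == [a.taxon_id for a in src]

    def test_unmatched_rule_errors_listing_it(self, fish_db, coi_params):
        with pytest.raises(ValueError, match="Esox"):
            apply_taxon_adjustments(self._assignments(fish_db, coi_params),
                                    [Adjustment("Esox", "remove")], fish_db)


class TestHitTable:
    def test_thirteen_column_roundtrip(self, tmp_path):
        rows = [["o1", "accA", 99.0, 300, 1, 0, 1, 300, 1, 300, 1e-50, 320.0, 6],
                ["o1", "accB", 98.0, 300, 2, 0, 1, 300, 1, 300, 1e-45, 310.0, 8]]
        path = tmp_path / "hits.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
        by_query = read_hit_table(path)
        assert len(by_query["o1"]) == 2
        assert by_query["o1"][0].bit_score == 320.0

    def test_twelve_columns_need_accession_map(self, tmp_path):
        rows = [["o1", "accA", 99.0, 300, 1, 0, 1, 300, 1, 300, 1e-50, 320.0]]
        path = tmp_path / "hits12.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
        with pytest.raises(ValueError, match="accession map"):
            read_hit_table(path)
        by_query = read_hit_table(path, acc_to_taxid={"accA": 6})
        assert by_query["o1"][0].taxon_id == 6
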