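"""Taxonomy loading and rank-penalized distance behavior."""

import random

import pytest

from rescue_rank.errors import TaxonomyStructureError, UnresolvableTaxonError
from rescue_rank.fixtures import make_random_tree, oracle_distance
from rescue_rank.taxonomy import (
    RankPenaltySchedule,
    load_taxonomy,
    max_distance,
    penalized_distance,
    resolve_with_fallback,
)

UNIT = RankPenaltySchedule(
    per_rank_penalty={
        r: 1.0
        for r in (
            "domain", "kingdom", "phylum", "class", "order",
            "family", "genus", "species", "strain", "no_rank",
        )
    },
    domain_crossing_penalty=1.0,
)


class TestLoadTaxonomy:
    def test_minimal_three_row_tree(self):
        tree = load_taxonomy("1\t1\tdomain\troot\n2\t1\tgenus\tG\n3\t2\tspecies\tS\n")
        assert tree.root_id == 1
        assert len(tree.nodes) == 3
        assert tree.nodes[3].rank == "species"

    def test_cycle_raises_structural_error(self):
        text = "1\t1\tno_rank\troot\n5\t6\tgenus\tx\n6\t5\tgenus\ty\n"
        with pytest.raises(TaxonomyStructureError, match="cyclic|5|6"):
            load_taxonomy(text)

    def test_dangling_parent_raises(self):
        with pytest.raises(TaxonomyStructureError, match="dangling"):
            load_taxonomy("1\t1\tno_rank\troot\n2\t99\tgenus\tx\n")

    def test_taxdump_dialect_node_count_matches_row_count(self):
        rows = ["1\t|\t1\t|\tno rank\t|"]
        for i in range(2, 21):
            rows.append(f"{i}\t|\t{i - 1}\t|\tspecies\t|")
        n_rows = len(rows)  # counted independently of the parser
        tree = load_taxonomy("\n".join(rows) + "\n")
        assert len(tree.nodes) == n_rows

    def test_unknown_rank_maps_to_no_rank(self, caplog):
        with caplog.at_level("WARNING"):
            tree = load_taxonomy("1\t1\tno_rank\troot\n2\t1\tbiotype\tx\n")
        assert tree.nodes[2].rank == "no_rank"
        assert any("unknown rank" in r.message for r in caplog.records)

    def test_names_table_fills_names(self):
        nodes = "1\t|\t1\t|\tno rank\t|\n2\t|\t1\t|\tspecies\t|"
        names = "2\t|\tEscherichia coli\t|\t\t|\tscientific name\t|"
        tree = load_taxonomy(nodes, names=names)
        assert tree.nodes[2].name == "Escherichia coli"


class TestResolveWithFallback:
    def test_present_taxon_zero_steps(self, small_tree):
        node, steps = resolve_with_fallback(small_tree, 6)
        assert node.taxon_id == 6 and steps == 0

    def test_absent_taxon_falls_back_to_parent(self, small_tree):
        node, steps = resolve_with_fallback(small_tree, 999, lineage=[4, 2, 1])
        assert node.taxon_id == 4 and steps == 1

    def test_deeper_fallback_counts_hops(self, small_tree):
        node, steps = resolve_with_fallback(small_tree, 999, lineage=[888, 5, 3])
        assert node.taxon_id == 5 and steps == 2

    def test_exhausted_lineage_raises(self, small_tree):
        with pytest.raises(UnresolvableTaxonError):
            resolve_with_fallback(small_tree, 999, lineage=[888, 777])


class TestPenalizedDistance:
    def test_identity_is_zero(self, small_tree):
        d = penalized_distance(small_tree, 6, 6, UNIT)
        assert d.raw_distance == 0
        assert d.path == [6]
        assert not d.crossed_domain

    def test_siblings_under_genus_unit_penalties(self, small_tree):
        assert penalized_distance(small_tree, 6, 7, UNIT).raw_distance == 2

    def test_domain_crossing_penalty_added_exactly_once(self, small_tree):
        low = RankPenaltySchedule(
            per_rank_penalty=dict(UNIT.per_rank_penalty), domain_crossing_penalty=1.0
        )
        high = RankPenaltySchedule(
            per_rank_penalty=dict(UNIT.per_rank_penalty), domain_crossing_penalty=5.0
        )
        d_low = penalized_distance(small_tree, 6, 8, low)
        d_high = penalized_distance(small_tree, 6, 8, high)
        assert d_low.crossed_domain and d_high.crossed_domain
        assert d_high.raw_distance - d_low.raw_distance == pytest.approx(4.0)
        # same-domain pair is unaffected by the surcharge
        assert (
            penalized_distance(small_tree, 6, 7, low).raw_distance
            == penalized_distance(small_tree, 6, 7, high).raw_distance
        )

    def test_unresolved_id_raises(self, small_tree):
        with pytest.raises(UnresolvableTaxonError):
            penalized_distance(small_tree, 6, 12345, UNIT)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_and_identity_on_random_trees(self, seed):
        rng = random.Random(seed)
        tree = make_random_tree(rng, rng.randint(10, 80))
        sched = RankPenaltySchedule()
        ids = list(tree.nodes)
        for _ in range(30):
            a, b = rng.choice(ids), rng.choice(ids)
            dab = penalized_distance(tree, a, b, sched).raw_distance
            dba = penalized_distance(tree, b, a, sched).raw_distance
            assert dab == pytest.approx(dba)
            assert penalized_distance(tree, a, a, sched).raw_distance == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_triangle_bound_via_intermediate(self, seed):
        rng = random.Random(100 + seed)
        tree = make_random_tree(rng, 50)
        sched = RankPenaltySchedule()
        ids = list(tree.nodes)
        for _ in range(30):
            a, b, c = (rng.choice(ids) for _ in range(3))
            direct = penalized_distance(tree, a, b, sched).raw_distance
            via = (
                penalized_distance(tree, a, c, sched).raw_distance
                + penalized_distance(tree, c, b, sched).raw_distance
            )
            assert via >= direct - 1e-9

    def test_monotone_in_penalties(self, small_tree):
        base = RankPenaltySchedule()
        ids = list(small_tree.nodes)
        for rank in ("genus", "species", "domain"):
            raised = dict(base.per_rank_penalty)
            raised[rank] = raised[rank] + 3.0
            sched_up = RankPenaltySchedule(
                per_rank_penalty=raised,
                domain_crossing_penalty=base.domain_crossing_penalty + 3.0,
            )
            for a in ids:
                for b in ids:
                    d0 = penalized_distance(small_tree, a, b, base).raw_distance
                    d1 = penalized_distance(small_tree, a, b, sched_up).raw_distance
                    assert d1 >= d0 - 1e-9


class TestMaxDistance:
    def test_single_node_tree_returns_floor(self):
        tree = load_taxonomy("1\t1\tno_rank\troot\n")
        assert max_distance(tree) == 1.0
        assert max_distance(tree, floor=2.5) == 2.5

    def test_small_two_domain_tree_matches_exhaustive_enumeration(self, small_tree):
        leaves = small_tree.leaves()
        expected = max(
            oracle_distance(small_tree, a, b, UNIT)
            for a in leaves
            for b in leaves
            if a != b
        )
        assert max_distance(small_tree, UNIT) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(4))
    def test_dominates_random_pair_distances(self, seed):
        rng = random.Random(7 + seed)
        tree = make_random_tree(rng, 120)
        sched = RankPenaltySchedule()
        maxd = max_distance(tree, sched)
        ids = list(tree.nodes)
        for _ in range(100):
            a, b = rng.choice(ids), rng.choice(ids)
            assert maxd >= penalized_distance(tree, a, b, sched).raw_distance - 1e-9

    def test_heuristic_mode_still_dominates_sampled_pairs(self):
        rng = random.Random(42)
        tree = make_random_tree(rng, 150)
        sched = RankPenaltySchedule()
        heuristic = max_distance(tree, sched, exact_leaf_limit=5)
        for _ in range(100):
            a, b = rng.choice(list(tree.nodes)), rng.choice(list(tree.nodes))
            assert heuristic >= penalized_distance(tree, a, b, sched).raw_distance - 1e-9
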