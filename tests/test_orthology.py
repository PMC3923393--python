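"""The assignment procedure: tree rule, E-value profile, five-orders
margin, the full decision chain and within-subfamily clade calls."""

import random

import pytest

from orthofam.io import SimilarityHit
from orthofam.orthology import (
    Assignment,
    ClassifyParams,
    ReferenceSet,
    UNCLASSIFIED,
    assign_by_five_orders,
    assign_by_tree,
    assign_clade,
    classify,
    read_assignments_tsv,
    subfamily_evalue_profile,
    write_assignments_tsv,
)
from orthofam.trees import read_newick

from conftest import random_tree_newick

PARAMS = ClassifyParams()

REFSET = ReferenceSet(
    family="FAM",
    subfamilies=(
        ("S1", (("S1", ("r1",)),)),
        ("S2", (("S2", ("r2",)),)),
    ),
    outgroups=("o",),
)


def _hit(q, s, e):
    return SimilarityHit(q, s, e, 50.0)


class TestReferenceSet:
    def test_duplicate_reference_rejected(self):
        with pytest.raises(ValueError, match="more than one"):
            ReferenceSet(
                family="F",
                subfamilies=(("A", (("A", ("x",)),)), ("B", (("B", ("x",)),))),
            )

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "ref.yaml"
        REFSET.to_yaml(p)
        back = ReferenceSet.from_yaml(p)
        assert back.reference_map() == REFSET.reference_map()
        assert back.subfamily_labels() == REFSET.subfamily_labels()

    def test_shipped_taxonomies_load(self):
        from orthofam import load_reference_set

        cdk = load_reference_set("cdk")
        assert len(cdk.subfamilies) == 8
        assert cdk.clades_of("CDK9") == ["CDK9", "CDK12/13"]
        assert cdk.clades_of("CDK10/11") == ["CDK10", "CDK11"]
        assert cdk.clades_of("CDK1") == ["CDK1", "CDK2/3"]
        assert cdk.clades_of("CDK5") == ["CDK5", "CDK16/17/18", "CDK14/15"]
        cyc = load_reference_set("cyclin")
        metazoan = [s for s in cyc.subfamily_labels() if s not in ("CLB", "CLN", "PCL")]
        assert len(metazoan) == 16
        groups = set(cyc.groups.values())
        assert groups == {"cyclin B-like", "cyclin Y-like", "cyclin C-like"}


class TestAssignByTree:
    def test_supported_single_subfamily(self):
        t = read_newick("((q,r1)90,(r2,o));")
        a = assign_by_tree(t, "q", REFSET, PARAMS)
        assert (a.subfamily, a.evidence, a.statistic) == ("S1", "tree", 90.0)

    def test_low_support_fails(self):
        t = read_newick("((q,r1)40,(r2,o));")
        assert assign_by_tree(t, "q", REFSET, PARAMS) is None

    def test_mixed_subfamilies_fail(self):
        t = read_newick("((q,(r1,r2)80)95,o);")
        assert assign_by_tree(t, "q", REFSET, PARAMS) is None

    def test_threshold_is_strict(self):
        t = read_newick("((q,r1)50,(r2,o));")
        assert assign_by_tree(t, "q", REFSET, PARAMS) is None

    def test_agrees_with_brute_force_clade_scan(self, rng):
        """Tree rule equals exhaustive evaluation over every clade."""
        for _ in range(60):
            n = rng.randint(4, 12)
            leaves = [f"L{j}" for j in range(n)]
            text = random_tree_newick(rng, leaves)
            t = read_newick(text)
            k = rng.randint(1, n - 1)
            ref_leaves = rng.sample(leaves, k)
            refset = ReferenceSet(
                family="F",
                subfamilies=tuple(
                    (f"S{j % 3}", ((f"S{j % 3}", tuple(
                        r for i, r in enumerate(ref_leaves) if i % 3 == j % 3
                    )),))
                    for j in range(min(3, k))
                ),
            )
            ref_map = refset.reference_map()
            queries = [l for l in leaves if l not in ref_map]
            if not queries:
                continue
            q = rng.choice(queries)

            # brute force: minimal clade containing q and any reference
            best = None
            for node in t.tree.preorder_node_iter():
                clade = frozenset(l.taxon.label for l in node.leaf_iter())
                refs_in = (clade & set(ref_map)) - {q}
                if q in clade and refs_in:
                    cand = (len(clade), clade, refs_in, getattr(node, "support", None))
                    if best is None or cand[0] < best[0]:
                        best = cand
            _, _, refs_in, support = best
            subfams = {ref_map[r] for r in refs_in}
            expected = None
            if len(subfams) == 1 and (support or 0) > PARAMS.min_support:
                expected = next(iter(subfams))

            got = assign_by_tree(t, q, refset, PARAMS)
            assert (got.subfamily if got else None) == expected


class TestEvalueProfile:
    def test_minimum_per_subfamily(self):
        refset = ReferenceSet(
            family="F", subfamilies=(("S1", (("S1", ("r1", "r1b")),)),)
        )
        hits = [_hit("q", "r1", 1e-30), _hit("q", "r1b", 1e-12)]
        assert subfamily_evalue_profile("q", hits, refset) == {"S1": 1e-30}

    def test_zero_evalue_floored(self):
        profile = subfamily_evalue_profile("q", [_hit("q", "r1", 0.0)], REFSET)
        assert profile == {"S1": 1e-180}

    def test_no_reference_hits_empty(self):
        assert subfamily_evalue_profile("q", [_hit("q", "zz", 1e-40)], REFSET) == {}


class TestFiveOrders:
    def test_clear_margin_assigns(self):
        a = assign_by_five_orders("q", {"S1": 1e-15, "S2": 1e-7}, PARAMS)
        assert a.subfamily == "S1" and a.statistic == pytest.approx(1e-8)

    def test_insufficient_margin_fails(self):
        assert assign_by_five_orders("q", {"S1": 1e-10, "S2": 1e-6}, PARAMS) is None

    def test_boundary_inclusive(self):
        a = assign_by_five_orders("q", {"S1": 1e-12, "S2": 1e-7}, PARAMS)
        assert a is not None and a.subfamily == "S1"

    def test_solo_profile_under_ceiling(self):
        a = assign_by_five_orders("q", {"S1": 1e-12}, PARAMS)
        assert a is not None and a.subfamily == "S1"

    def test_solo_profile_above_ceiling_fails(self):
        assert assign_by_five_orders("q", {"S1": 1e-8}, PARAMS) is None

    def test_empty_profile_none(self):
        assert assign_by_five_orders("q", {}, PARAMS) is None

    def test_scale_invariance(self, rng):
        """Decisions are unchanged by global E-value rescaling (the
        criterion is a ratio)."""
        for _ in range(200):
            k = rng.randint(2, 5)
            profile = {f"S{i}": 10.0 ** rng.uniform(-100, -3) for i in range(k)}
            c = 10.0 ** rng.uniform(-3, 0)
            scaled = {s: e * c for s, e in profile.items()}
            if min(scaled.values()) < PARAMS.evalue_floor:
                continue
            a = assign_by_five_orders("q", profile, PARAMS)
            b = assign_by_five_orders("q", scaled, PARAMS)
            assert (a.subfamily if a else None) == (b.subfamily if b else None)


class TestAssignClade:
    CDK9ISH = ReferenceSet(
        family="F",
        subfamilies=(
            ("S9", (("C9", ("r9",)), ("C12", ("r12a", "r12b")))),
            ("S1", (("S1", ("r1",)),)),
        ),
    )

    def test_inside_clade(self):
        t = read_newick("(((q,r12a)85,r12b)90,(r9,(r1,o)));")
        assert assign_clade(t, "q", "S9", self.CDK9ISH, PARAMS) == "C12"

    def test_below_common_stem_gives_none(self):
        t = read_newick("((q,((r12a,r12b)80,r9)75)90,(r1,o));")
        assert assign_clade(t, "q", "S9", self.CDK9ISH, PARAMS) is None

    def test_single_clade_subfamily_trivial(self):
        t = read_newick("((q,r1)90,(r9,o));")
        assert assign_clade(t, "q", "S1", self.CDK9ISH, PARAMS) == "S1"


class TestClassify:
    def test_tree_takes_precedence_over_evalues(self):
        t = read_newick("((q,r1)90,(r2,o));")
        hits = [_hit("q", "r2", 1e-100), _hit("q", "r1", 1e-3)]
        (a,) = classify([t], hits, REFSET, PARAMS, queries=["q"])
        assert a.evidence == "tree" and a.subfamily == "S1"

    def test_fallback_chain_to_five_orders(self):
        t = read_newick("((q,r1)40,(r2,o));")
        hits = [_hit("q", "r1", 1e-20), _hit("q", "r2", 1e-5)]
        (a,) = classify([t], hits, REFSET, PARAMS, queries=["q"])
        assert a.evidence == "five_orders" and a.subfamily == "S1"

    def test_unclassified_when_both_fail(self):
        t = read_newick("((q,r1)40,(r2,o));")
        hits = [_hit("q", "r1", 1e-8), _hit("q", "r2", 1e-6)]
        (a,) = classify([t], hits, REFSET, PARAMS, queries=["q"])
        assert a.subfamily == UNCLASSIFIED and a.evidence == "unclassified"

    def test_exactly_one_assignment_per_query(self):
        t = read_newick("(((qa,r1)90,qb)20,(r2,o));")
        hits = [_hit("qb", "r1", 1e-30)]
        out = classify([t], hits, REFSET, PARAMS)
        assert sorted(a.query for a in out) == ["qa", "qb"]

    def test_multi_tree_highest_support_wins(self):
        t1 = read_newick("((q,r1)60,(r2,o));")
        t2 = read_newick("((q,r1)95,(r2,o));")
        (a,) = classify([t1, t2], [], REFSET, PARAMS, queries=["q"])
        assert a.statistic == 95.0

    def test_conflicting_trees_fall_back(self):
        t1 = read_newick("((q,r1)90,(r2,o));")
        t2 = read_newick("((q,r2)95,(r1,o));")
        hits = [_hit("q", "r1", 1e-30), _hit("q", "r2", 1e-4)]
        (a,) = classify([t1, t2], hits, REFSET, PARAMS, queries=["q"])
        assert a.evidence == "five_orders"
        assert "conflict" in a.notes

    def test_uncovered_query_is_error(self):
        with pytest.raises(ValueError, match="zz"):
            classify([], [_hit("q", "r1", 1e-30)], REFSET, PARAMS, queries=["zz"])

    def test_tsv_round_trip(self, tmp_path):
        t = read_newick("((q,r1)90,(r2,o));")
        out = classify([t], [], REFSET, PARAMS, queries=["q"])
        p = tmp_path / "a.tsv"
        write_assignments_tsv(out, p)
        assert read_assignments_tsv(p) == out
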