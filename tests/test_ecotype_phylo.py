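import numpy as np
import pytest
import skbio

from mitorec import ecotype_phylo as eco
from mitorec.align_core import encode
from mitorec.formats_io import Interval


# ---------------------------------------------------------------------------
# SNP caller boundary semantics
# ---------------------------------------------------------------------------

def _pileup(columns):
    """columns: list of (ref_base, {base: count}) -> pileup + ref codes."""
    L = len(columns)
    counts = np.zeros((4, L), dtype=np.int32)
    ref = np.zeros(L, dtype=np.uint8)
    for i, (r, by_base) in enumerate(columns):
        ref[i] = "ACGT".index(r)
        for b, n in by_base.items():
            counts["ACGT".index(b), i] = n
    return counts, ref

def test_snp_called_depth6_fraction_83():
    counts, ref = _pileup([("A", {"A": 1, "T": 5})])
    calls = eco.call_snps(counts, ref)
    assert len(calls) == 1
    assert calls[0].alt_allele == "T"
    assert calls[0].depth == 6
    assert calls[0].allele_fraction == pytest.approx(5 / 6)


def test_snp_not_called_depth5():
    counts, ref = _pileup([("A", {"T": 5})])
    assert eco.call_snps(counts, ref) == []  # depth not > 5


def test_snp_not_called_fraction_exactly_80():
    counts, ref = _pileup([("A", {"A": 2, "T": 8})])
    assert eco.call_snps(counts, ref) == []  # fraction not > 0.8


def test_snp_mask_suppresses():
    counts, ref = _pileup([("A", {"T": 30}), ("C", {"G": 30})])
    calls = eco.call_snps(counts, ref, mask=[Interval(0, 1)])
    assert [c.position for c in calls] == [1]


# ---------------------------------------------------------------------------
# stoichiometry
# ---------------------------------------------------------------------------

def test_substoichiometric_example():
    label, fraction = eco.label_stoichiometry(2, median_depth=200)
    assert label == "substoichiometric"
    assert fraction < 0.05


def test_predominant_at_expected_support():
    expected = 200 / 72 * 148
    label, fraction = eco.label_stoichiometry(int(expected), median_depth=200)
    assert label == "predominant"
    assert fraction == pytest.approx(1.0, abs=0.01)


def test_intermediate_band():
    expected = 200 / 72 * 148
    label, _ = eco.label_stoichiometry(int(0.2 * expected), median_depth=200)
    assert label == "intermediate"


def test_zero_median_depth_raises():
    with pytest.raises(ValueError):
        eco.label_stoichiometry(5, median_depth=0)


# ---------------------------------------------------------------------------
# TN93 + NJ
# ---------------------------------------------------------------------------

def test_tn93_identical_zero():
    a = encode("ACGTACGTAC")
    assert eco.tn93_distance(a, a) == 0.0


def test_tn93_symmetric():
    rng = np.random.default_rng(0)
    a = rng.integers(0, 4, 200).astype(np.uint8)
    b = a.copy()
    b[rng.choice(200, 20, replace=False)] = rng.integers(0, 4, 20)
    assert eco.tn93_distance(a, b) == pytest.approx(eco.tn93_distance(b, a))


def test_tn93_increases_with_divergence():
    rng = np.random.default_rng(1)
    a = rng.integers(0, 4, 500).astype(np.uint8)
    prev = 0.0
    for k in (5, 25, 60):
        b = a.copy()
        idx = rng.choice(500, k, replace=False)
        b[idx] = (b[idx] + rng.integers(1, 4, k)) % 4
        d = eco.tn93_distance(a, b)
        assert d > prev
        prev = d


def test_nj_recovers_additive_four_taxon_tree():
    # ((A,B),(C,D)) with internal edge 3
    D = np.array(
        [
            [0, 2, 9, 9],
            [2, 0, 9, 9],
            [9, 9, 0, 2],
            [9, 9, 2, 0],
        ],
        dtype=float,
    )
    tree = skbio.TreeNode.read([eco.neighbor_joining(D, ["A", "B", "C", "D"])])
    sides = {
        frozenset(t.name for t in n.tips())
        for n in tree.traverse(include_self=False)
        if not n.is_tip()
    }
    assert frozenset({"A", "B"}) in sides or frozenset({"C", "D"}) in sides


def test_nj_identical_taxa_sisters():
    D = np.array(
        [[0, 0, 5], [0, 0, 5], [5, 5, 0]], dtype=float
    )
    nwk = eco.neighbor_joining(D, ["A", "B", "C"])
    tree = skbio.TreeNode.read([nwk])
    assert sorted(t.name for t in tree.tips()) == ["A", "B", "C"]


def test_nj_three_taxa_newick_valid():
    D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
    tree = skbio.TreeNode.read([eco.neighbor_joining(D, ["x", "y", "z"])])
    assert len(list(tree.tips())) == 3


def test_nj_input_order_independence():
    rng = np.random.default_rng(2)
    n = 8
    # additive distances from a random tree: use random ultrametric-ish
    base = rng.random((n, n))
    D = (base + base.T) / 2 + 1
    np.fill_diagonal(D, 0)
    names = [f"t{i}" for i in range(n)]
    t1 = skbio.TreeNode.read([eco.neighbor_joining(D, names)])
    order = rng.permutation(n)
    D2 = D[np.ix_(order, order)]
    names2 = [names[i] for i in order]
    t2 = skbio.TreeNode.read([eco.neighbor_joining(D2, names2)])
    tips = frozenset(names)
    b1 = set(eco._bipartitions(t1, tips))
    b2 = set(eco._bipartitions(t2, tips))
    assert b1 == b2


def test_distance_matrix_triangle_inequality(panel_results):
    # log-corrected (TN93) distances are convex in the mismatch fraction and
    # can overshoot strict additivity at the third decimal; the panel matrix
    # must still be metric to within that correction-scale tolerance
    D = panel_results.phylogeny.distances.values
    n = len(D)
    rng = np.random.default_rng(3)
    for _ in range(500):
        i, j, k = rng.integers(0, n, 3)
        assert D[i, j] <= D[i, k] + D[k, j] + 0.01


# ---------------------------------------------------------------------------
# matrix building and exclusions
# ---------------------------------------------------------------------------

def test_exclude_columns_rules():
    m = eco.SnpMatrix(
        names=["a", "b", "c", "d"],
        positions=np.array([10, 20, 30]),
        data=np.array(
            [
                [0, eco.MISSING, 1],
                [0, eco.MISSING, 1],
                [1, eco.MISSING, eco.MISSING],
                [1, 2, 1],
            ],
            dtype=np.uint8,
        ),
    )
    out = eco.exclude_columns(m)
    # column 1 missing in 75% -> dropped; column 2 has one missing cell -> dropped
    assert list(out.positions) == [10]


def test_build_phylogeny_requires_three():
    m = eco.SnpMatrix(
        names=["a", "b"], positions=np.array([1]), data=np.zeros((2, 1), np.uint8)
    )
    with pytest.raises(ValueError):
        eco.build_phylogeny(m)


def test_star_tree_flagged():
    m = eco.SnpMatrix(
        names=["a", "b", "c", "d"],
        positions=np.arange(5),
        data=np.zeros((4, 5), np.uint8),
    )
    phy = eco.build_phylogeny(m, n_bootstrap=5)
    assert phy.star


# ---------------------------------------------------------------------------
# group assignment
# ---------------------------------------------------------------------------

def test_assign_groups_k1():
    tree = skbio.TreeNode.read(["((a:1,b:1):2,(c:1,d:1):2,e:1);"])
    groups = eco.assign_groups(tree, k=1)
    assert set(groups.values()) == {0}


def test_assign_groups_k_exceeds_leaves():
    tree = skbio.TreeNode.read(["(a:1,b:1,c:1);"])
    with pytest.raises(ValueError):
        eco.assign_groups(tree, k=5)


def test_assign_groups_star_tree_errors():
    tree = skbio.TreeNode.read(["(a:1,b:1,c:1,d:1);"])
    with pytest.raises(ValueError):
        eco.assign_groups(tree, k=3)


def test_assign_groups_cuts_longest_edges():
    tree = skbio.TreeNode.read(["((a:1,b:1):5,(c:1,d:1):5,(e:1,f:1):0.1);"])
    groups = eco.assign_groups(tree, k=3)
    as_sets = {}
    for nm, g in groups.items():
        as_sets.setdefault(g, set()).add(nm)
    assert sorted(map(sorted, as_sets.values())) == [["a", "b"], ["c", "d"], ["e", "f"]]


def test_panel_groups_recover_planted_clades(panel_fixture, panel_results):
    from collections import defaultdict

    inv = defaultdict(set)
    tinv = defaultdict(set)
    for e, g in panel_results.groups.items():
        inv[g].add(e)
    for e, g in panel_fixture.truth.groups.items():
        tinv[g].add(e)
    assert sorted(map(sorted, inv.values())) == sorted(map(sorted, tinv.values()))


# ---------------------------------------------------------------------------
# structural variants on the panel
# ---------------------------------------------------------------------------

def test_panel_sv_type_recovery(panel_fixture, panel_results):
    truth = panel_fixture.truth
    res = panel_results
    for sv in truth.svs:
        matches = [
            k
            for k, car in res.sv_carriers.items()
            if k.startswith(sv.kind)
            and set(sv.carriers) <= (car | res.sv_trace.get(k, set()))
        ]
        assert matches, f"{sv.name} ({sv.kind}) not recovered"


def test_panel_rec_calls_carry_repeat(panel_results):
    for calls in panel_results.sv_calls.values():
        for c in calls:
            if c.kind == "REC":
                assert c.repeat_name
            if c.kind == "NHEJ":
                assert not c.repeat_name


def test_panel_del_sizes_close_to_truth(panel_fixture, panel_results):
    truth = panel_fixture.truth
    dels = [sv for sv in truth.svs if sv.kind == "DEL"]
    for sv in dels:
        carrier = sv.carriers[0]
        called = [
            c
            for c in panel_results.sv_calls[carrier]
            if c.kind == "DEL" and abs(c.breakpoint1.start - sv.start) < 40
        ]
        assert called
        # gap edges blur by a few bases where overhanging reads taper off
        assert abs(called[0].size - (sv.end - sv.start)) <= 6


def test_trace_events_substoichiometric(panel_fixture, panel_results):
    truth = panel_fixture.truth
    traced = [(e.name, sv) for e in truth.ecotypes for sv, f in e.trace]
    assert traced
    for name, sv_name in traced:
        assert any(name in carriers for carriers in panel_results.sv_trace.values()), (
            name, sv_name,
        )


def test_snp_precision_recall_on_panel(panel_fixture, panel_results):
    truth = panel_fixture.truth
    # exclude repeat copies collapsed by a REC event in that ecotype: the
    # hybrid copy legitimately reads as sequence change
    def rec_spans(name):
        spans = []
        for svn in truth.ecotype(name).svs:
            sv = truth.sv(svn)
            if sv.kind == "REC":
                r = truth.reference.repeat(sv.repeat_name)
                spans += [(r.copy1.start, r.copy1.end), (r.copy2.start, r.copy2.end)]
        return spans

    fp = fn = 0
    for e in truth.ecotypes:
        spans = rec_spans(e.name)
        skip = lambda p: any(a <= p < b for a, b in spans)
        planted = {(p, alt) for p, _, alt in e.snps if not skip(p)}
        called = {
            (s.position, s.alt_allele)
            for s in panel_results.snps[e.name]
            if not skip(s.position)
        }
        fp += len(called - planted)
        fn += len(planted - called)
    assert fp == 0 and fn == 0


def test_concordance_examples():
    groups = {"a": 0, "b": 0, "c": 1, "d": 1}
    df, overall = eco.concordance_report(
        {"stem": {"a", "b"}, "terminal": {"c"}, "cross": {"a", "c"}}, groups
    )
    rows = {r.sv: r for r in df.itertuples()}
    assert rows["stem"].max_group_fraction == 1.0
    assert rows["terminal"].nested
    assert rows["cross"].max_group_fraction == 0.5 and not rows["cross"].nested
    assert overall == pytest.approx(2 / 3)


def test_stem_svs_perfectly_nested(panel_results):
    df = panel_results.concordance
    assert panel_results.concordance_overall == 1.0
    assert df["nested"].all()
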