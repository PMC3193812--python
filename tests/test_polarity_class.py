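import numpy as np
import pytest

from mitorec import mapper as mp
from mitorec import pipeline as pl
from mitorec import polarity_class as pc
from mitorec import synthetic_data as sd
from mitorec.align_core import RepeatPair
from mitorec.formats_io import Interval


# ---------------------------------------------------------------------------
# flank_depth
# ---------------------------------------------------------------------------

def test_wt_flank_depths_symmetric(deep_fixture, deep_results):
    truth = deep_fixture.truth
    res = deep_results
    wt = res.placements["WT"]
    r = next(
        p for p, _ in res.calls.active if p.length > 150
    )
    counts, flags = pc.flank_depth(wt, r, catalog=res.catalog)
    vals = np.array([counts[k] for k in (1, 2, 3, 4) ], dtype=float)
    assert vals.min() > 0
    # identical stoichiometry: within binomial noise of each other
    assert vals.max() / vals.min() < 1.6


def test_class_one_mixture_arithmetic(deep_fixture, deep_results, deep_truth_match):
    truth = deep_fixture.truth
    res = deep_results
    gen1_f, adv_f = sd.default_fractions(truth, deep_fixture.seed)
    inv = {v: k for k, v in deep_truth_match.items()}
    for planted in truth.repeats:
        if planted.spec.fate_class != "I":
            continue
        table = res.flank_tables[inv[planted.name]]
        f = adv_f[planted.name]
        dep_region = 1 if planted.spec.donor == 1 else 3
        inc_region = 3 if planted.spec.donor == 1 else 1
        assert table.changes["msh1_adv"][dep_region] == pytest.approx(-f, abs=0.22)
        assert table.changes["msh1_adv"][inc_region] > 0.2


def test_flank_window_shrinks_near_neighbor():
    g_len = 50_000
    pair = RepeatPair(
        name="A", copy1=Interval(10_000, 10_200), copy2=Interval(30_000, 30_200),
        orientation="direct", length=200, identity=99.0, genome_length=g_len,
    )
    neighbor = RepeatPair(
        name="B", copy1=Interval(10_300, 10_400), copy2=Interval(40_000, 40_100),
        orientation="direct", length=100, identity=99.0, genome_length=g_len,
    )
    from mitorec.formats_io import GenomeSeq

    ps = mp.PlacementSet(
        genome=GenomeSeq("m", "A" * g_len), read_length=36, insert_mean=220,
        insert_sd=20, status=np.empty(0, np.int8), pos1=np.empty(0, np.int64),
        strand1=np.empty(0, np.int8), pos2=np.empty(0, np.int64),
        strand2=np.empty(0, np.int8), end_distance=np.empty(0, np.int64),
        rescued=np.empty(0, np.int8),
        reads_fwd1=np.empty((0, 36), np.uint8), reads_rev1=np.empty((0, 36), np.uint8),
        reads_fwd2=np.empty((0, 36), np.uint8), reads_rev2=np.empty((0, 36), np.uint8),
    )
    counts, flags = pc.flank_depth(ps, pair, catalog=[pair, neighbor])
    assert any("shrunk" in f and "100 bp" in f for f in flags)


# ---------------------------------------------------------------------------
# polarity
# ---------------------------------------------------------------------------

def test_polarity_full_recovery(deep_fixture, deep_results, deep_truth_match):
    truth = deep_fixture.truth
    inv = {v: k for k, v in deep_truth_match.items()}
    assert len(inv) == 47
    for planted in truth.repeats:
        call = deep_results.polarity[inv[planted.name]]
        assert call.donor == planted.spec.donor, planted.name


def test_class_one_geometry(deep_fixture, deep_results, deep_truth_match):
    # donor = copy1, class I: depleted region 1, increased region 3
    truth = deep_fixture.truth
    inv = {v: k for k, v in deep_truth_match.items()}
    checked = 0
    for planted in truth.repeats:
        if planted.spec.fate_class != "I" or planted.spec.donor != 1:
            continue
        call = deep_results.polarity[inv[planted.name]]
        assert call.depleted_region == 1
        assert call.increased_region == 3
        checked += 1
    assert checked >= 5


def test_fate_full_recovery(deep_fixture, deep_results, deep_truth_match):
    truth = deep_fixture.truth
    inv = {v: k for k, v in deep_truth_match.items()}
    for planted in truth.repeats:
        call = deep_results.polarity[inv[planted.name]]
        assert call.fate_class == planted.spec.fate_class, planted.name


def test_flat_table_without_junction_is_indeterminate():
    table = pc.FlankChangeTable(
        repeat="X",
        regions={r: {"WT": 1.0, "msh1_adv": 1.0} for r in (1, 2, 3, 4)},
        changes={"msh1_adv": {1: 0.02, 2: -0.05, 3: 0.01, 4: 0.03}},
    )
    from mitorec.junction_detect import JunctionCluster

    cluster = JunctionCluster(
        window1=Interval(1, 2), window2=Interval(5_000, 5_001),
        signature=(0, 1), members=[], support_by_library={},
    )
    pair = RepeatPair(
        name="X", copy1=Interval(10_000, 10_100), copy2=Interval(30_000, 30_100),
        orientation="direct", length=100, identity=99.0, genome_length=50_000,
    )
    call = pc.call_polarity(table, cluster, pair)
    assert call.fate_class == "indeterminate"
    assert call.donor is None


# ---------------------------------------------------------------------------
# classify_fate on constructed tables
# ---------------------------------------------------------------------------

def _table(gen1, adv):
    return pc.FlankChangeTable(
        repeat="X",
        regions={r: {} for r in (1, 2, 3, 4)},
        changes={
            "msh1_gen1": dict(zip((1, 2, 3, 4), gen1)),
            "msh1_adv": dict(zip((1, 2, 3, 4), adv)),
        },
    )


def test_fate_class_one_example():
    t = _table([-0.2, 0.0, 0.1, 0.0], [-0.8, 0.0, 0.4, 0.0])
    assert pc.classify_fate(t, {"msh1_gen1": 0.1, "msh1_adv": 0.3}) == "I"


def test_fate_class_two_example():
    t = _table([0.02, 0.1, 0.05, 0.03], [-0.04, 0.2, 0.1, 0.02])
    assert pc.classify_fate(t, {"msh1_gen1": 15.0, "msh1_adv": 60.0}) == "II"


def test_fate_no_progression_indeterminate():
    t = _table([-0.3, 0.0, 0.1, 0.0], [-0.3, 0.0, 0.1, 0.0])
    assert pc.classify_fate(t, {"msh1_gen1": 0.3, "msh1_adv": 0.3}) == "indeterminate"


def test_fate_requires_both_generations():
    t = _table([0, 0, 0, 0], [0, 0, 0, 0])
    t.changes.pop("msh1_gen1")
    with pytest.raises(ValueError):
        pc.classify_fate(t, {})


# ---------------------------------------------------------------------------
# generation trend
# ---------------------------------------------------------------------------

def test_class_one_panel_trend_strongly_negative():
    # a class-I-only panel couples recombinant gain to parental loss
    rng = np.random.default_rng(60)
    specs = [
        sd.RepeatSpec(
            name=f"C{i}", length=int(rng.integers(100, 220)),
            identity=float(rng.uniform(93, 97)), donor=int(rng.integers(1, 3)),
            fate_class="I",
        )
        for i in range(8)
    ]
    truth = sd.build_reference(40_000, specs, seed=61)
    recs = [sd.make_recombinant(truth, s.name, seed=61) for s in specs]
    adv_f = {s.name: float(rng.uniform(0.4, 0.85)) for s in specs}
    gen1_f = {k: 0.6 * v for k, v in adv_f.items()}
    libs = {}
    for cond, cov, fr, stream in (
        ("WT", 150, {}, 0), ("msh1_gen1", 200, gen1_f, 1), ("msh1_adv", 200, adv_f, 2)
    ):
        libs[cond] = sd.simulate_library(
            truth, recs, sd.LibrarySpec(condition=cond, coverage=cov, fractions=fr),
            seed=61, stream=stream,
        )
    res = pl.analyze_recombination(truth.genome, libs)
    assert len(res.calls.active) == 8
    assert res.trend_correlation < -0.8


def test_class_two_panel_parental_flat(deep_fixture, deep_results, deep_truth_match):
    truth = deep_fixture.truth
    inv = {v: k for k, v in deep_truth_match.items()}
    changes = []
    for planted in truth.repeats:
        if planted.spec.fate_class != "II":
            continue
        table = deep_results.flank_tables[inv[planted.name]]
        changes.append(table.min_change("msh1_adv")[1])
    assert np.mean(np.abs(changes)) < 0.15


def test_single_repeat_trend_correlation_nan():
    t = _table([-0.2, 0, 0, 0], [-0.7, 0, 0, 0])
    df, corr = pc.generation_trend({"X": t}, {"X": {"msh1_gen1": 0.1, "msh1_adv": 0.4}})
    assert len(df) == 1
    assert np.isnan(corr)


def test_generation_trend_requires_two_generations():
    with pytest.raises(ValueError):
        pc.generation_trend({}, {}, generations=("msh1_adv",))


# ---------------------------------------------------------------------------
# normalization invariance
# ---------------------------------------------------------------------------

def _triple(ps: mp.PlacementSet) -> mp.PlacementSet:
    rep = lambda a: np.concatenate([a, a, a])
    rep2 = lambda a: np.concatenate([a, a, a], axis=0)
    return mp.PlacementSet(
        genome=ps.genome, read_length=ps.read_length, insert_mean=ps.insert_mean,
        insert_sd=ps.insert_sd, status=rep(ps.status), pos1=rep(ps.pos1),
        strand1=rep(ps.strand1), pos2=rep(ps.pos2), strand2=rep(ps.strand2),
        end_distance=rep(ps.end_distance), rescued=rep(ps.rescued),
        reads_fwd1=rep2(ps.reads_fwd1), reads_rev1=rep2(ps.reads_rev1),
        reads_fwd2=rep2(ps.reads_fwd2), reads_rev2=rep2(ps.reads_rev2),
        mm1=rep(ps.mm1), mm2=rep(ps.mm2),
    )


def test_median_normalization_coverage_invariance(deep_results):
    res = deep_results
    pair = res.calls.active[0][0]
    base = pc.flank_change_table(
        pair, res.placements, res.median_depth, catalog=res.catalog
    )
    scaled_pl = {k: (_triple(v) if k == "msh1_adv" else v) for k, v in res.placements.items()}
    scaled_md = {
        k: (3 * v if k == "msh1_adv" else v) for k, v in res.median_depth.items()
    }
    scaled = pc.flank_change_table(pair, scaled_pl, scaled_md, catalog=res.catalog)
    for r in (1, 2, 3, 4):
        assert scaled.changes["msh1_adv"][r] == pytest.approx(
            base.changes["msh1_adv"][r], abs=1e-9
        )
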