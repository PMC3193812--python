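import hashlib

import numpy as np
import pytest

from mitorec import synthetic_data as sd
from mitorec.align_core import global_align, smith_waterman
from mitorec.formats_io import revcomp


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

def test_default_catalog_shape():
    cat = sd.default_catalog(0)
    assert len(cat) == 47
    novel = [s for s in cat if s.novel]
    assert len(novel) == 14
    assert min(s.length for s in novel) == 50
    assert max(s.length for s in novel) == 250
    assert max(s.length for s in cat) == 556
    assert all(85.0 <= s.identity <= 98.0 for s in cat)
    # the smallest novel repeats carry the highest identity
    ordered = sorted(novel, key=lambda s: s.length)
    idents = [s.identity for s in ordered]
    assert idents == sorted(idents, reverse=True)


# ---------------------------------------------------------------------------
# build_reference
# ---------------------------------------------------------------------------

def test_identical_pair_embeds_equal_windows():
    spec = sd.RepeatSpec(name="X", length=100, identity=100.0)
    truth = sd.build_reference(10_000, [spec], seed=1, n_decoys=0)
    r = truth.repeats[0]
    g = truth.genome.sequence
    assert g[r.copy1.start : r.copy1.end] == g[r.copy2.start : r.copy2.end]


def test_96_5_percent_pair_has_three_mismatch_columns():
    # round(86 * (1 - 0.965)) == 3; verified by exhaustive pairwise alignment
    spec = sd.RepeatSpec(name="X", length=86, identity=96.5)
    truth = sd.build_reference(10_000, [spec], seed=2, n_decoys=0)
    r = truth.repeats[0]
    aln = global_align(r.seq1, r.seq2)
    assert aln.mismatches == 3
    assert aln.gap_columns == 0


def test_planted_identity_matches_recomputed():
    truth = sd.build_reference(100_000, sd.default_catalog(3), seed=3)
    for r in truth.repeats:
        aln = smith_waterman(r.seq1, r.seq2)
        assert aln.identity == pytest.approx(r.identity, abs=0.5), r.name


def test_full_catalog_bounds(msh1_fixture):
    truth = msh1_fixture.truth
    assert len(truth.repeats) == 47
    lengths = [r.columns for r in truth.repeats]
    idents = [r.identity for r in truth.repeats]
    assert min(lengths) == 50 and max(lengths) == 556
    assert min(idents) == pytest.approx(85.0, abs=0.05)
    assert max(idents) <= 98.0


def test_infeasible_placement_raises():
    cat = sd.default_catalog(0)
    with pytest.raises(ValueError, match="genome"):
        sd.build_reference(20_000, cat, seed=0)


def test_manual_placement_conflict_raises():
    specs = [
        sd.RepeatSpec(name="A", length=100, identity=100.0, copy1_start=1000, copy2_start=1050),
    ]
    with pytest.raises(ValueError, match="conflict"):
        sd.build_reference(10_000, specs, seed=0, n_decoys=0)


def test_inverted_pair_planted():
    spec = sd.RepeatSpec(name="I", length=120, identity=100.0, orientation="inverted")
    truth = sd.build_reference(12_000, [spec], seed=4, n_decoys=0)
    r = truth.repeats[0]
    g = truth.genome.sequence
    assert g[r.copy2.start : r.copy2.end] == revcomp(g[r.copy1.start : r.copy1.end])


# ---------------------------------------------------------------------------
# make_recombinant
# ---------------------------------------------------------------------------

def test_recombinant_identical_pair():
    spec = sd.RepeatSpec(name="X", length=556, identity=100.0, donor=1)
    truth = sd.build_reference(20_000, [spec], seed=5, n_decoys=0)
    mol = sd.make_recombinant(truth, "X")
    r = truth.repeats[0]
    g = truth.genome
    assert mol.sequence.startswith(
        g.fetch(r.copy2.start - mol.flank, r.copy2.start)
    )  # recipient (copy2) upstream flank
    assert mol.sequence.endswith(g.fetch(r.copy1.end, r.copy1.end + mol.flank))
    assert mol.site_origin == {}


def test_recombinant_carries_donor_alleles(msh1_fixture):
    truth = msh1_fixture.truth
    cc = truth.repeat("CC")
    mol = sd.make_recombinant(truth, "CC")
    donor_seq = cc.seq1 if cc.spec.donor == 1 else cc.seq2
    rep = mol.sequence[mol.repeat_start : mol.repeat_start + mol.repeat_len]
    assert rep == donor_seq
    assert all(v == "donor" for v in mol.site_origin.values())


def test_recombinant_snp_override():
    spec = sd.RepeatSpec(name="X", length=120, identity=95.0, donor=1)
    truth = sd.build_reference(12_000, [spec], seed=6, n_decoys=0)
    r = truth.repeats[0]
    snp_cols = [p.column for p in r.polymorphisms if p.kind == "SNP"]
    mol = sd.make_recombinant(truth, "X", snp_overrides={snp_cols[0]: "recipient"})
    rep = mol.sequence[mol.repeat_start : mol.repeat_start + mol.repeat_len]
    poly = r.polymorphisms[0]
    # donor is copy1; the overridden site carries the copy2 (recipient) allele
    assert rep[poly.offset1] == poly.allele2
    assert mol.site_origin[snp_cols[0]] == "recipient"


def test_recombinant_both_products_refused(msh1_fixture):
    with pytest.raises(ValueError, match="reciprocal"):
        sd.make_recombinant(msh1_fixture.truth, "CC", both_products=True)


def test_recombinant_short_repeat_refused():
    spec = sd.RepeatSpec(name="S", length=40, identity=100.0)
    truth = sd.build_reference(10_000, [spec], seed=7, n_decoys=0)
    with pytest.raises(ValueError, match="50"):
        sd.make_recombinant(truth, "S")


# ---------------------------------------------------------------------------
# simulate_library
# ---------------------------------------------------------------------------

def test_library_total_bases():
    spec = sd.RepeatSpec(name="X", length=100, identity=100.0)
    truth = sd.build_reference(10_000, [spec], seed=8, n_decoys=0)
    lib = sd.simulate_library(
        truth, [], sd.LibrarySpec(condition="WT", coverage=10), seed=8
    )
    total = lib.n_pairs * 2 * lib.read_length
    assert abs(total - 100_000) / 100_000 < 0.05


def test_wt_library_has_no_recombinant_molecules(msh1_fixture):
    wt = msh1_fixture.libraries["WT"]
    assert all(not n.startswith("rec_") for n in wt.mol_names)


def test_recombinant_fraction_recovered_in_truth():
    spec = sd.RepeatSpec(name="F", length=100, identity=97.0, donor=1, fate_class="II")
    truth = sd.build_reference(10_000, [spec], seed=9, n_decoys=0)
    mol = sd.make_recombinant(truth, "F")
    lib = sd.simulate_library(
        truth, [mol],
        sd.LibrarySpec(condition="adv", coverage=50, fractions={"F": 0.4}),
        seed=9,
    )
    rec_idx = lib.mol_names.index("rec_F")
    n_rec = int((lib.mol_index == rec_idx).sum())
    seg_len = len(mol.sequence)
    expected = 0.4 * 50 * seg_len / 72
    assert abs(n_rec - expected) <= 3 * np.sqrt(expected)


def test_unknown_repeat_fraction_raises():
    spec = sd.RepeatSpec(name="X", length=100, identity=100.0)
    truth = sd.build_reference(10_000, [spec], seed=10, n_decoys=0)
    with pytest.raises(ValueError, match="unknown repeat"):
        sd.simulate_library(
            truth, [], sd.LibrarySpec(condition="x", coverage=5, fractions={"NOPE": 0.5}),
            seed=0,
        )


def test_fraction_out_of_range_raises():
    with pytest.raises(ValueError):
        sd.LibrarySpec(condition="x", coverage=5, fractions={"A": 1.5})


def test_insert_length_truncation():
    spec = sd.RepeatSpec(name="X", length=100, identity=100.0)
    truth = sd.build_reference(10_000, [spec], seed=11, n_decoys=0)
    lib = sd.simulate_library(
        truth, [], sd.LibrarySpec(condition="WT", coverage=20), seed=11
    )
    assert lib.frag_len.min() >= 2 * lib.read_length
    assert lib.frag_len.max() <= 220 + 4 * 20


def test_deterministic_fastq(tmp_path):
    spec = sd.RepeatSpec(name="X", length=100, identity=100.0)
    truth = sd.build_reference(10_000, [spec], seed=12, n_decoys=0)
    sums = []
    for run in range(2):
        lib = sd.simulate_library(
            truth, [], sd.LibrarySpec(condition="WT", coverage=10), seed=99
        )
        p1, p2 = tmp_path / f"r{run}_1.fq", tmp_path / f"r{run}_2.fq"
        lib.to_fastq(p1, p2)
        sums.append(
            (hashlib.md5(p1.read_bytes()).hexdigest(), hashlib.md5(p2.read_bytes()).hexdigest())
        )
    assert sums[0] == sums[1]


def test_truth_table_completeness(msh1_fixture):
    for lib in msh1_fixture.libraries.values():
        assert (lib.mol_index >= 0).all()
        assert lib.mol_index.max() < len(lib.mol_names)
        assert len(lib.mol_index) == lib.n_pairs


def test_asymmetry_one_junction_per_repeat(msh1_fixture):
    # exactly one recombinant molecule exists per repeat; no reciprocal form
    for lib in msh1_fixture.libraries.values():
        rec_names = [n for n in lib.mol_names if n.startswith("rec_")]
        assert len(rec_names) == len(set(rec_names))


def test_error_model_substitutions():
    spec = sd.RepeatSpec(name="X", length=100, identity=100.0)
    truth = sd.build_reference(10_000, [spec], seed=13, n_decoys=0)
    clean = sd.simulate_library(
        truth, [], sd.LibrarySpec(condition="WT", coverage=10), seed=13
    )
    noisy = sd.simulate_library(
        truth, [], sd.LibrarySpec(condition="WT", coverage=10, error_rate=0.01),
        seed=13,
    )
    diff = (clean.codes1 != noisy.codes1).mean()
    assert 0.004 < diff < 0.02


# ---------------------------------------------------------------------------
# ecotype panel generator
# ---------------------------------------------------------------------------

def test_panel_genomes_match_truth_edits():
    ref = sd.build_reference(50_000, sd.panel_reference_catalog(1), 1, n_decoys=2)
    spec = sd.EcotypePanelSpec(n_ecotypes=6, n_groups=2, trace_events=0)
    truth = sd.make_ecotype_panel(ref, spec, seed=20)
    for e in truth.ecotypes:
        g = truth.ecotype_genome(e.name)
        deleted = sum(truth.sv(n).end - truth.sv(n).start for n in e.svs)
        assert g.length == ref.genome.length - deleted


def test_panel_single_branch_snp_counts():
    ref = sd.build_reference(50_000, sd.panel_reference_catalog(2), 2, n_decoys=2)
    spec = sd.EcotypePanelSpec(
        n_ecotypes=4, n_groups=2, n_nhej=0, n_rec=0, n_del=0, trace_events=0
    )
    truth = sd.make_ecotype_panel(ref, spec, seed=21)
    for e in truth.ecotypes:
        g = truth.ecotype_genome(e.name)
        diffs = sum(
            1 for a, b in zip(g.sequence, ref.genome.sequence) if a != b
        )
        assert diffs == len(e.snps)


def test_panel_snp_suppression_in_large_repeats(panel_fixture):
    truth = panel_fixture.truth
    ref = truth.reference
    large = [
        iv
        for r in ref.repeats
        if r.columns >= 1000
        for iv in (r.copy1, r.copy2)
    ]
    large_bp = sum(iv.length for iv in large)
    all_positions = {p for e in truth.ecotypes for p, _, _ in e.snps}
    inside = sum(
        1 for p in all_positions if any(iv.start <= p < iv.end for iv in large)
    )
    genome_density = len(all_positions) / ref.genome.length
    expected_unsuppressed = genome_density * large_bp
    # suppression factor 66: essentially no SNPs land inside large repeats
    assert inside <= max(3, expected_unsuppressed / 8)


def test_panel_groups_are_guide_tree_clades(panel_fixture):
    import skbio

    truth = panel_fixture.truth
    tree = skbio.TreeNode.read([truth.tree_newick])
    sides = [
        frozenset(t.name for t in n.tips())
        for n in tree.traverse(include_self=False)
        if not n.is_tip()
    ]
    from collections import defaultdict

    groups = defaultdict(set)
    for e, g in truth.groups.items():
        groups[g].add(e)
    n_clades = sum(1 for mem in groups.values() if frozenset(mem) in sides)
    assert n_clades >= len(groups) - 1  # the root-adjacent group may be the complement


def test_panel_truth_records_every_sv(panel_fixture):
    truth = panel_fixture.truth
    spec = truth.spec
    kinds = [sv.kind for sv in truth.svs]
    assert kinds.count("REC") == spec.n_rec
    assert kinds.count("NHEJ") == spec.n_nhej
    assert kinds.count("DEL") == spec.n_del
    for sv in truth.svs:
        assert sv.carriers
        for c in sv.carriers:
            assert sv.name in truth.ecotype(c).svs


def test_panel_del_sizes_in_range(panel_fixture):
    spec = panel_fixture.truth.spec
    for sv in panel_fixture.truth.svs:
        if sv.kind == "DEL":
            assert spec.del_size[0] <= sv.end - sv.start <= spec.del_size[1]


def test_secondary_molecule_requires_chained_layout(msh1_fixture):
    truth = msh1_fixture.truth
    mol = sd.make_recombinant(truth, "CC")
    with pytest.raises(ValueError, match="novel"):
        sd.make_secondary_molecule(truth, mol, "F")
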