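"""Synthetic inputs: reference genome with a planted repeat catalog,
recombinant molecules with asymmetric junctions, paired-end read libraries,
and a multi-ecotype panel with tree-structured SNPs and planted structural
variants.

Everything is deterministic given a master seed; sub-generators derive
independent streams through fixed spawn keys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .align_core import encode
from .formats_io import GenomeSeq, Interval, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

READ_LENGTH = 36
INSERT_MEAN = 220
INSERT_SD = 20
# flank carried on each side of a recombinant molecule: long enough for a
# mate to sit fully inside a 220-bp flank window (220 + read + margin), but
# short enough that recombinant coverage never tilts the genome-wide median
REC_FLANK = 260

# placement guards
_GAP_MIN = 260  # minimum background gap between planted features
_MATE_MIN_DIST = 1500  # minimum edge distance between a pair's copies
_EDGE_KEEPOUT = 11  # polymorphisms stay this far from repeat edges


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


# ---------------------------------------------------------------------------
# repeat catalog
# ---------------------------------------------------------------------------

@dataclass
class RepeatSpec:
    """Requested properties of one planted repeat pair."""

    name: str
    length: int  # bp of copy 1
    identity: float  # target percent identity (column-based)
    novel: bool = False
    orientation: str = "direct"
    donor: int = 1  # which copy donates the invading strand
    fate_class: str = "I"  # I | II
    n_indels: int = 0  # single-base insertion polymorphisms in copy 2
    copy1_start: int = -1  # >=0 pins the copy explicitly (manual layouts)
    copy2_start: int = -1
    exact_identity: bool = False  # force achieved identity == identity


@dataclass
class Polymorphism:
    """One difference between the two copies (truth-side record)."""

    column: int  # column index in the copy1-vs-copy2 alignment
    kind: str  # SNP | insertion | deletion
    offset1: int  # offset in copy1 (for insertion: offset of next base)
    offset2: int
    allele1: str  # "" for a base absent from copy1
    allele2: str


@dataclass
class PlantedRepeat:
    spec: RepeatSpec
    copy1: Interval
    copy2: Interval
    seq1: str
    seq2: str
    ops: np.ndarray  # copy1-vs-copy2 alignment column ops (_kernels OP_*)
    polymorphisms: list[Polymorphism]

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def columns(self) -> int:
        return len(self.ops)

    @property
    def identity(self) -> float:
        return 100.0 * (self.columns - len(self._diff_columns())) / self.columns

    def _diff_columns(self) -> set[int]:
        return {
            c
            for p in self.polymorphisms
            for c in range(p.column, p.column + max(len(p.allele1), len(p.allele2), 1))
        }

    def donor_interval(self) -> Interval:
        return self.copy1 if self.spec.donor == 1 else self.copy2

    def recipient_interval(self) -> Interval:
        return self.copy2 if self.spec.donor == 1 else self.copy1


@dataclass
class ReferenceTruth:
    genome: GenomeSeq
    repeats: list[PlantedRepeat]
    decoys: list[tuple[Interval, Interval]]
    seed: int

    def repeat(self, name: str) -> PlantedRepeat:
        for r in self.repeats:
            if r.name == name:
                return r
        raise KeyError(f"no planted repeat named {name!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.repeats:
            rows.append(
                {
                    "name": r.name,
                    "copy1_start": r.copy1.start + 1,  # 1-based in reports
                    "copy1_end": r.copy1.end,
                    "copy2_start": r.copy2.start + 1,
                    "copy2_end": r.copy2.end,
                    "orientation": r.spec.orientation,
                    "columns": r.columns,
                    "identity": round(r.identity, 2),
                    "novel": r.spec.novel,
                    "donor": r.spec.donor,
                    "fate_class": r.spec.fate_class,
                    "n_polymorphisms": len(r.polymorphisms),
                }
            )
        return pd.DataFrame(rows)

    def bed_rows(self):
        for r in self.repeats:
            yield (self.genome.name, r.copy1, f"{r.name}/1")
            yield (self.genome.name, r.copy2, f"{r.name}/2")


def _letter_names(n: int) -> list[str]:
    names = [chr(ord("A") + i) for i in range(26)]
    i = 0
    while len(names) < n + 5:
        names.append("A" + chr(ord("A") + i))
        i += 1
    # reserved for specially constructed pairs
    for special in ("F", "CC"):
        if special in names:
            names.remove(special)
    return names[:n]


def default_catalog(seed: int = 0) -> list[RepeatSpec]:
    """The packaged intermediate-repeat catalog: 47 pairs, 50-556 bp,
    85-98 % identity; 14 of them flagged novel (50-250 bp); includes the
    maximum-length 556-bp pair ("F"), a designated minimum-identity pair at
    exactly 85.0 %, and the 86-bp worked-example pair ("CC") with three
    SNPs and one single-base insertion."""
    rng = _rng(seed, 901)
    specs: list[RepeatSpec] = []

    known_lengths = np.linspace(108, 540, 31).round().astype(int).tolist()
    known_ids = np.linspace(88.0, 97.0, 31)
    rng.shuffle(known_ids)
    names = _letter_names(31)
    for name, L, ident in zip(names, known_lengths, known_ids):
        specs.append(RepeatSpec(name=name, length=int(L), identity=float(ident)))
    # the 556-bp maximum-length pair and the exact-85% minimum-identity pair
    specs.append(RepeatSpec(name="F", length=556, identity=86.0))
    specs.append(
        RepeatSpec(name="MINID", length=520, identity=85.0, exact_identity=True)
    )
    # worked example: 86 bp, 3 SNPs + 1 single-base insertion
    specs = [s for s in specs if s.length != 86]
    specs[5] = replace(specs[5], name="CC", length=86, identity=95.4, n_indels=1)

    novel_lengths = np.linspace(50, 250, 14).round().astype(int)
    for i, L in enumerate(novel_lengths):
        # smallest repeats carry the highest identity
        ident = 98.0 - (int(L) - 50) / 200.0 * 12.5
        specs.append(
            RepeatSpec(name=f"N{i + 1:02d}", length=int(L), identity=ident, novel=True)
        )

    # donor copy and fate class assignments
    for i, s in enumerate(specs):
        specs[i] = replace(
            s,
            donor=int(rng.integers(1, 3)),
            fate_class="I" if rng.random() < 0.5 else "II",
        )
    assert len(specs) == 47
    return specs


def _draw_polymorphism_layout(
    L: int, n_sub: int, n_ins: int, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """Substitution offsets and insertion offsets for a planted pair.

    Constraints: keep-out of 11 bp at each edge; >=4 bp between
    substitutions; >=12 bp around insertions; at least three inter-event
    gaps of >=14 bp (guaranteed exact-seed windows for discovery); for
    repeats >=150 bp at least two substitutions within [12, 130) of the
    start so recombinant junctions stay visible to short-insert pairs.
    """
    # keep 12 identical bases at each end so an exact 12-mer seed always
    # anchors discovery at both repeat edges
    lo, hi = _EDGE_KEEPOUT + 1, L - _EDGE_KEEPOUT - 2
    if n_sub + n_ins == 0:
        return [], []
    span = hi - lo
    if span < 4 * (n_sub + n_ins) + 8:
        raise ValueError(f"repeat of {L} bp cannot hold {n_sub + n_ins} polymorphisms")

    # two anchor substitutions near the start keep recombinant junctions
    # visible to short-insert read pairs on long repeats
    early: list[int] = []
    if L >= 150 and n_sub >= 2 and span / (n_sub + 1) > 25:
        # sparse layouts would otherwise leave the junction-side 130 bp
        # free of substitutions
        e1 = lo + int(rng.integers(0, 40))
        e2 = e1 + 20 + int(rng.integers(0, min(50, 128 - e1 - 20)))
        early = [e1, e2]
    rest_n = n_sub - len(early)
    start = (early[-1] + 4) if early else lo
    # remaining substitutions: minimum inter-event gap of 4, built from a
    # multinomial slack split, then three gaps widened to >=16 so exact
    # 12-mer seed windows survive even at 85 % identity
    n_gaps = rest_n + 1
    slack = (hi - start) - 4 * rest_n
    if slack < 0:
        raise ValueError(f"repeat of {L} bp cannot hold {n_sub} substitutions")
    ins_sep = 12 if span >= 20 * (n_sub + n_ins) else 8
    last_err = None
    for _attempt in range(50):
        extras = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps))
        gaps = [4 + int(x) for x in extras]
        # widen up to three gaps into exact-seed oases, as slack permits
        # (short repeats chain through their identical 12-bp edges instead)
        n_oases = 0 if L < 140 else min(3, max(0, slack // 14))
        widen = sorted(range(n_gaps), key=lambda i: -gaps[i])[:n_oases]
        for w in widen:
            need = 16 - gaps[w]
            if need <= 0:
                continue
            for d in sorted(range(n_gaps), key=lambda i: -gaps[i]):
                if d in widen:
                    continue
                give = min(need, gaps[d] - 4)
                gaps[d] -= give
                gaps[w] += give
                need -= give
                if need <= 0:
                    break
        subs = list(early)
        pos = start
        for gi in range(rest_n):
            pos += gaps[gi]
            subs.append(pos)
        assert len(subs) == n_sub and (not subs or subs[-1] <= hi)
        ins: list[int] = []
        ok = True
        for _ in range(n_ins):
            for _try in range(500):
                p = int(rng.integers(lo + 6, hi - 6))
                if all(abs(p - q) >= ins_sep for q in subs + ins):
                    ins.append(p)
                    break
            else:
                ok = False
                last_err = f"could not place {n_ins} insertions in {L} bp"
                break
        if ok:
            return sorted(subs), sorted(ins)
    raise ValueError(last_err or f"could not lay out polymorphisms in {L} bp")


def _mutate_copy(
    seq1: str, spec: RepeatSpec, rng: np.random.Generator
) -> tuple[str, np.ndarray, list[Polymorphism]]:
    """Derive copy 2 from copy 1 with the planted differences."""
    L = len(seq1)
    n_ins = spec.n_indels
    columns = L + n_ins
    target_diff = int(round(columns * (1.0 - spec.identity / 100.0)))
    n_sub = max(0, target_diff - n_ins)
    if not spec.exact_identity:
        # never let achieved identity dip below the catalog floor of 85.1
        # (the designated minimum pair keeps its exact value)
        while n_sub + n_ins > 0 and 100.0 * (columns - n_sub - n_ins) / columns < 85.1:
            n_sub -= 1
    subs, ins = _draw_polymorphism_layout(L, n_sub, n_ins, rng)
    sub_set, ins_set = set(subs), set(ins)
    out = []
    ops = []
    polys = []
    off2 = 0
    for i, base in enumerate(seq1):
        if i in ins_set:
            extra = "ACGT"[rng.integers(0, 4)]
            polys.append(
                Polymorphism(
                    column=len(ops),
                    kind="insertion",
                    offset1=i,
                    offset2=off2,
                    allele1="",
                    allele2=extra,
                )
            )
            out.append(extra)
            ops.append(_kernels.OP_GAP_A)  # consumes copy2 only
            off2 += 1
        if i in sub_set:
            alt = _other_base(rng, base)
            polys.append(
                Polymorphism(
                    column=len(ops),
                    kind="SNP",
                    offset1=i,
                    offset2=off2,
                    allele1=base,
                    allele2=alt,
                )
            )
            out.append(alt)
        else:
            out.append(base)
        ops.append(_kernels.OP_DIAG)
        off2 += 1
    return "".join(out), np.array(ops, dtype=np.uint8), polys


def build_reference(
    genome_length: int,
    catalog: Sequence[RepeatSpec],
    seed: int,
    n_decoys: int = 8,
) -> ReferenceTruth:
    """Assemble a circular genome with every catalog pair embedded.

    Also embeds short (<50 bp) identical decoy pairs that never receive
    recombinants.  Raises when the catalog cannot be placed.
    """
    rng = _rng(seed, 1)
    manual = any(s.copy1_start >= 0 for s in catalog)
    if manual and not all(s.copy1_start >= 0 and s.copy2_start >= 0 for s in catalog):
        raise ValueError("mix of pinned and unpinned repeat placements")

    # generate copy sequences first
    seqs: dict[str, tuple[str, str, np.ndarray, list[Polymorphism]]] = {}
    for s in catalog:
        seq1 = _random_seq(rng, s.length)
        seq2, ops, polys = _mutate_copy(seq1, s, rng)
        if s.orientation == "inverted":
            seqs[s.name] = (seq1, revcomp(seq2), ops, polys)
        else:
            seqs[s.name] = (seq1, seq2, ops, polys)
    # decoys stay <= 40 bp so chance flank matches can never stretch a local
    # alignment across the 50-bp reporting floor
    decoy_lengths = (
        rng.integers(28, 41, n_decoys) if n_decoys else np.empty(0, dtype=int)
    )
    decoy_seqs = [_random_seq(rng, int(L)) for L in decoy_lengths]

    pieces: list[tuple[str, int, str]] = []  # (kind:name:copy, length, sequence)
    for s in catalog:
        pieces.append((f"r:{s.name}:1", len(seqs[s.name][0]), seqs[s.name][0]))
        pieces.append((f"r:{s.name}:2", len(seqs[s.name][1]), seqs[s.name][1]))
    for i, ds in enumerate(decoy_seqs):
        pieces.append((f"d:{i}:1", len(ds), ds))
        pieces.append((f"d:{i}:2", len(ds), ds))

    if manual:
        placement = {}
        for s in catalog:
            placement[f"r:{s.name}:1"] = s.copy1_start
            placement[f"r:{s.name}:2"] = s.copy2_start
        # decoys appended after the last pinned feature; mates interleaved
        # (all first copies, then all second copies) so the two copies of an
        # identical decoy pair never sit adjacent
        cursor = max(
            placement[k] + dict((p[0], p[1]) for p in pieces)[k] for k in placement
        ) + _GAP_MIN
        for c in (1, 2):
            for i, ds in enumerate(decoy_seqs):
                placement[f"d:{i}:{c}"] = cursor
                cursor += len(ds) + _GAP_MIN
        starts = placement
        _validate_manual(starts, pieces, genome_length, catalog)
    else:
        starts = _auto_place(pieces, genome_length, catalog, rng)

    background = np.frombuffer(_random_seq(rng, genome_length).encode(), dtype=np.uint8).copy()
    for key, L, seq in pieces:
        st = starts[key]
        background[st : st + L] = np.frombuffer(seq.encode(), dtype=np.uint8)
    _guard_boundaries(background, pieces, starts, catalog, rng, genome_length)
    genome = GenomeSeq(name="mito", sequence=background.tobytes().decode(), circular=True)

    repeats = []
    for s in catalog:
        seq1, seq2, ops, polys = seqs[s.name]
        c1 = Interval(starts[f"r:{s.name}:1"], starts[f"r:{s.name}:1"] + len(seq1))
        c2 = Interval(
            starts[f"r:{s.name}:2"],
            starts[f"r:{s.name}:2"] + len(seq2),
            "-" if s.orientation == "inverted" else "+",
        )
        repeats.append(
            PlantedRepeat(
                spec=s, copy1=c1, copy2=c2, seq1=seq1, seq2=seq2, ops=ops,
                polymorphisms=polys,
            )
        )
    repeats.sort(key=lambda r: r.copy1.start)
    decoys = []
    for i, ds in enumerate(decoy_seqs):
        a = starts[f"d:{i}:1"]
        b = starts[f"d:{i}:2"]
        decoys.append((Interval(a, a + len(ds)), Interval(b, b + len(ds))))
    return ReferenceTruth(genome=genome, repeats=repeats, decoys=decoys, seed=seed)


def _auto_place(pieces, genome_length, catalog, rng, max_tries: int = 300):
    total = sum(p[1] for p in pieces)
    n = len(pieces)
    slack = genome_length - total - (n + 1) * _GAP_MIN
    if slack < 0:
        raise ValueError(
            f"catalog needs {total + (n + 1) * _GAP_MIN} bp but genome is "
            f"{genome_length} bp; offending specs: all"
        )
    for _ in range(max_tries):
        order = rng.permutation(n)
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        starts = {}
        cursor = _GAP_MIN + int(extra[0])
        for gi, pi in enumerate(order):
            key, L, _ = pieces[pi]
            starts[key] = cursor
            cursor += L + _GAP_MIN + int(extra[gi + 1])
        ok = True
        for s in catalog:
            a0 = starts[f"r:{s.name}:1"]
            b0 = starts[f"r:{s.name}:2"]
            la = next(p[1] for p in pieces if p[0] == f"r:{s.name}:1")
            lb = next(p[1] for p in pieces if p[0] == f"r:{s.name}:2")
            d = _edge_distance(a0, a0 + la, b0, b0 + lb, genome_length)
            if d < _MATE_MIN_DIST:
                ok = False
                break
        if ok:
            # copy1 = lower coordinate
            for s in catalog:
                if starts[f"r:{s.name}:1"] > starts[f"r:{s.name}:2"]:
                    starts[f"r:{s.name}:1"], starts[f"r:{s.name}:2"] = (
                        starts[f"r:{s.name}:2"],
                        starts[f"r:{s.name}:1"],
                    )
            return starts
    raise ValueError("could not place catalog with mate-distance constraints")


def _edge_distance(a0, a1, b0, b1, L):
    if a1 <= b0:
        return min(b0 - a1, L - (b1 - a0))
    if b1 <= a0:
        return min(a0 - b1, L - (a1 - b0))
    return 0


def _validate_manual(starts, pieces, genome_length, catalog):
    ivs = []
    lens = {p[0]: p[1] for p in pieces}
    for key, st in starts.items():
        if st < 0 or st + lens[key] > genome_length:
            raise ValueError(f"feature {key} outside genome")
        ivs.append((st, st + lens[key], key))
    ivs.sort()
    for (s0, e0, k0), (s1, e1, k1) in zip(ivs, ivs[1:]):
        if s1 < e0:
            raise ValueError(f"placement conflict between {k0} and {k1}")


def _guard_boundaries(background, pieces, starts, catalog, rng, genome_length):
    """Force the two bases just outside copy2 to differ from the bases just
    outside copy1, so local alignment cannot extend past the planted pair."""
    by_key = {p[0]: p[1] for p in pieces}
    pair_keys = [(f"r:{s.name}:1", f"r:{s.name}:2") for s in catalog]
    pair_keys += sorted(
        {
            (k.rsplit(":", 1)[0] + ":1", k.rsplit(":", 1)[0] + ":2")
            for k in by_key
            if k.startswith("d:")
        }
    )
    for k1, k2 in pair_keys:
        a0 = starts[k1]
        a1 = a0 + by_key[k1]
        b0 = starts[k2]
        b1 = b0 + by_key[k2]
        for off in (1, 2):
            for pa, pb in (((a0 - off), (b0 - off)), ((a1 + off - 1), (b1 + off - 1))):
                pa %= genome_length
                pb %= genome_length
                if background[pb] == background[pa]:
                    cur = chr(background[pb])
                    background[pb] = ord(_other_base(rng, cur))


# ---------------------------------------------------------------------------
# recombinant molecules
# ---------------------------------------------------------------------------

@dataclass
class RecombinantMolecule:
    """The single crossover product at one repeat pair.

    The molecule joins the recipient copy's upstream flank to the donor
    copy's downstream flank through one repeat interval whose polymorphic
    sites carry donor alleles (unless overridden).
    """

    name: str
    repeat_name: str
    sequence: str
    flank: int
    repeat_start: int  # offset of the repeat interval within the molecule
    repeat_len: int
    recipient_upstream: Interval  # genome interval of the upstream flank
    donor_downstream: Interval  # genome interval of the downstream flank
    site_origin: dict[int, str]  # polymorphism column -> donor | recipient


def make_recombinant(
    truth: ReferenceTruth,
    repeat_name: str,
    flank: int = REC_FLANK,
    snp_overrides: Optional[dict[int, str]] = None,
    indel_resolution: str = "donor",
    both_products: bool = False,
    seed: int = 0,
) -> RecombinantMolecule:
    """Build the asymmetric crossover product for one catalog repeat.

    ``snp_overrides`` maps polymorphism column -> "recipient" to plant
    conversion-tract exceptions; ``indel_resolution`` is "donor",
    "recipient" or "random" (per indel).
    """
    if both_products:
        raise ValueError(
            "asymmetric exchange: only one crossover product exists; "
            "the reciprocal product cannot be requested"
        )
    r = truth.repeat(repeat_name)
    if min(len(r.seq1), len(r.seq2)) < 50:
        raise ValueError(f"repeat {repeat_name} is shorter than the 50-bp floor")
    if r.spec.orientation != "direct":
        raise NotImplementedError("recombinant construction requires a direct pair")
    rng = _rng(seed, 7, abs(hash(repeat_name)) % (2**31))
    donor_iv = r.donor_interval()
    recip_iv = r.recipient_interval()
    overrides = dict(snp_overrides or {})
    site_origin: dict[int, str] = {}
    for p in r.polymorphisms:
        if p.kind == "SNP":
            site_origin[p.column] = overrides.get(p.column, "donor")
        else:
            if indel_resolution == "random":
                site_origin[p.column] = "donor" if rng.random() < 0.5 else "recipient"
            else:
                site_origin[p.column] = indel_resolution
    donor_is_1 = r.spec.donor == 1
    rep_seq = _resolve_repeat_sequence(r, site_origin, donor_is_1)
    g = truth.genome
    up = g.fetch(recip_iv.start - flank, recip_iv.start)
    down = g.fetch(donor_iv.end, donor_iv.end + flank)
    return RecombinantMolecule(
        name=f"rec_{repeat_name}",
        repeat_name=repeat_name,
        sequence=up + rep_seq + down,
        flank=flank,
        repeat_start=len(up),
        repeat_len=len(rep_seq),
        recipient_upstream=Interval((recip_iv.start - flank) % g.length,
                                    recip_iv.start)
        if recip_iv.start - flank >= 0
        else Interval(0, recip_iv.start),
        donor_downstream=Interval(donor_iv.end, min(g.length, donor_iv.end + flank)),
        site_origin=site_origin,
    )


def _resolve_repeat_sequence(r: PlantedRepeat, site_origin, donor_is_1: bool) -> str:
    """Walk the copy alignment emitting donor alleles except where a site's
    origin says recipient."""
    by_col = {p.column: p for p in r.polymorphisms}
    out = []
    i = j = 0
    col = 0
    for op in r.ops:
        poly = by_col.get(col)
        use = "donor"
        if poly is not None:
            use = site_origin.get(col, "donor")
        take_copy1 = (use == "donor") == donor_is_1
        if op == _kernels.OP_DIAG:
            out.append(r.seq1[i] if take_copy1 else r.seq2[j])
            i += 1
            j += 1
        elif op == _kernels.OP_GAP_A:  # base present only in copy2
            if not take_copy1:
                out.append(r.seq2[j])
            j += 1
        else:  # base present only in copy1
            if take_copy1:
                out.append(r.seq1[i])
            i += 1
        col += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# read libraries
# ---------------------------------------------------------------------------

@dataclass
class LibrarySpec:
    condition: str  # WT | msh1_gen1 | msh1_adv | ecotype name
    coverage: float
    read_length: int = READ_LENGTH
    insert_mean: int = INSERT_MEAN
    insert_sd: int = INSERT_SD
    fractions: dict[str, float] = field(default_factory=dict)  # repeat -> fraction
    error_rate: float = 0.0
    extra_molecules: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self):
        for name, f in self.fractions.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"recombinant fraction for {name} out of [0,1]: {f}")


@dataclass
class ReadLibrary:
    """An in-memory paired library with per-pair molecule attribution."""

    condition: str
    read_length: int
    insert_mean: int
    insert_sd: int
    codes1: np.ndarray  # (n, read_length) uint8, as sequenced
    codes2: np.ndarray
    mol_names: list[str]  # molecule table; index 0 is the parental genome
    mol_index: np.ndarray  # (n,) int32 into mol_names
    frag_start: np.ndarray  # (n,) fragment start in molecule coordinates
    frag_len: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.mol_index)

    def names(self) -> list[str]:
        return [f"{self.condition}_{i}" for i in range(self.n_pairs)]

    def sequences(self) -> tuple[list[str], list[str]]:
        dec = _BASES[np.clip(self.codes1, 0, 3)]
        dec2 = _BASES[np.clip(self.codes2, 0, 3)]
        rl = self.read_length
        b1, b2 = dec.tobytes(), dec2.tobytes()
        s1 = [b1[i * rl : (i + 1) * rl].decode() for i in range(self.n_pairs)]
        s2 = [b2[i * rl : (i + 1) * rl].decode() for i in range(self.n_pairs)]
        return s1, s2

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names(),
                "molecule": [self.mol_names[i] for i in self.mol_index],
                "frag_start": self.frag_start,
                "frag_len": self.frag_len,
            }
        )

    def to_fastq(self, path1, path2) -> None:
        from .formats_io import write_fastq_pair

        s1, s2 = self.sequences()
        write_fastq_pair(self.names(), s1, s2, path1, path2)


def simulate_library(
    truth: ReferenceTruth,
    recombinants: Sequence[RecombinantMolecule],
    spec: LibrarySpec,
    seed: int,
    stream: int = 0,
) -> ReadLibrary:
    """Draw paired-end reads from the weighted molecule mixture.

    Parental fragments are uniform on the circular genome; each recombinant
    contributes fragments so its local depth is ``fraction`` times the
    parental depth; class I repeats additionally down-weight parental
    fragments over the donor locus by (1 - fraction).  Inserts are
    Normal(mean, sd) truncated to [2*read_length, mean + 4 sd].
    """
    if spec.coverage <= 0:
        raise ValueError("coverage must be positive")
    rl = spec.read_length
    by_name = {r.repeat_name: r for r in recombinants}
    for name in spec.fractions:
        if name not in {r.name for r in truth.repeats}:
            raise ValueError(f"fraction set for unknown repeat {name!r}")
    rng = _rng(seed, 11, stream)
    g = truth.genome
    L = g.length
    lo_ins, hi_ins = 2 * rl, spec.insert_mean + 4 * spec.insert_sd

    # class I rejection windows over the donor parental locus
    rej_windows = []
    rej_fracs = []
    for r in truth.repeats:
        f = spec.fractions.get(r.name, 0.0)
        if f > 0 and r.spec.fate_class == "I":
            # rejecting fragments that touch the donor copy depletes exactly
            # the repeat-linked pairs of the donor parental form, without
            # bleeding into neighbouring repeats' flank windows
            div = r.donor_interval()
            rej_windows.append((div.start, div.end))
            rej_fracs.append(f)

    def draw_inserts(n):
        out = np.empty(n, dtype=np.int64)
        got = 0
        while got < n:
            x = rng.normal(spec.insert_mean, spec.insert_sd, n - got).round().astype(np.int64)
            x = x[(x >= lo_ins) & (x <= hi_ins)]
            out[got : got + len(x)] = x
            got += len(x)
        return out

    molecules: list[tuple[str, np.ndarray, int]] = []  # (name, codes, n_frags)
    gcodes = encode(g.sequence)
    gpad = np.concatenate([gcodes, gcodes[: hi_ins + 1]])
    n_parental = int(round(spec.coverage * L / (2 * rl)))
    molecules.append(("parental", gpad, n_parental))
    for r in truth.repeats:
        f = spec.fractions.get(r.name, 0.0)
        if f <= 0:
            continue
        if r.name not in by_name:
            raise ValueError(f"fraction set for {r.name} but no recombinant supplied")
        mol = by_name[r.name]
        seg = encode(mol.sequence)
        n = int(round(f * spec.coverage * len(seg) / (2 * rl)))
        molecules.append((mol.name, seg, n))
    for name, seq, frac in spec.extra_molecules:
        seg = encode(seq)
        n = int(round(frac * spec.coverage * len(seg) / (2 * rl)))
        molecules.append((name, seg, n))

    all_c1, all_c2, all_mi, all_fs, all_fl = [], [], [], [], []
    for mi, (name, codes, n) in enumerate(molecules):
        if n <= 0:
            continue
        inserts = draw_inserts(n)
        if name == "parental":
            starts = rng.integers(0, L, n)
            if rej_windows:
                # rejection sampling: each fragment is tested once per draw;
                # survivors are settled, only redrawn fragments are re-tested
                active = np.ones(n, dtype=bool)
                for _ in range(100):
                    idx = np.flatnonzero(active)
                    if len(idx) == 0:
                        break
                    s = starts[idx]
                    e = s + inserts[idx]
                    reject = np.zeros(len(idx), dtype=bool)
                    for (w0, w1), f in zip(rej_windows, rej_fracs):
                        hit = (s < w1) & (e > w0)
                        reject |= hit & (rng.random(len(idx)) < f)
                    starts[idx[reject]] = rng.integers(0, L, int(reject.sum()))
                    active[:] = False
                    active[idx[reject]] = True
        else:
            lim = len(codes) - inserts
            bad = lim < 0
            inserts[bad] = len(codes)
            lim[bad] = 0
            starts = (rng.random(n) * (lim + 1)).astype(np.int64)
        offs = np.arange(rl)
        c1 = codes[starts[:, None] + offs]
        c2 = codes[(starts + inserts)[:, None] - rl + offs].astype(np.int16)
        c2 = 3 - c2[:, ::-1]  # revcomp in code space
        c2[c2 < 0] = 4  # N stays N
        all_c1.append(c1)
        all_c2.append(c2)
        all_mi.append(np.full(n, mi, dtype=np.int32))
        all_fs.append(starts)
        all_fl.append(inserts)

    codes1 = np.vstack(all_c1) if all_c1 else np.empty((0, rl), np.uint8)
    codes2 = np.vstack(all_c2) if all_c2 else np.empty((0, rl), np.uint8)
    codes1 = codes1.astype(np.uint8)
    codes2 = codes2.astype(np.uint8)
    if spec.error_rate > 0:
        for arr in (codes1, codes2):
            mask = rng.random(arr.shape) < spec.error_rate
            shift = rng.integers(1, 4, mask.sum())
            arr[mask] = ((arr[mask] + shift) % 4).astype(np.uint8)
    return ReadLibrary(
        condition=spec.condition,
        read_length=rl,
        insert_mean=spec.insert_mean,
        insert_sd=spec.insert_sd,
        codes1=codes1,
        codes2=codes2,
        mol_names=[m[0] for m in molecules],
        mol_index=np.concatenate(all_mi) if all_mi else np.empty(0, np.int32),
        frag_start=np.concatenate(all_fs) if all_fs else np.empty(0, np.int64),
        frag_len=np.concatenate(all_fl) if all_fl else np.empty(0, np.int64),
    )


def default_fractions(
    truth: ReferenceTruth, seed: int
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-repeat recombinant fractions for (gen1, advanced) libraries.

    Class I repeats reach high advanced-generation fractions (their donor
    parental form is lost); class II stay moderate; first-generation
    fractions are a fixed 0.6 of advanced, so activity grows over
    generations at every repeat.
    """
    rng = _rng(seed, 21)
    gen1, adv = {}, {}
    for r in truth.repeats:
        if r.spec.fate_class == "I":
            fa = float(rng.uniform(0.70, 0.85))
        else:
            fa = float(rng.uniform(0.55, 0.70))
        adv[r.name] = fa
        gen1[r.name] = 0.6 * fa
    return gen1, adv


def default_library_specs(
    truth: ReferenceTruth, seed: int, profile: str = "standard"
) -> dict[str, LibrarySpec]:
    """WT / first-generation / advanced-generation library specifications.

    ``standard`` is the desk-scale profile (40/60/40-fold); ``deep`` mirrors
    the flank-coverage analysis depth (200/250/250-fold).
    """
    gen1_f, adv_f = default_fractions(truth, seed)
    if profile == "standard":
        cov = {"WT": 40, "msh1_gen1": 60, "msh1_adv": 40}
    elif profile == "deep":
        cov = {"WT": 200, "msh1_gen1": 250, "msh1_adv": 250}
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return {
        "WT": LibrarySpec(condition="WT", coverage=cov["WT"], fractions={}),
        "msh1_gen1": LibrarySpec(
            condition="msh1_gen1", coverage=cov["msh1_gen1"], fractions=gen1_f
        ),
        "msh1_adv": LibrarySpec(
            condition="msh1_adv", coverage=cov["msh1_adv"], fractions=adv_f
        ),
    }


def make_secondary_molecule(
    truth: ReferenceTruth,
    primary: RecombinantMolecule,
    secondary_name: str,
    flank: int = REC_FLANK,
) -> tuple[str, str]:
    """A molecule carrying a junction that only exists on the primary
    recombinant's novel environment: the primary product truncated at the
    secondary repeat's first copy, joined to the second copy's downstream
    flank.  Returns (name, sequence)."""
    r2 = truth.repeat(secondary_name)
    prim_r = truth.repeat(primary.repeat_name)
    donor_end = prim_r.donor_interval().end
    # the secondary repeat's copy1 must sit inside the primary product's
    # donor-downstream flank
    if not (donor_end <= r2.copy1.start < donor_end + primary.flank):
        raise ValueError(
            f"secondary repeat {secondary_name} does not lie in the novel "
            f"environment created by {primary.repeat_name}"
        )
    cut = primary.repeat_start + primary.repeat_len + (r2.copy1.end - donor_end)
    head = primary.sequence[:cut]
    tail = truth.genome.fetch(r2.copy2.end, r2.copy2.end + flank)
    return f"rec2_{secondary_name}", head + tail


# ---------------------------------------------------------------------------
# ecotype panel
# ---------------------------------------------------------------------------

@dataclass
class EcotypePanelSpec:
    n_ecotypes: int = 72
    n_groups: int = 6
    snp_rate: float = 5e-4  # per bp per unit branch length
    suppression: float = 66.0  # SNP suppression inside >1-kb repeats
    n_nhej: int = 3
    n_rec: int = 3
    n_del: int = 4
    # deletions below ~6 bp sit under the coverage-gap detection floor of a
    # 36-bp-read mapper and are not planted by default
    del_size: tuple[int, int] = (6, 50)
    coverage: float = 25.0
    trace_events: int = 1  # substoichiometric junction molecules
    trace_coverage: float = 150.0
    trace_fraction: float = 0.02
    stem_length: float = 1.8
    terminal_length: float = 0.15
    internal_length: float = 0.10


@dataclass
class PlantedSV:
    name: str
    kind: str  # NHEJ | REC | DEL
    start: int  # deleted interval on the reference, 0-based half-open
    end: int
    repeat_name: str = ""  # for REC
    microhomology: int = 0  # for NHEJ
    branch: str = ""  # tree node name whose subtree carries the event
    carriers: tuple[str, ...] = ()


@dataclass
class EcotypeTruth:
    name: str
    group: int
    snps: list[tuple[int, str, str]]  # (ref pos, ref base, alt base)
    svs: list[str]  # PlantedSV names
    coverage: float
    trace: list[tuple[str, float]] = field(default_factory=list)  # (SV name, fraction)


@dataclass
class PanelTruth:
    reference: ReferenceTruth
    spec: EcotypePanelSpec
    tree_newick: str
    ecotypes: list[EcotypeTruth]
    svs: list[PlantedSV]
    groups: dict[str, int]
    seed: int

    def ecotype(self, name: str) -> EcotypeTruth:
        for e in self.ecotypes:
            if e.name == name:
                return e
        raise KeyError(name)

    def sv(self, name: str) -> PlantedSV:
        for s in self.svs:
            if s.name == name:
                return s
        raise KeyError(name)

    def ecotype_genome(self, name: str) -> GenomeSeq:
        """Apply the ecotype's planted edits to the reference."""
        e = self.ecotype(name)
        seq = list(self.reference.genome.sequence)
        dels = sorted(
            ((self.sv(n).start, self.sv(n).end) for n in e.svs), reverse=True
        )
        for pos, ref, alt in e.snps:
            if seq[pos] != ref:
                raise AssertionError("truth SNP inconsistent with reference")
            seq[pos] = alt
        for s, t in dels:
            del seq[s:t]
        return GenomeSeq(name=e.name, sequence="".join(seq), circular=True)

    def library_spec(self, name: str) -> LibrarySpec:
        e = self.ecotype(name)
        extra = []
        for sv_name, frac in e.trace:
            sv = self.sv(sv_name)
            g = self.reference.genome
            seg = g.fetch(sv.start - REC_FLANK, sv.start) + g.fetch(
                sv.end, sv.end + REC_FLANK
            )
            extra.append((f"trace_{sv_name}", seg, frac))
        return LibrarySpec(
            condition=name, coverage=e.coverage, extra_molecules=extra
        )


def panel_reference_catalog(seed: int = 0) -> list[RepeatSpec]:
    """Compact catalog for ecotype-panel references: six intermediate pairs
    (REC substrates, copies 2-3 kb apart so repeat-mediated deletions stay
    desk-scale) and one large (1.5-kb) 96 %-identity pair.  The layout is
    pinned for a 50-kb reference."""
    rng = _rng(seed, 31)
    specs = []
    layout = [
        (140, 6000, 8200),
        (160, 11000, 13400),
        (180, 16000, 18500),
        (200, 21500, 24000),
        (220, 27000, 29400),
        (240, 32000, 34500),
    ]
    for i, (L, c1, c2) in enumerate(layout):
        specs.append(
            RepeatSpec(
                name=f"P{i + 1}", length=L, identity=float(rng.uniform(96.0, 98.5)),
                donor=1, fate_class="II", copy1_start=c1, copy2_start=c2,
            )
        )
    specs.append(
        RepeatSpec(
            name="LARGE", length=1500, identity=96.0, fate_class="II",
            copy1_start=37500, copy2_start=40500,
        )
    )
    return specs


def _random_binary_tree(names: list[str], rng, branch_len) -> tuple[str, float]:
    """Random topology over names -> (newick fragment, 0 extra height)."""
    nodes = [(n, branch_len()) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        (na, la), (nb, lb) = nodes[i], nodes[j]
        merged = (f"({na}:{la:.4f},{nb}:{lb:.4f})", branch_len())
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return nodes[0]


def make_ecotype_panel(
    reference: ReferenceTruth, spec: EcotypePanelSpec, seed: int
) -> PanelTruth:
    """Plant tree-structured SNPs and NHEJ/REC/DEL structural variants on a
    multi-ecotype panel derived from ``reference``."""
    import skbio

    rng = _rng(seed, 41)
    n, k = spec.n_ecotypes, spec.n_groups
    if n < k:
        raise ValueError("fewer ecotypes than groups")
    L = reference.genome.length
    names = [f"E{i + 1:02d}" for i in range(n)]
    group_of = {}
    per = [n // k + (1 if i < n % k else 0) for i in range(k)]
    idx = 0
    clades = []
    for gi, cnt in enumerate(per):
        leaves = names[idx : idx + cnt]
        idx += cnt
        for nm in leaves:
            group_of[nm] = gi
        sub, _ = _random_binary_tree(
            leaves, rng, lambda: float(rng.uniform(0.5, 1.5) * spec.terminal_length)
        )
        clades.append(f"{sub}:{spec.stem_length:.4f}")
    backbone = clades[0]
    for c in clades[1:]:
        backbone = f"({backbone},{c}):{spec.internal_length:.4f}"
    newick = backbone.rsplit(":", 1)[0] + ";"
    tree = skbio.TreeNode.read([newick])
    for i, node in enumerate(tree.non_tips(include_self=True)):
        if node.name is None:
            node.name = f"node{i}"
    newick = str(tree).strip()

    # homologous-base map over planted repeat copies: a planted SNP never
    # converts a position to its paralog's allele, which would make reads
    # map cleanly (and wrongly) to the other copy
    paralog: dict[int, str] = {}
    for r in reference.repeats:
        i = j = 0
        for op in r.ops:
            if op == _kernels.OP_DIAG:
                paralog[r.copy1.start + i] = r.seq2[j]
                paralog[r.copy2.start + j] = r.seq1[i]
                i += 1
                j += 1
            elif op == _kernels.OP_GAP_A:
                j += 1
            else:
                i += 1

    # large-repeat intervals where SNPs are suppressed
    suppressed = [
        (r.copy1.start, r.copy1.end)
        for r in reference.repeats
        if r.columns >= 1000
    ] + [
        (r.copy2.start, r.copy2.end)
        for r in reference.repeats
        if r.columns >= 1000
    ]

    # ---- structural variants ----
    svs: list[PlantedSV] = []
    used: list[tuple[int, int]] = [(s - 300, e + 300) for s, e in suppressed]
    # keep SVs away from identical decoy pairs, where deleting one copy is
    # invisible to a 36-bp mapper
    for d1, d2 in reference.decoys:
        used.append((d1.start - 150, d1.end + 150))
        used.append((d2.start - 150, d2.end + 150))

    def reserve(s, e):
        for us, ue in used:
            if s < ue and e > us:
                return False
        used.append((s, e))
        return True

    inter_repeats = [r for r in reference.repeats if 50 <= r.columns < 1000]
    rng.shuffle(inter_repeats)
    seq = reference.genome.sequence
    # prefer REC substrates whose copies are close enough that the deleted
    # span stays desk-scale but still > 1 kb (junction discordance)
    pool = sorted(
        inter_repeats,
        key=lambda r: (r.copy2.start - r.copy1.start > 6000, rng.random()),
    )
    for i in range(spec.n_rec):
        placed = False
        while pool:
            r = pool.pop(0)
            s, e = r.copy1.start, r.copy2.start
            if reserve(s - 300, e + r.copy2.length + 300):
                svs.append(
                    PlantedSV(
                        name=f"REC{i + 1}", kind="REC", start=s, end=e,
                        repeat_name=r.name,
                    )
                )
                placed = True
                break
        if not placed:
            raise ValueError("could not place REC events without collisions")
    for i in range(spec.n_nhej):
        for _ in range(300):
            b1 = int(rng.integers(2000, L - 6000))
            span = int(rng.integers(1200, 3000))
            b2 = b1 + span
            mh = int(rng.integers(0, 6))
            if mh and seq[b1 - mh : b1] != seq[b2 - mh : b2]:
                # scan forward for a junction with the requested microhomology
                probe = seq[b1 - mh : b1]
                found = seq.find(probe, b1 + 1200, min(L - 1000, b1 + 4000))
                if found == -1:
                    mh = 0
                else:
                    b2 = found + mh
            if reserve(b1 - 300, b2 + 300):
                svs.append(
                    PlantedSV(
                        name=f"NHEJ{i + 1}", kind="NHEJ", start=b1, end=b2,
                        microhomology=mh,
                    )
                )
                break
        else:
            raise ValueError("could not place NHEJ events without collisions")
    for i in range(spec.n_del):
        for _ in range(300):
            size = int(rng.integers(spec.del_size[0], spec.del_size[1] + 1))
            s = int(rng.integers(1000, L - 1000 - size))
            if reserve(s - 150, s + size + 150):
                svs.append(PlantedSV(name=f"DEL{i + 1}", kind="DEL", start=s, end=s + size))
                break
        else:
            raise ValueError("could not place DEL events without collisions")

    # assign SVs to branches: the first events go on clade stem branches,
    # the rest on terminal branches
    stem_nodes = []
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        tips = {t.name for t in node.tips()}
        for gi in range(k):
            if tips == {nm for nm in names if group_of[nm] == gi}:
                stem_nodes.append((gi, node))
    stem_nodes.sort(key=lambda t: t[0])
    tip_nodes = list(tree.tips())
    sv_carriers: dict[str, tuple[str, ...]] = {}
    for i, sv in enumerate(svs):
        if i < len(stem_nodes):
            gi, node = stem_nodes[i]
            sv.branch = node.name
            sv.carriers = tuple(sorted(t.name for t in node.tips()))
        else:
            node = tip_nodes[int(rng.integers(0, len(tip_nodes)))]
            sv.branch = node.name
            sv.carriers = (node.name,)
        sv_carriers[sv.name] = sv.carriers

    # ---- SNPs on branches ----
    # candidate positions come from a jittered grid with >= 37 bp spacing
    # (one read-length), so no ecotype ever carries two mismatches inside a
    # single read half; positions stay 50 bp clear of planted SV spans so
    # junction-bleed reads cannot mimic them
    ecol_snps: dict[str, list[tuple[int, str, str]]] = {nm: [] for nm in names}
    sv_spans = [(sv.start, sv.end) for sv in svs]
    pool = []
    for base in range(40, L - 40, 45):
        p = base + int(rng.integers(0, 9))
        if any(s - 50 <= p < e + 50 for s, e in sv_spans):
            continue
        if any(s <= p < e for s, e in suppressed):
            # a position inside a >1-kb repeat enters the pool with
            # probability 1/suppression, decided once
            if rng.random() >= 1.0 / spec.suppression:
                continue
        pool.append(p)
    rng.shuffle(pool)

    def draw_positions(count):
        out = []
        while len(out) < count and pool:
            out.append(pool.pop())
        return out

    for node in tree.traverse(include_self=False):
        blen = node.length or 0.0
        cnt = rng.poisson(blen * spec.snp_rate * L)
        if cnt == 0:
            continue
        tips = (
            [node.name] if node.is_tip() else [t.name for t in node.tips()]
        )
        for p in draw_positions(int(cnt)):
            ref = reference.genome.sequence[p]
            banned = {ref, paralog.get(p, "")}
            choices = [b for b in "ACGT" if b not in banned]
            alt = choices[int(rng.integers(0, len(choices)))]
            for nm in tips:
                ecol_snps[nm].append((p, ref, alt))

    # ---- per-ecotype truth ----
    ecotypes = []
    trace_pool = [sv for sv in svs if sv.kind in ("REC", "NHEJ") and len(sv.carriers) > 1]
    trace_assignments: dict[str, list[tuple[str, float]]] = {}
    for t in range(spec.trace_events):
        if not trace_pool:
            break
        sv = trace_pool[t % len(trace_pool)]
        outsiders = [nm for nm in names if nm not in sv.carriers]
        target = outsiders[int(rng.integers(0, len(outsiders)))]
        trace_assignments.setdefault(target, []).append((sv.name, spec.trace_fraction))
    for nm in names:
        carried = [sv.name for sv in svs if nm in sv.carriers]
        snps = sorted(ecol_snps[nm])
        # drop SNPs inside spans deleted in this ecotype
        spans = [(self_sv.start, self_sv.end) for self_sv in svs if nm in self_sv.carriers]
        snps = [s for s in snps if not any(a <= s[0] < b for a, b in spans)]
        cov = spec.trace_coverage if nm in trace_assignments else spec.coverage
        ecotypes.append(
            EcotypeTruth(
                name=nm,
                group=group_of[nm],
                snps=snps,
                svs=carried,
                coverage=cov,
                trace=trace_assignments.get(nm, []),
            )
        )
    return PanelTruth(
        reference=reference,
        spec=spec,
        tree_newick=newick,
        ecotypes=ecotypes,
        svs=svs,
        groups=group_of,
        seed=seed,
    )
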