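"""Pairwise alignment primitives and repeat-pair discovery.

Percent identity is column-based: 100 * matches / aligned columns, with gap
columns counted in the denominator.  This single definition is used for
discovery, reporting and all downstream polymorphism work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .formats_io import GenomeSeq, Interval, revcomp

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase


def encode(seq: str) -> np.ndarray:
    """ACGTN string -> uint8 codes (A,C,G,T -> 0..3; anything else -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed base-4 codes of every k-mer (positions 0..len-k); N-containing
    k-mers are flagged with the sentinel 2**63."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        out = (out << np.uint64(2)) | window.astype(np.uint64)
        bad |= window >= 4
    out[bad] = np.uint64(2**63)
    return out


@dataclass
class Alignment:
    """A gapped pairwise alignment between two intervals."""

    query: Interval
    subject: Interval
    score: int
    matches: int
    mismatches: int
    gap_columns: int
    ops: np.ndarray  # _kernels OP_* codes, alignment order
    orientation: str = "direct"

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gap_columns

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0


def _ops_stats(a_codes, b_codes, a_start, b_start, ops) -> tuple[int, int, int]:
    i, j = a_start, b_start
    matches = mismatches = gaps = 0
    for op in ops:
        if op == _kernels.OP_DIAG:
            if a_codes[i] == b_codes[j] and a_codes[i] < 4:
                matches += 1
            else:
                mismatches += 1
            i += 1
            j += 1
        elif op == _kernels.OP_GAP_B:
            gaps += 1
            i += 1
        else:
            gaps += 1
            j += 1
    return matches, mismatches, gaps


def smith_waterman(a: str, b: str) -> Optional[Alignment]:
    """Optimal local alignment of two sequences, or None if the best score
    is not positive."""
    ac, bc = encode(a), encode(b)
    score, i0, i1, j0, j1, ops_rev, n_ops = _kernels.sw_local(ac, bc)
    if score <= 0 or n_ops == 0:
        return None
    ops = ops_rev[:n_ops][::-1].copy()
    m, x, g = _ops_stats(ac, bc, i0, j0, ops)
    return Alignment(
        query=Interval(i0, i1),
        subject=Interval(j0, j1),
        score=int(score),
        matches=m,
        mismatches=x,
        gap_columns=g,
        ops=ops,
    )


def global_align(a: str, b: str) -> Alignment:
    """End-to-end alignment of two sequences (affine gaps)."""
    ac, bc = encode(a), encode(b)
    score, ops_rev, n_ops = _kernels.nw_global(ac, bc)
    ops = ops_rev[:n_ops][::-1].copy()
    m, x, g = _ops_stats(ac, bc, 0, 0, ops)
    return Alignment(
        query=Interval(0, len(a)),
        subject=Interval(0, len(b)),
        score=int(score),
        matches=m,
        mismatches=x,
        gap_columns=g,
        ops=ops,
    )


# ---------------------------------------------------------------------------
# seeded local search
# ---------------------------------------------------------------------------

_DIAG_BAND = 40  # seeds within this diagonal spread may belong to one hit
_CHAIN_GAP = 700  # max along-query gap when chaining seeds (> longest
# intermediate repeat, so end-anchored seeds of one pair always chain)
_WINDOW_PAD = 60
_WINDOW_CAP = 1500  # DP window edge cap; longer blocks are reported piecewise


def _seed_pairs(a_codes: np.ndarray, b_codes: np.ndarray, k: int,
                self_mode: bool = False) -> np.ndarray:
    """(i, j) positions of shared exact k-mers; for self_mode only i < j."""
    ka = kmer_codes(a_codes, k)
    kb = ka if self_mode else kmer_codes(b_codes, k)
    order_a = np.argsort(ka, kind="stable")
    order_b = order_a if self_mode else np.argsort(kb, kind="stable")
    sa, sb = ka[order_a], kb[order_b]
    pairs = []
    ia = 0
    ib = 0
    na, nb = len(sa), len(sb)
    sentinel = np.uint64(2**63)
    while ia < na and ib < nb:
        va, vb = sa[ia], sb[ib]
        if va == sentinel or vb == sentinel:
            break
        if va < vb:
            ia += 1
        elif va > vb:
            ib += 1
        else:
            ja = ia
            while ja < na and sa[ja] == va:
                ja += 1
            jb = ib
            while jb < nb and sb[jb] == vb:
                jb += 1
            block_a = order_a[ia:ja]
            block_b = order_b[ib:jb]
            if len(block_a) * len(block_b) <= 400:  # skip huge low-complexity blocks
                for x in block_a:
                    for y in block_b:
                        if self_mode and y <= x:
                            continue
                        pairs.append((x, y))
            ia, ib = ja, jb
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(pairs, dtype=np.int64)


def _chain_seeds(pairs: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Group seed pairs into candidate blocks -> (i_min, i_max, j_min, j_max)."""
    if len(pairs) == 0:
        return []
    diag = pairs[:, 0] - pairs[:, 1]
    order = np.argsort(pairs[:, 0], kind="stable")
    # greedy clustering: a seed joins a group when its diagonal is within the
    # band of the group's running diagonal and it is close along the query
    groups: list[dict] = []
    for idx in order:
        i, j, d = int(pairs[idx, 0]), int(pairs[idx, 1]), int(diag[idx])
        target = None
        for g in groups:
            # the diagonal is anchored at the group's first seed: a group
            # may only drift by indel-scale offsets, never walk across to a
            # neighbouring repeat's diagonal
            if (
                abs(d - g["d"]) <= _DIAG_BAND
                and i - g["i_max"] <= _CHAIN_GAP
                and abs(j - g["j_max"]) <= _CHAIN_GAP + _DIAG_BAND
            ):
                target = g
                break
        if target is None:
            groups.append(
                {"i_min": i, "i_max": i, "j_min": j, "j_max": j, "d": d}
            )
        else:
            target["i_min"] = min(target["i_min"], i)
            target["i_max"] = max(target["i_max"], i)
            target["j_min"] = min(target["j_min"], j)
            target["j_max"] = max(target["j_max"], j)
    return [
        (g["i_min"], g["i_max"], g["j_min"], g["j_max"]) for g in groups
    ]


def local_align(
    a: str,
    b: str,
    min_identity: float = 85.0,
    min_length: int = 50,
    k: int = 12,
    full_dp_limit: int = 250_000,
) -> list[Alignment]:
    """All maximal local alignments of a vs b meeting both thresholds.

    Exact k-mer seeds are chained into candidate blocks and each block is
    resolved by full affine-gap DP on a padded window.  For small inputs
    (<= ``full_dp_limit`` DP cells) the globally optimal local alignment is
    additionally computed directly, so on short sequences the result equals
    exhaustive Smith-Waterman.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if not (0 < min_identity <= 100):
        raise ValueError(f"min_identity out of range: {min_identity}")
    if min_length < 1:
        raise ValueError(f"min_length out of range: {min_length}")
    ac, bc = encode(a), encode(b)
    hits: list[Alignment] = []
    if len(a) * len(b) <= full_dp_limit:
        best = smith_waterman(a, b)
        if best is not None:
            hits.append(best)
    blocks = _chain_seeds(_seed_pairs(ac, bc, k))
    for i0, i1, j0, j1 in blocks:
        hits.extend(_window_align(a, b, i0, i1, j0, j1, k))
    hits = [
        h for h in hits if h.columns >= min_length and h.identity >= min_identity
    ]
    return _dedup_hits(hits)


def _reciprocal_overlap(x: Interval, y: Interval) -> float:
    ov = x.overlap_len(y)
    if ov == 0:
        return 0.0
    return min(ov / x.length, ov / y.length)


def _dedup_hits(hits: list[Alignment]) -> list[Alignment]:
    """Merge hits whose query AND subject intervals overlap >= 80%
    reciprocally, keeping the highest score (ties: longer, lower coords)."""
    ranked = sorted(
        hits,
        key=lambda h: (-h.score, -h.columns, h.query.start, h.subject.start),
    )
    kept: list[Alignment] = []
    for h in ranked:
        dup = False
        for other in kept:
            if (
                _reciprocal_overlap(h.query, other.query) >= 0.8
                and _reciprocal_overlap(h.subject, other.subject) >= 0.8
            ):
                dup = True
                break
        if not dup:
            kept.append(h)
    kept.sort(key=lambda h: (h.query.start, h.subject.start))
    return kept


# ---------------------------------------------------------------------------
# repeat pairs
# ---------------------------------------------------------------------------

SIZE_SHORT = "short"
SIZE_INTERMEDIATE = "intermediate"
SIZE_LARGE = "large"


def size_class(columns: int) -> str:
    if columns < 50:
        return SIZE_SHORT
    if columns < 1000:
        return SIZE_INTERMEDIATE
    return SIZE_LARGE


@dataclass
class RepeatPair:
    """Two homologous genomic intervals plus their four flank windows.

    Flank regions are numbered 1-4 as (copy1 upstream, copy1 downstream,
    copy2 upstream, copy2 downstream) in genome orientation.
    """

    name: str
    copy1: Interval
    copy2: Interval
    orientation: str  # direct | inverted
    length: int  # alignment columns
    identity: float  # percent, column-based
    flank_window: int = 220
    genome_length: int = 0
    score: int = 0

    @property
    def klass(self) -> str:
        return size_class(self.length)

    def flank(self, region: int) -> Interval:
        """Flank window for region 1..4, clipped to genome bounds."""
        w = self.flank_window
        L = self.genome_length or 10**12
        if region == 1:
            s, e = self.copy1.start - w, self.copy1.start
        elif region == 2:
            s, e = self.copy1.end, self.copy1.end + w
        elif region == 3:
            s, e = self.copy2.start - w, self.copy2.start
        elif region == 4:
            s, e = self.copy2.end, self.copy2.end + w
        else:
            raise ValueError(f"region must be 1..4, got {region}")
        return Interval(max(0, s), min(L, e))

    @property
    def flanks(self) -> tuple[Interval, Interval, Interval, Interval]:
        return tuple(self.flank(r) for r in (1, 2, 3, 4))


def find_repeat_pairs(
    genome: GenomeSeq,
    min_length: int = 50,
    min_identity: float = 85.0,
    flank_window: int = 220,
    k: int = 12,
) -> list[RepeatPair]:
    """Self-alignment repeat discovery on both strands.

    Each unordered pair of homologous intervals is reported once, with
    copy1 at the lower coordinate, sorted by copy1 position.  The trivial
    self-diagonal is excluded.
    """
    if genome.length < 2 * min_length:
        raise ValueError("genome shorter than twice min_length")
    seq = genome.sequence
    codes = encode(seq)
    hits: list[Alignment] = []

    # direct orientation: genome vs itself, i < j seeds only
    pairs = _seed_pairs(codes, codes, k, self_mode=True)
    if len(pairs):
        # drop near-diagonal seeds (trivial self matches / tiny tandems)
        keep = pairs[:, 1] - pairs[:, 0] >= 30
        pairs = pairs[keep]
    for i0, i1, j0, j1 in _chain_seeds(pairs):
        for aln in _window_align(seq, seq, i0, i1, j0, j1, k):
            if not aln.query.overlaps(aln.subject):
                hits.append(aln)

    # inverted orientation: genome vs its reverse complement
    rc = revcomp(seq)
    rc_codes = encode(rc)
    L = genome.length
    ipairs = _seed_pairs(codes, rc_codes, k)
    inv_hits: list[Alignment] = []
    inv_raw: list[Alignment] = []
    for i0, i1, j0, j1 in _chain_seeds(ipairs):
        inv_raw.extend(_window_align(seq, rc, i0, i1, j0, j1, k))
    for aln in inv_raw:
        fwd_subject = Interval(L - aln.subject.end, L - aln.subject.start, "-")
        aln = Alignment(
            query=aln.query,
            subject=fwd_subject,
            score=aln.score,
            matches=aln.matches,
            mismatches=aln.mismatches,
            gap_columns=aln.gap_columns,
            ops=aln.ops,
            orientation="inverted",
        )
        if aln.query.overlaps(aln.subject):
            continue  # palindrome/self overlap
        if aln.subject.start < aln.query.start:
            aln = Alignment(
                query=Interval(aln.subject.start, aln.subject.end),
                subject=Interval(aln.query.start, aln.query.end, "-"),
                score=aln.score,
                matches=aln.matches,
                mismatches=aln.mismatches,
                gap_columns=aln.gap_columns,
                ops=aln.ops[::-1].copy(),
                orientation="inverted",
            )
        inv_hits.append(aln)
    hits.extend(_dedup_hits(inv_hits))

    hits = [
        h
        for h in hits
        if h.columns >= min_length and h.identity >= min_identity
    ]
    hits = _dedup_hits(hits)
    out = []
    for idx, h in enumerate(hits):
        out.append(
            RepeatPair(
                name=f"R{idx + 1:03d}",
                copy1=h.query,
                copy2=h.subject,
                orientation=h.orientation,
                length=h.columns,
                identity=h.identity,
                flank_window=flank_window,
                genome_length=genome.length,
                score=h.score,
            )
        )
    return out


def _window_align(a, b, i0, i1, j0, j1, k) -> list[Alignment]:
    """Resolve one seed block by DP on a padded window.

    After the best local alignment is extracted, the query range on either
    side of it is re-aligned recursively, so a window that happens to span
    two distinct repeats still yields both."""
    wa0 = max(0, i0 - _WINDOW_PAD)
    wa1 = min(len(a), i1 + k + _WINDOW_PAD)
    wb0 = max(0, j0 - _WINDOW_PAD)
    wb1 = min(len(b), j1 + k + _WINDOW_PAD)
    if wa1 - wa0 > _WINDOW_CAP:
        wa1 = wa0 + _WINDOW_CAP
    if wb1 - wb0 > _WINDOW_CAP:
        wb1 = wb0 + _WINDOW_CAP
    return _window_hits(a, b, wa0, wa1, wb0, wb1, depth=4)


def _window_hits(a, b, wa0, wa1, wb0, wb1, depth: int) -> list[Alignment]:
    if wa1 - wa0 < 20 or wb1 - wb0 < 20:
        return []
    aln = smith_waterman(a[wa0:wa1], b[wb0:wb1])
    if aln is None or aln.columns < 20:
        return []
    placed = Alignment(
        query=Interval(aln.query.start + wa0, aln.query.end + wa0),
        subject=Interval(aln.subject.start + wb0, aln.subject.end + wb0),
        score=aln.score,
        matches=aln.matches,
        mismatches=aln.mismatches,
        gap_columns=aln.gap_columns,
        ops=aln.ops,
    )
    hits = [placed]
    if depth > 0:
        hits += _window_hits(a, b, wa0, placed.query.start, wb0, wb1, depth - 1)
        hits += _window_hits(a, b, placed.query.end, wa1, wb0, wb1, depth - 1)
    return hits


def realign_pair(genome: GenomeSeq, pair: RepeatPair) -> Alignment:
    """Re-align the two copies of a pair (local DP on the copy sequences)."""
    s1 = genome.fetch(pair.copy1.start, pair.copy1.end)
    s2 = genome.fetch(pair.copy2.start, pair.copy2.end)
    if pair.orientation == "inverted":
        s2 = revcomp(s2)
    aln = smith_waterman(s1, s2)
    if aln is None:
        raise ValueError(f"copies of {pair.name} do not align")
    return aln


def assign_junction_to_repeat(
    genome: GenomeSeq,
    window1: Interval,
    window2: Interval,
    catalog: Sequence[RepeatPair],
    pad: int = 260,
) -> Optional[RepeatPair]:
    """Assign a junction (two clustered endpoint windows) to a catalog pair.

    A pair qualifies when its two copies respectively overlap the two
    endpoint windows expanded by ``pad`` (insert mean + 2 sd by default);
    among qualifiers the pair with the highest local-alignment score of the
    junction region against its copies wins (ties: longer repeat, then
    lower coordinate).  Returns None when nothing qualifies (the junction
    is an NHEJ candidate).
    """
    L = genome.length
    w1 = Interval(max(0, window1.start - pad), min(L, window1.end + pad))
    w2 = Interval(max(0, window2.start - pad), min(L, window2.end + pad))
    candidates = []
    for pair in catalog:
        if (pair.copy1.overlaps(w1) and pair.copy2.overlaps(w2)) or (
            pair.copy1.overlaps(w2) and pair.copy2.overlaps(w1)
        ):
            candidates.append(pair)
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]
    region = genome.fetch(w1.start, w1.end) + genome.fetch(w2.start, w2.end)
    scored = []
    for pair in candidates:
        score = 0
        for iv in (pair.copy1, pair.copy2):
            s = genome.fetch(iv.start, iv.end)
            aln = smith_waterman(region, s)
            if aln is not None:
                score += aln.score
        scored.append((score, pair))
    scored.sort(key=lambda t: (-t[0], -t[1].length, t[1].copy1.start))
    return scored[0][1]
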