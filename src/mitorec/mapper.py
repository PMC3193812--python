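"""Minimal circular-genome paired-end mapper and pair classification.

Each 36-bp end is placed by exact k-mer seeding (k = read length / 2, both
strands) and verified allowing up to 3 mismatches.  An end with several
equally good loci (repeat-internal) is ambiguous on its own but rescued
through a uniquely mapped mate, choosing the locus that minimises the
circular end distance.  Pairs whose ends lie more than 1,000 bp apart
(circular distance, strict) are discordant by distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from . import _kernels
from .align_core import encode
from .formats_io import GenomeSeq, Interval, ReadPairRecord

DISCORDANT_DISTANCE = 1000  # "> 1,000 bp", strict
MAX_MISMATCHES = 3
MAX_BEST = 8

STATUS_CONCORDANT = 0
STATUS_DISC_DISTANCE = 1
STATUS_DISC_ORIENTATION = 2
STATUS_ODD_INSERT = 3
STATUS_AMBIGUOUS = 4
STATUS_UNMAPPED = 5

STATUS_NAMES = {
    STATUS_CONCORDANT: "concordant",
    STATUS_DISC_DISTANCE: "discordant",
    STATUS_DISC_ORIENTATION: "discordant",
    STATUS_ODD_INSERT: "odd_insert",
    STATUS_AMBIGUOUS: "ambiguous",
    STATUS_UNMAPPED: "unmapped",
}


class GenomeIndex:
    """Sorted k-mer index over a (circular) genome."""

    def __init__(self, genome: GenomeSeq, k: int):
        if genome.length < k:
            raise ValueError("genome shorter than seed length")
        self.genome = genome
        self.k = k
        codes = encode(genome.sequence)
        pad = np.concatenate([codes, codes[: k - 1]]) if genome.circular else codes
        kc = _kmer_codes_u64(pad, k)
        if genome.circular:
            kc = kc[: genome.length]
        valid = kc != np.uint64(2**63)
        positions = np.flatnonzero(valid).astype(np.int64)
        kc = kc[valid]
        order = np.argsort(kc, kind="stable")
        self.sorted_codes = kc[order]
        self.sorted_pos = positions[order]
        # genome padded for full-read verification across the origin
        ext = 512
        self.pad = (
            np.concatenate([codes, codes[:ext]]) if genome.circular else codes
        )


def _kmer_codes_u64(codes: np.ndarray, k: int) -> np.ndarray:
    n = len(codes) - k + 1
    out = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        w = codes[j : j + n]
        out = (out << np.uint64(2)) | w.astype(np.uint64)
        bad |= w >= 4
    out[bad] = np.uint64(2**63)
    return out


def _revcomp_codes(arr: np.ndarray) -> np.ndarray:
    rc = (3 - arr[:, ::-1].astype(np.int16)).astype(np.int16)
    rc[rc < 0] = 4
    return rc.astype(np.uint8)


@dataclass
class PlacementSet:
    """Vectorised pair placements for one library against one genome."""

    genome: GenomeSeq
    read_length: int
    insert_mean: int
    insert_sd: int
    status: np.ndarray  # int8 STATUS_*
    pos1: np.ndarray  # int64 read start (genome forward), -1 if unplaced
    strand1: np.ndarray  # int8, 0 forward / 1 reverse
    pos2: np.ndarray
    strand2: np.ndarray
    end_distance: np.ndarray  # circular distance between read starts
    rescued: np.ndarray  # 0 none, 1 end1 rescued, 2 end2 rescued
    reads_fwd1: np.ndarray  # (n, rl) uint8 genome-forward sequence if strand 0
    reads_rev1: np.ndarray  # revcomp rows (genome-forward sequence if strand 1)
    reads_fwd2: np.ndarray
    reads_rev2: np.ndarray
    mm1: Optional[np.ndarray] = None  # per-end placement mismatches (-1 unknown)
    mm2: Optional[np.ndarray] = None

    @property
    def n_pairs(self) -> int:
        return len(self.status)

    @property
    def placed(self) -> np.ndarray:
        return self.status <= STATUS_ODD_INSERT

    @property
    def discordant_by_distance(self) -> np.ndarray:
        return self.status == STATUS_DISC_DISTANCE

    def end_codes(self, end: int, row: int) -> np.ndarray:
        """Genome-forward base codes of one mapped end."""
        if end == 1:
            return (self.reads_fwd1 if self.strand1[row] == 0 else self.reads_rev1)[row]
        return (self.reads_fwd2 if self.strand2[row] == 0 else self.reads_rev2)[row]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for code, name in STATUS_NAMES.items():
            n = int((self.status == code).sum())
            out[name] = out.get(name, 0) + n
        return out


def map_reads(
    library,
    genome_or_index,
    max_mismatches: int = MAX_MISMATCHES,
    insert_mean: Optional[int] = None,
    insert_sd: Optional[int] = None,
) -> PlacementSet:
    """Map an in-memory paired library (synthetic_data.ReadLibrary) to the
    circular reference and classify every pair."""
    if isinstance(genome_or_index, GenomeIndex):
        index = genome_or_index
    else:
        rl = library.read_length
        index = GenomeIndex(genome_or_index, k=rl // 2)
    genome = index.genome
    rl = library.read_length
    if rl // 2 != index.k:
        raise ValueError("index k does not match read length / 2")
    im = insert_mean if insert_mean is not None else library.insert_mean
    isd = insert_sd if insert_sd is not None else library.insert_sd

    fwd1 = np.ascontiguousarray(library.codes1)
    fwd2 = np.ascontiguousarray(library.codes2)
    rev1 = np.ascontiguousarray(_revcomp_codes(fwd1))
    rev2 = np.ascontiguousarray(_revcomp_codes(fwd2))

    res1 = _kernels.place_ends(
        index.pad, genome.length, fwd1, rev1, index.sorted_codes, index.sorted_pos,
        index.k, max_mismatches, MAX_BEST,
    )
    res2 = _kernels.place_ends(
        index.pad, genome.length, fwd2, rev2, index.sorted_codes, index.sorted_pos,
        index.k, max_mismatches, MAX_BEST,
    )
    status, p1, s1, p2, s2, dist, rescued = _kernels.resolve_pairs(
        res1[0], res1[1], res1[2], res1[3],
        res2[0], res2[1], res2[2], res2[3],
        genome.length, rl, max_mismatches,
        im - 4 * isd, im + 4 * isd, DISCORDANT_DISTANCE, MAX_BEST,
    )
    return PlacementSet(
        genome=genome,
        read_length=rl,
        insert_mean=im,
        insert_sd=isd,
        status=status,
        pos1=p1,
        strand1=s1,
        pos2=p2,
        strand2=s2,
        end_distance=dist,
        rescued=rescued,
        reads_fwd1=fwd1,
        reads_rev1=rev1,
        reads_fwd2=fwd2,
        reads_rev2=rev2,
        mm1=res1[0].astype(np.int16),
        mm2=res2[0].astype(np.int16),
    )


def classify_pair(
    p1: int, s1: str, p2: int, s2: str, genome: GenomeSeq,
    read_length: int = 36, insert_mean: int = 220, insert_sd: int = 20,
) -> tuple[str, int]:
    """Classify a single placed pair -> (label, circular end distance).

    Label is concordant / discordant / odd_insert; discordance requires a
    circular end distance strictly greater than 1,000 bp or an improper
    orientation.
    """
    L = genome.length
    d = genome.circular_distance(p1, p2)
    if d > DISCORDANT_DISTANCE:
        return "discordant", d
    if s1 == s2:
        return "discordant", d
    fwd_to_rev = (p2 - p1) % L if s1 == "+" else (p1 - p2) % L
    if fwd_to_rev != d:
        return "discordant", d
    span = d + read_length
    if insert_mean - 4 * insert_sd <= span <= insert_mean + 4 * insert_sd:
        return "concordant", d
    return "odd_insert", d


def placements_from_sam(
    records: Iterable[ReadPairRecord],
    genome: GenomeSeq,
    read_length: int = 36,
    insert_mean: int = 220,
    insert_sd: int = 20,
) -> PlacementSet:
    """Build a PlacementSet from externally aligned (SAM) read pairs, so the
    downstream pipeline is independent of the internal mapper."""
    rows = [
        r
        for r in records
        if r.end1.interval is not None and r.end2.interval is not None
    ]
    n = len(rows)
    rl = read_length
    p1 = np.full(n, -1, np.int64)
    p2 = np.full(n, -1, np.int64)
    s1 = np.zeros(n, np.int8)
    s2 = np.zeros(n, np.int8)
    f1 = np.zeros((n, rl), np.uint8)
    f2 = np.zeros((n, rl), np.uint8)
    status = np.zeros(n, np.int8)
    dist = np.zeros(n, np.int64)
    for i, r in enumerate(rows):
        p1[i] = r.end1.interval.start
        p2[i] = r.end2.interval.start
        s1[i] = 0 if r.end1.strand == "+" else 1
        s2[i] = 0 if r.end2.strand == "+" else 1
        # SAM stores the genome-forward sequence
        fwdseq1 = encode(r.end1.sequence)[:rl]
        fwdseq2 = encode(r.end2.sequence)[:rl]
        f1[i, : len(fwdseq1)] = fwdseq1
        f2[i, : len(fwdseq2)] = fwdseq2
        label, d = classify_pair(
            int(p1[i]), r.end1.strand, int(p2[i]), r.end2.strand, genome,
            rl, insert_mean, insert_sd,
        )
        dist[i] = d
        if label == "concordant":
            status[i] = STATUS_CONCORDANT
        elif label == "odd_insert":
            status[i] = STATUS_ODD_INSERT
        else:
            status[i] = (
                STATUS_DISC_DISTANCE if d > DISCORDANT_DISTANCE else STATUS_DISC_ORIENTATION
            )
    # genome-forward codes are stored in the fwd arrays regardless of strand;
    # end_codes() must therefore see identical fwd/rev rows
    return PlacementSet(
        genome=genome,
        read_length=rl,
        insert_mean=insert_mean,
        insert_sd=insert_sd,
        status=status,
        pos1=p1,
        strand1=s1,
        pos2=p2,
        strand2=s2,
        end_distance=dist,
        rescued=np.zeros(n, np.int8),
        reads_fwd1=f1,
        reads_rev1=f1,
        reads_fwd2=f2,
        reads_rev2=f2,
        mm1=np.full(n, -1, np.int16),
        mm2=np.full(n, -1, np.int16),
    )


def coverage_track(
    placements: PlacementSet,
    include_discordant: bool = True,
    max_mismatches: Optional[int] = None,
) -> np.ndarray:
    """Per-base read depth from uniquely placed / mate-rescued reads.

    Depth counts read bases, wraps circularly, and excludes ambiguous and
    unmapped pairs.  Conservation: depth.sum() == read_length * number of
    counted reads.  ``max_mismatches`` restricts to a high-confidence view
    (ends with unknown mismatch counts are kept).
    """
    L = placements.genome.length
    rl = placements.read_length
    keep = placements.placed
    if not include_discordant:
        keep = keep & (placements.status != STATUS_DISC_DISTANCE) & (
            placements.status != STATUS_DISC_ORIENTATION
        )
    keep1 = keep2 = keep
    if max_mismatches is not None and placements.mm1 is not None:
        keep1 = keep & ((placements.mm1 <= max_mismatches) | (placements.mm1 < 0))
        keep2 = keep & ((placements.mm2 <= max_mismatches) | (placements.mm2 < 0))
    starts = np.concatenate([placements.pos1[keep1], placements.pos2[keep2]])
    diff = np.zeros(L + rl, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, starts + rl, -1)
    depth = np.cumsum(diff)[:-1]
    wrap = depth[L:]
    depth = depth[:L].copy()
    depth[: len(wrap)] += wrap
    return depth


def base_pileup(
    placements: PlacementSet, max_mismatches: Optional[int] = None
) -> np.ndarray:
    """(4, L) base-count pileup over placed reads (genome-forward bases).

    ``max_mismatches`` restricts to ends placed with at most that many
    mismatches (junction-spanning reads that bleed a few bases across a
    breakpoint are placed with 2-3 mismatches and would otherwise mimic
    clustered variants).
    """
    L = placements.genome.length
    base_keep = placements.placed
    counts = np.zeros((4, L), dtype=np.int32)
    for end in (1, 2):
        keep = base_keep
        mm = placements.mm1 if end == 1 else placements.mm2
        if max_mismatches is not None and mm is not None:
            keep = base_keep & ((mm <= max_mismatches) | (mm < 0))
        pos = (placements.pos1 if end == 1 else placements.pos2)[keep]
        strand = (placements.strand1 if end == 1 else placements.strand2)[keep]
        fwd = (placements.reads_fwd1 if end == 1 else placements.reads_fwd2)[keep]
        rev = (placements.reads_rev1 if end == 1 else placements.reads_rev2)[keep]
        _kernels.accumulate_pileup(counts, pos, strand, fwd, rev, L)
    return counts
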