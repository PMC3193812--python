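"""Heteroduplex-repair / gene-conversion analysis at nonidentical repeats:
inter-copy polymorphism catalog, recombinant consensus at polymorphic
sites, and donor/recipient resolution.

Phasing note: with 36-bp reads and ~220-bp inserts a read pair links a
repeat-internal site to a flank only when the site lies within roughly 180
bp of a repeat edge; deeper sites in long repeats stay "uncovered",
mirroring the library geometry.  The phased pileup consists of (a) the
junction cluster's own pairs and (b) pairs anchored in the donor-downstream
flank, a side that recipient-parental molecules never produce; residual
donor-parental reads in (b) carry donor-template alleles and shrink with
class I depletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .align_core import RepeatPair, encode, global_align
from .formats_io import GenomeSeq, Interval, revcomp
from .junction_detect import JunctionCluster
from .mapper import PlacementSet

log = logging.getLogger(__name__)

MIN_PHASED_READS = 5
MIN_AGREEMENT = 0.8


@dataclass
class RepeatPolymorphism:
    repeat: str
    column: int  # column index in the copy1-vs-copy2 alignment
    kind: str  # SNP | insertion | deletion
    allele1: str  # copy1 allele ("" when absent)
    allele2: str
    offset1: int  # offset in copy1 (next consumed base for insertions)
    offset2: int
    genome_pos1: int
    genome_pos2: int


def catalog_polymorphisms(
    pair: RepeatPair, genome: GenomeSeq
) -> list[RepeatPolymorphism]:
    """Global alignment of the two copies; every non-identical column is
    emitted, with runs of adjacent gap columns merged into single indel
    events.  An identical pair yields an empty catalog."""
    s1 = genome.fetch(pair.copy1.start, pair.copy1.end)
    s2 = genome.fetch(pair.copy2.start, pair.copy2.end)
    inverted = pair.orientation == "inverted"
    if inverted:
        s2 = revcomp(s2)
    aln = global_align(s1, s2)
    out: list[RepeatPolymorphism] = []
    i = j = 0
    col = 0
    ops = list(aln.ops)
    n = len(ops)
    idx = 0
    while idx < n:
        op = ops[idx]
        if op == _kernels.OP_DIAG:
            if s1[i] != s2[j]:
                out.append(
                    _poly(pair, genome, "SNP", col, s1[i], s2[j], i, j, inverted)
                )
            i += 1
            j += 1
            idx += 1
            col += 1
            continue
        # merge a run of identical gap ops into one indel event
        run = idx
        while run < n and ops[run] == op:
            run += 1
        length = run - idx
        if op == _kernels.OP_GAP_A:  # bases present only in copy2
            out.append(
                _poly(pair, genome, "insertion", col, "", s2[j : j + length], i, j, inverted)
            )
            j += length
        else:  # bases present only in copy1
            out.append(
                _poly(pair, genome, "deletion", col, s1[i : i + length], "", i, j, inverted)
            )
            i += length
        idx = run
        col += length
    return out


def _poly(pair, genome, kind, col, a1, a2, off1, off2, inverted) -> RepeatPolymorphism:
    g1 = pair.copy1.start + off1
    if inverted:
        # offset in the reverse-complemented copy2 maps from the far end
        g2 = pair.copy2.end - 1 - off2
    else:
        g2 = pair.copy2.start + off2
    return RepeatPolymorphism(
        repeat=pair.name, column=col, kind=kind,
        allele1=a1 if isinstance(a1, str) else str(a1),
        allele2=a2 if isinstance(a2, str) else str(a2),
        offset1=off1, offset2=off2, genome_pos1=g1, genome_pos2=g2,
    )


@dataclass
class SiteCall:
    column: int
    kind: str
    n_copy1: int
    n_copy2: int
    consensus: str  # copy1 | copy2 | mixed | uncovered
    resolution: str = ""  # donor | recipient | mixed | uncovered (set later)

    @property
    def depth(self) -> int:
        return self.n_copy1 + self.n_copy2


@dataclass
class ConversionReport:
    repeat: str
    sites: list[SiteCall]
    phased_rows: list[tuple[int, int]] = field(default_factory=list)  # (row, end)
    warning: str = ""

    def covered_sites(self) -> list[SiteCall]:
        return [s for s in self.sites if s.consensus in ("copy1", "copy2", "mixed")]


def recombinant_consensus(
    placements: PlacementSet,
    pair: RepeatPair,
    polymorphisms: Sequence[RepeatPolymorphism],
    cluster: Optional[JunctionCluster],
    donor: int,
    library: Optional[str] = None,
    min_reads: int = MIN_PHASED_READS,
    min_agreement: float = MIN_AGREEMENT,
) -> ConversionReport:
    """Per-site allele calls over reads phased to the recombinant molecule.

    Phased pairs are (a) members of the selected junction cluster for this
    repeat (restricted to ``library`` when given) and (b) pairs anchored in
    the donor-downstream flank window with the mate overlapping a repeat
    copy.  Sites with fewer than ``min_reads`` phased reads are
    "uncovered"; the majority allele needs ``min_agreement`` support.
    """
    rl = placements.read_length
    genome = placements.genome
    donor_iv = pair.copy1 if donor == 1 else pair.copy2
    rows: dict[tuple[int, int], None] = {}

    def repeat_end_of(row: int) -> Optional[int]:
        for end, pos in ((1, placements.pos1[row]), (2, placements.pos2[row])):
            for c in (pair.copy1, pair.copy2):
                if pos + rl > c.start and pos < c.end:
                    return end
        return None

    if cluster is not None:
        for lib, row in cluster.members:
            if library is not None and lib != library:
                continue
            end = repeat_end_of(row)
            if end is not None:
                rows[(row, end)] = None

    down = Interval(donor_iv.end, min(genome.length, donor_iv.end + placements.insert_mean))
    placed = placements.placed
    for anchor_end, mate_end in ((1, 2), (2, 1)):
        apos = placements.pos1 if anchor_end == 1 else placements.pos2
        anchored = placed & (apos >= down.start) & (apos + rl <= down.end)
        for row in np.flatnonzero(anchored):
            end = repeat_end_of(int(row))
            if end == mate_end:
                rows[(int(row), end)] = None

    if not rows:
        log.warning("no phased reads for repeat %s", pair.name)
        return ConversionReport(repeat=pair.name, sites=[
            SiteCall(p.column, p.kind, 0, 0, "uncovered") for p in polymorphisms
        ], warning="no phased reads")

    tallies = {p.column: [0, 0] for p in polymorphisms}
    ctx = _site_contexts(genome, pair, polymorphisms)
    for row, end in rows:
        pos = int((placements.pos1 if end == 1 else placements.pos2)[row])
        codes = placements.end_codes(end, row)
        on_copy1 = pos + rl > pair.copy1.start and pos < pair.copy1.end
        for p in polymorphisms:
            g = p.genome_pos1 if on_copy1 else p.genome_pos2
            if not (pos <= g < pos + rl):
                continue
            if p.kind == "SNP":
                base = int(codes[g - pos])
                a1 = encode(p.allele1)[0]
                a2 = encode(p.allele2)[0]
                if pair.orientation == "inverted" and not on_copy1:
                    a1, a2 = (3 - a1) % 4, (3 - a2) % 4  # alleles on - strand
                if base == a1:
                    tallies[p.column][0] += 1
                elif base == a2:
                    tallies[p.column][1] += 1
            else:
                which = _indel_allele(codes, ctx[p.column])
                if which is not None:
                    tallies[p.column][which] += 1

    sites = []
    for p in polymorphisms:
        n1, n2 = tallies[p.column]
        total = n1 + n2
        if total < min_reads:
            consensus = "uncovered"
        elif n1 / total > min_agreement:
            consensus = "copy1"
        elif n2 / total > min_agreement:
            consensus = "copy2"
        else:
            consensus = "mixed"
        sites.append(SiteCall(p.column, p.kind, n1, n2, consensus))
    return ConversionReport(repeat=pair.name, sites=sites, phased_rows=list(rows))


def _site_contexts(genome, pair, polymorphisms, pad: int = 50):
    """Per-indel context sequences from both copies (for read re-scoring)."""
    out = {}
    s1 = genome.fetch(pair.copy1.start, pair.copy1.end)
    s2 = genome.fetch(pair.copy2.start, pair.copy2.end)
    if pair.orientation == "inverted":
        s2 = revcomp(s2)
    for p in polymorphisms:
        if p.kind == "SNP":
            continue
        c1 = s1[max(0, p.offset1 - pad) : p.offset1 + len(p.allele1) + pad]
        c2 = s2[max(0, p.offset2 - pad) : p.offset2 + len(p.allele2) + pad]
        out[p.column] = (encode(c1), encode(c2))
    return out


def _indel_allele(read_codes: np.ndarray, contexts) -> Optional[int]:
    """0 if the read matches the copy1 indel state better, 1 for copy2."""
    c1, c2 = contexts
    s1 = _kernels.sw_local(read_codes, c1)[0]
    s2 = _kernels.sw_local(read_codes, c2)[0]
    if s1 == s2:
        return None
    return 0 if s1 > s2 else 1


@dataclass
class DirectionSummary:
    repeat: str
    verdict: str  # donor-biased | mixed | no data | polarity-unknown
    snp_donor: int
    snp_recipient: int
    snp_mixed: int
    snp_uncovered: int
    indel_donor: int
    indel_recipient: int
    indel_other: int


def resolve_direction(report: ConversionReport, donor: Optional[int]) -> DirectionSummary:
    """Map per-site consensus through donor identity.

    With indeterminate polarity (donor None) resolutions stay relative to
    copy1/copy2 and the verdict is "polarity-unknown".  Indels are
    summarized separately, with no directional expectation.
    """
    if donor is None:
        for s in report.sites:
            s.resolution = s.consensus
        return DirectionSummary(
            repeat=report.repeat, verdict="polarity-unknown",
            snp_donor=0, snp_recipient=0, snp_mixed=0,
            snp_uncovered=sum(1 for s in report.sites if s.kind == "SNP" and s.consensus == "uncovered"),
            indel_donor=0, indel_recipient=0, indel_other=0,
        )
    donor_label = "copy1" if donor == 1 else "copy2"
    counts = {"SNP": {"donor": 0, "recipient": 0, "mixed": 0, "uncovered": 0},
              "indel": {"donor": 0, "recipient": 0, "other": 0}}
    for s in report.sites:
        if s.consensus == "uncovered":
            s.resolution = "uncovered"
        elif s.consensus == "mixed":
            s.resolution = "mixed"
        else:
            s.resolution = "donor" if s.consensus == donor_label else "recipient"
        if s.kind == "SNP":
            counts["SNP"][s.resolution] += 1
        else:
            counts["indel"][s.resolution if s.resolution in ("donor", "recipient") else "other"] += 1
    covered = counts["SNP"]["donor"] + counts["SNP"]["recipient"] + counts["SNP"]["mixed"]
    if covered == 0 and counts["indel"]["donor"] + counts["indel"]["recipient"] == 0:
        verdict = "no data"
    elif counts["SNP"]["recipient"] == 0 and counts["SNP"]["mixed"] == 0 and covered > 0:
        verdict = "donor-biased"
    else:
        verdict = "mixed"
    return DirectionSummary(
        repeat=report.repeat, verdict=verdict,
        snp_donor=counts["SNP"]["donor"],
        snp_recipient=counts["SNP"]["recipient"],
        snp_mixed=counts["SNP"]["mixed"],
        snp_uncovered=counts["SNP"]["uncovered"],
        indel_donor=counts["indel"]["donor"],
        indel_recipient=counts["indel"]["recipient"],
        indel_other=counts["indel"]["other"],
    )
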