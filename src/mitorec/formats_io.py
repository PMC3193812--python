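"""Shared domain types, coordinate conventions and external-format IO.

Internal coordinates are 0-based half-open throughout the package; every
human-facing table is written 1-based inclusive.  BED stays 0-based
half-open, per the format.  Circularity is a per-sequence flag supplied by
configuration -- FASTA carries no such tag.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_ALPHABET = set("ACGTN")

COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class GenomeSeq:
    """A named genome sequence, optionally circular.

    Residues of a circular genome are addressed modulo ``length``.
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.name!r} contains non-ACGTN characters: {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end); wraps on circular genomes."""
        L = self.length
        if 0 <= start <= end <= L:
            return self.sequence[start:end]
        if not self.circular:
            raise IndexError(f"[{start}, {end}) outside linear genome of length {L}")
        out = []
        pos = start % L
        remaining = max(0, end - start)
        while remaining > 0:
            take = min(remaining, L - pos)
            out.append(self.sequence[pos : pos + take])
            remaining -= take
            pos = (pos + take) % L
        return "".join(out)

    def circular_distance(self, a: int, b: int) -> int:
        """min(d, L - d) between two positions."""
        d = abs(a - b) % self.length
        return min(d, self.length - d) if self.circular else abs(a - b)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval.

    A wrapping interval on a circular genome is represented by the caller as
    an ordered pair of non-wrapping intervals; this class is always
    non-wrapping.
    """

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlap_len(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def to_1based(self) -> tuple[int, int]:
        """(first, last) in 1-based inclusive coordinates."""
        return (self.start + 1, self.end)

    @staticmethod
    def from_1based(first: int, last: int, strand: str = "+") -> "Interval":
        return Interval(first - 1, last, strand)


@dataclass
class ReadEnd:
    sequence: str  # aligned (genome-forward) orientation, as SAM stores it
    interval: Optional[Interval]  # None when unmapped
    strand: str
    mapq: int = 255
    n_mismatch: int = -1


@dataclass
class ReadPairRecord:
    """Two ends of one sequenced fragment."""

    read_id: str
    end1: ReadEnd
    end2: ReadEnd


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path, circular: bool = True) -> list[GenomeSeq]:
    """Read a FASTA file into GenomeSeq objects (uppercased, file order).

    Circularity comes from the ``circular`` argument, never from the file.
    An empty file yields an empty list with a warning.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    out = []
    with open(path) as fh:
        first = fh.read(1)
        if first == "":
            log.warning("FASTA file %s is empty", path)
            return []
        if first != ">":
            raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        try:
            out.append(GenomeSeq(name=rec.id, sequence=seq, circular=circular))
        except FormatError as e:
            raise FormatError(f"{path}: record {rec.id!r}: {e}") from e
    return out


def write_fasta(genomes: Iterable[GenomeSeq], path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.name, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq_pair(names, seqs1, seqs2, path1, path2, qual_char: str = "I") -> None:
    """Write one paired FASTQ library; read names get /1 and /2 suffixes."""
    for path, seqs, suffix in ((path1, seqs1, "/1"), (path2, seqs2, "/2")):
        with open(path, "w") as fh:
            parts = []
            for name, s in zip(names, seqs):
                parts.append(f"@{name}{suffix}\n{s}\n+\n{qual_char * len(s)}\n")
            fh.write("".join(parts))


def read_fastq(path) -> tuple[list[str], list[str]]:
    """Read a FASTQ file -> (names, sequences); /1 and /2 suffixes stripped."""
    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        name = rec.id
        if name.endswith("/1") or name.endswith("/2"):
            name = name[:-2]
        names.append(name)
        seqs.append(str(rec.seq).upper())
    return names, seqs


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

class SamPairReader:
    """Stream mate-joined read pairs from a SAM file.

    Only POS, FLAG, MAPQ and the sequence are consumed.  Records whose mate
    never appears are dropped; ``.orphans`` holds their count once the
    stream is exhausted.
    """

    def __init__(self, path):
        self.path = str(path)
        self.orphans = 0

    def __iter__(self) -> Iterator[ReadPairRecord]:
        import pysam

        pending: dict[str, object] = {}
        with pysam.AlignmentFile(self.path, "r", check_sq=True) as fh:
            if not fh.header.get("SQ"):
                raise FormatError(f"{self.path}: SAM header missing @SQ lines")
            ref_lens = {r["SN"]: r["LN"] for r in fh.header["SQ"]}
            for rec in fh:
                if rec.is_secondary or rec.is_supplementary:
                    continue
                if not rec.is_paired:
                    self.orphans += 1
                    continue
                if not rec.is_unmapped:
                    L = ref_lens.get(rec.reference_name, 0)
                    if rec.reference_start >= L:
                        raise FormatError(
                            f"{self.path}: {rec.query_name}: POS "
                            f"{rec.reference_start + 1} outside reference of length {L}"
                        )
                key = rec.query_name
                if key in pending:
                    other = pending.pop(key)
                    first, second = (other, rec) if other.is_read1 else (rec, other)
                    yield ReadPairRecord(
                        read_id=key, end1=_sam_end(first), end2=_sam_end(second)
                    )
                else:
                    pending[key] = rec
        self.orphans += len(pending)
        if self.orphans:
            log.info("dropped %d orphan/unpaired SAM records", self.orphans)


def read_alignments(path) -> SamPairReader:
    return SamPairReader(path)


def _sam_end(rec) -> ReadEnd:
    if rec.is_unmapped:
        return ReadEnd(sequence=rec.query_sequence or "", interval=None, strand="+", mapq=0)
    seq = rec.query_sequence or ""
    iv = Interval(rec.reference_start, rec.reference_end or rec.reference_start + len(seq))
    return ReadEnd(
        sequence=seq,
        interval=iv,
        strand="-" if rec.is_reverse else "+",
        mapq=rec.mapping_quality,
    )


def write_sam(placements, genome: GenomeSeq, path) -> None:
    """Minimal SAM emission for mapped pairs (used for the equivalence path)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": genome.name, "LN": genome.length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pl in placements:
            rp = pl.pair
            for idx, end in ((1, rp.end1), (2, rp.end2)):
                if end.interval is None:
                    continue
                a = pysam.AlignedSegment()
                a.query_name = rp.read_id
                a.query_sequence = end.sequence  # already in aligned orientation
                flag = 0x1 | (0x40 if idx == 1 else 0x80)
                if end.strand == "-":
                    flag |= 0x10
                other = rp.end2 if idx == 1 else rp.end1
                if other.interval is not None and other.strand == "-":
                    flag |= 0x20
                a.flag = flag
                a.reference_id = 0
                a.reference_start = end.interval.start
                a.mapping_quality = end.mapq
                a.cigarstring = f"{len(end.sequence)}M"
                if other.interval is not None:
                    a.next_reference_id = 0
                    a.next_reference_start = other.interval.start
                else:
                    a.next_reference_id = -1
                    a.next_reference_start = -1
                a.query_qualities = pysam.qualitystring_to_array("I" * len(end.sequence))
                out.write(a)


# ---------------------------------------------------------------------------
# BED / TSV / VCF / Newick / bedGraph
# ---------------------------------------------------------------------------

def write_bed(rows: Iterable[tuple[str, Interval, str]], path) -> None:
    """rows of (chrom, interval, name) -> BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, iv, name in rows:
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path) -> list[tuple[str, Interval, str]]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {i}: fewer than 3 BED columns")
            strand = parts[5] if len(parts) > 5 else "+"
            out.append(
                (parts[0], Interval(int(parts[1]), int(parts[2]), strand),
                 parts[3] if len(parts) > 3 else f"feature{i}")
            )
    return out


def write_bedgraph(depth: np.ndarray, chrom: str, path) -> None:
    """Per-base depth vector -> bedGraph with runs collapsed."""
    with open(path, "w") as fh:
        if len(depth) == 0:
            return
        boundaries = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(depth)]))
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{s}\t{e}\t{depth[s]:g}\n")


def write_tsv(df, path) -> None:
    df.to_csv(path, sep="\t", index=False)


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(snps, chrom: str, path) -> None:
    """Minimal VCF v4.2 for SNP calls (1-based POS)."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for s in snps:
            fh.write(
                f"{chrom}\t{s.position + 1}\t.\t{s.ref_allele}\t{s.alt_allele}\t.\t"
                f"PASS\tDP={s.depth};AF={s.allele_fraction:.4f}\n"
            )


def read_newick(path):
    import skbio

    return skbio.TreeNode.read(str(path))


def write_newick(newick_string: str, path) -> None:
    with open(path, "w") as fh:
        s = newick_string.strip()
        fh.write(s if s.endswith(";") else s + ";")
        fh.write("\n")


def ensure_outdir(out_dir) -> str:
    try:
        os.makedirs(out_dir, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out_dir}: {e}") from e
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir} is not writable")
    return str(out_dir)
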