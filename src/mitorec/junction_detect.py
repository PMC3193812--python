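"""Cluster discordant pairs into junctions, apply the support filter, and
call recombination-active repeat pairs.

Clusters are built by single-linkage over all libraries at once: two
discordant pairs join when both corresponding endpoints lie within the
joining radius (insert mean + 3 sd) of each other and their orientation
signatures match.  Support is counted per library; matched wild-type
support is subtracted before the strict "> min_support in every required
library" filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align_core import RepeatPair, assign_junction_to_repeat
from .formats_io import GenomeSeq, Interval
from .mapper import PlacementSet

log = logging.getLogger(__name__)

DEFAULT_MIN_SUPPORT = 10  # "more than 10 reads": strict, i.e. keep >= 11


@dataclass
class JunctionCluster:
    """A group of discordant read pairs defining one putative junction."""

    window1: Interval  # lower-coordinate endpoint window
    window2: Interval
    signature: tuple[int, int]  # strands of (lower, upper) endpoint reads
    members: list[tuple[str, int]]  # (library, pair row)
    support_by_library: dict[str, int]
    assigned_repeat: Optional[RepeatPair] = None
    call: str = "background"  # repeat-mediated | NHEJ-candidate | background
    secondary_of: Optional[str] = None
    anomaly: bool = False

    @property
    def support(self) -> int:
        return sum(self.support_by_library.values())

    def net_support(self, library: str, wt: str = "WT") -> int:
        return self.support_by_library.get(library, 0) - self.support_by_library.get(
            wt, 0
        )

    def span(self, genome: GenomeSeq) -> int:
        return genome.circular_distance(self.window1.start, self.window2.start)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_discordant(
    placements_by_library: dict[str, PlacementSet],
    radius: Optional[int] = None,
) -> list[JunctionCluster]:
    """Single-linkage clustering of distance-discordant pairs, pooled over
    libraries so per-library supports refer to identical windows."""
    libs = list(placements_by_library)
    if not libs:
        return []
    any_pl = placements_by_library[libs[0]]
    genome = any_pl.genome
    rl = any_pl.read_length
    if radius is None:
        radius = any_pl.insert_mean + 3 * any_pl.insert_sd

    rows = []  # (lib, idx, lo_pos, hi_pos, sig)
    for lib, pl in placements_by_library.items():
        for i in np.flatnonzero(pl.discordant_by_distance):
            a = (int(pl.pos1[i]), int(pl.strand1[i]))
            b = (int(pl.pos2[i]), int(pl.strand2[i]))
            (lo, slo), (hi, shi) = sorted((a, b))
            rows.append((lib, int(i), lo, hi, (slo, shi)))
    if not rows:
        return []
    rows.sort(key=lambda r: r[2])
    n = len(rows)
    uf = _UnionFind(n)
    for i in range(n):
        _, _, lo_i, hi_i, sig_i = rows[i]
        j = i - 1
        while j >= 0 and lo_i - rows[j][2] <= radius:
            if rows[j][4] == sig_i and abs(hi_i - rows[j][3]) <= radius:
                uf.union(i, j)
            j -= 1
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    clusters = []
    for members in groups.values():
        los = [rows[i][2] for i in members]
        his = [rows[i][3] for i in members]
        sig = rows[members[0]][4]
        support: dict[str, int] = {}
        mem = []
        for i in members:
            support[rows[i][0]] = support.get(rows[i][0], 0) + 1
            mem.append((rows[i][0], rows[i][1]))
        clusters.append(
            JunctionCluster(
                window1=Interval(min(los), max(los) + rl),
                window2=Interval(min(his), max(his) + rl),
                signature=sig,
                members=mem,
                support_by_library=support,
            )
        )
    clusters.sort(key=lambda c: (c.window1.start, c.window2.start))
    return clusters


def filter_clusters(
    clusters: Sequence[JunctionCluster],
    min_support: int = DEFAULT_MIN_SUPPORT,
    require_libraries: Sequence[str] = ("msh1_gen1", "msh1_adv"),
    wt_library: Optional[str] = "WT",
    known_libraries: Optional[set[str]] = None,
) -> list[JunctionCluster]:
    """Keep clusters whose support is strictly greater than ``min_support``
    in EVERY required library after subtracting matched wild-type support."""
    if known_libraries is not None:
        missing = [l for l in require_libraries if l not in known_libraries]
        if missing:
            raise ValueError(f"required libraries absent: {missing}")
    out = []
    for c in clusters:
        wt = c.support_by_library.get(wt_library, 0) if wt_library else 0
        if all(
            c.support_by_library.get(lib, 0) - wt > min_support
            for lib in require_libraries
        ):
            out.append(c)
    log.info(
        "filter_clusters: %d/%d clusters pass >%d in %s (WT-subtracted)",
        len(out), len(clusters), min_support, list(require_libraries),
    )
    return out


@dataclass
class ActiveRepeatCalls:
    active: list[tuple[RepeatPair, list[JunctionCluster]]]
    nhej_candidates: list[JunctionCluster]
    anomalies: list[str] = field(default_factory=list)

    @property
    def active_names(self) -> list[str]:
        return [p.name for p, _ in self.active]


def call_active_repeats(
    selected: Sequence[JunctionCluster],
    catalog: Sequence[RepeatPair],
    genome: GenomeSeq,
    pad: int = 260,
) -> ActiveRepeatCalls:
    """Assign each selected cluster to a repeat pair; a pair is active when
    at least one selected cluster assigns to it.

    If two selected clusters assign to the same pair with different
    orientation signatures (both reciprocal products present) the pair is
    flagged as a symmetric-exchange anomaly rather than suppressed.
    Clusters whose endpoint window falls in a flank of another active
    repeat that itself contains a copy of the cluster's own repeat are
    annotated as secondary events.
    """
    if not catalog:
        log.warning("empty catalog: all %d junctions are NHEJ candidates", len(selected))
    by_repeat: dict[str, list[JunctionCluster]] = {}
    pair_by_name: dict[str, RepeatPair] = {}
    nhej = []
    for c in selected:
        pair = (
            assign_junction_to_repeat(genome, c.window1, c.window2, catalog, pad=pad)
            if catalog
            else None
        )
        if pair is None:
            c.call = "NHEJ-candidate"
            nhej.append(c)
        else:
            c.call = "repeat-mediated"
            c.assigned_repeat = pair
            by_repeat.setdefault(pair.name, []).append(c)
            pair_by_name[pair.name] = pair

    anomalies = []
    for name, cs in by_repeat.items():
        if len({c.signature for c in cs}) > 1:
            anomalies.append(name)
            for c in cs:
                c.anomaly = True

    # secondary-event annotation
    for name, cs in by_repeat.items():
        mine = pair_by_name[name]
        for other_name, other_cs in by_repeat.items():
            if other_name == name:
                continue
            other = pair_by_name[other_name]
            for flank in other.flanks:
                if not (mine.copy1.overlaps(flank) or mine.copy2.overlaps(flank)):
                    continue
                for c in cs:
                    if c.window1.overlaps(flank) or c.window2.overlaps(flank):
                        c.secondary_of = other_name
    active = sorted(by_repeat.items(), key=lambda kv: pair_by_name[kv[0]].copy1.start)
    return ActiveRepeatCalls(
        active=[(pair_by_name[n], cs) for n, cs in active],
        nhej_candidates=nhej,
        anomalies=anomalies,
    )


def clusters_frame(clusters: Sequence[JunctionCluster], genome: GenomeSeq):
    """Cluster table (1-based windows) plus circle-plot columns
    (end midpoints, radius = support)."""
    import pandas as pd

    base_cols = [
        "window1_start", "window1_end", "window2_start", "window2_end",
        "span", "signature", "support", "assigned_repeat", "call",
        "secondary_of", "anomaly", "circle_x", "circle_y", "circle_radius",
    ]
    if not clusters:
        return pd.DataFrame(columns=base_cols)
    rows = []
    for c in clusters:
        w1s, w1e = c.window1.to_1based()
        w2s, w2e = c.window2.to_1based()
        row = {
            "window1_start": w1s,
            "window1_end": w1e,
            "window2_start": w2s,
            "window2_end": w2e,
            "span": c.span(genome),
            "signature": f"{'+-'[c.signature[0]]}{'+-'[c.signature[1]]}",
            "support": c.support,
            "assigned_repeat": c.assigned_repeat.name if c.assigned_repeat else "",
            "call": c.call,
            "secondary_of": c.secondary_of or "",
            "anomaly": c.anomaly,
            "circle_x": (c.window1.start + c.window1.end) // 2,
            "circle_y": (c.window2.start + c.window2.end) // 2,
            "circle_radius": c.support,
        }
        for lib, s in sorted(c.support_by_library.items()):
            row[f"support_{lib}"] = s
        rows.append(row)
    return pd.DataFrame(rows)
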