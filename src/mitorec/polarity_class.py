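"""Flank-coverage quantification, strand-invasion polarity, and class I/II
fate calling.

Flank regions are numbered 1-4 as (copy1 upstream, copy1 downstream, copy2
upstream, copy2 downstream).  A single asymmetric crossover joins the
recipient copy's upstream flank to the donor copy's downstream flank, so
the recombinant raises repeat-linked pair counts in the recipient-upstream
and donor-downstream regions, while loss of the donor parental form (class
I) depletes the donor-upstream region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align_core import RepeatPair
from .formats_io import Interval
from .junction_detect import JunctionCluster
from .mapper import PlacementSet

log = logging.getLogger(__name__)

CLASS_I_DEPLETION = -0.5  # depleted-region relative change threshold (advanced)
CLASS_II_BAND = 0.25  # retention band for the candidate depleted region


@dataclass
class FlankChangeTable:
    """Normalized flank-region depths and relative changes vs wild type."""

    repeat: str
    regions: dict[int, dict[str, float]]  # region -> {library: normalized depth}
    changes: dict[str, dict[int, float]]  # library -> {region: rel change vs WT}
    flags: list[str] = field(default_factory=list)

    def min_change(self, library: str) -> tuple[int, float]:
        ch = self.changes[library]
        region = min(ch, key=lambda r: (ch[r], r))
        return region, ch[region]

    def max_change(self, library: str) -> tuple[int, float]:
        ch = self.changes[library]
        region = max(ch, key=lambda r: (ch[r], -r))
        return region, ch[region]


@dataclass
class PolarityCall:
    repeat: str
    donor: Optional[int]  # 1 | 2 | None
    recipient: Optional[int]
    depleted_region: Optional[int]
    increased_region: Optional[int]
    confidence: float
    fate_class: str = "indeterminate"  # I | II | indeterminate
    coverage_vote: Optional[int] = None
    junction_vote: Optional[int] = None


def flank_depth(
    placements: PlacementSet,
    repeat: RepeatPair,
    window: Optional[int] = None,
    catalog: Optional[Sequence[RepeatPair]] = None,
) -> tuple[dict[int, int], list[str]]:
    """Count pairs with one end overlapping either repeat copy and the mate
    fully inside each flank window.

    A window that would overlap another catalog repeat is shrunk to the gap
    and flagged.  Returns ({region: count}, flags).
    """
    w = window if window is not None else placements.insert_mean
    rl = placements.read_length
    flags: list[str] = []
    regions: dict[int, Interval] = {}
    for r in (1, 2, 3, 4):
        iv = RepeatPair(
            name=repeat.name, copy1=repeat.copy1, copy2=repeat.copy2,
            orientation=repeat.orientation, length=repeat.length,
            identity=repeat.identity, flank_window=w,
            genome_length=repeat.genome_length,
        ).flank(r)
        if catalog:
            for other in catalog:
                if other.name == repeat.name:
                    continue
                for copy in (other.copy1, other.copy2):
                    if iv.overlaps(copy):
                        if copy.start >= iv.start:
                            iv = Interval(iv.start, max(iv.start + 1, copy.start))
                        else:
                            iv = Interval(min(copy.end, iv.end - 1), iv.end)
                        flags.append(
                            f"region {r} shrunk to {iv.length} bp "
                            f"(overlaps {other.name})"
                        )
        regions[r] = iv

    keep = placements.placed
    p1 = placements.pos1
    p2 = placements.pos2

    def overlaps_repeat(pos):
        out = np.zeros(len(pos), dtype=bool)
        for c in (repeat.copy1, repeat.copy2):
            out |= (pos + rl > c.start) & (pos < c.end)
        return out

    on_rep1 = overlaps_repeat(p1) & keep
    on_rep2 = overlaps_repeat(p2) & keep
    counts = {}
    for r, iv in regions.items():
        in_w1 = (p1 >= iv.start) & (p1 + rl <= iv.end) & keep
        in_w2 = (p2 >= iv.start) & (p2 + rl <= iv.end) & keep
        counts[r] = int(((in_w1 & on_rep2) | (in_w2 & on_rep1)).sum())
    return counts, flags


def flank_change_table(
    repeat: RepeatPair,
    placements_by_library: dict[str, PlacementSet],
    median_depth: dict[str, float],
    wt_library: str = "WT",
    window: Optional[int] = None,
    catalog: Optional[Sequence[RepeatPair]] = None,
) -> FlankChangeTable:
    """Normalized per-region depths and relative changes versus wild type.

    Depths are normalized by each library's genome-wide median read depth,
    making the table invariant to global coverage rescaling.
    """
    if wt_library not in placements_by_library:
        raise ValueError(f"wild-type library {wt_library!r} missing")
    regions: dict[int, dict[str, float]] = {r: {} for r in (1, 2, 3, 4)}
    flags: list[str] = []
    for lib, pl in placements_by_library.items():
        med = median_depth[lib]
        if med <= 0:
            raise ValueError(f"zero median depth for library {lib}")
        counts, fl = flank_depth(pl, repeat, window=window, catalog=catalog)
        flags.extend(f"{lib}: {x}" for x in fl)
        for r in (1, 2, 3, 4):
            regions[r][lib] = counts[r] / med
    changes: dict[str, dict[int, float]] = {}
    for lib in placements_by_library:
        if lib == wt_library:
            continue
        changes[lib] = {}
        for r in (1, 2, 3, 4):
            wt = regions[r][wt_library]
            if wt <= 0:
                changes[lib][r] = float("nan")
                flags.append(f"{lib}: region {r} has zero WT depth")
            else:
                changes[lib][r] = regions[r][lib] / wt - 1.0
    return FlankChangeTable(repeat=repeat.name, regions=regions, changes=changes, flags=flags)


def _junction_polarity_vote(
    cluster: JunctionCluster, repeat: RepeatPair
) -> Optional[int]:
    """Infer the donor copy from junction geometry alone.

    The single product joins the recipient upstream flank to the donor
    copy/downstream side, so one endpoint window sits in a copy's upstream
    flank (recipient) while the other overlaps the opposite copy or its
    downstream flank (donor).
    """
    w = repeat.flank_window

    def hyp_score(donor: int) -> int:
        recip = 2 if donor == 1 else 1
        recip_iv = repeat.copy1 if recip == 1 else repeat.copy2
        donor_iv = repeat.copy1 if donor == 1 else repeat.copy2
        up = repeat.flank(1 if recip == 1 else 3)
        donor_side = Interval(donor_iv.start, min(donor_iv.end + w, repeat.genome_length or donor_iv.end + w))
        best = 0
        for wa, wb in ((cluster.window1, cluster.window2), (cluster.window2, cluster.window1)):
            recip_window = Interval(up.start, min(up.end + recip_iv.length // 2 + 1, recip_iv.end))
            score = wa.overlap_len(recip_window) + wb.overlap_len(donor_side)
            if wa.overlap_len(donor_iv) > wa.overlap_len(recip_window):
                score = 0  # endpoint explained better by the donor side
            best = max(best, score)
        return best

    s1, s2 = hyp_score(1), hyp_score(2)
    if s1 == s2:
        return None
    return 1 if s1 > s2 else 2


def call_polarity(
    table: FlankChangeTable,
    cluster: JunctionCluster,
    repeat: RepeatPair,
    library: Optional[str] = None,
    depletion_threshold: float = CLASS_I_DEPLETION,
) -> PolarityCall:
    """Combine the flank-coverage signature with junction geometry.

    When parental depletion is present the depleted region's copy is the
    donor; without depletion (class II pattern) polarity is taken from the
    junction orientation alone.  Conflicting votes yield an indeterminate
    call carrying both votes.
    """
    lib = library or sorted(table.changes)[-1]
    dep_region, dep = table.min_change(lib)
    inc_region, inc = table.max_change(lib)
    coverage_vote: Optional[int] = None
    if np.isfinite(dep) and dep <= depletion_threshold:
        coverage_vote = 1 if dep_region in (1, 2) else 2
    junction_vote = _junction_polarity_vote(cluster, repeat)
    if coverage_vote is not None and junction_vote is not None and coverage_vote != junction_vote:
        return PolarityCall(
            repeat=table.repeat, donor=None, recipient=None,
            depleted_region=dep_region, increased_region=inc_region,
            confidence=0.0, fate_class="indeterminate",
            coverage_vote=coverage_vote, junction_vote=junction_vote,
        )
    donor = coverage_vote if coverage_vote is not None else junction_vote
    if donor is None:
        return PolarityCall(
            repeat=table.repeat, donor=None, recipient=None,
            depleted_region=dep_region, increased_region=inc_region,
            confidence=0.0, fate_class="indeterminate",
        )
    confidence = abs(dep) - abs(depletion_threshold) if coverage_vote else max(0.0, CLASS_II_BAND - abs(dep))
    return PolarityCall(
        repeat=table.repeat,
        donor=donor,
        recipient=2 if donor == 1 else 1,
        depleted_region=dep_region,
        increased_region=inc_region,
        confidence=float(confidence),
        coverage_vote=coverage_vote,
        junction_vote=junction_vote,
    )


def classify_fate(
    table: FlankChangeTable,
    junction_support: dict[str, float],
    gen1: str = "msh1_gen1",
    adv: str = "msh1_adv",
    depletion_threshold: float = CLASS_I_DEPLETION,
    retention_band: float = CLASS_II_BAND,
) -> str:
    """Class I: the depleted region's change decreases monotonically from
    first to advanced generation and passes the depletion threshold.
    Class II: normalized junction support grows across generations while
    the candidate depleted region stays inside the retention band."""
    if gen1 not in table.changes or adv not in table.changes:
        raise ValueError("both generations required for fate classification")
    dep_region, dep_adv = table.min_change(adv)
    dep_gen1 = table.changes[gen1][dep_region]
    if np.isfinite(dep_adv) and dep_adv <= depletion_threshold and dep_adv < dep_gen1:
        return "I"
    min_gen1 = table.min_change(gen1)[1]
    support_grows = junction_support.get(adv, 0.0) > junction_support.get(gen1, 0.0)
    if (
        support_grows
        and np.isfinite(dep_adv)
        and abs(dep_adv) <= retention_band
        and abs(min_gen1) <= retention_band
    ):
        return "II"
    return "indeterminate"


def generation_trend(
    tables: dict[str, FlankChangeTable],
    gains: dict[str, dict[str, float]],
    generations: Sequence[str] = ("msh1_gen1", "msh1_adv"),
):
    """Per-repeat paired series of recombinant gain (normalized junction
    support) and parental depleted-flank change, with the cross-repeat
    Pearson correlation in the final generation.

    ``gains``: repeat -> {generation: normalized junction support}.
    """
    import pandas as pd

    if len(generations) < 2:
        raise ValueError("need at least two generations")
    rows = []
    last = generations[-1]
    for name, table in tables.items():
        row = {"repeat": name}
        for gen in generations:
            if gen in table.changes:
                region, change = table.min_change(gen)
                row[f"parental_change_{gen}"] = change
            row[f"gain_{gen}"] = gains.get(name, {}).get(gen, float("nan"))
        rows.append(row)
    df = pd.DataFrame(rows)
    corr = float("nan")
    if len(df) >= 2:
        x = df[f"gain_{last}"]
        y = df[f"parental_change_{last}"]
        if x.notna().all() and y.notna().all() and x.std() > 0 and y.std() > 0:
            corr = float(np.corrcoef(x, y)[0, 1])
    return df, corr
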