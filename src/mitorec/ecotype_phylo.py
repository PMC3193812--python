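"""Cross-ecotype analysis: threshold SNP calling, NHEJ/REC/DEL structural
classification, substoichiometric labelling, TN93 + neighbor-joining
phylogeny with column bootstrap, and tree-based group assignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align_core import RepeatPair, assign_junction_to_repeat
from .formats_io import GenomeSeq, Interval
from .junction_detect import JunctionCluster

log = logging.getLogger(__name__)

SNP_MIN_DEPTH = 5  # "more than 5x coverage": strict
SNP_MIN_FRACTION = 0.8  # "more than 80% of the reads": strict
SUBSTOICHIOMETRIC_MAX = 0.05
PREDOMINANT_MIN = 0.5

_BASE_CHARS = "ACGT"


@dataclass(frozen=True)
class SnpCall:
    position: int  # 0-based reference coordinate
    ref_allele: str
    alt_allele: str
    depth: int
    allele_fraction: float


def call_snps(
    pileup: np.ndarray,
    ref_codes: np.ndarray,
    min_depth: int = SNP_MIN_DEPTH,
    min_fraction: float = SNP_MIN_FRACTION,
    mask: Optional[Sequence[Interval]] = None,
) -> list[SnpCall]:
    """Strict-threshold SNP calling from a (4, L) base-count pileup.

    A SNP is emitted only where depth > ``min_depth`` AND the alternate
    allele fraction > ``min_fraction`` (both strict).  Positions inside
    ``mask`` intervals (poorly aligned regions) are suppressed.
    """
    depth = pileup.sum(axis=0)
    L = pileup.shape[1]
    alt_counts = pileup.copy()
    valid_ref = ref_codes < 4
    alt_counts[ref_codes[valid_ref], np.flatnonzero(valid_ref)] = 0
    alt_idx = alt_counts.argmax(axis=0)
    alt_n = alt_counts.max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, alt_n / np.maximum(depth, 1), 0.0)
    keep = (depth > min_depth) & (frac > min_fraction) & (alt_n > 0) & valid_ref
    if mask:
        for iv in mask:
            keep[iv.start : iv.end] = False
    out = []
    for p in np.flatnonzero(keep):
        out.append(
            SnpCall(
                position=int(p),
                ref_allele=_BASE_CHARS[ref_codes[p]],
                alt_allele=_BASE_CHARS[alt_idx[p]],
                depth=int(depth[p]),
                allele_fraction=float(frac[p]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# structural variants
# ---------------------------------------------------------------------------

@dataclass
class StructuralVariantCall:
    ecotype: str
    kind: str  # NHEJ | REC | DEL
    breakpoint1: Interval
    breakpoint2: Optional[Interval]
    size: int
    repeat_name: str = ""
    support: int = 0
    stoichiometry: str = ""  # predominant | intermediate | substoichiometric
    support_fraction: float = float("nan")


def label_stoichiometry(
    support: int,
    median_depth: float,
    insert_mean: int = 220,
    read_length: int = 36,
) -> tuple[str, float]:
    """Label a junction's stoichiometry from its support relative to the
    expected junction-spanning pair count at median depth.

    Expected spanning pairs = fragment-start density * clear-window length
    = median_depth / (2 * read_length) * (insert_mean - 2 * read_length).
    """
    if median_depth <= 0:
        raise ValueError("zero median depth")
    expected = median_depth / (2 * read_length) * (insert_mean - 2 * read_length)
    fraction = support / expected
    if fraction < SUBSTOICHIOMETRIC_MAX:
        label = "substoichiometric"
    elif fraction >= PREDOMINANT_MIN:
        label = "predominant"
    else:
        label = "intermediate"
    return label, float(fraction)


def classify_svs(
    ecotype: str,
    clusters: Sequence[JunctionCluster],
    depth: np.ndarray,
    catalog: Sequence[RepeatPair],
    genome: GenomeSeq,
    median_depth: Optional[float] = None,
    insert_mean: int = 220,
    read_length: int = 36,
    near_zero: int = 1,
    min_flank_depth: int = 10,
    rec_breakpoint_pad: int = 20,
) -> list[StructuralVariantCall]:
    """Type junction clusters and coverage gaps for one ecotype.

    Repeat-assigned junctions -> REC; unassigned junctions -> NHEJ;
    coverage gaps not explained by a junction -> DEL, unless the gap's
    breakpoints coincide with a catalog pair's copies (REC without junction
    reads).  Gaps coinciding with a called junction's deleted span are
    treated as corroborating evidence, not separate calls.
    """
    med = float(np.median(depth)) if median_depth is None else median_depth
    calls: list[StructuralVariantCall] = []
    junction_spans: list[tuple[int, int]] = []
    for c in clusters:
        support = c.support_by_library.get(ecotype, c.support)
        if support <= 0:
            continue
        pair = assign_junction_to_repeat(genome, c.window1, c.window2, catalog)
        kind = "REC" if pair is not None else "NHEJ"
        size = genome.circular_distance(c.window1.end, c.window2.start)
        label, fraction = label_stoichiometry(support, med, insert_mean, read_length)
        calls.append(
            StructuralVariantCall(
                ecotype=ecotype, kind=kind, breakpoint1=c.window1,
                breakpoint2=c.window2, size=size,
                repeat_name=pair.name if pair else "", support=support,
                stoichiometry=label, support_fraction=fraction,
            )
        )
        junction_spans.append((c.window1.end, c.window2.start))

    # coverage gaps
    low = depth <= near_zero
    if low.any():
        runs = []
        in_run = False
        s = 0
        for i, v in enumerate(low):
            if v and not in_run:
                in_run, s = True, i
            elif not v and in_run:
                runs.append((s, i))
                in_run = False
        if in_run:
            runs.append((s, len(low)))
        for s, e in runs:
            if e - s < 2:
                continue
            # flanking depth is sampled one read-length away from the gap,
            # clear of the edge taper left by partially overhanging reads
            lf = depth[max(0, s - read_length - 30) : max(0, s - read_length)]
            rf = depth[e + read_length : e + read_length + 30]
            if len(lf) == 0 or len(rf) == 0:
                continue
            if np.median(lf) < min_flank_depth or np.median(rf) < min_flank_depth:
                continue
            if any(
                abs(s - js) <= 120 and abs(e - je) <= 120 for js, je in junction_spans
            ):
                continue  # evidence for an already-called junction
            rec_pair = None
            for pair in catalog:
                near1 = (
                    pair.copy1.start - rec_breakpoint_pad
                    <= s
                    <= pair.copy1.end + rec_breakpoint_pad
                )
                near2 = (
                    pair.copy2.start - rec_breakpoint_pad
                    <= e
                    <= pair.copy2.end + rec_breakpoint_pad
                )
                if near1 and near2:
                    rec_pair = pair
                    break
            if rec_pair is not None:
                calls.append(
                    StructuralVariantCall(
                        ecotype=ecotype, kind="REC",
                        breakpoint1=Interval(s, max(s + 1, e)), breakpoint2=None,
                        size=e - s, repeat_name=rec_pair.name,
                        stoichiometry="predominant", support=0,
                    )
                )
            else:
                calls.append(
                    StructuralVariantCall(
                        ecotype=ecotype, kind="DEL",
                        breakpoint1=Interval(s, max(s + 1, e)), breakpoint2=None,
                        size=e - s, stoichiometry="predominant", support=0,
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# SNP matrix, TN93, neighbor joining, bootstrap
# ---------------------------------------------------------------------------

MISSING = 255


@dataclass
class SnpMatrix:
    names: list[str]
    positions: np.ndarray  # reference positions of the columns
    data: np.ndarray  # (n_taxa, n_cols) uint8 base codes, 255 = missing


def build_snp_matrix(
    snps_by_ecotype: dict[str, list[SnpCall]],
    depth_by_ecotype: dict[str, np.ndarray],
    ref_codes: np.ndarray,
    min_depth: int = SNP_MIN_DEPTH,
) -> SnpMatrix:
    """Ecotypes x concatenated-SNP-position allele matrix.

    A cell is the called alternate allele, the reference allele when the
    position is adequately covered but not called, and missing otherwise.
    """
    names = sorted(snps_by_ecotype)
    positions = sorted({s.position for calls in snps_by_ecotype.values() for s in calls})
    pos_arr = np.array(positions, dtype=np.int64)
    n, m = len(names), len(positions)
    data = np.full((n, m), MISSING, dtype=np.uint8)
    col_of = {p: i for i, p in enumerate(positions)}
    for i, name in enumerate(names):
        depth = depth_by_ecotype[name]
        covered = depth[pos_arr] > min_depth
        data[i, covered] = ref_codes[pos_arr[covered]]
        for s in snps_by_ecotype[name]:
            data[i, col_of[s.position]] = _BASE_CHARS.index(s.alt_allele)
    return SnpMatrix(names=names, positions=pos_arr, data=data)


def exclude_columns(matrix: SnpMatrix, max_missing_fraction: float = 0.5) -> SnpMatrix:
    """Drop columns missing in more than half the ecotypes, then drop any
    column still containing a missing cell, so the concatenation is
    complete for every ecotype."""
    miss = (matrix.data == MISSING).mean(axis=0)
    keep = miss <= max_missing_fraction
    data = matrix.data[:, keep]
    positions = matrix.positions[keep]
    complete = ~(data == MISSING).any(axis=0)
    return SnpMatrix(names=matrix.names, positions=positions[complete],
                     data=data[:, complete])


_PURINE = {0, 2}  # A, G


def tn93_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Tamura-Nei 1993 distance between two gap-free coded sequences."""
    ok = (a < 4) & (b < 4)
    a, b = a[ok], b[ok]
    n = len(a)
    if n == 0:
        return 0.0
    pooled = np.concatenate([a, b])
    freqs = np.bincount(pooled, minlength=4) / (2 * n)
    gA, gC, gG, gT = (float(f) for f in freqs)
    gR, gY = gA + gG, gC + gT
    diff = a != b
    transitions_R = diff & np.isin(a, (0, 2)) & np.isin(b, (0, 2))
    transitions_Y = diff & np.isin(a, (1, 3)) & np.isin(b, (1, 3))
    p1 = float(transitions_R.sum()) / n
    p2 = float(transitions_Y.sum()) / n
    q = float(diff.sum()) / n - p1 - p2
    if p1 + p2 + q == 0:
        return 0.0
    eps = 1e-12
    k1 = 2 * gA * gG / gR if gR > eps else 0.0
    k2 = 2 * gC * gT / gY if gY > eps else 0.0
    k3 = 2 * (gR * gY - (gA * gG * gY / gR if gR > eps else 0.0)
              - (gC * gT * gR / gY if gY > eps else 0.0))
    cap = 10.0
    d = 0.0
    if k1 > eps:
        w = 1 - p1 / k1 - q / (2 * gR)
        if w <= eps:
            return cap
        d -= k1 * math.log(w)
    elif p1 > 0:
        return cap
    if k2 > eps:
        w = 1 - p2 / k2 - q / (2 * gY)
        if w <= eps:
            return cap
        d -= k2 * math.log(w)
    elif p2 > 0:
        return cap
    if k3 > eps:
        w = 1 - q / (2 * gR * gY)
        if w <= eps:
            return cap
        d -= k3 * math.log(w)
    return min(d, cap)


def distance_matrix(matrix: SnpMatrix) -> pd.DataFrame:
    n = len(matrix.names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = tn93_distance(matrix.data[i], matrix.data[j])
    return pd.DataFrame(D, index=matrix.names, columns=matrix.names)


def neighbor_joining(D: np.ndarray, names: Sequence[str]) -> str:
    """Neighbor-joining tree (newick, unrooted trifurcating root).

    Deterministic: taxa are processed in the given order and Q-matrix ties
    break toward the smallest index pair.
    """
    n = len(names)
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        d = max(D[0, 1], 0.0)
        return f"({names[0]}:{d / 2:.6f},{names[1]}:{d / 2:.6f});"
    D = D.astype(float).copy()
    labels = [f"{nm}" for nm in names]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        idx = int(np.argmin(Q))
        i, j = divmod(idx, m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_label = f"({labels[ai]}:{li:.6f},{labels[aj]}:{lj:.6f})"
        new_dist = 0.5 * (sub[i, :] + sub[j, :] - dij)
        # grow matrix with the new node
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        for t, at in enumerate(active):
            D[k, at] = D[at, k] = max(new_dist[t], 0.0)
        labels.append(new_label)
        active = [a for a in active if a not in (ai, aj)] + [k]
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return (
        f"({labels[a]}:{la:.6f},{labels[b]}:{lb:.6f},{labels[c]}:{lc:.6f});"
    )


def _bipartitions(tree, all_tips: frozenset[str]) -> dict[frozenset, object]:
    """Internal-edge bipartitions, canonicalized to the side not containing
    the alphabetically first tip."""
    anchor = min(all_tips)
    out = {}
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(all_tips) - 1:
            continue
        if anchor in side:
            side = all_tips - side
        out[side] = node
    return out


@dataclass
class PanelPhylogeny:
    matrix: SnpMatrix
    distances: pd.DataFrame
    newick: str
    tree: object  # skbio.TreeNode
    supports: dict[frozenset, float]
    n_bootstrap: int
    star: bool = False


def build_phylogeny(
    matrix: SnpMatrix,
    n_bootstrap: int = 100,
    seed: int = 0,
    max_missing_fraction: float = 0.5,
) -> PanelPhylogeny:
    """TN93 distances on the concatenated SNP columns, neighbor joining,
    and column-bootstrap supports on internal edges."""
    import skbio

    if len(matrix.names) < 3:
        raise ValueError("need at least three ecotypes")
    used = exclude_columns(matrix, max_missing_fraction)
    D = distance_matrix(used)
    star = bool((D.values == 0).all())
    if star:
        log.warning("all pairwise distances are zero: star tree")
    newick = neighbor_joining(D.values, used.names)
    tree = skbio.TreeNode.read([newick])
    all_tips = frozenset(used.names)
    main_bip = _bipartitions(tree, all_tips)
    counts = {bp: 0 for bp in main_bip}
    rng = np.random.default_rng(seed)
    ncol = used.data.shape[1]
    for _ in range(n_bootstrap):
        cols = rng.integers(0, ncol, ncol) if ncol else np.empty(0, np.int64)
        boot = SnpMatrix(
            names=used.names, positions=used.positions[cols], data=used.data[:, cols]
        )
        bD = distance_matrix(boot)
        btree = skbio.TreeNode.read([neighbor_joining(bD.values, boot.names)])
        bbip = set(_bipartitions(btree, all_tips))
        for bp in counts:
            if bp in bbip:
                counts[bp] += 1
    supports = {
        bp: 100.0 * c / n_bootstrap if n_bootstrap else float("nan")
        for bp, c in counts.items()
    }
    for bp, node in main_bip.items():
        node.name = f"{supports[bp]:.0f}"
    return PanelPhylogeny(
        matrix=used, distances=D, newick=str(tree).strip(), tree=tree,
        supports=supports, n_bootstrap=n_bootstrap, star=star,
    )


def assign_groups(tree, k: int = 6) -> dict[str, int]:
    """Cut the k-1 longest internal edges; connected components are groups.

    Ties break toward the better-balanced split, then the lexicographically
    smallest subtree leaf set.  Groups are numbered by their smallest leaf
    name.  Raises on k > leaf count or when the tree lacks enough internal
    edges (star tree).
    """
    tips = [t.name for t in tree.tips()]
    if k > len(tips):
        raise ValueError(f"k={k} exceeds {len(tips)} leaves")
    if k == 1:
        return {t: 0 for t in tips}
    internal = []
    total = len(tips)
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        sub = sorted(t.name for t in node.tips())
        balance = min(len(sub), total - len(sub))
        internal.append((-(node.length or 0.0), -balance, tuple(sub), node))
    internal.sort(key=lambda t: (t[0], t[1], t[2]))
    if len(internal) < k - 1:
        raise ValueError("not enough internal edges to form the requested groups")
    cut_nodes = {id(t[3]) for t in internal[: k - 1]}
    groups: dict[str, int] = {}
    comp_of_tip: dict[str, tuple] = {}
    for tip in tree.tips():
        node = tip
        key = ("root",)
        cur = tip
        while cur.parent is not None:
            if id(cur) in cut_nodes:
                key = ("node", id(cur))
                break
            cur = cur.parent
        comp_of_tip[tip.name] = key
    comps: dict[tuple, list[str]] = {}
    for name, key in comp_of_tip.items():
        comps.setdefault(key, []).append(name)
    ordered = sorted(comps.values(), key=lambda names: min(names))
    for gi, names in enumerate(ordered):
        for nm in names:
            groups[nm] = gi
    return groups


def concordance_report(
    carriers_by_sv: dict[str, set[str]], groups: dict[str, int]
) -> tuple[pd.DataFrame, float]:
    """Per-SV fraction of carriers inside a single group, and the panel
    concordance (fraction of SVs perfectly nested in one group)."""
    rows = []
    nested = 0
    for sv, carriers in sorted(carriers_by_sv.items()):
        if not carriers:
            continue
        counts: dict[int, int] = {}
        for c in carriers:
            counts[groups[c]] = counts.get(groups[c], 0) + 1
        best = max(counts.values())
        frac = best / len(carriers)
        if frac == 1.0:
            nested += 1
        rows.append(
            {
                "sv": sv,
                "n_carriers": len(carriers),
                "n_groups": len(counts),
                "max_group_fraction": frac,
                "nested": frac == 1.0,
            }
        )
    df = pd.DataFrame(rows)
    overall = nested / len(rows) if rows else float("nan")
    return df, overall
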