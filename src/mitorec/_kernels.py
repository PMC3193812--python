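"""Numba kernels: affine-gap alignment DP and the read-placement inner loop.

Scoring convention everywhere: match +1, mismatch -2, a gap of length g
costs 5 + 2*(g-1).  Sequences are uint8 arrays with A,C,G,T -> 0..3 and
N -> 4 (N never matches anything, including N).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**7)

MATCH = 1
MISMATCH = -2
GAP_OPEN = -5  # cost of the first gap column
GAP_EXT = -2  # each additional gap column

# traceback op codes (emitted in alignment order by the python wrappers)
OP_DIAG = 0  # consume one char of each sequence
OP_GAP_B = 1  # consume a only (gap in b)
OP_GAP_A = 2  # consume b only (gap in a)


@njit(cache=True)
def _subst(x, y):
    if x >= 4 or y >= 4:
        return MISMATCH
    return MATCH if x == y else MISMATCH


@njit(cache=True)
def sw_local(a, b):
    """Optimal local (Smith-Waterman/Gotoh) alignment of a vs b.

    Returns (score, a_start, a_end, b_start, b_end, ops, n_ops) with ops in
    REVERSED order (end to start).
    """
    la, lb = len(a), len(b)
    H = np.zeros((la + 1, lb + 1), np.int32)
    E = np.full((la + 1, lb + 1), NEG, np.int32)  # gap in a (consumes b)
    F = np.full((la + 1, lb + 1), NEG, np.int32)  # gap in b (consumes a)
    ptrH = np.zeros((la + 1, lb + 1), np.uint8)  # 0 stop, 1 diag, 2 fromE, 3 fromF
    ptrE = np.zeros((la + 1, lb + 1), np.uint8)  # 1 open (from H), 0 extend
    ptrF = np.zeros((la + 1, lb + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            eo = H[i, j - 1] + GAP_OPEN
            ee = E[i, j - 1] + GAP_EXT
            if eo >= ee:
                E[i, j] = eo
                ptrE[i, j] = 1
            else:
                E[i, j] = ee
                ptrE[i, j] = 0
            fo = H[i - 1, j] + GAP_OPEN
            fe = F[i - 1, j] + GAP_EXT
            if fo >= fe:
                F[i, j] = fo
                ptrF[i, j] = 1
            else:
                F[i, j] = fe
                ptrF[i, j] = 0
            d = H[i - 1, j - 1] + _subst(a[i - 1], b[j - 1])
            h = 0
            p = 0
            if d > h:
                h = d
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    ops = np.empty(la + lb, np.uint8)
    n_ops = 0
    i, j = bi, bj
    state = 0  # 0 in H, 1 in E, 2 in F
    while i > 0 or j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                ops[n_ops] = OP_DIAG
                n_ops += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[n_ops] = OP_GAP_A
            n_ops += 1
            opened = ptrE[i, j]
            j -= 1
            if opened == 1:
                state = 0
        else:
            ops[n_ops] = OP_GAP_B
            n_ops += 1
            opened = ptrF[i, j]
            i -= 1
            if opened == 1:
                state = 0
    return best, i, bi, j, bj, ops, n_ops


@njit(cache=True)
def nw_global(a, b):
    """Global (Needleman-Wunsch/Gotoh) alignment; returns (score, ops, n_ops).

    ops are in REVERSED order.
    """
    la, lb = len(a), len(b)
    H = np.full((la + 1, lb + 1), NEG, np.int32)
    E = np.full((la + 1, lb + 1), NEG, np.int32)
    F = np.full((la + 1, lb + 1), NEG, np.int32)
    ptrH = np.zeros((la + 1, lb + 1), np.uint8)
    ptrE = np.zeros((la + 1, lb + 1), np.uint8)
    ptrF = np.zeros((la + 1, lb + 1), np.uint8)
    H[0, 0] = 0
    for j in range(1, lb + 1):
        E[0, j] = GAP_OPEN + GAP_EXT * (j - 1)
        H[0, j] = E[0, j]
        ptrH[0, j] = 2
        ptrE[0, j] = 1 if j == 1 else 0
    for i in range(1, la + 1):
        F[i, 0] = GAP_OPEN + GAP_EXT * (i - 1)
        H[i, 0] = F[i, 0]
        ptrH[i, 0] = 3
        ptrF[i, 0] = 1 if i == 1 else 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            eo = H[i, j - 1] + GAP_OPEN
            ee = E[i, j - 1] + GAP_EXT
            if eo >= ee:
                E[i, j] = eo
                ptrE[i, j] = 1
            else:
                E[i, j] = ee
                ptrE[i, j] = 0
            fo = H[i - 1, j] + GAP_OPEN
            fe = F[i - 1, j] + GAP_EXT
            if fo >= fe:
                F[i, j] = fo
                ptrF[i, j] = 1
            else:
                F[i, j] = fe
                ptrF[i, j] = 0
            d = H[i - 1, j - 1] + _subst(a[i - 1], b[j - 1])
            h = d
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
    ops = np.empty(la + lb, np.uint8)
    n_ops = 0
    i, j = la, lb
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 1:
                ops[n_ops] = OP_DIAG
                n_ops += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[n_ops] = OP_GAP_A
            n_ops += 1
            opened = ptrE[i, j]
            j -= 1
            if opened == 1:
                state = 0
        else:
            ops[n_ops] = OP_GAP_B
            n_ops += 1
            opened = ptrF[i, j]
            i -= 1
            if opened == 1:
                state = 0
    return H[la, lb], ops, n_ops


@njit(cache=True)
def place_ends(
    genome_pad,
    L,
    reads_fwd,
    reads_rev,
    sorted_codes,
    sorted_pos,
    k,
    max_mm,
    max_best,
):
    """Place each read on the circular genome by exact-seed + mismatch check.

    Seeds are the two k-mers at offsets 0 and k on both strands.  Candidate
    start positions are verified over the full read length against the
    wrap-padded genome; the best (fewest-mismatch) placements are kept, up
    to ``max_best`` ties.

    Returns (best_mm, n_best, pos, strand):
      best_mm  int16[n]  mismatches of the best placement (255 = none found)
      n_best   int32[n]  number of equally good placements (may exceed max_best)
      pos      int64[n, max_best]
      strand   int8[n, max_best]  0 = forward, 1 = reverse
    """
    n, rl = reads_fwd.shape
    best_mm = np.full(n, 255, np.int16)
    n_best = np.zeros(n, np.int32)
    pos = np.full((n, max_best), -1, np.int64)
    strand = np.zeros((n, max_best), np.int8)
    cand = np.empty(256, np.int64)
    cand_strand = np.empty(256, np.int8)
    n_codes = len(sorted_codes)
    for r in range(n):
        ncand = 0
        for s in range(2):
            read = reads_fwd[r] if s == 0 else reads_rev[r]
            for off in range(0, 2 * k, k):
                code = np.uint64(0)
                valid = True
                for j in range(k):
                    base = read[off + j]
                    if base >= 4:
                        valid = False
                        break
                    code = (code << np.uint64(2)) | np.uint64(base)
                if not valid:
                    continue
                lo = np.searchsorted(sorted_codes, code, side="left")
                hi = np.searchsorted(sorted_codes, code, side="right")
                for t in range(lo, hi):
                    start = sorted_pos[t] - off
                    if start < 0:
                        start += L
                    dup = False
                    for c in range(ncand):
                        if cand[c] == start and cand_strand[c] == s:
                            dup = True
                            break
                    if not dup and ncand < 256:
                        cand[ncand] = start
                        cand_strand[ncand] = s
                        ncand += 1
        for c in range(ncand):
            p = cand[c]
            read = reads_fwd[r] if cand_strand[c] == 0 else reads_rev[r]
            mm = 0
            limit = best_mm[r] if best_mm[r] < max_mm else max_mm
            for j in range(rl):
                x = read[j]
                y = genome_pad[p + j]
                if x != y or x >= 4:
                    mm += 1
                    if mm > limit:
                        break
            if mm > max_mm:
                continue
            if mm < best_mm[r]:
                best_mm[r] = mm
                n_best[r] = 1
                pos[r, 0] = p
                strand[r, 0] = cand_strand[c]
            elif mm == best_mm[r]:
                if n_best[r] < max_best:
                    pos[r, n_best[r]] = p
                    strand[r, n_best[r]] = cand_strand[c]
                n_best[r] += 1
    return best_mm, n_best, pos, strand


@njit(cache=True)
def _circ_dist(a, b, L):
    d = a - b
    if d < 0:
        d = -d
    d = d % L
    if L - d < d:
        d = L - d
    return d


@njit(cache=True)
def resolve_pairs(
    best_mm1,
    n_best1,
    pos1,
    strand1,
    best_mm2,
    n_best2,
    pos2,
    strand2,
    L,
    rl,
    max_mm,
    band_lo,
    band_hi,
    disc_dist,
    max_best,
):
    """Join per-end placements into classified pair placements.

    Status codes: 0 concordant, 1 discordant(distance), 2
    discordant(orientation), 3 odd-insert, 4 ambiguous, 5 unmapped.
    An end with several equally good loci is rescued through its unique
    mate by choosing the candidate minimising the circular end distance.
    """
    n = len(best_mm1)
    status = np.full(n, 5, np.int8)
    out_p1 = np.full(n, -1, np.int64)
    out_p2 = np.full(n, -1, np.int64)
    out_s1 = np.zeros(n, np.int8)
    out_s2 = np.zeros(n, np.int8)
    out_dist = np.full(n, -1, np.int64)
    rescued = np.zeros(n, np.int8)
    for r in range(n):
        ok1 = best_mm1[r] <= max_mm and n_best1[r] >= 1
        ok2 = best_mm2[r] <= max_mm and n_best2[r] >= 1
        if not ok1 or not ok2:
            status[r] = 5
            continue
        u1 = n_best1[r] == 1
        u2 = n_best2[r] == 1
        if not u1 and not u2:
            status[r] = 4
            continue
        if u1 and u2:
            p1, s1 = pos1[r, 0], strand1[r, 0]
            p2, s2 = pos2[r, 0], strand2[r, 0]
        elif u1:
            p1, s1 = pos1[r, 0], strand1[r, 0]
            m = min(n_best2[r], max_best)
            bi = 0
            bd = _circ_dist(p1, pos2[r, 0], L)
            for c in range(1, m):
                d = _circ_dist(p1, pos2[r, c], L)
                if d < bd or (d == bd and pos2[r, c] < pos2[r, bi]):
                    bd = d
                    bi = c
            p2, s2 = pos2[r, bi], strand2[r, bi]
            rescued[r] = 2
        else:
            p2, s2 = pos2[r, 0], strand2[r, 0]
            m = min(n_best1[r], max_best)
            bi = 0
            bd = _circ_dist(p2, pos1[r, 0], L)
            for c in range(1, m):
                d = _circ_dist(p2, pos1[r, c], L)
                if d < bd or (d == bd and pos1[r, c] < pos1[r, bi]):
                    bd = d
                    bi = c
            p1, s1 = pos1[r, bi], strand1[r, bi]
            rescued[r] = 1
        out_p1[r] = p1
        out_p2[r] = p2
        out_s1[r] = s1
        out_s2[r] = s2
        dist = _circ_dist(p1, p2, L)
        out_dist[r] = dist
        if dist > disc_dist:
            status[r] = 1
            continue
        if s1 == s2:
            status[r] = 2
            continue
        # proper orientation: the forward read sits upstream of the reverse
        # read along the short arc
        if s1 == 0:
            fwd_to_rev = (p2 - p1) % L
        else:
            fwd_to_rev = (p1 - p2) % L
        if fwd_to_rev != dist:
            status[r] = 2
            continue
        span = dist + rl
        if band_lo <= span <= band_hi:
            status[r] = 0
        else:
            status[r] = 3
    return status, out_p1, out_s1, out_p2, out_s2, out_dist, rescued


@njit(cache=True)
def accumulate_pileup(counts, starts, strands, reads_fwd, reads_rev, L):
    """Add read bases into a (4, L) base-count matrix, wrapping circularly."""
    n, rl = reads_fwd.shape
    for r in range(n):
        read = reads_fwd[r] if strands[r] == 0 else reads_rev[r]
        p = starts[r]
        for j in range(rl):
            base = read[j]
            if base < 4:
                q = p + j
                if q >= L:
                    q -= L
                counts[base, q] += 1
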