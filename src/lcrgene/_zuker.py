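"""Dynamic-programming kernel for DNA minimum-free-energy folding.

Implements the classic Zuker recursions (paired matrix V, multibranch helper
WM, external contour W) over a single strand, or over the concatenation of two
strands separated by a nick for co-folding.  Energies are free energies at the
evaluation temperature, precomputed by the caller.

Co-fold conventions (must match ``thermo.score_structure`` and the test
oracle):

* a loop is "nicked" when one of its backbone bonds is the strand junction;
* nicked hairpin/bulge/internal loops cost nothing and are exempt from the
  minimum hairpin size and the loop-size cap (they are exterior-like);
* multibranch loops keep the standard linear penalty, nicked or not;
* the bimolecular initiation term is *not* part of the DP energies — the
  kernel returns the best spanning (inter-strand) and non-spanning scores
  separately and the caller adds initiation to the spanning one.

Decision matrices are filled alongside the energies so the traceback is a
cheap table walk.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1.0e30

# V decision codes
V_HAIRPIN = 0
V_INTERIOR = 1  # stack / bulge / internal, interior pair recorded
V_MULTI = 2  # multibranch, split point recorded
V_NICK_FREE = 3  # zero-penalty nicked loop; interior pair recorded

# WM decision codes
WM_TRIM_I = 0
WM_TRIM_J = 1
WM_BRANCH = 2
WM_SPLIT = 3


@njit(cache=False)
def fill(seq, nick, can_pair, g_stack, g_hairpin, g_bulge, g_internal,
         g_mla, g_mlb, cap):
    """Fill V/WM and external arrays; return matrices and summary energies.

    Returns (V, Vt, Vk, Vl, WM, WMt, WMk, wpref, sbsuf,
             intra_best, span_best, span_p, span_q).

    ``wpref[t]`` is the best external score of prefix 0..t (restarting at the
    nick for the second strand); ``sbsuf[q]`` the best external score of the
    suffix q..n-1 of strand b (co-fold only).  ``intra_best`` is the best
    score with no inter-strand pair; ``span_best`` the best score containing
    at least one spanning pair, initiation not included.
    """
    n = seq.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    Vt = np.zeros((n, n), np.int8)
    Vk = np.full((n, n), -1, np.int32)
    Vl = np.full((n, n), -1, np.int32)
    WMt = np.zeros((n, n), np.int8)
    WMk = np.full((n, n), -1, np.int32)

    # nick-exempt bookkeeping: best V over pairs wholly inside strand b with
    # right end <= j (pbr), and wholly inside strand a with left end >= i (pbl)
    colmin_b = np.full(n, INF)  # min over k>=nick of V[k, l]
    rowmin_a = np.full(n, INF)  # min over l<nick of V[k, l]
    pbr = np.full(n + 1, INF)
    pbl = np.full(n + 1, INF)

    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            si = seq[i]
            sj = seq[j]
            # ---- V ----
            if can_pair[si, sj]:
                best = INF
                bt = np.int8(0)
                bk = -1
                bl = -1
                spanning = nick >= 0 and i < nick and nick <= j
                # hairpin
                if spanning:
                    best = 0.0
                    bt = V_HAIRPIN
                else:
                    size = j - i - 1
                    if size >= 3:
                        best = g_hairpin[size]
                        bt = V_HAIRPIN
                # nick-exempt interior pair (one gap holds the nick)
                if spanning:
                    cand = pbr[j - 1] if j - 1 >= nick else INF
                    if cand < best:
                        best = cand
                        bt = V_NICK_FREE
                    cand = pbl[i + 1] if i + 1 < nick else INF
                    if cand < best:
                        best = cand
                        bt = V_NICK_FREE
                # stack / bulge / internal (nick-free loops only)
                kmax = min(i + cap + 1, j - 1)
                for k in range(i + 1, kmax + 1):
                    l1 = k - i - 1
                    if nick >= 0 and i < nick and nick <= k:
                        continue  # nicked left gap: covered by pbr/pbl
                    lmin = max(k + 1, j - 1 - (cap - l1))
                    for l in range(j - 1, lmin - 1, -1):
                        if not can_pair[seq[k], seq[l]]:
                            continue
                        if nick >= 0 and l < nick and nick <= j:
                            continue  # nicked right gap
                        l2 = j - l - 1
                        v = V[k, l]
                        if v >= INF:
                            continue
                        if l1 == 0 and l2 == 0:
                            cand = g_stack[si, seq[i + 1]] + v
                        elif l1 == 0 or l2 == 0:
                            cand = g_bulge[l1 + l2] + v
                        else:
                            cand = g_internal[l1 + l2] + v
                        if cand < best:
                            best = cand
                            bt = V_INTERIOR
                            bk = k
                            bl = l
                # multibranch
                if d >= 2:
                    for k in range(i + 1, j - 1):
                        a = WM[i + 1, k]
                        if a >= INF:
                            continue
                        b = WM[k + 1, j - 1]
                        if b >= INF:
                            continue
                        cand = g_mla + g_mlb + a + b
                        if cand < best:
                            best = cand
                            bt = V_MULTI
                            bk = k
                V[i, j] = best
                Vt[i, j] = bt
                Vk[i, j] = bk
                Vl[i, j] = bl
            # ---- WM ----
            best = WM[i + 1, j] if i + 1 <= j else INF
            bt = np.int8(WM_TRIM_I)
            bk = -1
            cand = WM[i, j - 1] if j - 1 >= i else INF
            if cand < best:
                best = cand
                bt = WM_TRIM_J
            cand = V[i, j] + g_mlb if V[i, j] < INF else INF
            if cand < best:
                best = cand
                bt = WM_BRANCH
            for k in range(i + 1, j):
                a = WM[i, k]
                if a >= INF:
                    continue
                b = WM[k + 1, j]
                if b >= INF:
                    continue
                cand = a + b
                if cand < best:
                    best = cand
                    bt = WM_SPLIT
                    bk = k
            WM[i, j] = best
            WMt[i, j] = bt
            WMk[i, j] = bk
        # refresh nick-exempt rectangles with this diagonal's pairs
        if nick >= 0:
            for i in range(0, n - d):
                j = i + d
                v = V[i, j]
                if v < INF:
                    if i >= nick and v < colmin_b[j]:
                        colmin_b[j] = v
                    if j < nick and v < rowmin_a[i]:
                        rowmin_a[i] = v
            acc = INF
            for j in range(nick, n):
                if colmin_b[j] < acc:
                    acc = colmin_b[j]
                pbr[j] = acc
            acc = INF
            for i in range(nick - 1, -1, -1):
                if rowmin_a[i] < acc:
                    acc = rowmin_a[i]
                pbl[i] = acc

    # ---- external contours ----
    wpref = np.zeros(n)
    start = 0
    for t in range(n):
        if nick >= 0 and t == nick:
            start = nick
        prev = wpref[t - 1] if t - 1 >= start else 0.0
        best = prev
        for s in range(start, t + 1):
            v = V[s, t]
            if v >= INF:
                continue
            base = wpref[s - 1] if s - 1 >= start else 0.0
            cand = base + v
            if cand < best:
                best = cand
        wpref[t] = best

    sbsuf = np.zeros(n + 1)
    span_best = INF
    span_p = -1
    span_q = -1
    intra_best = 0.0
    if nick >= 0:
        for q in range(n - 1, nick - 1, -1):
            best = sbsuf[q + 1]
            for t in range(q, n):
                v = V[q, t]
                if v >= INF:
                    continue
                cand = v + sbsuf[t + 1]
                if cand < best:
                    best = cand
            sbsuf[q] = best
        for p in range(0, nick):
            base = wpref[p - 1] if p >= 1 else 0.0
            for q in range(nick, n):
                v = V[p, q]
                if v >= INF:
                    continue
                cand = base + v + sbsuf[q + 1]
                if cand < span_best:
                    span_best = cand
                    span_p = p
                    span_q = q
        intra_best = wpref[nick - 1] + wpref[n - 1]
    else:
        intra_best = wpref[n - 1]

    return (V, Vt, Vk, Vl, WM, WMt, WMk, wpref, sbsuf,
            intra_best, span_best, span_p, span_q)
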