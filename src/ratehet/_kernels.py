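"""Numba kernels for the Wright-Fisher forward simulator.

Haplotypes are stored column-per-mutation. Neutral columns are
bit-packed into uint64 words (bit c of a row = column c); selected
columns, which are needed every generation for fitness, are a dense
uint8 matrix. Mutations younger than the last purge live in a sparse
"newborn" store as per-column carrier lists.

Crossover breakpoints use the convention that a breakpoint value b
switches the source haplotype starting at the first site with
position >= b; a site p therefore descends from the starting haplotype
flipped once per breakpoint <= p.
"""

import numba
import numpy as np
from numba import njit

_U1 = np.uint64(1)
_FULL = np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _copy_bits(src, dst, c0, c1):
    """Copy bit range [c0, c1) from src row to dst row (uint64 words)."""
    if c1 <= c0:
        return
    w0 = c0 >> 6
    b0 = c0 & 63
    w1 = (c1 - 1) >> 6
    b1 = ((c1 - 1) & 63) + 1  # 1..64, end bit in last word
    if w0 == w1:
        if b1 - b0 == 64:
            dst[w0] = src[w0]
        else:
            mask = ((_U1 << np.uint64(b1 - b0)) - _U1) << np.uint64(b0)
            dst[w0] = (dst[w0] & ~mask) | (src[w0] & mask)
        return
    if b0 == 0:
        dst[w0] = src[w0]
    else:
        mask = _FULL << np.uint64(b0)
        dst[w0] = (dst[w0] & ~mask) | (src[w0] & mask)
    dst[w0 + 1:w1] = src[w0 + 1:w1]
    if b1 == 64:
        dst[w1] = src[w1]
    else:
        mask = (_U1 << np.uint64(b1)) - _U1
        dst[w1] = (dst[w1] & ~mask) | (src[w1] & mask)


@njit(cache=True)
def recombine(par_packed, child_packed, n_pos, Sn,
              par_sel, child_sel, s_pos, Ss,
              parent_idx, xflat, xoff, start_hap, n_gam):
    """Build child haplotype rows by meiosis from sampled parents.

    Sorts each gamete's breakpoints in place (xflat) so later kernels
    can reuse them.
    """
    for g in range(n_gam):
        p = parent_idx[g]
        lo = xoff[g]
        hi = xoff[g + 1]
        for i in range(lo + 1, hi):  # insertion sort, few breakpoints
            key = xflat[i]
            j = i - 1
            while j >= lo and xflat[j] > key:
                xflat[j + 1] = xflat[j]
                j -= 1
            xflat[j + 1] = key
        if Sn > 0:
            src = 2 * p + start_hap[g]
            oth = 2 * p + (1 - start_hap[g])
            c0 = 0
            for t in range(lo, hi + 1):
                if t < hi:
                    c1 = np.searchsorted(n_pos[:Sn], xflat[t])
                else:
                    c1 = Sn
                if c1 > c0:
                    _copy_bits(par_packed[src], child_packed[g], c0, c1)
                c0 = c1
                tmp = src
                src = oth
                oth = tmp
        if Ss > 0:
            src = 2 * p + start_hap[g]
            oth = 2 * p + (1 - start_hap[g])
            c0 = 0
            for t in range(lo, hi + 1):
                if t < hi:
                    c1 = np.searchsorted(s_pos[:Ss], xflat[t])
                else:
                    c1 = Ss
                for c in range(c0, c1):
                    child_sel[g, c] = par_sel[src, c]
                c0 = c1
                tmp = src
                src = oth
                oth = tmp


@njit(cache=True)
def fitness_selected(sel, n_ind, Ss, lhet, lhom, logw):
    """Multiplicative log-fitness over the dense selected store."""
    for i in range(n_ind):
        a = sel[2 * i]
        b = sel[2 * i + 1]
        acc = 0.0
        for c in range(Ss):
            gsum = a[c] + b[c]
            if gsum == 1:
                acc += lhet[c]
            elif gsum == 2:
                acc += lhom[c]
        logw[i] = acc


@njit(cache=True)
def fitness_newborn(car_off, car_hap, lhet, lhom, nb_n, stamp, logw):
    """Add newborn-mutation fitness contributions.

    ``stamp`` (length = number of individuals, filled with -1 by the
    caller) detects the second haplotype of a homozygous carrier;
    carrier entries must be grouped by column.
    """
    for c in range(nb_n):
        lh = lhet[c]
        lH = lhom[c]
        if lh == 0.0 and lH == 0.0:
            continue
        for e in range(car_off[c], car_off[c + 1]):
            i = car_hap[e] >> 1
            if stamp[i] == c:
                logw[i] += lH - 2.0 * lh
            else:
                stamp[i] = c
                logw[i] += lh


@njit(cache=True)
def transmit_newborns(nb_pos, nb_n, car_off, car_hap,
                      parent_idx, n_gam, n_par_ind,
                      xflat, xoff, start_hap,
                      new_off, new_hap, cap, cnt, order):
    """Propagate newborn-column carriers from parents to children.

    Returns the number of new carrier entries, or -1 if ``cap`` was
    exceeded (the caller grows the buffer and reruns; no state is
    modified). Requires xflat sorted per gamete (done by recombine);
    ``cnt`` (n_par_ind + 2) and ``order`` (n_gam) are scratch buffers.
    """
    cnt[:n_par_ind + 2] = 0
    for g in range(n_gam):
        cnt[parent_idx[g] + 2] += 1
    for i in range(n_par_ind):
        cnt[i + 2] += cnt[i + 1]
    # cnt[i+1] is now the bucket start for parent i; fill advances it
    for g in range(n_gam):
        p = parent_idx[g]
        order[cnt[p + 1]] = g
        cnt[p + 1] += 1
    # after filling, cnt[i] .. cnt[i+1] spans parent i's children
    m = 0
    new_off[0] = 0
    for c in range(nb_n):
        pcol = nb_pos[c]
        for e in range(car_off[c], car_off[c + 1]):
            h = car_hap[e]
            ind = h >> 1
            w = h & 1
            for gi in range(cnt[ind], cnt[ind + 1]):  # noqa: bucket span
                g = order[gi]
                k = 0
                for t in range(xoff[g], xoff[g + 1]):
                    if xflat[t] <= pcol:
                        k += 1
                    else:
                        break
                if ((start_hap[g] + k) & 1) == w:
                    if m >= cap:
                        return -1
                    new_hap[m] = g
                    m += 1
        new_off[c + 1] = m
    return m


@njit(cache=True)
def accept_new_sites(cand, occupied, sites, filled):
    """Accept candidate mutation sites that are currently unoccupied
    (infinite sites at finite positions); returns the new fill count."""
    for i in range(len(cand)):
        c = cand[i]
        if occupied[c] == 0:
            occupied[c] = 1
            sites[filled] = c
            filled += 1
    return filled


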