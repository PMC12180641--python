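"""Numba-compiled inner loops: Metropolis copy attempts and lattice scans.

All functions operate on flat per-label arrays (indexed by lattice label) and
a 6x6 contact-energy matrix indexed by type code.  The copy-attempt kernel
uses numba's internal PRNG; seed it with :func:`seed_kernel` once per run.

Conventions (fixed for the whole package):
  * 2nd-order Moore neighbourhood (8 neighbours) for proposals and contacts;
  * x wraps periodically, y is a fixed boundary (missing neighbours are
    simply absent — they carry no contact energy and attract no proposals);
  * label 0 = medium, label 1 = frozen basal membrane, labels >= 2 = cells;
  * a cell's surface is its count of heterotypic pixel faces.
"""

import numpy as np
from numba import njit

# (dy, dx) Moore offsets; duplicated from constants to keep the kernel
# self-contained for numba.
_OFFS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)

MEDIUM_LABEL = 0
BM_LABEL = 1
FIRST_CELL_LABEL = 2


@njit(cache=True)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def copy_delta(labels, ctype, va, vt, sa, st, lamv, lams, jmat, ty, tx, s, t):
    """Energy change of overwriting pixel (ty, tx) holding label ``t`` with
    label ``s``, plus the surface changes of the two affected cells.

    Returns (dE, dS_s, dS_t).  ``jmat`` must already include the adhesion
    weight lambda_A.
    """
    h, w = labels.shape
    n_s = 0
    n_t = 0
    k_valid = 0
    d_adh = 0.0
    ts = ctype[s]
    tt = ctype[t]
    for k in range(8):
        ny = ty + _OFFS[k, 0]
        if ny < 0 or ny >= h:
            continue
        nx = (tx + _OFFS[k, 1]) % w
        l = labels[ny, nx]
        k_valid += 1
        if l == s:
            n_s += 1
        if l == t:
            n_t += 1
        tl = ctype[l]
        if l != s:
            d_adh += jmat[ts, tl]
        if l != t:
            d_adh -= jmat[tt, tl]
    d_e = d_adh
    d_s_s = k_valid - 2 * n_s
    d_s_t = 2 * n_t - k_valid
    if s >= FIRST_CELL_LABEL:
        dv1 = va[s] + 1.0 - vt[s]
        dv0 = va[s] - vt[s]
        d_e += lamv[ts] * (dv1 * dv1 - dv0 * dv0)
        ds1 = sa[s] + d_s_s - st[s]
        ds0 = sa[s] - st[s]
        d_e += lams[ts] * (ds1 * ds1 - ds0 * ds0)
    if t >= FIRST_CELL_LABEL:
        dv1 = va[t] - 1.0 - vt[t]
        dv0 = va[t] - vt[t]
        d_e += lamv[tt] * (dv1 * dv1 - dv0 * dv0)
        ds1 = sa[t] + d_s_t - st[t]
        ds0 = sa[t] - st[t]
        d_e += lams[tt] * (ds1 * ds1 - ds0 * ds0)
    return d_e, d_s_s, d_s_t


@njit(cache=True)
def run_attempts(labels, ctype, va, vt, sa, st, lamv, lams, jmat, temp, n_attempts):
    """Perform ``n_attempts`` Metropolis copy attempts in place.

    Each attempt picks a uniform source pixel and a uniform Moore neighbour
    as target, proposes overwriting the target with the source label, and
    accepts with probability min(1, exp(-dE/T)).  Proposals into or out of
    the frozen BM region, degenerate proposals (same label) and proposals
    whose target falls outside the fixed y boundary are consumed as
    rejections.  Returns the number of accepted copies.
    """
    h, w = labels.shape
    accepted = 0
    for _ in range(n_attempts):
        x = int(np.random.random() * w)
        y = int(np.random.random() * h)
        k = int(np.random.random() * 8)
        ty = y + _OFFS[k, 0]
        if ty < 0 or ty >= h:
            continue
        tx = (x + _OFFS[k, 1]) % w
        s = labels[y, x]
        t = labels[ty, tx]
        if s == t or s == BM_LABEL or t == BM_LABEL:
            continue
        d_e, d_s_s, d_s_t = copy_delta(
            labels, ctype, va, vt, sa, st, lamv, lams, jmat, ty, tx, s, t
        )
        if d_e <= 0.0 or np.random.random() < np.exp(-d_e / temp):
            labels[ty, tx] = s
            if s >= FIRST_CELL_LABEL:
                va[s] += 1
                sa[s] += d_s_s
            if t >= FIRST_CELL_LABEL:
                va[t] -= 1
                sa[t] += d_s_t
            accepted += 1
    return accepted


@njit(cache=True)
def scan_geometry(labels, va_out, sa_out, touch_m, touch_b, med_faces):
    """Recompute per-label pixel counts, surfaces, contact flags and the
    number of faces each cell presents to the medium."""
    h, w = labels.shape
    va_out[:] = 0
    sa_out[:] = 0
    touch_m[:] = False
    touch_b[:] = False
    med_faces[:] = 0
    for y in range(h):
        for x in range(w):
            lab = labels[y, x]
            if lab < FIRST_CELL_LABEL:
                continue
            va_out[lab] += 1
            for k in range(8):
                ny = y + _OFFS[k, 0]
                if ny < 0 or ny >= h:
                    continue
                nx = (x + _OFFS[k, 1]) % w
                l = labels[ny, nx]
                if l != lab:
                    sa_out[lab] += 1
                    if l == MEDIUM_LABEL:
                        touch_m[lab] = True
                        med_faces[lab] += 1
                    elif l == BM_LABEL:
                        touch_b[lab] = True


@njit(cache=True)
def adhesion_total(labels, ctype, jmat):
    """Total contact energy over unordered heterolabel neighbour pairs.

    ``jmat`` here is the raw J matrix (without lambda_A)."""
    h, w = labels.shape
    total = 0.0
    # the 4 forward offsets enumerate each unordered Moore pair once
    for k in range(4):
        dy = _OFFS[k + 4, 0]
        dx = _OFFS[k + 4, 1]
        for y in range(h):
            ny = y + dy
            if ny < 0 or ny >= h:
                continue
            for x in range(w):
                nx = (x + dx) % w
                a = labels[y, x]
                b = labels[ny, nx]
                if a != b:
                    total += jmat[ctype[a], ctype[b]]
    return total


@njit(cache=True)
def column_modes(labels, starts, width, y0):
    """Per-row majority label inside each sampling window.

    For every window (given by its start x and pixel ``width``, wrapping in
    x) and every row from ``y0`` upward, find the most frequent label among
    the window's pixels.  Ties prefer cell labels over medium, then the
    larger label.  Returns an (n_windows, h - y0) int64 array.
    """
    h, w = labels.shape
    nwin = starts.shape[0]
    out = np.empty((nwin, h - y0), dtype=np.int64)
    vals = np.empty(width, dtype=np.int64)
    for i in range(nwin):
        x0 = starts[i]
        for y in range(y0, h):
            for j in range(width):
                vals[j] = labels[y, (x0 + j) % w]
            best = -1
            best_n = -1
            for j in range(width):
                v = vals[j]
                n = 0
                for j2 in range(width):
                    if vals[j2] == v:
                        n += 1
                better = False
                if n > best_n:
                    better = True
                elif n == best_n:
                    # prefer cells over medium/BM, then larger label
                    if (v >= FIRST_CELL_LABEL) and (best < FIRST_CELL_LABEL):
                        better = True
                    elif ((v >= FIRST_CELL_LABEL) == (best >= FIRST_CELL_LABEL)) and v > best:
                        better = True
                if better:
                    best = v
                    best_n = n
            out[i, y - y0] = best
    return out
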