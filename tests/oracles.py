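"""Independent brute-force oracles for the texture matrices and Otsu.

These deliberately use naive nested loops / flood fill so they share no code
path with the package implementations they check.
"""

import numpy as np


def otsu_brute(values, nbins=256):
    """Exhaustive search over all interior histogram-bin edges."""
    values = np.asarray(values, dtype=float).ravel()
    lo, hi = values.min(), values.max()
    edges = np.linspace(lo, hi, nbins + 1)[1:-1]
    best, best_sigma = None, -1.0
    n = values.size
    for t in edges:
        c0 = values[values <= t]
        c1 = values[values > t]
        if len(c0) == 0 or len(c1) == 0:
            continue
        w0 = len(c0) / n
        sigma = w0 * (1 - w0) * (c0.mean() - c1.mean()) ** 2
        if sigma > best_sigma + 1e-15:
            best_sigma, best = sigma, t
    return best


def glcm_counts_brute(levels, offset, n_levels):
    nr, nc = levels.shape
    dr, dc = offset
    C = np.zeros((n_levels, n_levels))
    for r in range(nr):
        for c in range(nc):
            a = levels[r, c]
            rr, cc = r + dr, c + dc
            if a > 0 and 0 <= rr < nr and 0 <= cc < nc:
                b = levels[rr, cc]
                if b > 0:
                    C[a - 1, b - 1] += 1
                    C[b - 1, a - 1] += 1
    return C


def glrlm_brute(levels, direction, n_levels, max_len):
    nr, nc = levels.shape
    dr, dc = direction
    R = np.zeros((n_levels, max_len))
    for r in range(nr):
        for c in range(nc):
            v = levels[r, c]
            if v == 0:
                continue
            pr, pc = r - dr, c - dc
            if 0 <= pr < nr and 0 <= pc < nc and levels[pr, pc] == v:
                continue  # interior of a run, not its start
            length = 0
            rr, cc = r, c
            while 0 <= rr < nr and 0 <= cc < nc and levels[rr, cc] == v:
                length += 1
                rr += dr
                cc += dc
            R[v - 1, length - 1] += 1
    return R


def glszm_zones_brute(levels):
    """(level, size) of every 8-connected iso-level zone, via flood fill."""
    nr, nc = levels.shape
    seen = np.zeros_like(levels, dtype=bool)
    zones = []
    for r in range(nr):
        for c in range(nc):
            if levels[r, c] == 0 or seen[r, c]:
                continue
            v = levels[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                y, x = stack.pop()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if (
                            0 <= yy < nr
                            and 0 <= xx < nc
                            and not seen[yy, xx]
                            and levels[yy, xx] == v
                        ):
                            seen[yy, xx] = True
                            stack.append((yy, xx))
            zones.append((int(v), size))
    return sorted(zones)


def gldm_brute(levels, n_levels, alpha=0.0):
    nr, nc = levels.shape
    P = np.zeros((n_levels, 9))
    for r in range(nr):
        for c in range(nc):
            v = levels[r, c]
            if v == 0:
                continue
            dep = 1  # the pixel depends on itself
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dy, dx) == (0, 0):
                        continue
                    yy, xx = r + dy, c + dx
                    if 0 <= yy < nr and 0 <= xx < nc and levels[yy, xx] > 0:
                        if abs(levels[yy, xx] - v) <= alpha:
                            dep += 1
            P[v - 1, dep - 1] += 1
    return P


def ngtdm_brute(levels, n_levels):
    nr, nc = levels.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for r in range(nr):
        for c in range(nc):
            v = levels[r, c]
            if v == 0:
                continue
            nbrs = []
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dy, dx) == (0, 0):
                        continue
                    yy, xx = r + dy, c + dx
                    if 0 <= yy < nr and 0 <= xx < nc and levels[yy, xx] > 0:
                        nbrs.append(levels[yy, xx])
            n_i[v - 1] += 1
            if nbrs:
                s_i[v - 1] += abs(v - float(np.mean(nbrs)))
    return n_i, s_i
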