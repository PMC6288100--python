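"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain scalar loops (or textbook numerics),
deliberately sharing no code with the package's vectorized implementations.
"""

import math

import numpy as np
from scipy import integrate, special


def corner_mean_loop(image, w):
    """Mean over the four w x w corner windows, pixel by pixel."""
    h, wid = image.shape
    vals = []
    for r in range(h):
        for c in range(wid):
            if (r < w or r >= h - w) and (c < w or c >= wid - w):
                vals.append(float(image[r, c]))
    return sum(vals) / len(vals)


def median_filter_loop(image, radius):
    """(2r+1)^2 median with replicated borders, by exhaustive sorting."""
    h, w = image.shape
    out = np.empty_like(np.asarray(image, dtype=float))
    for r in range(h):
        for c in range(w):
            vals = []
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    rr = min(max(r + dr, 0), h - 1)
                    cc = min(max(c + dc, 0), w - 1)
                    vals.append(float(image[rr, cc]))
            vals.sort()
            out[r, c] = vals[len(vals) // 2]
    return out


def ratio_loop(fret, donor, mask, floor):
    """Per-pixel scalar division with the donor-floor and positivity guards."""
    h, w = fret.shape
    ratio = np.zeros((h, w))
    valid = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            if mask[r, c] and donor[r, c] >= max(floor, 5e-324) and donor[r, c] > 0:
                q = float(fret[r, c]) / float(donor[r, c])
                if q > 0 and math.isfinite(q):
                    ratio[r, c] = q
                    valid[r, c] = True
    return ratio, valid


def bin_percentages_loop(ratio, valid, flow, n_bins):
    """Flow-axis binning by per-pixel assignment.

    Implements the package's documented convention with simple scalars:
    bin 0 holds the largest projections; a pixel exactly on an interior bin
    edge contributes half its weight to each adjacent bin.
    """
    pix = [(r, c) for r in range(valid.shape[0]) for c in range(valid.shape[1])
           if valid[r, c]]
    proj = [r * flow[0] + c * flow[1] for (r, c) in pix]
    lo, hi = min(proj), max(proj)
    span = hi - lo
    sums = [[] for _ in range(n_bins)]
    allw = []
    for (r, c), p in zip(pix, proj):
        wgt = float(ratio[r, c])
        u = (hi - p) * (n_bins / span)
        k = math.floor(u)
        if u == k and 1 <= k <= n_bins - 1:
            sums[k - 1].append(wgt / 2.0)
            sums[k].append(wgt / 2.0)
            allw.extend([wgt / 2.0, wgt / 2.0])
        else:
            kk = min(max(k, 0), n_bins - 1)
            sums[kk].append(wgt)
            allw.append(wgt)
    total = math.fsum(allw)
    return np.array([100.0 * math.fsum(s) / total for s in sums])


def welch_p_value(a, b):
    """Two-tailed Welch p by numerical integration of the t density."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return _two_tailed_t_p(abs(t), df)


def student_p_value(a, b):
    """Two-tailed pooled-variance t-test p by numerical integration."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return _two_tailed_t_p(abs(t), na + nb - 2)


def _two_tailed_t_p(t_abs, df):
    def density(x):
        return math.exp(
            special.gammaln((df + 1) / 2)
            - special.gammaln(df / 2)
            - 0.5 * math.log(df * math.pi)
            - (df + 1) / 2 * math.log1p(x * x / df)
        )

    tail, _ = integrate.quad(density, t_abs, np.inf)
    return 2.0 * tail
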