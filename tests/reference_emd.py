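"""Independently coded sifting decomposition used as a cross-check oracle.

Same algorithmic contract as the package implementation (natural cubic
spline envelopes, two mirrored extrema per end, SD stop criterion plus the
IMF oscillation requirement, at most four modes) but written separately,
with plain-loop extrema detection, so that agreement between the two is
meaningful.
"""

import numpy as np
from scipy.interpolate import CubicSpline


def _extrema_loop(x):
    """Plain-loop local maxima/minima with plateau midpoints."""
    maxima, minima = [], []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i] == x[i - 1]:
            i += 1
            continue
        j = i
        while j + 1 < n and x[j + 1] == x[j]:
            j += 1
        if j + 1 >= n:
            break
        mid = (i + j) // 2
        if x[i] > x[i - 1] and x[j] > x[j + 1]:
            maxima.append(mid)
        elif x[i] < x[i - 1] and x[j] < x[j + 1]:
            minima.append(mid)
        i = j + 1
    return maxima, minima


def _spline_envelope(x, idx):
    n = len(x)
    pts = [(int(i), float(x[i])) for i in idx]
    k = min(2, len(pts))
    left = [(-t, v) for t, v in pts[:k]][::-1]
    right = [(2 * (n - 1) - t, v) for t, v in pts[-k:]][::-1]
    allpts = left + pts + right
    dedup = [allpts[0]]
    for t, v in allpts[1:]:
        if t > dedup[-1][0]:
            dedup.append((t, v))
    t = np.array([p[0] for p in dedup], dtype=float)
    v = np.array([p[1] for p in dedup], dtype=float)
    return CubicSpline(t, v, bc_type="natural")(np.arange(n))


def _zero_crossings(x):
    count = 0
    prev = 0.0
    for v in x:
        if v == 0.0:
            continue
        if prev != 0.0 and (v > 0) != (prev > 0):
            count += 1
        prev = v
    return count


def reference_decompose(x, max_imfs=4, sd_threshold=0.2, max_sift=100):
    """Returns (list of IMFs, residue); IMF list is NOT zero-padded."""
    x = np.asarray(x, dtype=float)
    residue = x.copy()
    imfs = []
    for _ in range(max_imfs):
        h = residue.copy()
        extracted = None
        for it in range(max_sift):
            maxima, minima = _extrema_loop(h)
            if len(maxima) < 2 or len(minima) < 2:
                extracted = h if it > 0 else None
                break
            upper = _spline_envelope(h, maxima)
            lower = _spline_envelope(h, minima)
            h_new = h - 0.5 * (upper + lower)
            denom = np.sum(h**2)
            sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
            h = h_new
            mx, mn = _extrema_loop(h)
            if sd < sd_threshold and abs(
                len(mx) + len(mn) - _zero_crossings(h)
            ) <= 1:
                extracted = h
                break
        else:
            extracted = h
        if extracted is None:
            break
        imfs.append(extracted)
        residue = residue - extracted
    return imfs, residue


def reference_partial_reconstruction(x, k, max_imfs=4):
    """Sum of IMF_k..IMF_4 plus residue, from the reference decomposition."""
    imfs, residue = reference_decompose(x, max_imfs=max_imfs)
    out = residue.copy()
    for imf in imfs[k - 1 :]:
        out = out + imf
    return out
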