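"""Independent reference implementations used as oracles by the tests.

Everything here is deliberately naive (pure-Python scalar loops, brute
force enumeration) and shares no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


def naive_attention_forward(A, params):
    """Scalar-loop reimplementation of the attention-fusion forward pass.

    ``params`` is a DAFMParams-like object with a 1x1 initial conv.
    Returns (Z, a1, a2, fused) as nested lists / numpy arrays.
    """
    H = len(A)
    W = len(A[0])
    k0 = float(np.asarray(params.initial_conv_weights).reshape(-1)[0])
    B = [[k0 * A[h][w] + params.initial_conv_bias for w in range(W)] for h in range(H)]
    c = [
        sum(B[h][w] * params.spatial_compress_weights[w] for w in range(W))
        + params.spatial_compress_bias
        for h in range(H)
    ]
    d = [
        sum(B[h][w] * params.temporal_compress_weights[h] for h in range(H))
        + params.temporal_compress_bias
        for w in range(W)
    ]
    l1 = [c[h] * params.v[h] for h in range(H)]
    l2 = [d[w] * params.w[w] for w in range(W)]
    m1 = max(l1)
    e1 = [math.exp(x - m1) for x in l1]
    s1 = sum(e1)
    a1 = [x / s1 for x in e1]
    m2 = max(l2)
    e2 = [math.exp(x - m2) for x in l2]
    s2 = sum(e2)
    a2 = [x / s2 for x in e2]
    fused = [[a1[h] * a2[w] for w in range(W)] for h in range(H)]
    Z = [
        [params.gamma * fused[h][w] * B[h][w] + B[h][w] for w in range(W)]
        for h in range(H)
    ]
    return np.array(Z), np.array(a1), np.array(a2), np.array(fused)


def brute_force_decode(scores, flash_codes, repetitions_used, layout):
    """Exhaustive 36-cell search: maximise row-sum + column-sum.

    Ties break lexicographically on (row code, column code), which matches
    the decoder's independent lowest-code argmax rule.
    """
    sums = {code: 0.0 for code in range(1, 13)}
    for rep in range(repetitions_used):
        for pos in range(12):
            sums[int(flash_codes[rep][pos])] += float(scores[rep][pos])
    best = None
    for row_code in range(7, 13):
        for col_code in range(1, 7):
            total = sums[row_code] + sums[col_code]
            if best is None or total > best[0] + 1e-12:
                best = (total, row_code, col_code)
    _, row_code, col_code = best
    return layout[row_code - 7][col_code - 1]


def loglog_psd_slope(x, fmin=0.005, fmax=0.4):
    """Least-squares slope of the log-log periodogram of one channel."""
    from scipy.signal import periodogram

    f, p = periodogram(x)
    keep = (f >= fmin) & (f <= fmax) & (p > 0)
    return np.polyfit(np.log10(f[keep]), np.log10(p[keep]), 1)[0]


def bandpower(x, sfreq, low, high):
    """Integrated periodogram power of one channel in [low, high] Hz."""
    from scipy.signal import periodogram

    f, p = periodogram(x, fs=sfreq)
    return float(p[(f >= low) & (f <= high)].sum())
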