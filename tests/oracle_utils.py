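"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with explicit loops and elementary
formulas, sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math


def brute_force_features(pixels, n_bins, value_range=None):
    """First-order features by explicit loops over pixels and bins."""
    xs = [float(v) for v in pixels]
    n = len(xs)
    mu = sum(xs) / n
    m2 = sum((v - mu) ** 2 for v in xs) / n
    m3 = sum((v - mu) ** 3 for v in xs) / n
    m4 = sum((v - mu) ** 4 for v in xs) / n
    sigma = math.sqrt(m2)
    mn = min(xs)
    mx = max(xs)

    vc = sigma / mu if mu != 0 else math.nan
    skew = m3 / sigma ** 3 if sigma > 0 else math.nan
    kurt = m4 / sigma ** 4 if sigma > 0 else math.nan

    if mx == mn:
        entropy = 0.0
    else:
        edges = [mn + (mx - mn) * i / n_bins for i in range(n_bins + 1)]
        counts = [0] * n_bins
        for v in xs:
            placed = False
            for k in range(n_bins - 1):
                if edges[k] <= v < edges[k + 1]:
                    counts[k] += 1
                    placed = True
                    break
            if not placed:
                counts[n_bins - 1] += 1  # last bin is closed on the right
        entropy = 0.0
        for c in counts:
            if c > 0:
                p = c / n
                entropy -= p * math.log2(p)

    span = (value_range[1] - value_range[0]) if value_range is not None else (mx - mn)
    if span > 0:
        s = sigma / span
        smooth = 1.0 - 1.0 / (1.0 + s * s)
    else:
        smooth = 0.0

    return {
        "Mean": mu,
        "VC": vc,
        "Max-Min": mx - mn,
        "Skewness": skew,
        "Entropy": entropy,
        "RelativeSmoothness": smooth,
        "Kurtosis": kurt,
    }


def brute_force_mannwhitney_exact_p(a, b):
    """Exact two-sided p by enumerating every group assignment.

    Tie-free inputs only.  Two-sided extremeness measured as distance of U
    from its null mean n1*n2/2.
    """
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "tie-free inputs required"
    n1 = len(a)

    def u_of(group_a):
        group_b = [v for v in pooled if v not in group_a]
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = sum(1 for x in a for y in b if x > y)
    mid = n1 * len(b) / 2.0
    d_obs = abs(u_obs - mid)
    total = 0
    extreme = 0
    for combo in itertools.combinations(pooled, n1):
        total += 1
        if abs(u_of(set(combo)) - mid) >= d_obs - 1e-12:
            extreme += 1
    return extreme / total


def pairwise_auc(scores, y):
    """AUC as the tie-aware probability that a positive outscores a negative."""
    pos = [s for s, lab in zip(scores, y) if lab == 1]
    neg = [s for s, lab in zip(scores, y) if lab == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_disc_mask(image_size, radius):
    """Per-pixel rasterization of a centered filled disc."""
    c = (image_size - 1) / 2.0
    rows = []
    for i in range(image_size):
        row = []
        for j in range(image_size):
            row.append((i - c) ** 2 + (j - c) ** 2 <= radius ** 2)
        rows.append(row)
    return rows
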