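"""Entropy-based dependence measures between discrete variables.

All entropies are Shannon entropies in base 2 (bits), computed from
empirical frequencies.  The three measures used for univariate feature
scoring are

* information gain   IG(S, A) = H(S) - H(S|A)  (the mutual information),
* gain ratio         GR(S, A) = IG(S, A) / H(A), and
* symmetrical uncertainty
                     SU(S, A) = 2 IG(S, A) / (H(S) + H(A)),

where S is the class label and A the discretized attribute.  GR is taken
as 0 when H(A) = 0 and SU as 0 when both entropies vanish, so a constant
attribute always scores zero.
"""

from __future__ import annotations

import numpy as np


def entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy (base 2) of a count vector."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def contingency(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Dense contingency table of two small non-negative integer vectors."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    nx = int(x.max()) + 1 if x.size else 0
    ny = int(y.max()) + 1 if y.size else 0
    table = np.zeros((nx, ny), dtype=np.int64)
    np.add.at(table, (x, y), 1)
    return table


def information_measures(
    feature_bins: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """IG, GR and SU (bits) between a discretized feature and binary labels.

    Vectors must have equal length >= 2.  IG is clipped at zero against
    floating-point round-off; GR and SU lie in [0, 1] and SU is symmetric
    in its two arguments.
    """
    a = np.asarray(feature_bins, dtype=np.int64)
    s = np.asarray(labels, dtype=np.int64)
    if a.shape != s.shape:
        raise ValueError(f"length mismatch: feature {a.shape} vs labels {s.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    table = contingency(a, s)  # bins x classes
    n = table.sum()
    h_s = entropy_bits(table.sum(axis=0))
    h_a = entropy_bits(table.sum(axis=1))
    # H(S|A) = sum_a p(a) H(S | A=a)
    h_s_given_a = 0.0
    for row in table:
        na = row.sum()
        if na > 0:
            h_s_given_a += (na / n) * entropy_bits(row)
    ig = max(0.0, h_s - h_s_given_a)
    gr = ig / h_a if h_a > 0 else 0.0
    su = 2.0 * ig / (h_s + h_a) if (h_s + h_a) > 0 else 0.0
    return ig, min(1.0, gr), min(1.0, su)


def symmetrical_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """SU between two arbitrary discrete vectors (used by the CFS merit)."""
    _, _, su = information_measures(x, y)
    return su
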