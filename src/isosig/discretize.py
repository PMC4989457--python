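"""Discretization of continuous PSI/TPM values for the entropy measures.

The default strategy is the supervised minimum-description-length
procedure (MDLP): candidate cuts are class-boundary midpoints, the cut
maximizing information gain is accepted when the gain exceeds the MDL
coding cost, and the procedure recurses into both halves.  When no cut is
accepted the feature falls back to a single median cut (two bins), so a
feature never silently disappears; a constant feature yields a single
degenerate bin and scores zero information.

An unsupervised equal-frequency strategy (three bins) is provided as a
config-switchable alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .infotheory import entropy_bits


@dataclass(frozen=True)
class Discretizer:
    """Total mapping from reals to bins via strictly increasing cut points.

    Value v maps to bin #{cuts < v}; with k cuts there are k+1 bins, and
    every real (including +/-inf) maps to exactly one bin.
    """

    cut_points: tuple[float, ...]

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cut_points)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError(f"cut points not strictly increasing: {cuts}")
        object.__setattr__(self, "cut_points", cuts)

    @property
    def n_bins(self) -> int:
        return len(self.cut_points) + 1

    def transform(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return np.searchsorted(np.asarray(self.cut_points), v, side="left").astype(np.int64)


def _entropy_of_labels(y: np.ndarray) -> float:
    return entropy_bits(np.bincount(y))


def _row_entropies(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / np.where(totals > 0, totals, 1)
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=1)


def _best_cut(values: np.ndarray, labels: np.ndarray) -> tuple[int, float] | None:
    """Best boundary index and its class-information entropy, or None.

    *values* must be sorted ascending.  Returns (i, e) meaning a cut
    between positions i-1 and i with weighted post-split entropy e.
    Candidates are the boundaries between distinct adjacent values, which
    provably contain the entropy-optimal cut; entropies of all candidate
    splits are evaluated in one vectorized pass.
    """
    n = len(values)
    n_classes = int(labels.max()) + 1
    onehot = np.zeros((n, n_classes), dtype=np.int64)
    onehot[np.arange(n), labels] = 1
    left_counts = np.cumsum(onehot, axis=0)  # counts in values[:i+1]
    boundaries = np.flatnonzero(values[1:] != values[:-1]) + 1
    if boundaries.size == 0:
        return None
    lc = left_counts[boundaries - 1]
    rc = left_counts[-1] - lc
    frac = boundaries / n
    e = frac * _row_entropies(lc) + (1.0 - frac) * _row_entropies(rc)
    j = int(np.argmin(e))  # first minimum, matching ascending-scan order
    return int(boundaries[j]), float(e[j])


def _mdlp_accepts(values: np.ndarray, labels: np.ndarray, i: int, e_split: float) -> bool:
    n = len(values)
    ent = _entropy_of_labels(labels)
    gain = ent - e_split
    left, right = labels[:i], labels[i:]
    k = len(np.unique(labels))
    k1 = len(np.unique(left))
    k2 = len(np.unique(right))
    delta = np.log2(3.0**k - 2.0) - (
        k * ent - k1 * _entropy_of_labels(left) - k2 * _entropy_of_labels(right)
    )
    threshold = (np.log2(n - 1) + delta) / n
    return gain > threshold


def _mdlp_recurse(values: np.ndarray, labels: np.ndarray, cuts: list[float]) -> None:
    if len(values) < 4:
        return
    best = _best_cut(values, labels)
    if best is None:
        return
    i, e_split = best
    if not _mdlp_accepts(values, labels, i, e_split):
        return
    cuts.append((values[i - 1] + values[i]) / 2.0)
    _mdlp_recurse(values[:i], labels[:i], cuts)
    _mdlp_recurse(values[i:], labels[i:], cuts)


def fit_discretizer(
    values: np.ndarray, labels: np.ndarray, strategy: str = "mdlp"
) -> Discretizer:
    """Fit per-feature cut points on finite values.

    strategy='mdlp' (default): supervised MDLP; if no cut is accepted the
    fallback is a single median cut.  strategy='equal_frequency_k3':
    tertile cuts, label-blind.  A constant feature yields zero cuts (one
    bin) under either strategy.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    if v.shape != y.shape:
        raise ValueError(f"length mismatch: values {v.shape} vs labels {y.shape}")
    finite = np.isfinite(v)
    v, y = v[finite], y[finite]
    if v.size < 4:
        raise ValueError(f"need >= 4 finite values, got {v.size}")
    if np.all(v == v[0]):
        return Discretizer(cut_points=())

    if strategy == "equal_frequency_k3":
        qs = np.quantile(v, [1 / 3, 2 / 3])
        cuts = sorted(set(float(q) for q in qs))
        cuts = [c for c in cuts if v.min() < c]  # drop degenerate edge cuts
        return Discretizer(cut_points=tuple(cuts)) if cuts else _median_fallback(v)
    if strategy != "mdlp":
        raise ValueError(f"unknown discretization strategy {strategy!r}")

    order = np.argsort(v, kind="stable")
    v_sorted, y_sorted = v[order], y[order]
    cuts: list[float] = []
    _mdlp_recurse(v_sorted, y_sorted, cuts)
    if not cuts:
        return _median_fallback(v)
    return Discretizer(cut_points=tuple(sorted(cuts)))


def _median_fallback(v: np.ndarray) -> Discretizer:
    med = float(np.median(v))
    if med <= v.min():  # median equal to the minimum: cut just above it
        uniq = np.unique(v)
        med = float((uniq[0] + uniq[1]) / 2.0)
    return Discretizer(cut_points=(med,))
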