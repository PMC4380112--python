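"""Segmentation evaluation: per-class Dice, Rand index, Variation of Information.

All three are computed from the contingency table of two label maps S
(segmentation) and R (reference): counts n_uv of pixels carrying label u in S
and label v in R.

* Dice, per class: ``2 |S_l ∩ R_l| / (|S_l| + |R_l|)``.
* Rand index: the fraction of the N(N-1)/2 unordered pixel pairs whose
  together/apart relationship agrees between the two partitions, evaluated in
  O(K_S * K_R) through pair-count identities rather than the O(N^2) pair loop.
* Variation of Information: ``H(R) + H(S) - 2 I(R, S)`` — a true metric on
  partitions; reported in bits (base 2) by default.

Because unsupervised cluster labels are arbitrary, :func:`match_labels` finds
the overlap-maximising one-to-one correspondence (Hungarian assignment on the
contingency table) before per-class scores are compared against a reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ContingencyTable",
    "contingency_table",
    "dice",
    "rand_index",
    "voi",
    "match_labels",
    "matched_agreement",
    "evaluate",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Joint label counts of two equally shaped label maps."""

    counts: np.ndarray  #: (K_S, K_R) integer matrix n_uv
    s_labels: np.ndarray  #: label values indexing the rows
    r_labels: np.ndarray  #: label values indexing the columns

    @property
    def N(self) -> int:
        return int(self.counts.sum())


def _flat_pair(S, R) -> tuple[np.ndarray, np.ndarray]:
    S = np.asarray(S)
    R = np.asarray(R)
    if S.shape != R.shape:
        raise ValueError(f"shape mismatch: {S.shape} vs {R.shape}")
    return S.ravel(), R.ravel()


def contingency_table(S, R) -> ContingencyTable:
    s, r = _flat_pair(S, R)
    s_labels, si = np.unique(s, return_inverse=True)
    r_labels, ri = np.unique(r, return_inverse=True)
    counts = np.zeros((len(s_labels), len(r_labels)), dtype=np.int64)
    np.add.at(counts, (si, ri), 1)
    return ContingencyTable(counts=counts, s_labels=s_labels, r_labels=r_labels)


def dice(S, R, label: int) -> float:
    """Dice overlap of one class: intersection over mean mask size."""
    s, r = _flat_pair(S, R)
    sm = s == label
    rm = r == label
    ns, nr = int(sm.sum()), int(rm.sum())
    if ns == 0 and nr == 0:
        raise ValueError(f"label {label} absent from both maps")
    return 2.0 * int((sm & rm).sum()) / (ns + nr)


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1.0) / 2.0


def rand_index(S, R) -> float:
    """Unordered-pair Rand index from contingency pair-count identities.

    With T = C(N,2): agreements = T + 2 Σ_uv C(n_uv,2) − Σ_u C(n_u·,2)
    − Σ_v C(n_·v,2); RI = agreements / T.
    """
    ct = contingency_table(S, R)
    N = ct.N
    if N < 2:
        raise ValueError("Rand index needs at least 2 elements")
    T = _comb2(N)
    pairs_both = _comb2(ct.counts).sum()
    pairs_s = _comb2(ct.counts.sum(axis=1)).sum()
    pairs_r = _comb2(ct.counts.sum(axis=0)).sum()
    return float((T + 2.0 * pairs_both - pairs_s - pairs_r) / T)


def _entropy(p: np.ndarray, base: float) -> float:
    p = p[p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())


def voi(S, R, base: float = 2.0) -> float:
    """Variation of Information between two partitions (0 · log 0 ≡ 0).

    ``VoI = H(R) + H(S) − 2 I(R, S)``, from the empirical joint distribution
    of the contingency table; identical partitions give exactly 0.
    """
    ct = contingency_table(S, R)
    p = ct.counts / ct.N
    hs = _entropy(p.sum(axis=1), base)
    hr = _entropy(p.sum(axis=0), base)
    hj = _entropy(p.ravel(), base)
    mi = hs + hr - hj
    return max(0.0, hs + hr - 2.0 * mi)


def match_labels(S, R) -> dict:
    """Overlap-maximising one-to-one map from S's labels to R's labels.

    Hungarian assignment on the contingency table; when the label sets differ
    in size, surplus labels map to -1 ("unmatched").
    """
    ct = contingency_table(S, R)
    rows, cols = linear_sum_assignment(ct.counts, maximize=True)
    mapping = {int(lbl): -1 for lbl in ct.s_labels}
    for i, j in zip(rows, cols):
        mapping[int(ct.s_labels[i])] = int(ct.r_labels[j])
    return mapping


def _apply_mapping(S: np.ndarray, mapping: dict) -> np.ndarray:
    out = np.full(S.shape, -1, dtype=np.int64)
    for src, dst in mapping.items():
        out[S == src] = dst
    return out


def matched_agreement(S, R) -> float:
    """Fraction of pixels agreeing with R after optimal label matching."""
    s, r = _flat_pair(S, R)
    mapped = _apply_mapping(s, match_labels(s, r))
    return float((mapped == r).mean())


def evaluate(S, R, *, base: float = 2.0) -> dict:
    """Full report: matched per-class Dice, Rand index, VoI, label map.

    The returned dict is JSON-serialisable (used by the CLI's metrics
    command).
    """
    s, r = _flat_pair(S, R)
    mapping = match_labels(s, r)
    mapped = _apply_mapping(s, mapping)
    per_class = {}
    for lbl in np.unique(r):
        per_class[int(lbl)] = dice(mapped, r, int(lbl))
    return {
        "dice_per_class": per_class,
        "rand_index": rand_index(s, r),
        "voi": voi(s, r, base=base),
        "label_mapping": {int(k): int(v) for k, v in mapping.items()},
        "agreement": float((mapped == r).mean()),
    }
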