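"""Privileged-substructure mining from binary fingerprints.

Two complementary statistics over each fingerprint bit:

* the class-frequency statistic
  freq_C = (N_frag_in_C * N_total) / (N_frag_total * N_C),
  the observed enrichment of the fragment in class C relative to the
  class's share of the dataset (1 means no enrichment); and

* the information gain IG = H(class) - H(class | bit) in bits
  (base-2 Shannon entropy over the pooled labeled set, 0*log 0 = 0).

A bit is a privileged substructure when it occurs often enough and is
more frequent in the inhibitor class than the non-inhibitor class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SubstructureStats",
    "class_frequency",
    "information_gain",
    "privileged_substructures",
    "stats_table",
]


@dataclass
class SubstructureStats:
    bit: str
    ig: float
    freq_p: float
    freq_n: float
    count_p: int
    count_n: int
    privileged: bool = False

    @property
    def count_total(self) -> int:
        return self.count_p + self.count_n


def _to_pn(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        return arr == "P"
    return arr.astype(bool)


def class_frequency(
    bit: np.ndarray, labels
) -> tuple[float, float, int, int]:
    """Class-wise fragment frequency statistic.

    Returns ``(freq_P, freq_N, count_P, count_N)`` where
    freq_C = (count_C * N_total) / (count_total * N_C).  A bit absent
    from every compound has undefined frequencies (NaN).
    """
    bit = np.asarray(bit).astype(bool)
    pos = _to_pn(labels)
    n_total = bit.size
    n_p, n_n = int(pos.sum()), int((~pos).sum())
    count_p = int((bit & pos).sum())
    count_n = int((bit & ~pos).sum())
    total = count_p + count_n
    if total == 0:
        return float("nan"), float("nan"), 0, 0
    freq_p = count_p * n_total / (total * n_p) if n_p else float("nan")
    freq_n = count_n * n_total / (total * n_n) if n_n else float("nan")
    return freq_p, freq_n, count_p, count_n


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(bit: np.ndarray, labels) -> float:
    """IG = H(class) - H(class | bit), base-2, over the full labeled set.

    Degenerate bits (all present or all absent) give exactly 0.
    """
    bit = np.asarray(bit).astype(bool)
    pos = _to_pn(labels)
    n = bit.size
    h_class = _entropy(np.array([pos.sum(), (~pos).sum()]))
    h_cond = 0.0
    for mask in (bit, ~bit):
        m = int(mask.sum())
        if m:
            h_cond += m / n * _entropy(
                np.array([(mask & pos).sum(), (mask & ~pos).sum()])
            )
    return max(0.0, h_class - h_cond)


def privileged_substructures(
    matrix: pd.DataFrame,
    labels,
    min_count: int = 5,
    min_ratio: float = 1.0,
) -> list[SubstructureStats]:
    """Mine privileged substructures from a binary fingerprint matrix.

    Bits occurring in at least ``min_count`` compounds with
    freq_P > freq_N * ``min_ratio`` are flagged privileged; the full
    per-bit statistics list is returned ranked by IG descending
    (ties by bit name) with only the privileged bits included.
    """
    if matrix.empty:
        raise ValueError("empty fingerprint matrix")
    out = []
    for name in matrix.columns:
        col = matrix[name].to_numpy()
        freq_p, freq_n, cp, cn = class_frequency(col, labels)
        if cp + cn < min_count or not np.isfinite(freq_p):
            continue
        if not (freq_p > freq_n * min_ratio):
            continue
        out.append(
            SubstructureStats(
                bit=name,
                ig=information_gain(col, labels),
                freq_p=freq_p,
                freq_n=freq_n,
                count_p=cp,
                count_n=cn,
                privileged=True,
            )
        )
    out.sort(key=lambda s: (-s.ig, s.bit))
    return out


def stats_table(stats: list[SubstructureStats]) -> pd.DataFrame:
    """Report in the value(count) style: bit, IG, FP, FN columns."""
    rows = [
        {
            "bit": s.bit,
            "IG": round(s.ig, 3),
            "FP": f"{s.freq_p:.2f}({s.count_p})",
            "FN": f"{s.freq_n:.2f}({s.count_n})",
        }
        for s in stats
    ]
    return pd.DataFrame(rows)
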