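"""Shared small statistical utilities."""

from __future__ import annotations

import numpy as np
from scipy import stats


def one_sided_wilcoxon_less(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided Wilcoxon signed-rank p-value for H1: a tends below b.

    Zero differences are dropped; if none remain the p-value is 1 (no
    evidence). The exact null distribution is used for up to 25 untied
    pairs, otherwise the normal approximation (scipy applies the tie
    correction to its variance).
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    ad = np.abs(d)
    exact = d.size <= 25 and np.unique(ad).size == ad.size
    res = stats.wilcoxon(
        d,
        alternative="less",
        zero_method="wilcox",
        method="exact" if exact else "approx",
    )
    return float(res.pvalue)


def lower_median(values: np.ndarray) -> float:
    """Median of an odd-length vector; lower middle value if even-length."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("empty vector")
    return float(values[(values.size - 1) // 2])
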