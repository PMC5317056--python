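"""Expression-based candidate-gene rules on FPKM matrices.

Two decision rules: (1) a gene is "tissue-specific" in tissue t when its
FPKM there falls outside the two-sided 95% t-interval built from the other
tissues' values; (2) a gene is differentially expressed between domesticated
and wild material when a Fisher exact test on read counts is significant and
the normalized fold change exceeds a cutoff.  Quantification from reads is
upstream and out of scope; the rules consume precomputed matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["tissue_specific_genes", "domestication_expression_test"]


def tissue_specific_genes(expr: pd.DataFrame, alpha: float = 0.05,
                          interval: str = "prediction") -> pd.DataFrame:
    """Flag (gene, tissue) pairs whose expression escapes the t-interval of
    the remaining tissues.

    ``expr`` is genes x tissues (FPKM).  For each focal tissue the other
    tissues give mean m, sd s over n values; the two-sided (1 - alpha)
    interval is m +/- t_crit * s * sqrt(1 + 1/n) ("prediction", default:
    the interval for one new observation) or m +/- t_crit * s / sqrt(n)
    ("mean").  A degenerate interval (s = 0) flags the pair whenever the
    focal value differs from m.  Returns the flagged pairs with the focal
    value and interval bounds.
    """
    if expr.shape[1] < 4:
        raise ValueError("need >= 4 tissues")
    if interval not in ("prediction", "mean"):
        raise ValueError("interval must be 'prediction' or 'mean'")
    x = expr.to_numpy(float)
    n_genes, n_tissues = x.shape
    n = n_tissues - 1
    tcrit = stats.t.ppf(1 - alpha / 2, df=n - 1)
    total = x.sum(axis=1)
    total_sq = (x ** 2).sum(axis=1)
    rows = []
    for t in range(n_tissues):
        rest_mean = (total - x[:, t]) / n
        rest_var = (total_sq - x[:, t] ** 2 - n * rest_mean ** 2) / (n - 1)
        rest_sd = np.sqrt(np.maximum(rest_var, 0.0))
        if interval == "prediction":
            half = tcrit * rest_sd * np.sqrt(1 + 1 / n)
        else:
            half = tcrit * rest_sd / np.sqrt(n)
        lo, hi = rest_mean - half, rest_mean + half
        outside = (x[:, t] < lo) | (x[:, t] > hi)
        degenerate = (rest_sd == 0) & (x[:, t] != rest_mean)
        flag = outside | degenerate
        for g in np.flatnonzero(flag):
            rows.append((expr.index[g], expr.columns[t], x[g, t],
                         lo[g], hi[g], bool(degenerate[g])))
    return pd.DataFrame(rows, columns=["gene", "tissue", "fpkm", "lower",
                                       "upper", "degenerate"])


def domestication_expression_test(counts_dom, counts_wild, total_dom: int,
                                  total_wild: int, genes=None,
                                  fc: float = 2.0, alpha: float = 0.05
                                  ) -> pd.DataFrame:
    """Per-gene Fisher exact test of domesticated vs wild read counts.

    The 2x2 table is [[count_dom, total_dom - count_dom],
    [count_wild, total_wild - count_wild]].  The fold change is the ratio
    of library-normalized counts (direction recorded as its sign).  A gene
    is called when p < ``alpha`` and fold change > ``fc`` in either
    direction.  Returns the full per-gene table with a ``called`` column.
    """
    cd = np.asarray(counts_dom, dtype=int)
    cw = np.asarray(counts_wild, dtype=int)
    if total_dom <= 0 or total_wild <= 0:
        raise ValueError("library totals must be positive")
    if (cd > total_dom).any() or (cw > total_wild).any():
        raise ValueError("count exceeds library total")
    if genes is None:
        genes = [f"gene{i:04d}" for i in range(len(cd))]
    rows = []
    for g, a, b in zip(genes, cd, cw):
        _, p = stats.fisher_exact([[a, total_dom - a],
                                   [b, total_wild - b]])
        rate_d = a / total_dom
        rate_w = b / total_wild
        if rate_w == 0 and rate_d == 0:
            fold = 1.0
        elif rate_w == 0:
            fold = np.inf
        else:
            fold = rate_d / rate_w
        up = fold >= 1
        mag = fold if up else (np.inf if fold == 0 else 1 / fold)
        rows.append((g, int(a), int(b), p, fold, "up" if up else "down",
                     p < alpha and mag > fc))
    return pd.DataFrame(rows, columns=["gene", "count_dom", "count_wild",
                                       "p", "fold_change", "direction",
                                       "called"])
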