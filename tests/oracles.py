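"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library code paths they check: the Mann–Whitney
oracle enumerates group assignments directly, and the Q^CNV oracle uses an
explicit sort + interpolated-percentile + counting loop.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def mw_exact_two_sided(x, y) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by full enumeration (distinct values)."""
    n1, n = len(x), len(x) + len(y)
    vals = sorted(list(x) + list(y))
    xset = set(x)

    def u_of(idx: set[int]) -> int:
        xs = [vals[i] for i in idx]
        ys = [vals[i] for i in range(n) if i not in idx]
        return sum(1 for a in xs for b in ys if a > b)

    obs = u_of({i for i, v in enumerate(vals) if v in xset})
    us = [u_of(set(c)) for c in combinations(range(n), n1)]
    cdf = sum(1 for u in us if u <= obs) / len(us)
    sf = sum(1 for u in us if u >= obs) / len(us)
    return float(obs), min(1.0, 2.0 * min(cdf, sf))


def interp_percentile(values, p_k: float) -> float:
    """Linear-interpolation percentile, written out longhand."""
    s = sorted(float(v) for v in values)
    if len(s) == 1:
        return s[0]
    pos = (len(s) - 1) * p_k / 100.0
    lo = math.floor(pos)
    if lo + 1 >= len(s):
        return s[-1]
    frac = pos - lo
    return s[lo] + frac * (s[lo + 1] - s[lo])


def q_gene_brute(cnv: np.ndarray, p_k: float = 99.9) -> np.ndarray:
    """Row-wise Q scores by explicit loops: per gene across cells."""
    n_genes, n_cells = cnv.shape
    out = np.empty_like(cnv, dtype=float)
    for g in range(n_genes):
        pk = interp_percentile(cnv[g, :], p_k)
        n_at = sum(1 for c in range(n_cells) if cnv[g, c] >= pk)
        for c in range(n_cells):
            out[g, c] = (cnv[g, c] - pk) / n_at if n_at else np.nan
    return out


def q_cell_brute(cnv: np.ndarray, p_k: float = 99.9) -> np.ndarray:
    """Column-wise mirror of :func:`q_gene_brute`: per cell across genes."""
    return q_gene_brute(cnv.T, p_k).T
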