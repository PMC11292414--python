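"""Cohen's h effect size and two-proportion sample-size computation.

Used to justify how many true-positive and true-negative cell lines are
needed before an ecDNA predictor can be evaluated at a target accuracy:
h = |2·arcsin√p1 − 2·arcsin√p2|, and the per-group n for a two-sided
two-independent-sample comparison on the arcsine scale.
"""

from __future__ import annotations

import math

from scipy.stats import norm


def cohens_h(p1: float, p2: float) -> float:
    """Magnitude of Cohen's h for two proportions (symmetric in arguments)."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion out of [0, 1]: {p}")
    return abs(2.0 * math.asin(math.sqrt(p1)) - 2.0 * math.asin(math.sqrt(p2)))


def achieved_power(h: float, n_per_group: float, alpha: float = 0.05) -> float:
    """Exact two-sided power of the normal test at effect size ``h`` and
    ``n_per_group`` samples per group."""
    z_a = norm.ppf(1.0 - alpha / 2.0)
    shift = abs(h) * math.sqrt(n_per_group / 2.0)
    return float(norm.sf(z_a - shift) + norm.cdf(-z_a - shift))


def required_sample_size(h: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Smallest integer n per group achieving the requested power.

    Starts from the closed form ceil(2·(z_{1−α/2} + z_power)² / h²) and
    adjusts by ±1 so the returned n is minimal under the exact two-sided
    power function (the two agree except in razor-edge cases where the
    second tail contributes).
    """
    if h <= 0:
        raise ValueError("effect size h must be > 0 (h = 0 needs infinite n)")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must lie in (0, 1)")
    z_a = norm.ppf(1.0 - alpha / 2.0)
    z_b = norm.ppf(power)
    n = max(1, math.ceil(2.0 * (z_a + z_b) ** 2 / h**2))
    while n > 1 and achieved_power(h, n - 1, alpha) >= power:
        n -= 1
    while achieved_power(h, n, alpha) < power:
        n += 1
    return n
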