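"""Shared exact-test helpers."""

from __future__ import annotations

from scipy.stats import fisher_exact as _scipy_fisher


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    The p-value is the sum of hypergeometric probabilities (margins
    fixed) of all tables whose point probability does not exceed that of
    the observed table (minimum-likelihood rule).  The odds ratio is the
    sample OR a*d/(b*c), with the Haldane-Anscombe +0.5 applied to all
    cells when any cell is zero.

    Returns ``(odds_ratio, p_two_sided)``.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells) or any(x != int(x) for x in cells):
        raise ValueError("cells must be non-negative integers")
    if all(x == 0 for x in cells):
        raise ValueError("all-zero table")
    a, b, c, d = (int(x) for x in cells)
    if min(a, b, c, d) == 0:
        oddsr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        oddsr = a * d / (b * c)
    _, p = _scipy_fisher([[a, b], [c, d]], alternative="two-sided")
    return float(oddsr), float(p)
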