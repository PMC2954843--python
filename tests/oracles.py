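"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive results by exhaustive enumeration from
first principles and share no code with the package internals.
"""

from __future__ import annotations

from math import comb

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# Fisher exact test: exact hypergeometric enumeration over the table support
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided p by minimum-likelihood enumeration with exact integers.

    Hypergeometric point probabilities share the denominator C(n, a+c),
    so tables are compared by their integer numerators
    C(r1, x) * C(r2, a+c-x); all tables with numerator <= observed
    (within 1e-7 relative, the conventional tie guard) are summed.
    """
    r1, r2, c1 = a + b, c + d, a + c
    num_obs = comb(r1, a) * comb(r2, c1 - a)
    denom = comb(r1 + r2, c1)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = comb(r1, x) * comb(r2, c1 - x)
        if num <= num_obs + num_obs * 1e-7:
            total += num
    return total / denom


# ---------------------------------------------------------------------------
# ROH calling: exhaustive window enumeration
# ---------------------------------------------------------------------------

def roh_windows_oracle(pos, geno, min_snps, max_het, max_missing,
                       density_bp_per_snp, max_gap_bp):
    """All emitted runs by brute force: enumerate every window, keep the
    valid ones that no single-marker extension keeps valid, then resolve
    overlaps greedily by (larger SNP count, smaller start, smaller end).

    Returns a list of (start_index, end_index) inclusive pairs.
    """
    pos = np.asarray(pos, dtype=np.int64)
    geno = np.asarray(geno)
    n = pos.size
    ch = np.concatenate([[0], np.cumsum(geno == 1)])
    cm = np.concatenate([[0], np.cumsum(geno == MISSING)])
    gap_ok = np.concatenate([[True], np.diff(pos) <= max_gap_bp])
    # cumulative count of gap violations before each marker
    gv = np.concatenate([[0], np.cumsum(~gap_ok)])

    def valid(a: int, b: int) -> bool:
        if a < 0 or b >= n or b - a + 1 < min_snps:
            return False
        if ch[b + 1] - ch[a] > max_het:
            return False
        if cm[b + 1] - cm[a] > max_missing:
            return False
        if gv[b + 1] - gv[a + 1] > 0:   # any gap violation strictly inside
            return False
        return (pos[b] - pos[a]) <= density_bp_per_snp * (b - a + 1)

    maximal = [(a, b)
               for a in range(n)
               for b in range(a + min_snps - 1, n)
               if valid(a, b) and not valid(a - 1, b) and not valid(a, b + 1)]

    chosen: list[tuple[int, int]] = []
    for a, b in sorted(maximal, key=lambda w: (-(w[1] - w[0]), w[0], w[1])):
        if all(b < a2 or a > b2 for a2, b2 in chosen):
            chosen.append((a, b))
    return sorted(chosen)


# ---------------------------------------------------------------------------
# IBS distance: naive per-pair loop
# ---------------------------------------------------------------------------

def ibs_pair_oracle(gi, gj):
    """(A, B, M): one-allele mismatches, two-allele mismatches, shared markers."""
    A = B = M = 0
    for x, y in zip(gi, gj):
        if x == MISSING or y == MISSING:
            continue
        M += 1
        diff = abs(int(x) - int(y))
        if diff == 1:
            A += 1
        elif diff == 2:
            B += 1
    return A, B, M
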