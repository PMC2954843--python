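"""Pairwise relatedness (pi-hat) from IBS sharing and allele frequencies.

The estimator is the standard method-of-moments used by array-era QC
tooling: observed counts of markers at which a pair shares 0/1/2
alleles identical by state are compared with their expectations under
IBD states 0/1/2, the IBD-state proportions are solved sequentially,
negative proportions are clamped to zero and renormalized, and
pi-hat = P(IBD=1)/2 + P(IBD=2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from popscan.genotypes import MISSING, GenotypeDataset


@dataclass
class RelatednessEstimate:
    sample_i: str
    sample_j: str
    idx_i: int
    idx_j: int
    ibs0: int
    ibs1: int
    ibs2: int
    pihat: float
    n_shared: int
    reliable: bool = True


def estimate_pihat(ds: GenotypeDataset, min_markers: int = 50
                   ) -> list[RelatednessEstimate]:
    """Estimate pi-hat for every unordered sample pair.

    IBS counts are taken over mutually non-missing markers; expectations
    use sample allele frequencies.  Pairs with fewer than ``min_markers``
    mutually non-missing markers are flagged ``reliable=False``.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples")
    G = ds.calls
    n, m = G.shape
    obs = (G != MISSING)
    X = [np.asarray((G == c) & obs, dtype=np.float64) for c in (0, 1, 2)]

    # cross-tabulated counts N[a][b][i,j] = #markers where i codes a, j codes b
    N = [[X[a] @ X[b].T for b in range(3)] for a in range(3)]
    ibs2 = N[0][0] + N[1][1] + N[2][2]
    ibs1 = N[0][1] + N[1][0] + N[1][2] + N[2][1]
    ibs0 = N[0][2] + N[2][0]
    Mpair = np.asarray(obs, dtype=np.float64) @ np.asarray(obs, dtype=np.float64).T

    p = ds.allele_b_freq()
    p = np.nan_to_num(p, nan=0.5)
    q = 1.0 - p
    # per-marker IBS-class probabilities conditional on IBD state
    e0_ibd0 = 2 * p**2 * q**2
    e1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e2_ibd0 = p**4 + 4 * p**2 * q**2 + q**4
    e1_ibd1 = 2 * p**2 * q + 2 * p * q**2
    e2_ibd1 = p**3 + q**3 + p**2 * q + p * q**2

    obsf = np.asarray(obs, dtype=np.float64)
    E0_0 = (obsf * e0_ibd0) @ obsf.T   # pairwise sums over shared markers
    E1_0 = (obsf * e1_ibd0) @ obsf.T
    E2_0 = (obsf * e2_ibd0) @ obsf.T
    E1_1 = (obsf * e1_ibd1) @ obsf.T
    E2_1 = (obsf * e2_ibd1) @ obsf.T

    with np.errstate(divide="ignore", invalid="ignore"):
        P0 = np.where(E0_0 > 0, ibs0 / E0_0, 0.0)
        P1 = np.where(E1_1 > 0, (ibs1 - P0 * E1_0) / E1_1, 0.0)
        P2 = np.where(Mpair > 0, (ibs2 - P0 * E2_0 - P1 * E2_1) / Mpair, 0.0)
    # clamp negative state proportions to 0, renormalize to sum 1
    P = np.stack([P0, P1, P2])
    P = np.clip(P, 0.0, None)
    tot = P.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(tot > 0, P / tot, P)
    pihat = np.clip(P[1] / 2.0 + P[2], 0.0, 1.0)

    out = []
    ids = ds.sample_ids
    for i in range(n):
        for j in range(i + 1, n):
            out.append(RelatednessEstimate(
                ids[i], ids[j], i, j,
                int(ibs0[i, j]), int(ibs1[i, j]), int(ibs2[i, j]),
                float(pihat[i, j]), int(Mpair[i, j]),
                reliable=Mpair[i, j] >= min_markers))
    return out


def prune_related(estimates: list[RelatednessEstimate],
                  threshold: float = 0.25,
                  sample_ids: list[str] | None = None) -> list[str]:
    """Remove one member of each related pair (pi-hat > threshold).

    Pairs are visited in ascending (i, j) index order; the member with
    the larger index is removed; pairs already broken by an earlier
    removal are skipped.  Returns surviving ids in original order.
    """
    if sample_ids is None:
        order: dict[int, str] = {}
        for e in estimates:
            order[e.idx_i] = e.sample_i
            order[e.idx_j] = e.sample_j
        sample_ids = [order[k] for k in sorted(order)]
    removed: set[str] = set()
    for e in sorted(estimates, key=lambda e: (e.idx_i, e.idx_j)):
        if e.pihat > threshold:
            if e.sample_i in removed or e.sample_j in removed:
                continue
            removed.add(e.sample_j)  # larger index
    return [s for s in sample_ids if s not in removed]
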