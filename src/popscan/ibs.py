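"""Identity-by-state distances, classical MDS, and permutation tests.

The pairwise IBS distance counts, over mutually non-missing markers,
the markers at which two subjects differ by one allele (A) and by two
alleles (B).  The default "normalized" convention returns
(0.5*A + B) / M, a scaled Hamming-type metric in [0, 1]; the
"as_printed" convention returns the raw count A + B/2, retained for
auditability of legacy reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from popscan.genotypes import MISSING, GenotypeDataset


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray            # symmetric, zero diagonal
    convention: str               # "normalized" | "as_printed"
    pair_n: np.ndarray            # per-pair mutually non-missing marker count

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


@dataclass
class MDSResult:
    ids: list[str]
    coords: np.ndarray            # (n, k)
    eigenvalues: np.ndarray       # top-k eigenvalues of the centered matrix
    padded_axes: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        k = self.coords.shape[1]
        df = pd.DataFrame(self.coords, columns=[f"axis{i+1}" for i in range(k)])
        df.insert(0, "id", self.ids)
        return df


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    n_perm: int
    perm_mean: float
    perm_sd: float
    perm_max: float
    p_value: float
    seed: int


def ibs_distance_matrix(ds: GenotypeDataset, convention: str = "normalized"
                        ) -> DistanceMatrix:
    """Pairwise IBS distances over mutually non-missing markers."""
    if convention not in ("normalized", "as_printed"):
        raise ValueError(f"unknown convention {convention!r}")
    G = ds.calls
    obs = G != MISSING
    X = [np.asarray((G == c) & obs, dtype=np.float64) for c in (0, 1, 2)]
    N = [[X[a] @ X[b].T for b in range(3)] for a in range(3)]
    A = N[0][1] + N[1][0] + N[1][2] + N[2][1]   # one-allele mismatches
    B = N[0][2] + N[2][0]                        # two-allele mismatches
    obsf = np.asarray(obs, dtype=np.float64)
    M = obsf @ obsf.T
    off = ~np.eye(ds.n_samples, dtype=bool)
    if (M[off] == 0).any():
        i, j = np.argwhere((M == 0) & off)[0]
        raise ValueError(
            f"pair ({ds.sample_ids[i]}, {ds.sample_ids[j]}) has no mutually "
            "non-missing markers")
    if convention == "normalized":
        D = (0.5 * A + B) / M
    else:
        D = A + B / 2.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(ds.sample_ids, D, convention, M.astype(np.int64))


def classical_mds(D: DistanceMatrix | np.ndarray, k: int = 2,
                  ids: list[str] | None = None) -> MDSResult:
    """Classical (Torgerson) metric scaling of a distance matrix.

    Double-centers -D**2/2, takes the top-k eigenpairs, and scales
    eigenvectors by sqrt(max(eigenvalue, 0)).  Sign convention: the
    first nonzero loading of each axis is positive.  Axes beyond the
    number of non-negative eigenvalues are zero-padded and flagged.
    """
    if isinstance(D, DistanceMatrix):
        ids = D.ids
        M = D.matrix
    else:
        M = np.asarray(D, dtype=float)
        ids = ids or [str(i) for i in range(M.shape[0])]
    n = M.shape[0]
    if not np.allclose(M, M.T) or not np.allclose(np.diag(M), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (M ** 2) @ J
    B = (B + B.T) / 2.0
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    vals_k = vals[order]
    coords = np.zeros((n, k))
    padded = []
    for a, (lam, col) in enumerate(zip(vals_k, order)):
        if lam <= 1e-12:
            padded.append(a)
            continue
        v = vecs[:, col]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            v = -v
        coords[:, a] = v * np.sqrt(lam)
    if len(vals_k) < k:
        padded.extend(range(len(vals_k), k))
        vals_k = np.pad(vals_k, (0, k - len(vals_k)))
    return MDSResult(list(ids), coords, vals_k, padded)


def cross_group_ibs_test(D: DistanceMatrix, labels, statistic: str = "median",
                         n_perm: int = 10_000, seed: int | None = None
                         ) -> PermutationResult:
    """One-sided permutation test on the cross-group IBS distance.

    The observed statistic is the median (or mean) of all cross-group
    pairwise distances; the null is built by shuffling group labels with
    group sizes fixed.  Direction is "greater": population separation
    inflates cross-group distance.  p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if seed is None:
        raise ValueError("seed is required for the permutation test")
    if statistic not in ("median", "mean"):
        raise ValueError(f"unknown statistic {statistic!r}")
    lab = np.asarray([labels[i] if isinstance(labels, dict) else labels[k]
                      for k, i in enumerate(D.ids)])
    groups = np.unique(lab)
    if groups.size != 2:
        raise ValueError(f"labels must form exactly 2 groups, got {groups.size}")
    g = lab == groups[0]
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValueError("each group must have at least 2 samples")
    stat = np.median if statistic == "median" else np.mean

    M = D.matrix
    observed = float(stat(M[np.ix_(g, ~g)]))
    rng = np.random.default_rng(seed)
    n = len(lab)
    count = 0
    perm_vals = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        gp = np.zeros(n, dtype=bool)
        gp[perm[:g.sum()]] = True
        perm_vals[b] = stat(M[np.ix_(gp, ~gp)])
    count = int(np.sum(perm_vals >= observed))
    p = (1 + count) / (1 + n_perm)
    return PermutationResult(statistic, observed, n_perm,
                             float(perm_vals.mean()), float(perm_vals.std()),
                             float(perm_vals.max()), p, seed)


# ---------------------------------------------------------------------------
# PHYLIP export (square distance matrix for external tree builders)
# ---------------------------------------------------------------------------

def export_phylip(D: DistanceMatrix) -> tuple[str, dict[str, str]]:
    """Square PHYLIP distance-matrix text ('%.6f'), with an id-truncation map.

    Ids longer than 10 characters are truncated; the returned mapping is
    truncated-id -> original id.  Duplicate truncated ids are an error.
    """
    mapping: dict[str, str] = {}
    short = []
    for sid in D.ids:
        t = sid[:10]
        if t in mapping and mapping[t] != sid:
            raise ValueError(f"duplicate truncated id {t!r} "
                             f"(from {mapping[t]!r} and {sid!r})")
        mapping[t] = sid
        short.append(t)
    lines = [f"{D.n}"]
    for i, t in enumerate(short):
        row = " ".join(f"{x:.6f}" for x in D.matrix[i])
        lines.append(f"{t:<10} {row}")
    return "\n".join(lines) + "\n", mapping


def parse_phylip(text: str) -> DistanceMatrix:
    """Parse a square PHYLIP distance matrix (round-trip of export_phylip)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    ids, rows = [], []
    for ln in lines[1:1 + n]:
        parts = ln.split()
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    M = np.asarray(rows)
    return DistanceMatrix(ids, M, "normalized", np.zeros_like(M, dtype=np.int64))


def distance_matrix_to_tsv(D: DistanceMatrix, path) -> None:
    """Write ids plus the lower triangle as TSV (coordinates 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write(f"# IBS distance matrix, convention={D.convention}\n")
        fh.write("id\t" + "\t".join(D.ids) + "\n")
        for i, sid in enumerate(D.ids):
            vals = "\t".join(f"{D.matrix[i, j]:.6g}" for j in range(i + 1))
            fh.write(f"{sid}\t{vals}\n")
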