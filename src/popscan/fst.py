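"""Per-marker fixation index from expected heterozygosity, and window scans.

The F_ST recipe follows the heterozygosity-proportion definition: with
subpopulation allele frequencies p1, p2 (sample sizes N1, N2) and the
pooled frequency p, H_T = p(1-p), H_S = (N1 p1(1-p1) + N2 p2(1-p2))/N,
and F_ST = 1 - H_S/H_T.  Note H lacks the conventional factor 2; the
ratio H_S/H_T — hence F_ST — is invariant to that factor.  By concavity
of p(1-p), H_S <= H_T, so F_ST lies in [0, 1]; it is undefined when
H_T = 0 (monomorphic pooled sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from popscan.genotypes import MISSING, GenotypeDataset, is_autosome


@dataclass
class MarkerFst:
    marker_id: str
    p1: float
    p2: float
    p: float
    n1: int
    n2: int
    n: int
    h_t: float
    h_s: float
    fst: float          # NaN when undefined
    defined: bool
    reason: str = ""


@dataclass
class WindowFstRecord:
    chrom: str
    start: int          # bp, window [start, start+width)
    end: int
    n_snps: int
    mean_fst: float
    median_fst: float
    ratio_mean: float
    ratio_median: float

    @property
    def coordinate(self) -> str:
        return (f"chr{self.chrom}:{self.start / 1e6:g}-"
                f"{self.end / 1e6:g} Mb")


def marker_fst(counts1, counts2, marker_id: str = "") -> MarkerFst:
    """F_ST at one biallelic marker from genotype counts (n0, n1, n2).

    ``counts*`` are counts of individuals with 0/1/2 copies of allele_b
    among non-missing calls in each subpopulation.
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    n1, n2 = int(c1.sum()), int(c2.sum())
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        return MarkerFst(marker_id, np.nan, np.nan, np.nan, n1, n2, n,
                         np.nan, np.nan, np.nan, False, "empty subpopulation")
    p1 = (c1[1] + 2 * c1[2]) / (2 * n1)
    p2 = (c2[1] + 2 * c2[2]) / (2 * n2)
    p = (c1[1] + 2 * c1[2] + c2[1] + 2 * c2[2]) / (2 * n)
    h_t = p * (1 - p)
    h_s = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / n
    if h_t <= 0:
        return MarkerFst(marker_id, p1, p2, p, n1, n2, n, h_t, h_s,
                         np.nan, False, "H_T = 0")
    fst = 1.0 - h_s / h_t
    return MarkerFst(marker_id, p1, p2, p, n1, n2, n, h_t, h_s,
                     float(max(fst, 0.0)), True)


def dataset_fst(ds: GenotypeDataset, labels) -> pd.DataFrame:
    """Vectorized per-marker F_ST for a two-group split of a dataset.

    ``labels`` maps sample id -> group; exactly two groups required.
    Returns a frame with columns id/chrom/pos/p1/p2/p/n1/n2/fst.
    """
    lab = np.asarray([labels[s] for s in ds.sample_ids])
    groups = np.unique(lab)
    if groups.size != 2:
        raise ValueError("labels must define exactly 2 groups")
    g1 = lab == groups[0]
    G = ds.calls
    obs = G != MISSING

    def freqs(mask):
        sub = G[mask]
        o = obs[mask]
        n = o.sum(axis=0).astype(float)
        alt = np.where(o, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2 * n), np.nan), n

    p1, n1 = freqs(g1)
    p2, n2 = freqs(~g1)
    n = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, (p1 * n1 + p2 * n2) / n, np.nan)
        h_t = p * (1 - p)
        h_s = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / n
        fst = np.where(h_t > 0, 1.0 - h_s / h_t, np.nan)
    fst = np.where(np.isnan(fst), np.nan, np.clip(fst, 0.0, 1.0))
    fst = np.where((n1 == 0) | (n2 == 0), np.nan, fst)
    return pd.DataFrame({
        "id": ds.marker_ids,
        "chrom": ds.chromosomes,
        "pos": ds.positions,
        "p1": p1, "p2": p2, "p": p,
        "n1": n1.astype(int), "n2": n2.astype(int),
        "fst": fst,
    })


def genomewide_fst_summary(fst_values) -> tuple[float, float, int]:
    """(mean, median, n_defined) over markers with defined F_ST only."""
    if isinstance(fst_values, pd.DataFrame):
        fst_values = fst_values["fst"].to_numpy()
    v = np.asarray(fst_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no markers with defined F_ST")
    return float(v.mean()), float(np.median(v)), int(v.size)


def sliding_window_fst(marker_table: pd.DataFrame, width: float = 5e6,
                       step: float = 2.5e6, min_snps: int = 200,
                       autosomes_only: bool = True) -> pd.DataFrame:
    """Sliding-window F_ST scan.

    Windows are anchored at position 0 on each chromosome and advance by
    ``step``; a marker belongs to window [s, s + width) by its bp
    position.  Windows with fewer than ``min_snps`` defined markers are
    suppressed.  Ratio columns divide the window mean/median by the
    genome-wide mean/median (over the same marker set).
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    df = marker_table
    if autosomes_only:
        df = df[df["chrom"].map(is_autosome)]
    df = df.dropna(subset=["fst"])
    gw_mean, gw_median, _ = genomewide_fst_summary(df["fst"].to_numpy())

    records = []
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        fst = sub["fst"].to_numpy()
        last = pos.max()
        s = 0
        while s <= last:
            in_win = (pos >= s) & (pos < s + width)
            k = int(in_win.sum())
            if k >= min_snps:
                mean = float(fst[in_win].mean())
                med = float(np.median(fst[in_win]))
                records.append(WindowFstRecord(
                    str(chrom), int(s), int(s + width), k, mean, med,
                    mean / gw_mean, med / gw_median if gw_median > 0 else np.nan))
            s += int(step)
    out = pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end,
        "coordinate": r.coordinate, "n_snps": r.n_snps,
        "mean_fst": r.mean_fst, "median_fst": r.median_fst,
        "ratio_mean": r.ratio_mean, "ratio_median": r.ratio_median,
    } for r in records])
    out.attrs["genomewide_mean"] = gw_mean
    out.attrs["genomewide_median"] = gw_median
    return out
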