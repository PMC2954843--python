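"""Runs of homozygosity: calling, summaries, group tests, interval scan.

A run of homozygosity (ROH) is an extended stretch of consecutive
autosomal markers at which a sample is homozygous, indicating
autozygosity.  A window of consecutive markers is *valid* when it
contains at most ``max_het`` heterozygous and ``max_missing`` missing
calls, no adjacent-marker gap exceeds ``max_gap_bp``, the segment-level
density satisfies (end - start) / n_snps <= ``min_density_bp_per_snp``,
and it holds at least ``min_snps`` markers.  The caller emits *maximal*
valid windows — windows that cannot be extended by one marker on either
side without violating a constraint — and resolves overlaps
deterministically in favor of the larger SNP count, ties broken by the
smaller start.  Exact agreement with a brute-force window-enumeration
oracle on small instances is enforced by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kruskal, mannwhitneyu

from popscan.genotypes import MISSING, GenotypeDataset, is_autosome
from popscan.stats import fisher_exact_2x2


@dataclass
class ROHParams:
    """Run constraints.  Defaults target ~550K-array marker density.

    ``max_gap_bp`` defaults to 1,000 kb: the conventional inter-marker
    gap limit for array data (a 1 kb limit, occasionally quoted for this
    analysis, would forbid any run at ~5.5 kb mean marker spacing; it
    remains reachable through this field).
    """

    min_snps: int = 100
    max_het: int = 1
    max_missing: int = 5
    min_density_bp_per_snp: int = 50_000
    max_gap_bp: int = 1_000_000

    def __post_init__(self):
        if min(self.min_snps, self.min_density_bp_per_snp, self.max_gap_bp) <= 0:
            raise ValueError("parameters must be positive")
        if self.max_het < 0 or self.max_missing < 0:
            raise ValueError("allowances must be non-negative")
        if self.max_het >= self.min_snps:
            raise ValueError("max_het must be < min_snps")


@dataclass
class ROHSegment:
    """One homozygous run; start/end are first/last SNP positions (1-based)."""

    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def _candidate_windows(pos: np.ndarray, het: np.ndarray, miss: np.ndarray,
                       p: ROHParams) -> list[tuple[int, int]]:
    """All maximal valid windows (index pairs, inclusive) on one chromosome.

    Density is checked through F[k] = pos[k] - d*k: the window [a, b]
    satisfies (pos[b]-pos[a]) <= d*(b-a+1) iff F[b] <= F[a] + d.
    """
    n = pos.size
    d = p.min_density_bp_per_snp
    F = pos.astype(np.int64) - d * np.arange(n, dtype=np.int64)

    # blocks separated by gaps > max_gap_bp
    gaps = np.diff(pos)
    breaks = np.flatnonzero(gaps > p.max_gap_bp)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [n - 1]])

    out: list[tuple[int, int]] = []
    for L, R in zip(starts, ends):
        if R - L + 1 < p.min_snps:
            continue
        # J[a] = max j with het/missing counts within limits: one marker
        # short of the (budget+1)-th event at or after a
        a_arr = np.arange(L, R + 1)
        J = np.full(R - L + 1, R, dtype=np.int64)
        for events, budget in ((np.flatnonzero(het[L:R + 1]) + L, p.max_het),
                               (np.flatnonzero(miss[L:R + 1]) + L,
                                p.max_missing)):
            if events.size == 0:
                continue
            k = np.searchsorted(events, a_arr) + budget
            lim = np.where(k < events.size,
                           events[np.minimum(k, events.size - 1)] - 1, R)
            J = np.minimum(J, lim)
        feasible = np.flatnonzero(J - a_arr + 1 >= p.min_snps) + L
        for a in feasible:
            a = int(a)
            hi = int(J[a - L])
            lo = a + p.min_snps - 1
            if lo > hi:
                continue
            bs = np.arange(lo, hi + 1)
            ok = F[bs] <= F[a] + d
            bs = bs[ok]
            if bs.size == 0:
                continue
            # right-inextensible: at het/miss bound, block end, or next
            # marker would break density
            nxt = np.where(bs < R, F[np.minimum(bs + 1, R)], np.iinfo(np.int64).max)
            right = (bs == hi) | (bs == R) | (nxt > F[a] + d)
            for b in bs[right]:
                b = int(b)
                if a > L:
                    # left extension valid iff within het/miss budget and density
                    if b <= J[a - 1 - L] and F[b] <= F[a - 1] + d:
                        continue
                out.append((a, b))
    return out


def _select_nonoverlapping(cands: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Greedy resolution of overlapping maximal windows.

    Larger SNP count wins; ties broken by smaller start, then smaller end.
    """
    chosen: list[tuple[int, int]] = []
    for a, b in sorted(cands, key=lambda w: (-(w[1] - w[0]), w[0], w[1])):
        if all(b < a2 or a > b2 for a2, b2 in chosen):
            chosen.append((a, b))
    return sorted(chosen)


def call_roh(ds: GenotypeDataset, params: ROHParams | None = None
             ) -> list[ROHSegment]:
    """Call ROH segments for every sample on autosomal markers."""
    p = params or ROHParams()
    segs: list[ROHSegment] = []
    chroms = ds.chromosomes
    pos_all = ds.positions
    for chrom in pd.unique(chroms):
        if not is_autosome(chrom):
            continue
        idx = np.flatnonzero(chroms == chrom)
        pos = pos_all[idx]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"markers on chromosome {chrom} are not sorted")
        if pos.size < p.min_snps:
            continue
        sub = ds.calls[:, idx]
        for i, sid in enumerate(ds.sample_ids):
            g = sub[i]
            het = g == 1
            miss = g == MISSING
            cands = _candidate_windows(pos, het, miss, p)
            for a, b in _select_nonoverlapping(cands):
                segs.append(ROHSegment(
                    sid, str(chrom), int(pos[a]), int(pos[b]),
                    b - a + 1, int(het[a:b + 1].sum()), int(miss[a:b + 1].sum())))
    segs.sort(key=lambda s: (s.sample, s.chrom, s.start))
    return segs


# ---------------------------------------------------------------------------
# Summaries and group comparisons
# ---------------------------------------------------------------------------

def summarize_roh(segments: list[ROHSegment], sample_ids: list[str]
                  ) -> pd.DataFrame:
    """Per-sample ROH count, total length (kb) and average length (kb).

    Samples with zero segments are included with zeros and flagged.
    """
    per: dict[str, list[int]] = {s: [] for s in sample_ids}
    for seg in segments:
        if seg.sample in per:
            per[seg.sample].append(seg.length_bp)
    rows = []
    for sid in sample_ids:
        lengths = per[sid]
        n = len(lengths)
        total_kb = sum(lengths) / 1000.0
        rows.append({"sample": sid, "n_roh": n, "total_kb": total_kb,
                     "avg_kb": total_kb / n if n else 0.0, "no_roh": n == 0})
    return pd.DataFrame(rows)


_METRICS = ("n_roh", "total_kb", "avg_kb")


def compare_roh_groups(summaries: pd.DataFrame, labels) -> pd.DataFrame:
    """Rank-based comparison of ROH summaries between groups.

    For each of n_roh/total_kb/avg_kb: two-sided Wilcoxon rank-sum
    (Mann-Whitney) p for every group pair and the k-group
    Kruskal-Wallis p, plus per-group medians.  Constant metrics yield
    p = 1 with a flag.
    """
    lab = summaries["sample"].map(lambda s: labels[s] if isinstance(labels, dict)
                                  else labels[s])
    groups = sorted(lab.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (lab == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    rows = []
    for metric in _METRICS:
        vals = {g: summaries.loc[lab == g, metric].to_numpy() for g in groups}
        constant = len(np.unique(summaries[metric])) == 1
        row = {"metric": metric, "constant": constant}
        for g in groups:
            row[f"median_{g}"] = float(np.median(vals[g]))
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                key = f"p_{groups[i]}_vs_{groups[j]}"
                if constant:
                    row[key] = 1.0
                else:
                    row[key] = float(mannwhitneyu(
                        vals[groups[i]], vals[groups[j]],
                        alternative="two-sided").pvalue)
        if len(groups) > 2:
            row["p_kruskal"] = 1.0 if constant else float(
                kruskal(*vals.values()).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Endpoint-interval association scan
# ---------------------------------------------------------------------------

def roh_interval_scan(segments: list[ROHSegment], labels,
                      min_carrier_frac: float = 0.05,
                      n_case: int | None = None,
                      n_ctrl: int | None = None,
                      marker_positions: dict[str, np.ndarray] | None = None
                      ) -> pd.DataFrame:
    """Fisher association of ROH carrier status over elementary intervals.

    All distinct segment start/end coordinates per chromosome are
    sorted; each pair of adjacent endpoints bounds an elementary
    interval, within which every sample's carrier status is constant
    (a sample carries the interval iff one of its segments fully covers
    it).  Intervals carried by at least ``floor(min_carrier_frac *
    n_total)`` samples are reported with a two-sided Fisher p and sample
    odds ratio; a Benjamini-Hochberg column is added.  Adjacent
    intervals with identical carrier sets are not merged.

    ``labels`` maps sample id -> 'case'/'control'; ``n_case``/``n_ctrl``
    default to the number of labelled samples of each status.
    """
    if not segments:
        return pd.DataFrame(columns=[
            "chrom", "start", "end", "size_bp", "n_snps", "carriers_case",
            "n_case", "carriers_ctrl", "n_ctrl", "carriers_total", "n_total",
            "odds_ratio", "p_fisher", "p_bh"])
    get = labels.get if isinstance(labels, dict) else labels.__getitem__
    if n_case is None:
        n_case = sum(1 for s in set(labels) if get(s) == "case")
    if n_ctrl is None:
        n_ctrl = sum(1 for s in set(labels) if get(s) == "control")
    n_total = n_case + n_ctrl
    min_carriers = int(np.floor(min_carrier_frac * n_total))

    rows = []
    by_chrom: dict[str, list[ROHSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom, key=str):
        segs = by_chrom[chrom]
        endpoints = sorted({x for s in segs for x in (s.start, s.end)})
        for a, b in zip(endpoints[:-1], endpoints[1:]):
            carriers = {s.sample for s in segs if s.start <= a and s.end >= b}
            if not carriers:
                continue
            cc = sum(1 for s in carriers if get(s) == "case")
            ct = sum(1 for s in carriers if get(s) == "control")
            total = cc + ct
            if total < max(min_carriers, 1):
                continue
            oddsr, pv = fisher_exact_2x2(cc, n_case - cc, ct, n_ctrl - ct)
            nsnp = 0
            if marker_positions is not None and chrom in marker_positions:
                mp = marker_positions[chrom]
                nsnp = int(((mp >= a) & (mp <= b)).sum())
            rows.append({"chrom": chrom, "start": a, "end": b,
                         "size_bp": b - a + 1, "n_snps": nsnp,
                         "carriers_case": cc, "n_case": n_case,
                         "carriers_ctrl": ct, "n_ctrl": n_ctrl,
                         "carriers_total": total, "n_total": n_total,
                         "odds_ratio": oddsr, "p_fisher": pv})
    df = pd.DataFrame(rows)
    if len(df):
        from statsmodels.stats.multitest import multipletests
        df["p_bh"] = multipletests(df["p_fisher"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Age/sex regression
# ---------------------------------------------------------------------------

def roh_age_regression(summaries: pd.DataFrame, age, sex) -> dict[str, pd.DataFrame]:
    """OLS of each ROH summary metric on AGE * SEX(male).

    Fits intercept, AGE, SEX(male) and the AGE x SEX(male) interaction;
    with a single-sex input the sex terms are dropped and flagged via
    the ``single_sex`` attr.  Returns metric -> coefficient table
    (coef, se, p).
    """
    import statsmodels.formula.api as smf

    df = summaries.copy()
    if isinstance(age, dict):
        df["age"] = df["sample"].map(age)
    else:
        df["age"] = np.asarray(age, dtype=float)
    if isinstance(sex, dict):
        df["sex"] = df["sample"].map(sex)
    else:
        df["sex"] = list(sex)
    if df["age"].isna().any() or df["sex"].isna().any():
        raise ValueError("age and sex must be available for all samples")
    df["male"] = (df["sex"] == "male").astype(int)
    single_sex = df["male"].nunique() == 1

    out: dict[str, pd.DataFrame] = {}
    for metric in _METRICS:
        formula = f"{metric} ~ age" if single_sex else f"{metric} ~ age * male"
        fit = smf.ols(formula, data=df).fit()
        tab = pd.DataFrame({"coef": fit.params, "se": fit.bse,
                            "p": fit.pvalues})
        if df[metric].nunique() == 1:
            # degenerate constant outcome: slopes carry no evidence
            tab.loc[tab.index != "Intercept", "p"] = 1.0
            tab.attrs["r2"] = 0.0
            tab.attrs["constant_outcome"] = True
        else:
            tab.attrs["r2"] = float(fit.rsquared)
            tab.attrs["constant_outcome"] = False
        tab.attrs["single_sex"] = single_sex
        out[metric] = tab
    return out


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """BED-like table of segments (1-based inclusive coordinates)."""
    return pd.DataFrame([{
        "sample": s.sample, "chrom": s.chrom, "start": s.start, "end": s.end,
        "n_snps": s.n_snps, "n_het": s.n_het, "n_missing": s.n_missing,
    } for s in segments])
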