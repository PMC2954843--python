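"""Quality control filtering and dataset merging.

The QC procedure is a fixed two-pass design: markers with high
missingness are discarded first, per-individual missingness is then
recomputed on the surviving markers, and finally marker missingness and
minor-allele frequency are re-evaluated on the surviving individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from popscan.genotypes import MISSING, GenotypeDataset, Marker, SampleInfo

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "0": "0"}


@dataclass
class QCReport:
    """Bookkeeping for a QC run; every dropped item has exactly one reason."""

    n_markers_in: int
    n_samples_in: int
    n_markers_out: int
    n_samples_out: int
    dropped_markers: dict[str, str] = field(default_factory=dict)  # id -> reason
    dropped_samples: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        assert self.n_markers_in - len(self.dropped_markers) == self.n_markers_out
        assert self.n_samples_in - len(self.dropped_samples) == self.n_samples_out

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        mk = pd.DataFrame(sorted(self.dropped_markers.items()),
                          columns=["marker", "reason"])
        sm = pd.DataFrame(sorted(self.dropped_samples.items()),
                          columns=["sample", "reason"])
        return mk, sm

    def summary(self) -> str:
        return (f"markers {self.n_markers_in} -> {self.n_markers_out}; "
                f"samples {self.n_samples_in} -> {self.n_samples_out}")


def qc_filter(ds: GenotypeDataset, snp_miss_max: float = 0.05,
              ind_miss_max: float = 0.05, maf_min: float = 0.05
              ) -> tuple[GenotypeDataset, QCReport]:
    """Two-pass QC filter.

    Pass 1 drops markers whose missing-call fraction is >= ``snp_miss_max``.
    Pass 2 recomputes per-individual missingness on the surviving markers
    and keeps individuals with missingness <= ``ind_miss_max``; marker
    missingness (<= ``snp_miss_max``) and MAF (>= ``maf_min``) are then
    re-evaluated on the surviving individuals.
    """
    if ds.n_markers == 0 or ds.n_samples == 0:
        raise ValueError("empty dataset")
    miss = ds.missing_mask()
    dropped_markers: dict[str, str] = {}
    dropped_samples: dict[str, str] = {}

    # pass 1: marker missingness ("5% or more" -> strict >= threshold)
    m_frac = miss.mean(axis=0)
    keep_m = m_frac < snp_miss_max
    for j in np.flatnonzero(~keep_m):
        dropped_markers[ds.markers[j].id] = "missingness"

    # pass 2: individual missingness on surviving markers
    if keep_m.sum() == 0:
        raise ValueError("empty after QC: all markers dropped in pass 1")
    i_frac = miss[:, keep_m].mean(axis=1)
    keep_s = i_frac <= ind_miss_max
    for i in np.flatnonzero(~keep_s):
        dropped_samples[ds.samples[i].id] = "missingness"
    if keep_s.sum() == 0:
        raise ValueError("empty after QC: all samples dropped")

    # re-evaluate marker missingness and MAF on surviving individuals
    sub = ds.subset(np.flatnonzero(keep_s), np.flatnonzero(keep_m))
    m_frac2 = sub.missing_mask().mean(axis=0)
    maf = sub.maf()
    ok_miss = m_frac2 <= snp_miss_max
    ok_maf = np.nan_to_num(maf, nan=-1.0) >= maf_min
    for j in np.flatnonzero(~(ok_miss & ok_maf)):
        reason = "missingness" if not ok_miss[j] else "maf"
        dropped_markers[sub.markers[j].id] = reason
    keep2 = ok_miss & ok_maf
    if keep2.sum() == 0:
        raise ValueError("empty after QC: all markers dropped")
    out = sub.subset(marker_idx=np.flatnonzero(keep2))

    report = QCReport(ds.n_markers, ds.n_samples, out.n_markers, out.n_samples,
                      dropped_markers, dropped_samples)
    return out, report


def _is_ambiguous(a: str, b: str) -> bool:
    return {a, b} in ({"A", "T"}, {"C", "G"})


def merge_datasets(ds1: GenotypeDataset, ds2: GenotypeDataset,
                   keep_ambiguous: bool = False
                   ) -> GenotypeDataset:
    """Merge two QC-filtered datasets on the intersection of marker ids.

    Allele labels of ``ds2`` are harmonized onto ``ds1``: codes are
    swapped (0<->2) when allele_a/allele_b are exchanged, mapped through
    the reverse-complement when the strand differs.  Strand-ambiguous
    A/T and C/G markers are dropped unless ``keep_ambiguous``, in which
    case orientation is inferred by matching allele frequencies.
    Samples are concatenated with cohort labels preserved.
    """
    common = set(ds1.sample_ids) & set(ds2.sample_ids)
    if common:
        raise ValueError(f"sample ids present in both datasets: {sorted(common)[:5]}")
    idx2 = {m.id: j for j, m in enumerate(ds2.markers)}
    shared = [(j1, idx2[m.id]) for j1, m in enumerate(ds1.markers) if m.id in idx2]
    if not shared:
        raise ValueError("no shared markers between datasets")

    f2 = ds2.allele_b_freq()
    f1 = ds1.allele_b_freq()
    keep1, keep2, flip = [], [], []
    dropped: list[str] = []
    for j1, j2 in shared:
        m1, m2 = ds1.markers[j1], ds2.markers[j2]
        pair1, pair2 = (m1.allele_a, m1.allele_b), (m2.allele_a, m2.allele_b)
        if _is_ambiguous(*pair1):
            if not keep_ambiguous:
                dropped.append(m1.id)
                continue
            # frequency-based strand inference: orient ds2 codes so its
            # allele_b frequency best matches ds1's
            do_flip = abs(f1[j1] - f2[j2]) > abs(f1[j1] - (1.0 - f2[j2]))
            keep1.append(j1); keep2.append(j2); flip.append(do_flip)
            continue
        comp2 = (_COMPLEMENT.get(pair2[0], "?"), _COMPLEMENT.get(pair2[1], "?"))
        if pair2 == pair1 or comp2 == pair1:
            do_flip = False
        elif pair2 == pair1[::-1] or comp2 == pair1[::-1]:
            do_flip = True
        elif "0" in pair2 or "0" in pair1:
            # monomorphic in one dataset: align on the observed allele
            if pair2[1] in (pair1[1], _COMPLEMENT.get(pair1[1], "?")):
                do_flip = False
            elif pair2[1] in (pair1[0], _COMPLEMENT.get(pair1[0], "?")):
                do_flip = True
            else:
                dropped.append(m1.id)
                continue
        else:
            dropped.append(m1.id)
            continue
        keep1.append(j1); keep2.append(j2); flip.append(do_flip)

    if not keep1:
        raise ValueError("no mergeable markers after harmonization")
    if dropped:
        import logging
        logging.getLogger(__name__).info(
            "merge: dropped %d ambiguous/incompatible markers", len(dropped))

    calls2 = ds2.calls[:, keep2].copy()
    flip = np.asarray(flip)
    if flip.any():
        cols = calls2[:, flip]
        swapped = np.where(cols == MISSING, MISSING, 2 - cols).astype(np.int8)
        calls2[:, flip] = swapped
    calls = np.vstack([ds1.calls[:, keep1], calls2])
    markers = [ds1.markers[j] for j in keep1]
    samples = ([SampleInfo(**vars(s)) for s in ds1.samples]
               + [SampleInfo(**vars(s)) for s in ds2.samples])
    merged = GenotypeDataset(markers, samples, calls)
    merged.dropped_ambiguous = dropped
    return merged
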