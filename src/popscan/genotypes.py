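"""Genotype data model and readers/writers for PLINK text and VCF.

Genotypes are stored as an ``int8`` matrix of shape
``(n_samples, n_markers)`` counting copies of ``allele_b`` (0, 1, 2)
with :data:`MISSING` (-1) as a distinct sentinel.  ``allele_b`` is, by
the PLINK-text reading convention, the minor allele observed in the
file.  All genomic coordinates are 1-based and inclusive at both ends.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.  Never conflated with code 0.
MISSING: int = -1

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "0": "0"}

_AUTOSOMES = {str(i) for i in range(1, 23)}


def is_autosome(chrom: str) -> bool:
    """True for chromosome labels 1-22, with or without a "chr" prefix."""
    return str(chrom).removeprefix("chr") in _AUTOSOMES


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP.  ``pos`` is the 1-based base-pair position."""

    id: str
    chrom: str
    pos: int
    allele_a: str = "0"
    allele_b: str = "0"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"marker {self.id}: pos must be >= 1, got {self.pos}")
        if self.allele_a == self.allele_b and self.allele_a != "0":
            raise ValueError(f"marker {self.id}: alleles must differ")


@dataclass
class SampleInfo:
    """Per-sample metadata; ``status`` is 'case', 'control' or None."""

    id: str
    cohort: str = ""
    status: str | None = None
    sex: str = "unknown"
    age: float | None = None


class GenotypeDataset:
    """Samples x biallelic markers with genotype codes {0,1,2,MISSING}.

    Parameters
    ----------
    markers : sequence of Marker, within each chromosome sorted by position.
    samples : sequence of SampleInfo with unique ids.
    calls : int array (n_samples, n_markers) counting copies of allele_b.
    """

    def __init__(self, markers: Sequence[Marker], samples: Sequence[SampleInfo],
                 calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(markers)):
            raise ValueError(
                f"calls shape {calls.shape} != (n_samples={len(samples)}, "
                f"n_markers={len(markers)})")
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        ids = [s.id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        self.markers = list(markers)
        self.samples = list(samples)
        self.calls = calls

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.pos for m in self.markers], dtype=np.int64)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([m.chrom for m in self.markers])

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def allele_b_freq(self) -> np.ndarray:
        """Frequency of allele_b per marker over non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        n = obs.sum(axis=0)
        tot = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        f = self.allele_b_freq()
        return np.minimum(f, 1.0 - f)

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeDataset":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeDataset(
            [self.markers[i] for i in mi],
            [self.samples[i] for i in si],
            self.calls[np.ix_(si, mi)],
        )

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(list(self.markers),
                               [SampleInfo(**vars(s)) for s in self.samples],
                               self.calls.copy())

    def autosomal(self) -> "GenotypeDataset":
        keep = [i for i, m in enumerate(self.markers) if is_autosome(m.chrom)]
        return self.subset(marker_idx=keep)

    def __repr__(self):
        return f"GenotypeDataset({self.n_samples} samples x {self.n_markers} markers)"


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)
# ---------------------------------------------------------------------------

def _as_lines(source) -> list[str]:
    if isinstance(source, (str, Path)):
        return Path(source).read_text().splitlines()
    if isinstance(source, io.IOBase):
        return source.read().splitlines()
    return list(source)


def read_plink_text(ped_source, map_source) -> GenotypeDataset:
    """Read whitespace-delimited PLINK .ped/.map files.

    ``allele_b`` is chosen as the minor allele observed in the file,
    ties broken lexicographically; "0 0" denotes a missing genotype.
    """
    map_rows = []
    for ln, line in enumerate(_as_lines(map_source), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f".map line {ln}: expected 4 fields, got {len(parts)}")
        chrom, mid, _gdist, pos = parts
        map_rows.append((chrom, mid, int(pos)))
    n_mark = len(map_rows)

    sample_rows = []
    raw_alleles = []  # per sample: list of (a1, a2)
    for ln, line in enumerate(_as_lines(ped_source), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_mark:
            raise ValueError(
                f".ped line {ln}: expected {6 + 2 * n_mark} fields for "
                f"{n_mark} markers, got {len(parts)}")
        fid, iid, _pat, _mat, sex_code, pheno = parts[:6]
        sex = {"1": "male", "2": "female"}.get(sex_code, "unknown")
        status = {"1": "control", "2": "case"}.get(pheno)
        sample_rows.append(SampleInfo(id=iid, cohort=fid, status=status, sex=sex))
        raw_alleles.append(list(zip(parts[6::2], parts[7::2])))

    n_samp = len(sample_rows)
    markers, calls = [], np.full((n_samp, n_mark), MISSING, dtype=np.int8)
    for j, (chrom, mid, pos) in enumerate(map_rows):
        counts: dict[str, int] = {}
        for i in range(n_samp):
            for a in raw_alleles[i][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise ValueError(f"marker {mid}: more than 2 distinct alleles {sorted(counts)}")
        # minor allele = allele_b; tie broken toward lexicographically smaller
        alleles = sorted(counts, key=lambda a: (counts[a], a))
        if len(alleles) == 2:
            allele_b, allele_a = alleles[0], alleles[1]
        elif len(alleles) == 1:
            allele_b, allele_a = alleles[0], "0"
        else:
            allele_b, allele_a = "0", "0"
        markers.append(Marker(mid, chrom, pos, allele_a, allele_b))
        for i in range(n_samp):
            a1, a2 = raw_alleles[i][j]
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 == allele_b) + (a2 == allele_b)
    return GenotypeDataset(markers, sample_rows, calls)


def write_plink_text(ds: GenotypeDataset, ped_path, map_path) -> None:
    """Write the dataset as PLINK .ped/.map text (missing genotypes as '0 0')."""
    with open(map_path, "w") as fh:
        for m in ds.markers:
            fh.write(f"{m.chrom}\t{m.id}\t0\t{m.pos}\n")
    sex_code = {"male": "1", "female": "2"}
    pheno_code = {"control": "1", "case": "2"}
    with open(ped_path, "w") as fh:
        for i, s in enumerate(ds.samples):
            fields = [s.cohort or "0", s.id, "0", "0",
                      sex_code.get(s.sex, "0"), pheno_code.get(s.status, "0")]
            row = ds.calls[i]
            for j, m in enumerate(ds.markers):
                g = row[j]
                if g == MISSING:
                    fields += ["0", "0"]
                else:
                    a = m.allele_a if m.allele_a != "0" else "A"
                    b = m.allele_b if m.allele_b != "0" else "B"
                    fields += {0: [a, a], 1: [a, b], 2: [b, b]}[int(g)]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path) -> GenotypeDataset:
    """Read biallelic SNP records with a GT field from a VCF file.

    GT 0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> missing.  Multiallelic or
    non-SNP records are skipped; the skip count is stored on the returned
    dataset as ``n_skipped_multiallelic`` and logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_rows = [SampleInfo(id=s) for s in vcf.samples]
    markers, rows = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        if var.format("GT") is None and var.gt_types is None:
            raise ValueError(f"record {var.CHROM}:{var.POS} has no GT field")
        markers.append(Marker(var.ID or f"{var.CHROM}:{var.POS}",
                              str(var.CHROM), var.POS, var.REF, var.ALT[0]))
        # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = var.gt_types
        code = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(code.astype(np.int8))
    if not markers:
        raise ValueError("no usable biallelic SNP records in VCF")
    calls = np.stack(rows, axis=1)
    ds = GenotypeDataset(markers, sample_rows, calls)
    ds.n_skipped_multiallelic = n_skipped
    if n_skipped:
        log.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    return ds


def write_vcf(ds: GenotypeDataset, path) -> None:
    """Write a minimal VCF 4.2 with GT only; allele_a as REF, allele_b as ALT."""
    chroms = sorted({m.chrom for m in ds.markers}, key=str)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popscan\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ds.sample_ids) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, m in enumerate(ds.markers):
            ref = m.allele_a if m.allele_a != "0" else "A"
            alt = m.allele_b if m.allele_b != "0" else "C"
            gts = "\t".join(gt_str[int(g)] for g in ds.calls[:, j])
            fh.write(f"{m.chrom}\t{m.pos}\t{m.id}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Sample metadata TSV
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV with columns id/cohort/status/sex/age."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "cohort", "status", "sex", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return df


def attach_metadata(ds: GenotypeDataset, meta: pd.DataFrame) -> GenotypeDataset:
    """Fill SampleInfo fields in-place from a metadata table; returns ds."""
    idx = meta.set_index("id")
    for s in ds.samples:
        if s.id in idx.index:
            row = idx.loc[s.id]
            s.cohort = str(row["cohort"])
            s.status = None if pd.isna(row["status"]) else str(row["status"])
            s.sex = str(row["sex"]) if not pd.isna(row["sex"]) else "unknown"
            s.age = None if pd.isna(row["age"]) else float(row["age"])
    return ds
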