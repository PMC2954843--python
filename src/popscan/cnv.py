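"""CNV call parsing, size-class summaries and case/control burden tests.

Input is the text dialect of array CNV callers ("rawcnv" lines):

    chr1:144943150-145824905 numsnp=207 length=881,756 state5,cn=3 AC0037 \
startsnp=rs6656361 endsnp=rs11240147

Copy number 2 is diploid and therefore not a variant call; such lines
are rejected.  Size classification uses the call record's length field
when present (honoring the source tool's reporting, which can differ
from the coordinate span), else the span.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from popscan.stats import fisher_exact_2x2


@dataclass
class CNVCall:
    chrom: str
    start: int                  # 1-based inclusive
    end: int
    n_snps: int
    copy_number: int            # in {0, 1, 3, 4+}; never 2
    sample: str
    length_kb: float | None = None   # from the call record when present
    start_snp: str | None = None
    end_snp: str | None = None

    def __post_init__(self):
        if self.copy_number == 2:
            raise ValueError("copy number 2 is not a variant")
        if self.end < self.start:
            raise ValueError("end < start")
        if self.length_kb is None:
            self.length_kb = (self.end - self.start + 1) / 1000.0

    @property
    def span_kb(self) -> float:
        return (self.end - self.start + 1) / 1000.0

    @property
    def is_duplication(self) -> bool:
        return self.copy_number > 2

    @property
    def is_deletion(self) -> bool:
        return self.copy_number < 2


_LINE_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>[\d,]+)\s+"
    r"length=(?P<length>[\d,]+)\s+"
    r"state\d+,cn=(?P<cn>\d+)\s+"
    r"(?P<sample>\S+)"
    r"(?:\s+startsnp=(?P<startsnp>\S+))?"
    r"(?:\s+endsnp=(?P<endsnp>\S+))?")


class RawCNVParseError(ValueError):
    pass


def read_rawcnv(source) -> tuple[list[CNVCall], list[tuple[int, str, str]]]:
    """Parse rawcnv text; returns (calls, errors).

    ``errors`` collects (line_number, line, reason) for malformed or
    rejected lines — they are reported, never silently dropped.  A file
    with no parsable lines raises :class:`RawCNVParseError`.
    """
    if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source
            and Path(source).exists()):
        lines = Path(source).read_text().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in source]
    calls: list[CNVCall] = []
    errors: list[tuple[int, str, str]] = []
    for ln, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        m = _LINE_RE.match(line.strip())
        if not m:
            errors.append((ln, line, "unparsable line"))
            continue
        cn = int(m["cn"])
        if cn == 2:
            errors.append((ln, line, "copy number 2 is not a variant"))
            continue
        length_bp = int(m["length"].replace(",", ""))
        calls.append(CNVCall(
            chrom=m["chrom"], start=int(m["start"]), end=int(m["end"]),
            n_snps=int(m["numsnp"].replace(",", "")), copy_number=cn,
            sample=m["sample"], length_kb=length_bp / 1000.0,
            start_snp=m["startsnp"], end_snp=m["endsnp"]))
    if not calls:
        raise RawCNVParseError("no parsable CNV calls in input")
    return calls, errors


def write_rawcnv(calls: list[CNVCall], path) -> None:
    state = {0: 1, 1: 2, 3: 5, 4: 6}
    with open(path, "w") as fh:
        for c in calls:
            extra = ""
            if c.start_snp:
                extra += f" startsnp={c.start_snp}"
            if c.end_snp:
                extra += f" endsnp={c.end_snp}"
            fh.write(
                f"{c.chrom}:{c.start}-{c.end} numsnp={c.n_snps} "
                f"length={int(round(c.length_kb * 1000)):,} "
                f"state{state.get(c.copy_number, 9)},cn={c.copy_number} "
                f"{c.sample}{extra}\n")


def filter_cnv(calls: list[CNVCall], min_snps: int = 10) -> list[CNVCall]:
    """Retain calls supported by at least ``min_snps`` SNPs (inclusive)."""
    return [c for c in calls if c.n_snps >= min_snps]


_CN_CLASSES = (0, 1, 3, 4)


def size_class_summary(calls: list[CNVCall], labels, group_sizes: dict[str, int],
                       thresholds_kb=(500, 1000, 2000)) -> pd.DataFrame:
    """Counts of calls above each size threshold, per group and CN class.

    Percentages follow the CNV-count-over-sample-count convention:
    100 * count / group size.  Size thresholds are strict ( > t kb ).
    """
    get = labels.get if isinstance(labels, dict) else labels.__getitem__
    for c in calls:
        if get(c.sample) is None:
            raise ValueError(f"sample {c.sample!r} has no group label")
    rows = []
    for t in thresholds_kb:
        big = [c for c in calls if c.length_kb > t]
        for group, size in group_sizes.items():
            sub = [c for c in big if get(c.sample) == group]
            row = {"threshold_kb": t, "group": group, "group_size": size,
                   "all": len(sub), "all_pct": 100.0 * len(sub) / size}
            for cn in _CN_CLASSES:
                k = sum(1 for c in sub if c.copy_number == cn)
                row[f"cn{cn}"] = k
                row[f"cn{cn}_pct"] = 100.0 * k / size
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BurdenResult:
    threshold_kb: float
    carriers_case: int
    n_case: int
    carriers_ctrl: int
    n_ctrl: int
    odds_ratio: float
    p_fisher: float

    @property
    def case_pct(self) -> float:
        return 100.0 * self.carriers_case / self.n_case

    @property
    def ctrl_pct(self) -> float:
        return 100.0 * self.carriers_ctrl / self.n_ctrl


def burden_test(calls: list[CNVCall], labels, group_sizes: dict[str, int],
                threshold_kb: float = 2000) -> BurdenResult:
    """Fisher test of carrying >= 1 CNV larger than ``threshold_kb``.

    A sample counts once regardless of how many qualifying calls it has.
    ``group_sizes`` must give {'case': N, 'control': N} — denominators
    are supplied by the caller, never inferred from the call list.
    """
    get = labels.get if isinstance(labels, dict) else labels.__getitem__
    carriers: dict[str, set[str]] = {"case": set(), "control": set()}
    for c in calls:
        if c.length_kb > threshold_kb:
            status = get(c.sample)
            if status not in carriers:
                raise ValueError(f"sample {c.sample!r} has no case/control label")
            carriers[status].add(c.sample)
    n_case, n_ctrl = group_sizes["case"], group_sizes["control"]
    cc, ct = len(carriers["case"]), len(carriers["control"])
    if cc > n_case or ct > n_ctrl:
        raise ValueError("more distinct carriers than the supplied group size")
    if cc == 0 and ct == 0:
        return BurdenResult(threshold_kb, 0, n_case, 0, n_ctrl, 1.0, 1.0)
    oddsr, p = fisher_exact_2x2(cc, n_case - cc, ct, n_ctrl - ct)
    return BurdenResult(threshold_kb, cc, n_case, ct, n_ctrl, oddsr, p)


def bundled_large_cnv_calls() -> tuple[list[CNVCall], list[CNVCall]]:
    """Bundled inventory of large (>500 kb) CNV calls.

    The inventory reproduces the published large-CNV tables of a
    103-case / 197-control SNP-array cohort (lengths as printed by the
    calling tool, which may differ slightly from the coordinate span).
    Returns (case_calls, control_calls).
    """
    pkg = resources.files("popscan") / "data"
    cases, _ = read_rawcnv((pkg / "large_cnv_cases.rawcnv").read_text())
    ctrls, _ = read_rawcnv((pkg / "large_cnv_controls.rawcnv").read_text())
    return cases, ctrls
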