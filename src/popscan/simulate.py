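"""Synthetic study generator with known ground truth.

Generates every input the pipeline consumes: structured two-cohort
genotypes under the Balding-Nichols model, planted homozygous tracts,
duplicate and parent-offspring pairs, CNV call sets, and age/sex
covariates.  All randomness flows from a single seed through
``numpy.random.default_rng``, so a fixed configuration is byte-for-byte
reproducible.  No linkage disequilibrium is simulated: none of the
downstream statistics model LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from popscan.cnv import CNVCall
from popscan.genotypes import MISSING, GenotypeDataset, Marker, SampleInfo


@dataclass
class ChromLayout:
    """Markers are laid down at fixed ``spacing_bp`` (default 5 kb, the
    genome density of a ~550K array) starting at ``spacing_bp``."""

    chrom_markers: list[tuple[str, int]] = field(
        default_factory=lambda: [("1", 4000)])
    spacing_bp: int = 5000


@dataclass
class SimulationConfig:
    """Study conditions for a structured two-cohort simulation.

    Defaults mirror a small case/control array study: two cohorts of
    103 and 203 subjects, low between-cohort differentiation
    (F_ST ~ 0.005, the order seen between neighboring European
    populations), ancestral minor-allele frequencies uniform on
    [0.05, 0.5], and 1% random missingness.
    """

    seed: int
    n_pop1: int = 103
    n_pop2: int = 203
    layout: ChromLayout = field(default_factory=ChromLayout)
    fst: float = 0.005
    maf_bounds: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must be in (0, 1)")

    @property
    def n_markers(self) -> int:
        return sum(n for _, n in self.layout.chrom_markers)


def _markers_from_layout(layout: ChromLayout) -> list[Marker]:
    markers = []
    for chrom, n in layout.chrom_markers:
        for k in range(n):
            pos = (k + 1) * layout.spacing_bp
            markers.append(Marker(f"snp_{chrom}_{k + 1}", chrom, pos, "A", "C"))
    return markers


def simulate_structured_cohort(cfg: SimulationConfig) -> GenotypeDataset:
    """Balding-Nichols genotypes for two cohorts.

    Ancestral frequency p ~ Uniform(maf_bounds); cohort frequencies
    ~ Beta(p(1-F)/F, (1-p)(1-F)/F) independently per cohort; genotypes
    Binomial(2, p_cohort); missing calls at ``missing_rate`` uniformly
    at random.  With ``n_pop2=0`` a single panmictic cohort is drawn at
    the ancestral frequencies.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_markers
    markers = _markers_from_layout(cfg.layout)
    p_anc = rng.uniform(*cfg.maf_bounds, size=m)
    F = cfg.fst

    def pop_freq():
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        return rng.beta(a, b)

    samples, blocks = [], []
    for pop, n in (("pop1", cfg.n_pop1), ("pop2", cfg.n_pop2)):
        if n == 0:
            continue
        pf = pop_freq() if cfg.n_pop2 > 0 else p_anc
        blocks.append(rng.binomial(2, pf, size=(n, m)).astype(np.int8))
        samples.extend(SampleInfo(id=f"{pop}_{i + 1:04d}", cohort=pop)
                       for i in range(n))
    calls = np.vstack(blocks)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING
    ds = GenotypeDataset(markers, samples, calls)
    ds.ancestral_freq = p_anc
    return ds


def plant_roh(ds: GenotypeDataset, region: tuple[str, int, int],
              carrier_ids: list[str], het_flank: int = 0) -> GenotypeDataset:
    """Overwrite a region to be fully homozygous in the carriers.

    Each marker in ``region`` (chrom, start, end; 1-based inclusive) is
    set to the homozygote of the allele the carrier already holds more
    copies of (heterozygotes and missing calls become allele_b
    homozygotes when the carrier has >= 1 copy, else allele_a).
    ``het_flank`` > 0 additionally forces that many markers immediately
    outside each edge heterozygous in carriers, sharply delimiting the
    planted tract for endpoint-recovery studies.  Non-carriers are
    untouched.  Returns a modified copy.
    """
    chrom, start, end = region
    out = ds.copy()
    chroms = out.chromosomes
    pos = out.positions
    on_chrom = np.flatnonzero(chroms == str(chrom))
    inside = on_chrom[(pos[on_chrom] >= start) & (pos[on_chrom] <= end)]
    if inside.size == 0:
        raise ValueError(f"region {region} contains no markers")
    sidx = {s: i for i, s in enumerate(out.sample_ids)}
    rows = [sidx[c] for c in carrier_ids]
    block = out.calls[np.ix_(rows, inside)]
    out.calls[np.ix_(rows, inside)] = np.where(block >= 1, 2, 0).astype(np.int8)
    if het_flank > 0:
        lo = on_chrom[on_chrom < inside[0]][-het_flank:]
        hi = on_chrom[on_chrom > inside[-1]][:het_flank]
        flank = np.concatenate([lo, hi])
        out.calls[np.ix_(rows, flank)] = 1
    return out


@dataclass
class RelatednessPlan:
    n_duplicates: int = 1
    n_parent_offspring: int = 2


def simulate_relatives(ds: GenotypeDataset, plan: RelatednessPlan, seed: int
                       ) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Append duplicate and parent-offspring samples.

    Duplicates copy an existing sample's genotypes; offspring inherit
    one allele per marker from the parent and draw the other from the
    sample allele frequency.  Returns the extended dataset and a
    ground-truth table (kind, parent id, new id, expected pi-hat).
    """
    total = plan.n_duplicates + plan.n_parent_offspring
    if total > ds.n_samples:
        raise ValueError("plan exceeds population size")
    rng = np.random.default_rng(seed)
    donors = rng.choice(ds.n_samples, size=total, replace=False)
    freq = np.nan_to_num(ds.allele_b_freq(), nan=0.5)
    new_rows, new_samples, truth = [], [], []
    k = 0
    for _ in range(plan.n_duplicates):
        i = donors[k]; k += 1
        new_id = f"dup_of_{ds.sample_ids[i]}"
        new_rows.append(ds.calls[i].copy())
        new_samples.append(SampleInfo(id=new_id, cohort=ds.samples[i].cohort))
        truth.append(("duplicate", ds.sample_ids[i], new_id, 1.0))
    for _ in range(plan.n_parent_offspring):
        i = donors[k]; k += 1
        g = ds.calls[i]
        # transmitted allele: 0 or 1 copy of allele_b from the parent
        transmit = np.where(g == 1, rng.integers(0, 2, size=g.size),
                            (g == 2).astype(np.int64))
        other = (rng.random(g.size) < freq).astype(np.int64)
        child = (transmit + other).astype(np.int8)
        child[g == MISSING] = MISSING
        new_id = f"child_of_{ds.sample_ids[i]}"
        new_rows.append(child)
        new_samples.append(SampleInfo(id=new_id, cohort=ds.samples[i].cohort))
        truth.append(("parent_offspring", ds.sample_ids[i], new_id, 0.5))
    ext = GenotypeDataset(
        list(ds.markers),
        [SampleInfo(**vars(s)) for s in ds.samples] + new_samples,
        np.vstack([ds.calls] + [r[None, :] for r in new_rows]))
    return ext, pd.DataFrame(truth, columns=["kind", "donor", "new_id",
                                             "expected_pihat"])


@dataclass
class CNVPlan:
    """Per-group carrier rates for large (>2 Mb) calls plus background calls.

    Default rates are anchored at the observed design of a small
    case/control array study: ~5% of cases and ~0.5% of controls carry a >2 Mb
    rearrangement; background calls 100 kb - 2 Mb occur at ~1 call per
    sample with a log-uniform size distribution.
    """

    case_rate_large: float = 0.05
    control_rate_large: float = 0.005
    large_size_range_kb: tuple[float, float] = (2000.0, 20000.0)
    background_calls_per_sample: float = 1.0
    background_size_range_kb: tuple[float, float] = (100.0, 2000.0)
    cn_mix: dict[int, float] = field(
        default_factory=lambda: {1: 0.45, 3: 0.45, 0: 0.05, 4: 0.05})
    snp_spacing_bp: int = 5000
    chrom_length_bp: int = 200_000_000


def simulate_cnv_calls(plan: CNVPlan, labels: dict[str, str], seed: int
                       ) -> tuple[list[CNVCall], set[str]]:
    """Simulate a rawcnv-style call set; returns (calls, large-carrier ids)."""
    rng = np.random.default_rng(seed)
    cns = list(plan.cn_mix)
    cnp = np.array([plan.cn_mix[c] for c in cns], dtype=float)
    cnp /= cnp.sum()

    def one_call(sample: str, size_range: tuple[float, float]) -> CNVCall:
        lo, hi = size_range
        size_kb = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        start = int(rng.integers(1, plan.chrom_length_bp))
        end = start + int(size_kb * 1000) - 1
        n_snps = max(1, int(size_kb * 1000 / plan.snp_spacing_bp))
        chrom = f"chr{rng.integers(1, 23)}"
        return CNVCall(chrom, start, end, n_snps,
                       int(rng.choice(cns, p=cnp)), sample,
                       length_kb=size_kb)

    calls: list[CNVCall] = []
    large_carriers: set[str] = set()
    for sample, status in labels.items():
        rate = (plan.case_rate_large if status == "case"
                else plan.control_rate_large)
        if rng.random() < rate:
            calls.append(one_call(sample, plan.large_size_range_kb))
            large_carriers.add(sample)
        for _ in range(rng.poisson(plan.background_calls_per_sample)):
            calls.append(one_call(sample, plan.background_size_range_kb))
    return calls, large_carriers


@dataclass
class AgeSexModel:
    age_mean: float = 21.5
    age_sd: float = 10.3
    age_range: tuple[float, float] = (4.0, 45.0)
    male_fraction: float = 81 / 103


def simulate_phenotypes(ids: list[str], model: AgeSexModel, seed: int
                        ) -> pd.DataFrame:
    """Ages from a normal truncated to ``age_range``; sex Bernoulli(male)."""
    rng = np.random.default_rng(seed)
    lo, hi = model.age_range
    ages = np.empty(len(ids))
    for i in range(len(ids)):
        a = rng.normal(model.age_mean, model.age_sd)
        while not (lo <= a <= hi):
            a = rng.normal(model.age_mean, model.age_sd)
        ages[i] = round(a, 1)
    male = rng.random(len(ids)) < model.male_fraction
    return pd.DataFrame({"id": ids, "age": ages,
                         "sex": np.where(male, "male", "female")})
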