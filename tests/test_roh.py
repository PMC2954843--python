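"""ROH calling (vs exhaustive oracle), summaries, interval scan, regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from popscan import (
    call_roh, compare_roh_groups, fisher_exact_2x2, roh_age_regression,
    roh_interval_scan, summarize_roh,
)
from popscan.roh import ROHParams, ROHSegment
from conftest import make_dataset
from oracles import fisher_two_sided_oracle, roh_windows_oracle


# ---------------------------------------------------------------------------
# call_roh
# ---------------------------------------------------------------------------

def _single_sample(geno, positions):
    return make_dataset(np.asarray(geno, dtype=np.int8)[None, :],
                        positions=positions)


class TestCallROH:
    def test_long_homozygous_run_called_in_full(self):
        pos = (np.arange(150) + 1) * 1000
        ds = _single_sample([0] * 150, pos)
        segs = call_roh(ds)
        assert len(segs) == 1
        s = segs[0]
        assert (s.start, s.end, s.n_snps, s.n_het) == (1000, 150000, 150, 0)

    def test_below_min_snps_no_call(self):
        pos = (np.arange(99) + 1) * 1000
        assert call_roh(_single_sample([2] * 99, pos)) == []

    def test_one_heterozygote_allowed_two_break_the_run(self):
        geno = [0] * 150
        geno[75] = 1
        pos = (np.arange(150) + 1) * 1000
        segs = call_roh(_single_sample(geno, pos))
        assert len(segs) == 1 and segs[0].n_snps == 150 and segs[0].n_het == 1

        geno[40] = 1   # second het: no 100-SNP window with <= 1 het remains
        segs = call_roh(_single_sample(geno, pos))
        assert all(s.n_snps >= 100 for s in segs)
        assert segs == [] or max(s.n_snps for s in segs) < 150

    def test_gap_splits_run(self):
        pos = np.concatenate([(np.arange(120) + 1) * 1000,
                              2_000_000 + (np.arange(120) + 1) * 1000])
        segs = call_roh(_single_sample([0] * 240, pos))
        assert len(segs) == 2
        assert {s.n_snps for s in segs} == {120}

    def test_density_constraint_blocks_sparse_run(self):
        pos = (np.arange(150) + 1) * 60_000     # 60 kb spacing > 50 kb/SNP
        assert call_roh(_single_sample([0] * 150, pos)) == []

    def test_unsorted_markers_raise(self):
        pos = [1000, 3000, 2000] + list(np.arange(4, 151) * 1000)
        with pytest.raises(ValueError, match="not sorted"):
            call_roh(_single_sample([0] * 150, pos))

    def test_non_autosomes_excluded(self):
        pos = (np.arange(150) + 1) * 1000
        ds = make_dataset(np.zeros((1, 150), dtype=np.int8), positions=pos,
                          chrom="X")
        assert call_roh(ds) == []


def _oracle_check(pos, geno, params):
    ds = _single_sample(geno, pos)
    segs = call_roh(ds, params)
    got = [(int(np.searchsorted(pos, s.start)),
            int(np.searchsorted(pos, s.end))) for s in segs]
    want = roh_windows_oracle(pos, geno, params.min_snps, params.max_het,
                              params.max_missing,
                              params.min_density_bp_per_snp,
                              params.max_gap_bp)
    assert got == want, (pos.tolist(), geno.tolist(), params)


@st.composite
def roh_instance(draw):
    n = draw(st.integers(5, 200))
    seed = draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    gaps = rng.choice([500, 1000, 5000, 40_000, 120_000],
                      p=[0.3, 0.3, 0.3, 0.07, 0.03], size=n)
    pos = np.cumsum(gaps) + 1
    het_rate = draw(st.sampled_from([0.02, 0.1, 0.3]))
    miss_rate = draw(st.sampled_from([0.0, 0.05]))
    geno = rng.choice([0, 2], size=n)
    geno[rng.random(n) < het_rate] = 1
    geno[rng.random(n) < miss_rate] = -1
    params = ROHParams(
        min_snps=draw(st.sampled_from([3, 5, 10, 25])),
        max_het=draw(st.sampled_from([0, 1, 2])),
        max_missing=draw(st.sampled_from([0, 1, 5])),
        min_density_bp_per_snp=draw(st.sampled_from([2_000, 20_000, 50_000])),
        max_gap_bp=draw(st.sampled_from([30_000, 100_000, 1_000_000])))
    return pos, geno, params


@settings(max_examples=250, deadline=None, derandomize=True)
@given(roh_instance())
def test_caller_matches_enumeration_oracle(instance):
    """The fast scan emits exactly the brute-force maximal windows."""
    pos, geno, params = instance
    _oracle_check(pos, geno, params)


def test_caller_matches_oracle_on_het_placement_example():
    # 150 homozygous SNPs with heterozygotes at ordinal positions 60 and 90:
    # semantics defined by the exhaustive enumeration
    pos = (np.arange(150) + 1) * 1000
    geno = np.zeros(150, dtype=np.int8)
    geno[59] = geno[89] = 1
    params = ROHParams(min_snps=20)
    _oracle_check(pos, geno, params)


# ---------------------------------------------------------------------------
# Summaries and group comparisons
# ---------------------------------------------------------------------------

class TestSummaries:
    def test_totals_and_average(self):
        segs = [ROHSegment("a", "1", 1, 1_000_000, 200, 0, 0),
                ROHSegment("a", "2", 1, 2_000_000, 400, 1, 0)]
        df = summarize_roh(segs, ["a", "b"])
        a = df[df["sample"] == "a"].iloc[0]
        assert a.n_roh == 2
        assert a.total_kb == pytest.approx(3000.0)
        assert a.avg_kb == pytest.approx(1500.0)
        b = df[df["sample"] == "b"].iloc[0]
        assert (b.n_roh, b.total_kb, b.avg_kb) == (0, 0.0, 0.0)
        assert bool(b.no_roh)

    def test_planted_tract_counts(self):
        from popscan.simulate import ChromLayout, SimulationConfig, \
            plant_roh, simulate_structured_cohort
        cfg = SimulationConfig(seed=21, n_pop1=30, n_pop2=0,
                               layout=ChromLayout([("1", 4000)]),
                               missing_rate=0.0)
        ds = simulate_structured_cohort(cfg)
        regions = [("1", 2_000_000, 4_000_000), ("1", 8_000_000, 10_000_000),
                   ("1", 14_000_000, 16_000_000)]
        for reg in regions:
            ds = plant_roh(ds, reg, ds.sample_ids, het_flank=2)
        df = summarize_roh(call_roh(ds), ds.sample_ids)
        assert df["n_roh"].median() == 3

    def test_identical_groups_all_p_one(self):
        df = pd.DataFrame({"sample": [f"s{i}" for i in range(8)],
                           "n_roh": [3] * 8, "total_kb": [100.0] * 8,
                           "avg_kb": [33.3] * 8})
        labels = {f"s{i}": "a" if i < 4 else "b" for i in range(8)}
        res = compare_roh_groups(df, labels)
        assert (res.filter(like="p_") == 1.0).all().all()

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(12)
        n = 50
        base = rng.normal(20_000, 2_000, size=2 * n)
        base[n:] += 10_000
        df = pd.DataFrame({"sample": [f"s{i}" for i in range(2 * n)],
                           "n_roh": 10, "total_kb": base, "avg_kb": 1.0})
        labels = {f"s{i}": "a" if i < n else "b" for i in range(2 * n)}
        res = compare_roh_groups(df, labels)
        assert res.set_index("metric").loc["total_kb", "p_a_vs_b"] < 1e-3


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

class TestFisher:
    @pytest.mark.parametrize("table,expect_p", [
        ((12, 91, 5, 193), 0.0025),    # reported ROH interval, chromosome 2
        ((15, 88, 9, 189), 0.0034),    # reported ROH interval, chromosome 6
        ((5, 98, 1, 196), 0.019),      # >2 Mb CNV burden
    ])
    def test_reported_contingency_tables(self, table, expect_p):
        oracle_p = fisher_two_sided_oracle(*table)
        oddsr, p = fisher_exact_2x2(*table)
        assert p == pytest.approx(oracle_p, rel=1e-9)
        assert float(f"{p:.2g}") == expect_p

    def test_symmetric_table(self):
        oddsr, p = fisher_exact_2x2(1, 1, 1, 1)
        assert (oddsr, p) == (1.0, 1.0)

    def test_haldane_or_on_zero_cell(self):
        oddsr, _ = fisher_exact_2x2(5, 95, 0, 100)
        assert oddsr == pytest.approx(5.5 * 100.5 / (95.5 * 0.5))

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60),
           st.integers(0, 60))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0 or (a + b == 0) or (c + d == 0):
            return
        _, p = fisher_exact_2x2(a, b, c, d)
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d),
                                  rel=1e-10, abs=1e-12)

    def test_one_sided_tail_monotone_in_case_carriers(self):
        from scipy.stats import fisher_exact as fe
        prev = 1.1
        for cc in range(0, 15):
            p = fe([[cc, 100 - cc], [5, 195]], alternative="greater")[1]
            assert p <= prev + 1e-12
            prev = p


# ---------------------------------------------------------------------------
# Endpoint-interval scan
# ---------------------------------------------------------------------------

def _labels(n_case, n_ctrl):
    lab = {f"case{i}": "case" for i in range(n_case)}
    lab.update({f"ctrl{i}": "control" for i in range(n_ctrl)})
    return lab


class TestIntervalScan:
    def test_single_segment_small_cohort_emitted(self):
        segs = [ROHSegment("case0", "1", 100, 500, 50, 0, 0)]
        res = roh_interval_scan(segs, _labels(5, 5))
        assert len(res) == 1
        r = res.iloc[0]
        assert (r.carriers_case, r.carriers_ctrl) == (1, 0)
        assert (r.n_case, r.n_ctrl) == (5, 5)

    def test_identical_spans_give_one_interval_two_carriers(self):
        segs = [ROHSegment("case0", "1", 100, 500, 50, 0, 0),
                ROHSegment("ctrl0", "1", 100, 500, 50, 0, 0)]
        res = roh_interval_scan(segs, _labels(3, 3))
        assert len(res) == 1
        assert res.iloc[0].carriers_total == 2

    def test_offset_segments_make_elementary_intervals(self):
        segs = [ROHSegment("case0", "1", 100, 500, 50, 0, 0),
                ROHSegment("ctrl0", "1", 300, 700, 50, 0, 0)]
        res = roh_interval_scan(segs, _labels(3, 3), min_carrier_frac=0.0)
        # endpoints 100,300,500,700 -> three intervals, middle shared
        assert list(res["start"]) == [100, 300, 500]
        assert list(res["carriers_total"]) == [1, 2, 1]

    def test_carrier_floor_threshold(self):
        segs = [ROHSegment("case0", "1", 100, 500, 50, 0, 0)]
        # n_total=40 -> floor(0.05*40)=2 > 1 carrier -> suppressed
        assert len(roh_interval_scan(segs, _labels(20, 20))) == 0

    def test_interval_tiling_conserves_union_length(self):
        rng = np.random.default_rng(3)
        segs = []
        for i in range(30):
            s = int(rng.integers(1, 10_000))
            e = s + int(rng.integers(100, 5_000))
            who = f"case{i % 5}" if i % 2 else f"ctrl{i % 5}"
            segs.append(ROHSegment(who, "1", s, e, 10, 0, 0))
        res = roh_interval_scan(segs, _labels(5, 5), min_carrier_frac=0.0)
        tiled = (res["end"] - res["start"]).sum()
        # union length via sweep over merged spans
        spans = sorted((s.start, s.end) for s in segs)
        union, cur_s, cur_e = 0, *spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                union += cur_e - cur_s
                cur_s, cur_e = s, e
        union += cur_e - cur_s
        assert tiled == union

    def test_empty_input_empty_result(self):
        assert len(roh_interval_scan([], _labels(2, 2))) == 0


# ---------------------------------------------------------------------------
# AGE * SEX regression
# ---------------------------------------------------------------------------

class TestAgeRegression:
    def _summaries(self, y):
        return pd.DataFrame({"sample": [f"s{i}" for i in range(len(y))],
                             "n_roh": y, "total_kb": y, "avg_kb": y})

    def test_age_slope_recovered(self):
        rng = np.random.default_rng(7)
        n = 100
        age = rng.uniform(4, 45, size=n)
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        y = 2000 - 10 * age + rng.normal(0, 50, size=n)
        tabs = roh_age_regression(self._summaries(y), dict(zip(
            [f"s{i}" for i in range(n)], age)), dict(zip(
            [f"s{i}" for i in range(n)], sex)))
        coef = tabs["total_kb"].loc["age", "coef"]
        assert coef == pytest.approx(-10, abs=1.0)

    def test_constant_outcome_flat_fit(self):
        n = 40
        rng = np.random.default_rng(5)
        age = rng.uniform(10, 40, n)
        sex = ["male"] * 20 + ["female"] * 20
        tabs = roh_age_regression(self._summaries(np.full(n, 7.0)),
                                  list(age), sex)
        tab = tabs["n_roh"]
        assert tab.attrs["r2"] == pytest.approx(0.0, abs=1e-10)

    def test_single_sex_drops_interaction(self):
        n = 30
        rng = np.random.default_rng(6)
        age = rng.uniform(10, 40, n)
        tabs = roh_age_regression(self._summaries(rng.normal(size=n)),
                                  list(age), ["male"] * n)
        assert tabs["n_roh"].attrs["single_sex"]
        assert "male" not in tabs["n_roh"].index

    def test_duplicated_design_rows_leave_coefficients_unchanged(self):
        rng = np.random.default_rng(7)
        n = 40
        age = rng.uniform(4, 45, n)
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        y = 100 + 3 * age + rng.normal(0, 5, n)
        one = roh_age_regression(self._summaries(y), list(age), list(sex))
        df2 = self._summaries(np.concatenate([y, y]))
        df2["sample"] = [f"s{i}" for i in range(2 * n)]
        two = roh_age_regression(df2, list(age) * 2, list(sex) * 2)
        np.testing.assert_allclose(one["n_roh"]["coef"], two["n_roh"]["coef"],
                                   atol=1e-8)
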