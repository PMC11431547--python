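"""Wilcoxon rank-sum implementation, cohort comparisons and table rendering."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vesselmorph.stats import (
    StatsError,
    compare_by_dr_severity,
    compare_by_t1d,
    format_iqr_cell,
    render_summary_tables,
    summarize,
    wilcoxon_rank_sum,
)
from vesselmorph.synthetic import (
    CohortSpec,
    GroupSpec,
    generate_cohort,
    two_group_spec,
)


def brute_force_p(x, y):
    """Independent oracle: enumerate every rank split with midranks."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, total = len(x), len(pooled)
    mu = n * (total + 1) / 2
    w_obs = ranks[:n].sum()
    hits = trials = 0
    for idx in combinations(range(total), n):
        trials += 1
        if abs(ranks[list(idx)].sum() - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / trials


class TestWilcoxonExact:
    def test_textbook_example(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_identical_multisets_give_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 2.0], [2.0, 1.0, 2.0], mode="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_for_all_small_sizes(self):
        """Exhaustive check against a brute-force oracle for n, m <= 8,
        including tied data."""
        rng = np.random.default_rng(2024)
        for n in range(1, 9):
            for m in range(1, 9):
                x = np.round(rng.normal(size=n), 1)  # rounding induces ties
                y = np.round(rng.normal(size=m), 1)
                ours = wilcoxon_rank_sum(x, y, mode="exact").p_value
                assert ours == pytest.approx(brute_force_p(x, y), abs=1e-12), (n, m)

    def test_matches_scipy_exact_without_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(7)
        for n, m in [(3, 5), (6, 6), (8, 4)]:
            x, y = rng.normal(size=n), rng.normal(size=m)
            ours = wilcoxon_rank_sum(x, y, mode="exact").p_value
            ref = mannwhitneyu(x, y, method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_auto_switches_to_exact_for_small_samples(self):
        small = wilcoxon_rank_sum(np.arange(5), np.arange(5) + 0.5)
        big = wilcoxon_rank_sum(np.arange(30), np.arange(30) + 0.5)
        assert small.method == "exact"
        assert big.method == "normal_approx_tie_corrected"

    def test_empty_sample_rejected(self):
        with pytest.raises(StatsError):
            wilcoxon_rank_sum([], [1.0])


@given(
    st.lists(st.integers(-500, 500), min_size=2, max_size=7),
    st.lists(st.integers(-500, 500), min_size=2, max_size=7),
)
def test_p_invariant_under_monotone_transform(x, y):
    """A rank test cannot see a common strictly monotone transformation."""
    x = np.asarray(x) / 7.0
    y = np.asarray(y) / 7.0
    p1 = wilcoxon_rank_sum(x, y, mode="exact").p_value
    f = lambda v: np.exp(v / 25.0)
    p2 = wilcoxon_rank_sum(f(x), f(y), mode="exact").p_value
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_type_one_error_within_binomial_band():
    rng = np.random.default_rng(99)
    reps, rejections = 2000, 0
    for _ in range(reps):
        if wilcoxon_rank_sum(rng.normal(size=55), rng.normal(size=55)).p_value <= 0.05:
            rejections += 1
    half = 1.96 * np.sqrt(0.05 * 0.95 / reps)
    assert abs(rejections / reps - 0.05) <= half


class TestCompareByT1d:
    def test_wall_effect_detected_with_power(self):
        """+4 um wall shift (n=30/80): W significant in >= 90% of replicates."""
        hits = 0
        reps = 200
        for rep in range(reps):
            cohort = generate_cohort(two_group_spec(seed=40_000 + rep))
            res = compare_by_t1d(cohort)
            hits += res["W"].p_value <= 0.05
        assert hits / reps >= 0.90

    def test_identical_tiny_strata_all_p_one(self):
        rows = []
        for i, t1d in enumerate([False] * 4 + [True] * 4):
            ld, w = 140.0, 15.0
            rows.append(
                {"t1d": t1d, "dr_group": "Control" if not t1d else "NoDR",
                 "LD": ld, "W": w, "ED": ld + 2 * w, "WLR": w / ld}
            )
        res = compare_by_t1d(pd.DataFrame(rows), mode="exact")
        assert all(r.p_value == pytest.approx(1.0) for r in res.values())
        assert all(r.method == "exact" for r in res.values())

    def test_empty_stratum_named(self):
        cohort = generate_cohort(two_group_spec(seed=1))
        with pytest.raises(StatsError, match="control"):
            compare_by_t1d(cohort[cohort["t1d"]])

    def test_published_iqr_identity(self):
        s = summarize([13.7, 13.7, 13.7, 18.0, 18.0, 18.0])
        assert s.q1 == pytest.approx(13.7)
        assert s.q3 == pytest.approx(18.0)
        assert s.iqr == pytest.approx(4.3)


class TestCompareByDrSeverity:
    @staticmethod
    def _graded_spec(seed, delta=2.0):
        means = [15.0, 15.0 + delta, 15.0 + 2 * delta, 15.0 + 3 * delta]
        labels = ["Control", "NoDR", "MildModNPDR", "SevNPDR_PDR"]
        groups = [
            GroupSpec(lab, 20, 140.0, 20.0, mu, 3.0, t1d=lab != "Control")
            for lab, mu in zip(labels, means)
        ]
        return CohortSpec(groups=groups, seed=seed)

    def test_monotone_effect_detected_by_omnibus(self):
        hits = 0
        reps = 200
        for rep in range(reps):
            cohort = generate_cohort(self._graded_spec(50_000 + rep))
            res = compare_by_dr_severity(cohort)
            hits += res["W"]["omnibus"]["p_value"] <= 0.05
        assert hits / reps >= 0.90

    def test_all_pairwise_contrasts_present(self):
        cohort = generate_cohort(self._graded_spec(1))
        res = compare_by_dr_severity(cohort)
        assert len(res["WLR"]["pairwise"]) == 6

    def test_identical_groups_no_rejection_under_exact(self):
        rows = []
        for g in ("Control", "NoDR", "MildModNPDR", "SevNPDR_PDR"):
            for _ in range(3):
                rows.append({"t1d": g != "Control", "dr_group": g, "LD": 140.0,
                             "W": 15.0, "ED": 170.0, "WLR": 15.0 / 140.0})
        res = compare_by_dr_severity(pd.DataFrame(rows), mode="exact")
        for metric in res.values():
            for pair in metric["pairwise"].values():
                assert pair.p_value > 0.05

    def test_jonckheere_switch(self):
        cohort = generate_cohort(self._graded_spec(2, delta=3.0))
        res = compare_by_dr_severity(cohort, omnibus="jonckheere")
        assert res["W"]["omnibus"]["test"] == "jonckheere"
        assert res["W"]["omnibus"]["p_value"] <= 0.05

    def test_fewer_than_two_groups_rejected(self):
        cohort = generate_cohort(two_group_spec(seed=3))
        with pytest.raises(StatsError):
            compare_by_dr_severity(cohort[cohort["dr_group"] == "Control"])


class TestRendering:
    def test_iqr_cell_format(self):
        s = summarize([0.10, 0.10, 0.12, 0.12])
        assert format_iqr_cell(s, 2) == "0.02 (0.10, 0.12)"

    def test_single_vessel_group_degenerate_quartiles(self):
        s = summarize([5.0])
        assert s.q1 == s.median == s.q3 == 5.0
        assert s.iqr == 0.0

    def test_quartiles_match_independent_rule(self):
        """Linear-interpolation quartiles agree with a hand-rolled oracle."""
        values = [1.0, 2.0, 3.0, 4.0]

        def oracle(v, q):
            v = sorted(v)
            pos = (len(v) - 1) * q
            lo = int(np.floor(pos))
            hi = int(np.ceil(pos))
            return v[lo] + (pos - lo) * (v[hi] - v[lo])

        s = summarize(values)
        assert s.q1 == pytest.approx(oracle(values, 0.25))
        assert s.q3 == pytest.approx(oracle(values, 0.75))

    def test_tables_render_with_expected_cells(self):
        cohort = generate_cohort(two_group_spec(seed=4))
        # add the remaining DR groups so the severity table is 4-wide
        extra = generate_cohort(
            CohortSpec(
                groups=[
                    GroupSpec("MildModNPDR", 12, 140, 20, 17, 3, t1d=True),
                    GroupSpec("SevNPDR_PDR", 12, 140, 20, 19, 3, t1d=True),
                ],
                seed=5,
            )
        )
        cohort = pd.concat(
            [cohort.replace({"dr_group": {"T1D": "NoDR"}}), extra],
            ignore_index=True,
        )
        t1d = compare_by_t1d(cohort)
        dr = compare_by_dr_severity(cohort)
        out = render_summary_tables(cohort, t1d, dr)
        assert list(out["t1d_table"]["Arteriolar parameter"]) == [
            "Wall-to-lumen ratio",
            "Mean wall thickness (um)",
            "Luminal diameter (um)",
            "External diameter (um)",
        ]
        wlr_ctrl = t1d["WLR"].summaries["Control"]
        assert format_iqr_cell(wlr_ctrl, 2) in out["t1d_table"].iloc[0, 1]
        assert set(out["boxplot"]["W"]) == {
            "Control", "NoDR", "MildModNPDR", "SevNPDR_PDR"
        }
        for g, desc in out["boxplot"]["W"].items():
            assert desc["q1"] <= desc["median"] <= desc["q3"]
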