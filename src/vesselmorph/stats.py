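"""Group-level nonparametric statistics for arteriole cohorts.

The unit of analysis is the arteriole.  Metrics (WLR, W, LD, ED) are
compared between T1D strata with the two-sided Wilcoxon rank-sum test and
across DR-severity groups with a Kruskal-Wallis omnibus plus all pairwise
rank-sum contrasts.  No multiplicity adjustment is applied (exploratory
convention: p <= 0.05 significant, p <= 0.1 trend-level).  Summaries use
the "IQR (Q1, Q3)" format with linear-interpolation quartiles; the quartile
rule is part of the contract because conventions differ on small samples.

The rank-sum test is implemented here rather than delegated: exact
enumeration of all rank assignments (with midranks for ties) when both
samples have <= ``exact_max_n`` observations, otherwise a tie-corrected
normal approximation with a 0.5 continuity correction.  Within-eye and
within-patient clustering is NOT modelled; ids are carried through so users
can aggregate before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

METRICS = ("WLR", "W", "LD", "ED")
DR_ORDER = ("Control", "NoDR", "MildModNPDR", "SevNPDR_PDR")

ALPHA_SIGNIFICANT = 0.05
ALPHA_TREND = 0.1

EXACT_MAX_N = 10             # exact enumeration when both n <= this
_ENUM_GUARD = 5_000_000      # refuse enumerations larger than this many splits


class StatsError(ValueError):
    pass


@dataclass
class GroupSummary:
    label: str
    n: int
    median: float
    q1: float
    q3: float
    mean: float
    sd: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass
class TestResult:
    metric: str
    grouping: str
    statistic: float        # rank sum of the first sample
    p_value: float
    method: str             # "exact" | "normal_approx_tie_corrected"
    summaries: dict

    @property
    def significant(self) -> bool:
        return self.p_value <= ALPHA_SIGNIFICANT

    @property
    def trend(self) -> bool:
        return self.p_value <= ALPHA_TREND


def summarize(values, label: str = "") -> GroupSummary:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise StatsError(f"empty sample for group {label!r}")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation rule
    return GroupSummary(
        label=label,
        n=int(v.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _exact_p(ranks: np.ndarray, n: int) -> tuple[float, float]:
    """Two-sided p by full enumeration of the C(n+m, n) rank assignments."""
    total = ranks.size
    n_splits = comb(total, n)
    if n_splits > _ENUM_GUARD:
        raise StatsError(f"exact enumeration of {n_splits} splits is infeasible")
    w_obs = ranks[:n].sum()
    mu = n * (total + 1) / 2.0
    dev = abs(w_obs - mu)
    idx = np.fromiter(
        (i for c in combinations(range(total), n) for i in c), dtype=np.intp,
        count=n_splits * n,
    ).reshape(n_splits, n)
    w_all = ranks[idx].sum(axis=1)
    count = int(np.sum(np.abs(w_all - mu) >= dev - 1e-9))
    return w_obs, count / n_splits


def _normal_approx_p(ranks: np.ndarray, n: int) -> tuple[float, float]:
    """Tie-corrected normal approximation with 0.5 continuity correction."""
    total = ranks.size
    m = total - n
    w = ranks[:n].sum()
    mu = n * (total + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (total * (total - 1))
    var = n * m / 12.0 * ((total + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return w, float(min(1.0, 2.0 * sps.norm.sf(z)))


def wilcoxon_rank_sum(x, y, mode: str = "auto", *, exact_max_n: int = EXACT_MAX_N,
                      metric: str = "", grouping: str = "") -> TestResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    ``mode="auto"`` uses exact enumeration when both samples have at most
    ``exact_max_n`` observations, and the tie-corrected normal
    approximation otherwise; ``mode="exact"``/``mode="approx"`` force one
    path.  Ties receive midranks in both paths.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both samples must be nonempty")
    if mode not in ("auto", "exact", "approx"):
        raise StatsError(f"unknown mode {mode!r}")
    ranks = _midranks(np.concatenate([x, y]))
    use_exact = mode == "exact" or (
        mode == "auto" and x.size <= exact_max_n and y.size <= exact_max_n
    )
    if use_exact:
        w, p = _exact_p(ranks, x.size)
        method = "exact"
    else:
        w, p = _normal_approx_p(ranks, x.size)
        method = "normal_approx_tie_corrected"
    return TestResult(
        metric=metric,
        grouping=grouping,
        statistic=float(w),
        p_value=float(p),
        method=method,
        summaries={},
    )


# ---------------------------------------------------------------------------
# cohort comparisons
# ---------------------------------------------------------------------------

def _check_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    required = {"t1d", "dr_group", *METRICS}
    missing = required - set(cohort.columns)
    if missing:
        raise StatsError(f"cohort table lacks columns: {sorted(missing)}")
    if (cohort[list(METRICS)] <= 0).any().any():
        raise StatsError("all metrics must be positive")
    control_t1d = cohort.loc[cohort["dr_group"] == "Control", "t1d"]
    if control_t1d.any():
        raise StatsError("Control group records must have t1d = False")
    resid = cohort["ED"] - cohort["LD"] * (1 + 2 * cohort["WLR"])
    if np.max(np.abs(resid)) > 1e-6 * np.max(cohort["ED"]):
        raise StatsError("ED = LD*(1+2*WLR) violated beyond tolerance")
    return cohort


def compare_by_t1d(cohort: pd.DataFrame, mode: str = "auto",
                   exact_max_n: int = EXACT_MAX_N) -> dict:
    """One rank-sum test per metric between the control and T1D strata."""
    cohort = _check_cohort(cohort)
    ctrl = cohort[~cohort["t1d"]]
    t1d = cohort[cohort["t1d"]]
    for name, stratum in (("control", ctrl), ("T1D", t1d)):
        if stratum.empty:
            raise StatsError(f"stratum {name!r} is empty")
    results = {}
    for metric in METRICS:
        res = wilcoxon_rank_sum(
            ctrl[metric], t1d[metric], mode=mode, exact_max_n=exact_max_n,
            metric=metric, grouping="t1d",
        )
        res.summaries = {
            "Control": summarize(ctrl[metric], "Control"),
            "T1D": summarize(t1d[metric], "T1D"),
        }
        results[metric] = res
    return results


def compare_by_dr_severity(cohort: pd.DataFrame, mode: str = "auto",
                           exact_max_n: int = EXACT_MAX_N,
                           omnibus: str = "kruskal") -> dict:
    """Kruskal-Wallis omnibus across DR-severity groups plus all pairwise
    rank-sum contrasts, per metric.  ``omnibus="jonckheere"`` switches to an
    ordered-trend permutation test."""
    cohort = _check_cohort(cohort)
    present = [g for g in DR_ORDER if (cohort["dr_group"] == g).any()]
    if len(present) < 2:
        raise StatsError("need at least 2 nonempty DR severity groups")
    out: dict = {}
    for metric in METRICS:
        samples = [cohort.loc[cohort["dr_group"] == g, metric].to_numpy() for g in present]
        if np.ptp(np.concatenate(samples)) == 0:
            stat, p = 0.0, 1.0  # fully tied data carry no group signal
        elif omnibus == "kruskal":
            stat, p = sps.kruskal(*samples)
        elif omnibus == "jonckheere":
            stat, p = _jonckheere(samples)
        else:
            raise StatsError(f"unknown omnibus test {omnibus!r}")
        pairwise = {}
        for (i, gi), (j, gj) in combinations(enumerate(present), 2):
            res = wilcoxon_rank_sum(
                samples[i], samples[j], mode=mode, exact_max_n=exact_max_n,
                metric=metric, grouping=f"{gi}_vs_{gj}",
            )
            res.summaries = {
                gi: summarize(samples[i], gi),
                gj: summarize(samples[j], gj),
            }
            pairwise[(gi, gj)] = res
        out[metric] = {
            "omnibus": {"statistic": float(stat), "p_value": float(p), "test": omnibus},
            "pairwise": pairwise,
            "summaries": {g: summarize(s, g) for g, s in zip(present, samples)},
        }
    return out


def _jonckheere(samples) -> tuple[float, float]:
    """Jonckheere-Terpstra ordered-trend statistic with normal approximation."""
    j = 0.0
    for a, b in combinations(range(len(samples)), 2):
        x, y = samples[a], samples[b]
        grid = y[None, :] - x[:, None]
        j += np.sum(grid > 0) + 0.5 * np.sum(grid == 0)
    ns = np.array([len(s) for s in samples])
    n = ns.sum()
    mu = (n**2 - np.sum(ns**2)) / 4.0
    var = (n**2 * (2 * n + 3) - np.sum(ns**2 * (2 * ns + 3))) / 72.0
    z = (j - mu) / np.sqrt(var)
    return float(j), float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def format_iqr_cell(summary: GroupSummary, decimals: int = 2) -> str:
    """'IQR (Q1, Q3)' cell in the published table layout."""
    fmt = f"{{:.{decimals}f}}"
    return f"{fmt.format(summary.iqr)} ({fmt.format(summary.q1)}, {fmt.format(summary.q3)})"


_METRIC_LABELS = {
    "WLR": ("Wall-to-lumen ratio", 2),
    "W": ("Mean wall thickness (um)", 1),
    "LD": ("Luminal diameter (um)", 1),
    "ED": ("External diameter (um)", 1),
}


def render_summary_tables(cohort: pd.DataFrame, t1d_results: dict,
                          dr_results: dict) -> dict:
    """Summary tables in the published layout plus box-plot descriptors.

    Returns ``{"t1d_table": DataFrame, "dr_table": DataFrame,
    "boxplot": dict}``; box-plot descriptors carry Q1/median/Q3/mean/sd per
    group (whiskers drawn at +-1 sd in the figures this mirrors).
    """
    rows_t1d, rows_dr = [], []
    boxplot: dict = {}
    dr_groups = [g for g in DR_ORDER if (cohort["dr_group"] == g).any()]
    for metric in METRICS:
        label, dec = _METRIC_LABELS[metric]
        res = t1d_results[metric]
        for s in res.summaries.values():
            assert abs(s.iqr - (s.q3 - s.q1)) < 1e-12
        rows_t1d.append(
            {
                "Arteriolar parameter": label,
                "Controls IQR (Q1, Q3)": format_iqr_cell(res.summaries["Control"], dec),
                "T1D IQR (Q1, Q3)": format_iqr_cell(res.summaries["T1D"], dec),
                "p value": f"{res.p_value:.4g}" + (" *" if res.significant else ""),
            }
        )
        summaries = dr_results[metric]["summaries"]
        row = {"Arteriolar parameter": label}
        for g in dr_groups:
            row[f"{g} IQR (Q1, Q3)"] = format_iqr_cell(summaries[g], dec)
        rows_dr.append(row)
        boxplot[metric] = {
            g: {
                "q1": s.q1,
                "median": s.median,
                "q3": s.q3,
                "mean": s.mean,
                "sd": s.sd,
                "n": s.n,
            }
            for g, s in summaries.items()
        }
    return {
        "t1d_table": pd.DataFrame(rows_t1d),
        "dr_table": pd.DataFrame(rows_dr),
        "boxplot": boxplot,
    }
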