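"""Group statistics and questionnaire scoring.

One-way ANOVA (from raw samples and, crucially, from printed group
summaries), pooled-variance pairwise t tests with Benjamini-Hochberg FDR
correction, Cohen's d, Pearson correlation, and Amsterdam Resting-State
Questionnaire (ARSQ) domain scores (ten domains, each the sum of three
1-5 Likert items).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class TestResult:
    statistic: float
    df: tuple[float, ...] | float
    p_raw: float
    p_fdr: float | None = None
    effect_size_d: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if self.p_fdr is not None and self.p_fdr < self.p_raw - 1e-12:
            raise ValueError("adjusted p cannot be below raw p")


def anova_oneway(groups: list[np.ndarray]) -> TestResult:
    """One-way fixed-effects ANOVA across >= 2 groups of raw values."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(np.var(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        raise ValueError("zero variance everywhere: F undefined")
    f, p = sps.f_oneway(*groups)
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    return TestResult(statistic=float(f), df=(k - 1, n_total - k), p_raw=float(p))


def anova_from_summary(summaries: list[GroupSummary]) -> TestResult:
    """One-way ANOVA from per-group (mean, SD, n) summaries.

    Standard sums-of-squares decomposition: SSb = sum n_i (m_i - m)^2 with m
    the grand (n-weighted) mean, SSw = sum (n_i - 1) sd_i^2, and
    F = [SSb/(k-1)] / [SSw/(N-k)]. Algebraically identical to
    :func:`anova_oneway` on the raw data the summaries came from.
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 group summaries")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    n_total = ns.sum()
    k = len(summaries)
    grand = float(np.sum(ns * means) / n_total)
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds ** 2))
    if ss_within == 0 and ss_between == 0:
        raise ValueError("zero variance everywhere: F undefined")
    df = (k - 1, n_total - k)
    f = (ss_between / df[0]) / (ss_within / df[1])
    p = float(sps.f.sf(f, *df))
    return TestResult(statistic=float(f), df=(df[0], int(df[1])), p_raw=p)


def pairwise_t(values_a: np.ndarray, values_b: np.ndarray,
               variant: str = "pooled") -> TestResult:
    """Two-sided independent-samples t test (pooled variance; Welch by flag)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    equal_var = variant == "pooled"
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = (len(a) + len(b) - 2) if equal_var else float(res.df)
    return TestResult(statistic=float(res.statistic), df=df,
                      p_raw=float(res.pvalue))


def cohens_d(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Cohen's d = (mean_a - mean_b) / pooled SD with (n_i - 1) weights."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    pooled_var = (((len(a) - 1) * np.var(a, ddof=1)
                   + (len(b) - 1) * np.var(b, ddof=1))
                  / (len(a) + len(b) - 2))
    if pooled_var == 0:
        if np.mean(a) == np.mean(b):
            return 0.0
        raise ValueError("zero pooled SD: d undefined")
    return float((np.mean(a) - np.mean(b)) / np.sqrt(pooled_var))


def fdr_bh(p_values: np.ndarray, alpha: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection mask at alpha)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("Pearson r undefined for zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# ARSQ domain scoring
# ---------------------------------------------------------------------------

ARSQ_DOMAINS = [
    "discontinuity_of_mind", "theory_of_mind", "self", "planning", "sleepiness",
    "comfort", "somatic_awareness", "health_concern", "visual_thought",
    "verbal_thought",
]

# Default mapping: items 1-30 in domain blocks of three (item indices 0-based).
DEFAULT_ITEM_MAP = {d: [3 * i, 3 * i + 1, 3 * i + 2]
                    for i, d in enumerate(ARSQ_DOMAINS)}


def arsq_domains(item_table: pd.DataFrame,
                 item_map: dict[str, list[int]] | None = None) -> pd.DataFrame:
    """Ten per-subject domain scores, each the sum of three 1-5 Likert items.

    ``item_table`` is subjects x 30 items. The item-to-domain mapping is
    configurable (the default assigns consecutive triples).
    """
    item_map = item_map or DEFAULT_ITEM_MAP
    values = item_table.to_numpy()
    if values.shape[1] != 30:
        raise ValueError(f"expected 30 items, got {values.shape[1]}")
    bad = np.argwhere((values < 1) | (values > 5) | (values != np.round(values)))
    if bad.size:
        subj, item = bad[0]
        raise ValueError(
            f"item value out of 1-5 range: subject {item_table.index[subj]}, "
            f"item {item_table.columns[item]}")
    out = {d: values[:, idx].sum(axis=1) for d, idx in item_map.items()}
    return pd.DataFrame(out, index=item_table.index)


# ---------------------------------------------------------------------------
# Full group-comparison report
# ---------------------------------------------------------------------------

PARAMETERS = ["gev_pct", "duration_ms", "coverage_pct", "occurrence_per_s"]


def group_comparison_report(metrics_table: pd.DataFrame,
                            parameters: list[str] | None = None,
                            alpha: float = 0.05,
                            fdr_family: str = "per_panel") -> pd.DataFrame:
    """ANOVA plus FDR-corrected pairwise t tests per parameter and state.

    For each (parameter, state): one ANOVA row and one row per group pair
    with pooled t, BH-adjusted p and Cohen's d. The FDR family is the three
    pairwise p values of one (parameter, state) panel by default
    (``per_panel``); ``per_parameter`` pools states, ``global`` pools
    everything.
    """
    parameters = parameters or PARAMETERS
    groups = sorted(metrics_table["group"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    rows = []
    for param in parameters:
        for state in sorted(metrics_table["state"].unique()):
            sub = metrics_table[metrics_table["state"] == state]
            samples = {g: sub.loc[sub["group"] == g, param].dropna().to_numpy()
                       for g in groups}
            if any(len(v) < 2 for v in samples.values()):
                continue
            an = anova_oneway([samples[g] for g in groups])
            rows.append(dict(parameter=param, state=state, test="anova",
                             group_a="all", group_b="all",
                             statistic=an.statistic, df1=an.df[0], df2=an.df[1],
                             p_raw=an.p_raw, p_fdr=np.nan, cohens_d=np.nan))
            for a, b in pairs:
                tt = pairwise_t(samples[a], samples[b])
                rows.append(dict(parameter=param, state=state, test="t",
                                 group_a=a, group_b=b, statistic=tt.statistic,
                                 df1=tt.df, df2=np.nan, p_raw=tt.p_raw,
                                 p_fdr=np.nan,
                                 cohens_d=cohens_d(samples[a], samples[b])))
    report = pd.DataFrame(rows)
    if report.empty:
        return report
    t_mask = report["test"] == "t"
    if fdr_family == "global":
        families = [t_mask]
    elif fdr_family == "per_parameter":
        families = [t_mask & (report["parameter"] == p) for p in parameters]
    else:  # per_panel: the three pairwise tests of one parameter x state
        families = [t_mask & (report["parameter"] == p) & (report["state"] == s)
                    for p in parameters
                    for s in sorted(metrics_table["state"].unique())]
    for fam in families:
        if fam.any():
            p_adj, _ = fdr_bh(report.loc[fam, "p_raw"].to_numpy(), alpha)
            report.loc[fam, "p_fdr"] = p_adj
    return report
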