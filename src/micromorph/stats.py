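"""Inferential tests with the study's test-to-comparison routing.

Routing: Welch's t for two-group cytokine n-fold comparisons; Pearson
chi-square (2x2, no continuity correction) for [round/amoeboid] vs
[polarized + ramified] morphotype proportions; Kruskal-Wallis followed by
Dunn's tie-corrected post hoc (Bonferroni adjustment) for multi-group
shape/count panels; one-way ANOVA with Tukey's HSD for Z-score panels.
Significance tiers: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TestResult",
    "welch_t",
    "chi2_morphotype",
    "kw_dunn",
    "anova_tukey",
    "stars",
]


def stars(p: float) -> str:
    """Significance tier of a p value."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p: float
    group_sizes: tuple[int, ...]
    p_adj: float | None = None
    df: float | None = None
    comparison: str = ""

    @property
    def stars(self) -> str:
        return stars(self.p_adj if self.p_adj is not None else self.p)


def welch_t(a: Sequence[float], b: Sequence[float], comparison: str = "") -> TestResult:
    """Two-tailed t test with Welch correction (Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return TestResult("welch_t", 0.0, 1.0, (a.size, b.size),
                              df=float(a.size + b.size - 2), comparison=comparison)
        raise ValueError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.pvalue),
                      (a.size, b.size), df=float(res.df), comparison=comparison)


def chi2_morphotype(
    control_counts: Sequence[int],
    treated_counts: Sequence[int],
    comparison: str = "",
) -> TestResult:
    """Pearson chi-square on the 2x2 table.

    Rows: [round/amoeboid, polarized+ramified]; columns: [control,
    treatment]. No Yates correction (cell counts in this design are in the
    hundreds to thousands, where the correction is negligible).
    """
    table = np.array([control_counts, treated_counts], dtype=float).T
    if table.shape != (2, 2):
        raise ValueError("expected two counts per group: [round, polarized+ramified]")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all table margins must be > 0")
    if (table.sum(axis=1) > 0).all() and np.allclose(
        table[:, 0] / table[:, 0].sum(), table[:, 1] / table[:, 1].sum()
    ):
        return TestResult("chi2", 0.0, 1.0,
                          tuple(int(s) for s in table.sum(axis=1)),
                          df=1.0, comparison=comparison)
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return TestResult("chi2", float(chi2), float(p),
                      tuple(int(s) for s in table.sum(axis=1)),
                      df=float(dof), comparison=comparison)


def _dunn_pairwise(groups: list[np.ndarray], comparison: str) -> list[TestResult]:
    """Dunn's z tests on midranks with tie correction, Bonferroni adjusted."""
    all_vals = np.concatenate(groups)
    n_total = all_vals.size
    ranks = sps.rankdata(all_vals)
    sizes = [g.size for g in groups]
    mean_ranks = []
    start = 0
    for s in sizes:
        mean_ranks.append(ranks[start:start + s].mean())
        start += s
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        out.append(
            TestResult("dunn", float(z), float(p), (sizes[i], sizes[j]),
                       p_adj=min(1.0, p * m),
                       comparison=f"{comparison}[{i} vs {j}]")
        )
    return out


def kw_dunn(
    groups: Sequence[Sequence[float]], comparison: str = ""
) -> tuple[TestResult, list[TestResult]]:
    """Kruskal-Wallis omnibus (tie-corrected H) plus Dunn's post hoc."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    concat = np.concatenate(arrays)
    if np.ptp(concat) == 0:
        omnibus = TestResult("kruskal_wallis", 0.0, 1.0,
                             tuple(a.size for a in arrays), comparison=comparison)
        pairwise = [
            TestResult("dunn", 0.0, 1.0, (arrays[i].size, arrays[j].size),
                       p_adj=1.0, comparison=f"{comparison}[{i} vs {j}]")
            for i, j in itertools.combinations(range(len(arrays)), 2)
        ]
        return omnibus, pairwise
    h, p = sps.kruskal(*arrays)
    omnibus = TestResult("kruskal_wallis", float(h), float(p),
                         tuple(a.size for a in arrays), comparison=comparison)
    return omnibus, _dunn_pairwise(arrays, comparison)


def anova_tukey(
    groups: Sequence[Sequence[float]], comparison: str = ""
) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA omnibus plus Tukey's HSD pairwise comparisons."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    concat = np.concatenate(arrays)
    sizes = tuple(a.size for a in arrays)
    if np.ptp(concat) == 0:
        omnibus = TestResult("anova", 0.0, 1.0, sizes, comparison=comparison)
        pairwise = [
            TestResult("tukey_hsd", 0.0, 1.0, (arrays[i].size, arrays[j].size),
                       p_adj=1.0, comparison=f"{comparison}[{i} vs {j}]")
            for i, j in itertools.combinations(range(len(arrays)), 2)
        ]
        return omnibus, pairwise
    f, p = sps.f_oneway(*arrays)
    omnibus = TestResult("anova", float(f), float(p), sizes, comparison=comparison)
    values = concat
    group_labels = np.concatenate(
        [np.full(a.size, i) for i, a in enumerate(arrays)]
    )
    tk = pairwise_tukeyhsd(values, group_labels)
    # statsmodels orders pairs as combinations of the sorted unique labels,
    # and our labels are 0..k-1
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    pairwise = []
    for row, (i, j) in enumerate(pairs):
        pairwise.append(
            TestResult("tukey_hsd", float(tk.meandiffs[row]), float(tk.pvalues[row]),
                       (arrays[i].size, arrays[j].size), p_adj=float(tk.pvalues[row]),
                       comparison=f"{comparison}[{i} vs {j}]")
        )
    return omnibus, pairwise
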