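"""Group comparison machinery: normality-gated tests and edge-wise FDR.

Behavioral, symptom and network-property comparisons follow the usual
clinical-statistics decision tree: Shapiro-Wilk normality gate, then a
t-family test (pooled or Welch for independent samples, chosen by a
variance-ratio F test; paired t for within-subject contrasts) or the
rank-based alternative (Mann-Whitney U / Wilcoxon signed-rank).  Network
edges are compared one t-test per unique electrode pair with
Benjamini-Hochberg false-discovery-rate correction over the edge family
(210 edges for a 21-node montage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .connectivity import CoherenceMatrix


@dataclass
class ComparisonResult:
    """One two-group (or paired) comparison."""

    test_name: str
    statistic: float
    df: float | None
    p: float
    direction: int  # sign of (group1 - group2) central tendency


@dataclass
class EdgeComparison:
    """Edge-wise group contrast: t, p, BH-adjusted q, significance mask."""

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    mask: np.ndarray
    alpha: float
    labels: tuple[str, ...]

    def significant_edges(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if self.mask[i, j]:
                    out.append((self.labels[i], self.labels[j]))
        return out


def _is_constant(x: np.ndarray) -> bool:
    return np.ptp(x) == 0


def choose_test(
    sample1: np.ndarray,
    sample2: np.ndarray,
    paired: bool = False,
    alpha: float = 0.05,
) -> str:
    """Select the comparison test by a Shapiro-Wilk normality gate.

    Normal data (Shapiro-Wilk p > alpha on both samples, or on the
    differences when paired) get a t-family test; otherwise the rank
    test.  For independent t-tests the pooled variant is used unless the
    variance-ratio F test rejects equality at ``alpha`` (then Welch).
    Degenerate (constant) samples fall through to the rank test.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if min(len(x), len(y)) < 3:
        raise ValueError("need at least 3 observations per sample")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        d = x - y
        if _is_constant(d):
            return "wilcoxon_signed_rank"
        return "paired_t" if sps.shapiro(d).pvalue > alpha else "wilcoxon_signed_rank"
    if _is_constant(x) or _is_constant(y):
        return "mann_whitney_u"
    if sps.shapiro(x).pvalue > alpha and sps.shapiro(y).pvalue > alpha:
        f = np.var(x, ddof=1) / np.var(y, ddof=1)
        p_f = 2.0 * min(
            sps.f.cdf(f, len(x) - 1, len(y) - 1),
            sps.f.sf(f, len(x) - 1, len(y) - 1),
        )
        return "welch_t" if p_f < alpha else "pooled_t"
    return "mann_whitney_u"


def two_sample_t(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> ComparisonResult:
    """Independent-samples t-test from summary statistics.

    Accepting summaries means printed group tables (mean +- SD, n) are
    directly checkable.
    """
    if sd1 < 0 or sd2 < 0 or n1 < 2 or n2 < 2:
        raise ValueError("need sd >= 0 and n >= 2 per group")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both samples have zero variance")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    equal_var = variant == "pooled"
    t, p = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return ComparisonResult(
        test_name=f"{variant}_t",
        statistic=float(t),
        df=float(df),
        p=float(p),
        direction=int(np.sign(mean1 - mean2)),
    )


def paired_t(values1: np.ndarray, values2: np.ndarray) -> ComparisonResult:
    """Paired t-test on the element-wise differences."""
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = x - y
    if _is_constant(d) and d[0] == 0:
        raise ValueError("identical samples: paired t undefined (zero variance)")
    if np.var(d, ddof=1) == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    t, p = sps.ttest_rel(x, y)
    return ComparisonResult("paired_t", float(t), float(len(x) - 1), float(p),
                            int(np.sign(np.mean(d))))


def mann_whitney_u(values1: np.ndarray, values2: np.ndarray) -> ComparisonResult:
    """Mann-Whitney U; the statistic is reported as min(U1, U2)."""
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("need at least one observation per group")
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    u1 = float(res.statistic)
    u = min(u1, len(x) * len(y) - u1)
    return ComparisonResult("mann_whitney_u", u, None, float(res.pvalue),
                            int(np.sign(np.median(x) - np.median(y))))


def wilcoxon_signed_rank(values1: np.ndarray, values2: np.ndarray) -> ComparisonResult:
    """Wilcoxon signed-rank test for paired samples."""
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if _is_constant(x - y) and (x - y)[0] == 0:
        raise ValueError("all paired differences zero: Wilcoxon undefined")
    res = sps.wilcoxon(x, y)
    return ComparisonResult("wilcoxon_signed_rank", float(res.statistic), None,
                            float(res.pvalue), int(np.sign(np.median(x - y))))


_RUNNERS = {
    "paired_t": paired_t,
    "wilcoxon_signed_rank": wilcoxon_signed_rank,
    "mann_whitney_u": mann_whitney_u,
}


def compare_samples(
    sample1: np.ndarray, sample2: np.ndarray, paired: bool = False
) -> ComparisonResult:
    """Gate with :func:`choose_test`, then run the selected test."""
    name = choose_test(sample1, sample2, paired=paired)
    if name in ("pooled_t", "welch_t"):
        x = np.asarray(sample1, dtype=float)
        y = np.asarray(sample2, dtype=float)
        return two_sample_t(
            x.mean(), x.std(ddof=1), len(x),
            y.mean(), y.std(ddof=1), len(y),
            variant=name.removesuffix("_t"),
        )
    return _RUNNERS[name](sample1, sample2)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject mask, adjusted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted


def edgewise_compare(
    group_a: list[CoherenceMatrix],
    group_b: list[CoherenceMatrix],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> EdgeComparison:
    """Per-edge independent t-tests across subjects with BH-FDR correction.

    The FDR family is the set of unique off-diagonal edges of one
    contrast (210 for 21 nodes).
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("need at least 3 subjects per group")
    labels = group_a[0].labels
    for m in group_a + group_b:
        if m.labels != labels:
            raise ValueError("label mismatch across matrices")
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    a = np.stack([m.values[iu] for m in group_a])   # (n_a, n_edges)
    b = np.stack([m.values[iu] for m in group_b])
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    # zero-variance edges (e.g. identical groups) are not evidence
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    reject, q = bh_fdr(p, q=alpha)

    def _sym(flat: np.ndarray, fill: float = 0.0) -> np.ndarray:
        m = np.full((n, n), fill)
        m[iu] = flat
        m[(iu[1], iu[0])] = flat
        return m

    t_m = _sym(t)
    p_m = _sym(p, fill=1.0)
    q_m = _sym(q, fill=1.0)
    np.fill_diagonal(p_m, 1.0)
    np.fill_diagonal(q_m, 1.0)
    mask = _sym(reject.astype(float)).astype(bool)
    np.fill_diagonal(mask, False)
    return EdgeComparison(t=t_m, p=p_m, q=q_m, mask=mask, alpha=alpha, labels=labels)


def correlate_with_fdr(
    pairs: list[tuple[np.ndarray, np.ndarray]], q: float = 0.05
) -> list[tuple[float, float, float]]:
    """Pearson r + two-sided p per pair, BH-adjusted across the family."""
    rs, ps = [], []
    for x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y) or len(x) < 3:
            raise ValueError("each pair needs equal lengths >= 3")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("zero-variance vector in correlation")
        r, p = sps.pearsonr(x, y)
        rs.append(float(r))
        ps.append(float(p))
    _, adjusted = bh_fdr(np.array(ps), q=q)
    return list(zip(rs, ps, adjusted.tolist()))


__all__ = [
    "ComparisonResult",
    "EdgeComparison",
    "choose_test",
    "two_sample_t",
    "paired_t",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "compare_samples",
    "bh_fdr",
    "edgewise_compare",
    "correlate_with_fdr",
]
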