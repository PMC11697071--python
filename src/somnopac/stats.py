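"""Normality-gated group comparisons and multiplicity control.

Normality is assessed per group with both the Shapiro–Wilk and the
Anderson–Darling tests; a metric is treated as parametric only when neither
test rejects at the 5% level in any group (disagreement between the two
tests therefore falls to the nonparametric branch — the conservative
choice). Parametric metrics are compared with the Tukey–Kramer HSD,
nonparametric ones with the Steel–Dwass (Dwass–Steel–Critchlow–Fligner)
pairwise rank procedure. Family-wise error across metric families uses the
Holm step-down correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .core import ValidationError, warn

__all__ = [
    "GroupComparison",
    "normality_gate",
    "compare_groups",
    "steel_dwass",
    "holm_bonferroni",
]


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p: float


@dataclass
class GroupComparison:
    """Outcome of one metric's group comparison."""

    metric: str
    test: str  # tukey_kramer_hsd | steel_dwass | ks_two_sample
    gate: str  # parametric | nonparametric
    pairwise: list[PairwiseResult] = field(default_factory=list)

    @property
    def p(self) -> float:
        """Smallest pairwise p (the family is already multiplicity-adjusted
        within the procedure for HSD/Steel–Dwass)."""
        return min(r.p for r in self.pairwise)

    @property
    def statistic(self) -> float:
        best = min(self.pairwise, key=lambda r: r.p)
        return best.statistic


def normality_gate(groups: dict[str, np.ndarray], alpha: float = 0.05) -> str:
    """'parametric' iff Shapiro–Wilk and Anderson–Darling both fail to reject
    normality in every group; groups smaller than 3 force 'nonparametric'."""
    for name, values in groups.items():
        x = np.asarray(values, dtype=float)
        if x.size < 3:
            warn(f"group {name!r} has n={x.size} < 3; treating as nonparametric")
            return "nonparametric"
        if np.ptp(x) == 0:
            return "nonparametric"  # degenerate; Shapiro is undefined
        if sst.shapiro(x).pvalue < alpha:
            return "nonparametric"
        try:
            ad_p = sst.anderson(x, dist="norm", method="interpolate").pvalue
            ad_reject = ad_p < alpha
        except TypeError:  # older scipy: compare against the 5% critical value
            ad = sst.anderson(x, dist="norm")
            crit = ad.critical_values[list(ad.significance_level).index(5.0)]
            ad_reject = ad.statistic > crit
        if ad_reject:
            return "nonparametric"
    return "parametric"


def _tukey(groups: dict[str, np.ndarray]) -> list[PairwiseResult]:
    names = list(groups)
    res = sst.tukey_hsd(*[np.asarray(groups[n], float) for n in names])
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            out.append(
                PairwiseResult(
                    names[i], names[j],
                    float(res.statistic[i, j]), float(res.pvalue[i, j]),
                )
            )
    return out


def steel_dwass(groups: dict[str, np.ndarray]) -> list[PairwiseResult]:
    """Dwass–Steel–Critchlow–Fligner all-pairs rank comparison.

    For each pair, a tie-corrected standardized Mann–Whitney statistic W is
    referred to the studentized range distribution with k groups:
    ``p = P(Q_{k,inf} ≥ |W|·√2)``.
    """
    names = list(groups)
    k = len(names)
    if k < 2:
        raise ValidationError("need at least two groups")
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            x = np.asarray(groups[names[i]], float)
            y = np.asarray(groups[names[j]], float)
            m, n = x.size, y.size
            combined = np.concatenate([x, y])
            ranks = sst.rankdata(combined)
            u = ranks[:m].sum() - m * (m + 1) / 2  # Mann-Whitney U for x
            _, tie_counts = np.unique(combined, return_counts=True)
            nt = m + n
            tie_term = ((tie_counts**3 - tie_counts).sum()) / ((nt) * (nt - 1))
            var = m * n / 12.0 * (nt + 1 - tie_term)
            w = 0.0 if var == 0 else (u - m * n / 2.0) / np.sqrt(var)
            p = float(sst.studentized_range.sf(abs(w) * np.sqrt(2.0), k, np.inf))
            out.append(PairwiseResult(names[i], names[j], float(w), min(p, 1.0)))
    return out


def compare_groups(
    groups: dict[str, np.ndarray],
    gate: str | None = None,
    metric: str = "",
    alpha: float = 0.05,
) -> GroupComparison:
    """Dispatch to Tukey–Kramer HSD or Steel–Dwass based on the normality gate."""
    if len(groups) < 2:
        raise ValidationError("need at least two groups to compare")
    if gate is None:
        gate = normality_gate(groups, alpha)
    if gate == "parametric":
        return GroupComparison(metric, "tukey_kramer_hsd", gate, _tukey(groups))
    return GroupComparison(metric, "steel_dwass", gate, steel_dwass(groups))


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS for distribution-level metrics (e.g. pooled PSD curves)."""
    res = sst.ks_2samp(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def holm_bonferroni(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down correction: (rejection mask, monotone adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, adjusted
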