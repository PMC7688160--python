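"""The study's statistical decision tree.

Every endpoint (hemodynamic, morphometric, dCt) goes through the same
selection rule: groups are parametric only if every group has n >= 7 and
passes the D'Agostino-Pearson omnibus normality test at alpha = 0.05.
Two parametric groups -> Student's t; three or more -> one-way ANOVA with
Tukey's post-hoc. Otherwise Mann-Whitney U, or Kruskal-Wallis with Dunn's
post-hoc. Paired 4-to-6-month change scores use a one-sample t test
(parametric) or the Wilcoxon signed-rank test. All tests are two-sided at
alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Branch",
    "ComparisonSpec",
    "TestPlan",
    "TestResult",
    "assess_normality",
    "select_test",
    "run_test",
    "compare",
    "report",
    "MIN_PARAMETRIC_N",
]

log = logging.getLogger(__name__)

#: groups smaller than this are analysed non-parametrically
MIN_PARAMETRIC_N = 7


class Branch(str, Enum):
    T = "t"
    MANN_WHITNEY = "mann_whitney"
    ANOVA_TUKEY = "anova_tukey"
    KRUSKAL_DUNN = "kruskal_dunn"
    ONE_SAMPLE_T = "one_sample_t"
    WILCOXON_SIGNED_RANK = "wilcoxon_signed_rank"


@dataclass(frozen=True)
class ComparisonSpec:
    """One endpoint comparison: named groups of finite values.

    `paired_change=True` marks a single group of within-subject change
    scores tested against zero.
    """

    endpoint: str
    groups: tuple[tuple[str, np.ndarray], ...]
    paired_change: bool = False
    alpha: float = 0.05

    def __post_init__(self) -> None:
        groups = tuple((str(n), np.asarray(v, dtype=np.float64)) for n, v in self.groups)
        if not groups:
            raise ValueError("at least one group is required")
        for name, vals in groups:
            if vals.size == 0 or not np.all(np.isfinite(vals)):
                raise ValueError(f"group {name!r} must be non-empty and finite")
        if self.paired_change and len(groups) != 1:
            raise ValueError("paired_change expects exactly one group of change scores")
        if not self.paired_change and len(groups) < 2:
            raise ValueError("unpaired comparison needs at least two groups")
        object.__setattr__(self, "groups", groups)


@dataclass(frozen=True)
class TestPlan:
    branch: Branch
    reasons: tuple[str, ...]  # per-group n / normality record


@dataclass(frozen=True)
class TestResult:
    endpoint: str
    branch: Branch
    statistic: float
    p_value: float
    significant: bool
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)  # adjusted p
    group_n: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def assess_normality(values: np.ndarray, alpha: float = 0.05) -> tuple[bool, float]:
    """D'Agostino-Pearson omnibus K^2 test; (passes, p).

    Requires n >= 8 (the skewness z-score is undefined below that);
    smaller groups are routed non-parametric by the sample-size rule
    before this test is consulted. A constant group fails with a warning.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 8:
        raise ValueError("omnibus normality test requires n >= 8")
    if np.ptp(values) == 0:
        log.warning("constant group: normality test degenerate, treating as non-normal")
        return False, 0.0
    stat, p = sps.normaltest(values)
    return bool(p >= alpha), float(p)


def _group_parametric(name: str, vals: np.ndarray, alpha: float) -> tuple[bool, str]:
    n = len(vals)
    if n < MIN_PARAMETRIC_N:
        return False, f"{name}: n={n} < {MIN_PARAMETRIC_N} -> non-parametric"
    try:
        ok, p = assess_normality(vals, alpha)
    except ValueError:
        return False, f"{name}: n={n}, normality not evaluable -> non-parametric"
    verdict = "normal" if ok else "non-normal"
    return ok, f"{name}: n={n}, normality p={p:.3g} ({verdict})"


def select_test(spec: ComparisonSpec) -> TestPlan:
    """Choose the branch of the decision tree for a comparison.

    The comparison is parametric only if every participating group has
    n >= 7 and passes normality; otherwise the whole comparison is
    non-parametric.
    """
    flags, reasons = zip(*(
        _group_parametric(name, vals, spec.alpha) for name, vals in spec.groups
    ))
    parametric = all(flags)
    if spec.paired_change:
        branch = Branch.ONE_SAMPLE_T if parametric else Branch.WILCOXON_SIGNED_RANK
    elif len(spec.groups) == 2:
        branch = Branch.T if parametric else Branch.MANN_WHITNEY
    else:
        branch = Branch.ANOVA_TUKEY if parametric else Branch.KRUSKAL_DUNN
    return TestPlan(branch, tuple(reasons))


def _dunn_posthoc(
    names: list[str], groups: list[np.ndarray], alpha: float
) -> dict[tuple[str, str], float]:
    """Dunn's pairwise rank comparisons after Kruskal-Wallis.

    Standard rank-sum z statistic with tie correction; two-sided p-values
    Bonferroni-adjusted over all pairs.
    """
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    m = len(groups) * (len(groups) - 1) // 2
    out: dict[tuple[str, str], float] = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(
                (n_total * (n_total + 1) / 12.0 - tie_term)
                * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            out[(names[i], names[j])] = min(1.0, p * m)
    return out


def run_test(plan: TestPlan, spec: ComparisonSpec) -> TestResult:
    """Execute the selected branch; post-hoc pairwise comparisons carry
    Tukey (parametric) or Dunn/Bonferroni (non-parametric) adjustment."""
    names = [n for n, _ in spec.groups]
    groups = [v for _, v in spec.groups]
    branch = plan.branch
    pairwise: dict[tuple[str, str], float] = {}

    if branch in (Branch.T, Branch.ANOVA_TUKEY):
        if any(np.ptp(g) == 0 for g in groups):
            log.warning(
                "%s: degenerate variance in a parametric branch; falling back to ranks",
                spec.endpoint,
            )
            branch = Branch.MANN_WHITNEY if branch is Branch.T else Branch.KRUSKAL_DUNN

    if branch is Branch.T:
        stat, p = sps.ttest_ind(groups[0], groups[1], equal_var=True)
    elif branch is Branch.MANN_WHITNEY:
        stat, p = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
    elif branch is Branch.ANOVA_TUKEY:
        stat, p = sps.f_oneway(*groups)
        hsd = sps.tukey_hsd(*groups)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pairwise[(names[i], names[j])] = float(hsd.pvalue[i, j])
    elif branch is Branch.KRUSKAL_DUNN:
        stat, p = sps.kruskal(*groups)
        pairwise = _dunn_posthoc(names, groups, spec.alpha)
    elif branch is Branch.ONE_SAMPLE_T:
        stat, p = sps.ttest_1samp(groups[0], 0.0)
    elif branch is Branch.WILCOXON_SIGNED_RANK:
        stat, p = sps.wilcoxon(groups[0])
    else:  # pragma: no cover
        raise ValueError(f"unknown branch {branch}")

    return TestResult(
        endpoint=spec.endpoint,
        branch=branch,
        statistic=float(stat),
        p_value=float(p),
        significant=bool(p < spec.alpha),
        pairwise=pairwise,
        group_n={n: len(v) for n, v in spec.groups},
    )


def compare(spec: ComparisonSpec) -> TestResult:
    """select_test + run_test in one call."""
    return run_test(select_test(spec), spec)


def report(results: list[TestResult]) -> pd.DataFrame:
    """Tidy study table: one row per comparison."""
    rows = []
    for r in results:
        rows.append(
            {
                "endpoint": r.endpoint,
                "branch": r.branch.value,
                "n": ";".join(f"{k}={v}" for k, v in r.group_n.items()),
                "statistic": r.statistic,
                "p_value": r.p_value,
                "significant": r.significant,
                "pairwise_adjusted": ";".join(
                    f"{a}|{b}={p:.4g}" for (a, b), p in r.pairwise.items()
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "endpoint", "branch", "n", "statistic", "p_value",
            "significant", "pairwise_adjusted",
        ],
    )
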