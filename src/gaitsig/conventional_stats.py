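"""Speed-independent contrast analyses and the a-priori power calculation.

These are the conventional comparisons that ignore the velocity dependence
of gait parameters: normality-gated two-sample tests, multi-group tests
with multiple-comparison correction, a summary-statistics t-test, and an
exact noncentral-t sample-size calculation for a paired design.  They exist
so the velocity-dependent curve comparison can be contrasted against the
conventional approach on the same data.

Routing convention: each sample (or the paired differences) is tested for
normality with the D'Agostino-Pearson omnibus K2 at p < 0.05; normally
distributed data go to t-tests, anything else to rank tests.  The routing
decision is always reported, never silent.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary",
    "TestReport",
    "MultiGroupReport",
    "t_from_summary",
    "compare_unpaired",
    "compare_paired",
    "compare_multi",
    "paired_t_power",
    "paired_t_sample_size",
    "EFFECT_CONVENTIONS",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD and size of one group, as printed in a results table."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass
class TestReport:
    """A single two-group test with its routing record."""

    test: str
    statistic: float
    df: float | None
    p: float
    routing: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "routing": self.routing,
        }


def t_from_summary(a: GroupSummary, b: GroupSummary, paired: bool = False) -> TestReport:
    """Pooled-variance two-sample t-test from printed group summaries.

    Only the unpaired path is possible from summaries (a paired test needs
    the per-pair correlation).  df = n_a + n_b - 2, two-tailed p.
    """
    if paired:
        raise ValueError(
            "paired t-test cannot be computed from group summaries alone"
        )
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    df = a.n + b.n - 2
    return TestReport(
        test="unpaired t (pooled, from summaries)",
        statistic=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
        routing={"source": "summary statistics"},
    )


def _normality_gate(x: np.ndarray, label: str) -> tuple[bool | None, dict]:
    """D'Agostino-Pearson gate; refused (None) below 8 observations."""
    if len(x) < 8:
        return None, {f"normality_p_{label}": None, f"note_{label}": "n < 8, gate refused"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(stats.normaltest(x).pvalue)
    return p >= 0.05, {f"normality_p_{label}": p}


def compare_unpaired(x: Sequence[float], y: Sequence[float]) -> TestReport:
    """Two independent samples: t-test if both pass normality, else Mann-Whitney."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    gx, rx = _normality_gate(x, "x")
    gy, ry = _normality_gate(y, "y")
    routing = {**rx, **ry}
    parametric = bool(gx) and bool(gy) and gx is not None and gy is not None
    routing["route"] = "t-test" if parametric else "rank"
    if parametric:
        res = stats.ttest_ind(x, y, equal_var=True)
        return TestReport(
            "unpaired t (pooled)",
            float(res.statistic),
            float(len(x) + len(y) - 2),
            float(res.pvalue),
            routing,
        )
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return TestReport(
        "Mann-Whitney U", float(res.statistic), None, float(res.pvalue), routing
    )


def compare_paired(x: Sequence[float], y: Sequence[float]) -> TestReport:
    """Paired samples: gate on the differences; t-test or Wilcoxon signed-rank."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
        return TestReport(
            "paired (refused)",
            0.0,
            float(len(d) - 1),
            1.0,
            {"route": "refused", "note": "zero-variance differences"},
        )
    gate, routing = _normality_gate(d, "differences")
    parametric = bool(gate) and gate is not None
    routing["route"] = "t-test" if parametric else "rank"
    if parametric:
        res = stats.ttest_rel(x, y)
        return TestReport(
            "paired t", float(res.statistic), float(len(d) - 1), float(res.pvalue), routing
        )
    res = stats.wilcoxon(x, y)
    return TestReport(
        "Wilcoxon signed-rank", float(res.statistic), None, float(res.pvalue), routing
    )


@dataclass
class MultiGroupReport:
    """Omnibus test plus all pairwise adjusted comparisons."""

    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    posthoc_test: str
    pairwise: list
    routing: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "omnibus_test": self.omnibus_test,
            "omnibus_statistic": self.omnibus_statistic,
            "omnibus_p": self.omnibus_p,
            "posthoc_test": self.posthoc_test,
            "pairwise": self.pairwise,
            "routing": self.routing,
        }


def _holm_sidak_pairwise(groups: list[np.ndarray]) -> list[dict]:
    """Pairwise t comparisons with pooled within-group variance, Holm-Sidak adjusted."""
    k = len(groups)
    ns = [len(g) for g in groups]
    means = [float(np.mean(g)) for g in groups]
    n_total = sum(ns)
    mse = sum(((g - m) ** 2).sum() for g, m in zip(groups, means)) / (n_total - k)
    df = n_total - k
    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    tstats = []
    for i, j in pairs:
        t = (means[i] - means[j]) / np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
        tstats.append(float(t))
        raw.append(float(2.0 * stats.t.sf(abs(t), df)))
    adj = multipletests(raw, method="holm-sidak")[1] if raw else []
    return [
        {
            "groups": (i, j),
            "statistic": tstats[m],
            "p_raw": raw[m],
            "p_adjusted": float(adj[m]),
        }
        for m, (i, j) in enumerate(pairs)
    ]


def _dunn_pairwise(groups: list[np.ndarray]) -> list[dict]:
    """Dunn's rank-sum z comparisons with Sidak-style family correction."""
    k = len(groups)
    ns = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0
    mean_ranks = []
    start = 0
    for sz in ns:
        mean_ranks.append(float(ranks[start : start + sz].mean()))
        start += sz
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / ns[i] + 1.0 / ns[j])
        z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        p_adj = float(min(1.0, 1.0 - (1.0 - min(p_raw, 1.0)) ** m))
        out.append(
            {"groups": (i, j), "statistic": float(z), "p_raw": p_raw, "p_adjusted": p_adj}
        )
    return out


def compare_multi(groups: Sequence[Sequence[float]]) -> MultiGroupReport:
    """Three or more groups with normality-gated routing.

    Normal data: one-way ANOVA with Holm-Sidak pairwise comparisons.
    Otherwise: Kruskal-Wallis with Dunn's multiple comparison test.
    Family-wise level 0.05.  Refused when any group has fewer than 3 values.
    """
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 3:
        raise ValueError("compare_multi requires at least 3 groups")
    if any(len(g) < 3 for g in gs):
        raise ValueError("every group needs at least 3 observations")
    routing = {}
    gates = []
    for idx, g in enumerate(gs):
        gate, r = _normality_gate(g, f"group{idx}")
        routing.update(r)
        gates.append(gate)
    parametric = all(g is True for g in gates)
    routing["route"] = "ANOVA + Holm-Sidak" if parametric else "Kruskal-Wallis + Dunn"
    if parametric:
        stat, p = stats.f_oneway(*gs)
        return MultiGroupReport(
            "one-way ANOVA",
            float(stat),
            float(p),
            "Holm-Sidak",
            _holm_sidak_pairwise(gs),
            routing,
        )
    stat, p = stats.kruskal(*gs)
    return MultiGroupReport(
        "Kruskal-Wallis", float(stat), float(p), "Dunn (Sidak)", _dunn_pairwise(gs), routing
    )


# ---------------------------------------------------------------------------
# power / sample size

#: Mappings from (mean_pre, sd_pre, mean_post, sd_post) to a standardized
#: paired effect size.  The study design that motivates this calculation
#: reports pre/post means with SDs but not the SD of the differences, so the
#: convention is an explicit argument.
EFFECT_CONVENTIONS = ("pooled_sd", "pre_sd", "post_sd", "independent_diff_sd")


def _effect_size(mean_pre, sd_pre, mean_post, sd_post, convention: str) -> float:
    delta = abs(mean_pre - mean_post)
    if convention == "pooled_sd":
        denom = np.sqrt((sd_pre**2 + sd_post**2) / 2.0)
    elif convention == "pre_sd":
        denom = sd_pre
    elif convention == "post_sd":
        denom = sd_post
    elif convention == "independent_diff_sd":
        denom = np.sqrt(sd_pre**2 + sd_post**2)
    else:
        raise ValueError(f"unknown effect convention {convention!r}")
    if denom <= 0:
        raise ValueError("effect-size denominator must be positive")
    return float(delta / denom)


def paired_t_power(n: int, effect: float, alpha: float = 0.05) -> float:
    """Exact two-tailed paired-t power at ``n`` pairs via the noncentral t."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = effect * np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def paired_t_sample_size(
    mean_pre: float,
    sd_pre: float,
    mean_post: float,
    sd_post: float,
    alpha: float = 0.05,
    power: float = 0.95,
    effect_convention: str = "pooled_sd",
    max_n: int = 100000,
) -> int:
    """Smallest n with exact noncentral-t power >= target, two-tailed paired test.

    The effect-size convention maps the four printed summaries to a
    standardized paired effect; the default divides the mean difference by
    the pooled SD of the two summaries.  Zero effect is refused.
    """
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    effect = _effect_size(mean_pre, sd_pre, mean_post, sd_post, effect_convention)
    if effect == 0:
        raise ValueError("zero effect size: required sample size is unbounded")
    for n in range(2, max_n + 1):
        if paired_t_power(n, effect, alpha) >= power:
            return n
    raise ValueError("required sample size exceeds max_n")
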