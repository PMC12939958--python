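"""Statistical procedures used across the pipeline.

Two-sided nonparametric tests throughout: the Kruskal-Wallis omnibus test for
three or more groups, the Wilcoxon rank-sum (Mann-Whitney) test for two, with
Benjamini-Hochberg (default) or Bonferroni correction for gated pairwise
comparisons.  The rank-sum test is exact for small tie-free samples (combined
n <= 20) and otherwise uses the normal approximation with continuity and
midrank tie corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "corrected_pairwise",
]

#: combined-sample-size ceiling for the exact rank-sum null distribution
EXACT_N_MAX = 20


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    group_summaries: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _summaries(groups: Sequence[Sequence[float]], labels: Sequence[str]) -> list[dict]:
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = sps.rankdata(pooled)
    out = []
    offset = 0
    for label, g in zip(labels, groups):
        n = len(g)
        out.append(
            {
                "label": label,
                "n": n,
                "mean": float(np.mean(g)) if n else float("nan"),
                "mean_rank": float(np.mean(ranks[offset : offset + n])) if n else float("nan"),
            }
        )
        offset += n
    return out


def kruskal_wallis(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> TestResult:
    """Kruskal-Wallis H test with midrank tie correction.

    The p-value uses the chi-square approximation with ``k - 1`` degrees of
    freedom.  When every pooled observation is identical the statistic is 0
    and the p-value 1 (ranks carry no information).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    nonempty = [g for g in groups if len(g)]
    if len(nonempty) < 2:
        raise ValueError("kruskal_wallis needs at least 2 non-empty groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(nonempty)
    if np.all(pooled == pooled[0]):
        # all pooled values identical: ranks carry no information
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*nonempty)
    return TestResult(float(h), float(min(p, 1.0)), "kruskal-wallis", _summaries(groups, labels))


def _ranksum_normal_p(w: float, n1: int, n2: int, ties: np.ndarray) -> tuple[float, float]:
    """Two-sided normal-approximation p for rank-sum W with continuity and
    midrank tie corrections.  Returns (z, p)."""
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    tie_term = float(np.sum(ties**3 - ties)) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    delta = w - mu
    # continuity correction shrinks |delta| by 0.5
    adj = max(abs(delta) - 0.5, 0.0)
    z = adj / np.sqrt(var)
    return float(np.sign(delta) * z), float(min(1.0, 2.0 * sps.norm.sf(z)))


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], labels: Sequence[str] = ("a", "b")
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    The reported statistic is the rank sum of the first sample.  Exact
    enumeration is used when the combined sample is tie-free and no larger
    than ``EXACT_N_MAX``; otherwise the tie-corrected normal approximation
    with continuity correction applies.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(np.sum(ranks[: len(a)]))
    _, ties = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(ties > 1))
    if not has_ties and len(pooled) <= EXACT_N_MAX:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        method = "wilcoxon-rank-sum/exact"
    else:
        _, p = _ranksum_normal_p(w, len(a), len(b), ties.astype(float))
        method = "wilcoxon-rank-sum/normal"
    return TestResult(w, min(p, 1.0), method, _summaries([a, b], labels))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def corrected_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    gate: float = 0.05,
    method: str = "bh",
) -> dict:
    """Kruskal-Wallis-gated pairwise rank-sum tests with multiplicity correction.

    Pairwise tests are emitted only when the omnibus p-value falls below
    ``gate``.  ``method`` selects the correction: ``"bh"`` (default) or
    ``"bonferroni"``.
    """
    if method not in ("bh", "bonferroni"):
        raise ValueError(f"unknown correction method {method!r}")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    omnibus = kruskal_wallis(groups, labels)
    out = {"omnibus": omnibus, "gate": gate, "correction": method, "pairwise": []}
    if omnibus.p_value >= gate:
        return out
    pairs = list(combinations(range(len(groups)), 2))
    results = [
        wilcoxon_rank_sum(groups[i], groups[j], labels=(labels[i], labels[j]))
        for i, j in pairs
    ]
    raw = [r.p_value for r in results]
    if method == "bh":
        adj = bh_adjust(raw)
    else:
        adj = np.minimum(1.0, np.asarray(raw) * len(raw))
    for (i, j), res, q in zip(pairs, results, adj):
        out["pairwise"].append(
            {"pair": (labels[i], labels[j]), "result": res, "p_adjusted": float(q)}
        )
    return out
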