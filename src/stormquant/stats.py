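"""Group comparison: Kruskal-Wallis with Dunn's multiple-comparison test.

The unit of analysis is the individual cell (per-cell density or
diameter); groups are experimental conditions.  The Kruskal-Wallis H
statistic uses mid-ranks and the standard tie correction; Dunn's
pairwise z statistics use the tie-corrected rank variance, with
Bonferroni adjustment over all pairs by default (the convention labeled
"Dunn's correction" in common statistics packages), Sidak optionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

__all__ = ["GroupSample", "TestResult", "kruskal_wallis", "dunn_posthoc",
           "significance_stars", "group_report"]


@dataclass(frozen=True)
class GroupSample:
    """Named group of per-cell values (densities in signals/um^2 or
    diameters in nm), optionally with a donor id per value."""

    label: str
    values: np.ndarray
    donors: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size < 1:
            raise ValueError(f"group {self.label!r} has no values")
        object.__setattr__(self, "values", v)
        if self.donors is not None:
            d = np.asarray(self.donors)
            if d.shape != v.shape:
                raise ValueError("donors must align with values")
            object.__setattr__(self, "donors", d)

    def per_donor_medians(self) -> "GroupSample":
        if self.donors is None:
            raise ValueError("no donor ids")
        df = pd.DataFrame({"donor": self.donors, "value": self.values})
        med = df.groupby("donor")["value"].median()
        return GroupSample(self.label, med.to_numpy(), med.index.to_numpy())


@dataclass
class TestResult:
    H: float
    df: int
    p_value: float
    n_total: int
    mean_ranks: dict
    tie_correction: float
    pairwise: list = dc_field(default_factory=list)


def _coerce_groups(groups):
    if isinstance(groups, dict):
        return [GroupSample(k, v) for k, v in groups.items()]
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, GroupSample):
            out.append(g)
        else:
            out.append(GroupSample(f"group{i + 1}", np.asarray(g, dtype=float)))
    return out


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis test across >= 2 groups.

    H = [12 / (N (N+1))] sum_g R_g^2 / n_g - 3 (N+1), divided by
    1 - sum(t^3 - t) / (N^3 - N); p from chi-square with k-1 df.
    Raises when every pooled value is identical (ranks degenerate).
    """
    gs = _coerce_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate([g.values for g in gs])
    N = len(pooled)
    if N < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = rankdata(pooled)
    sizes = [len(g.values) for g in gs]
    bounds = np.cumsum([0] + sizes)
    rank_sums = [ranks[bounds[i]:bounds[i + 1]].sum() for i in range(len(gs))]

    h = 12.0 / (N * (N + 1)) * sum(rs ** 2 / n for rs, n in zip(rank_sums, sizes)) \
        - 3.0 * (N + 1)
    _, t = np.unique(pooled, return_counts=True)
    tie = 1.0 - float(np.sum(t ** 3 - t)) / (N ** 3 - N)
    if tie == 0.0:
        raise ValueError("degenerate ranks: all pooled values are identical")
    h /= tie
    df = len(gs) - 1
    p = float(chi2.sf(h, df))
    mean_ranks = {g.label: rs / n for g, rs, n in zip(gs, rank_sums, sizes)}
    return TestResult(H=float(h), df=df, p_value=p, n_total=N,
                      mean_ranks=mean_ranks, tie_correction=tie)


def dunn_posthoc(groups, correction: str = "bonferroni") -> list:
    """Dunn's pairwise comparisons after Kruskal-Wallis.

    z_ij = (meanrank_i - meanrank_j) / sqrt(S * (1/n_i + 1/n_j)) with
    S = N (N+1) / 12 - sum(t^3 - t) / (12 (N-1)); two-sided normal p,
    adjusted over all m pairs (Bonferroni: min(1, m p); Sidak:
    1 - (1-p)^m).

    Returns a list of dicts (pair, mean-rank difference, z, p, adjusted p).
    """
    if correction not in ("bonferroni", "sidak"):
        raise ValueError("correction must be 'bonferroni' or 'sidak'")
    gs = _coerce_groups(groups)
    pooled = np.concatenate([g.values for g in gs])
    N = len(pooled)
    ranks = rankdata(pooled)
    sizes = [len(g.values) for g in gs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(gs))]
    _, t = np.unique(pooled, return_counts=True)
    S = N * (N + 1) / 12.0 - float(np.sum(t ** 3 - t)) / (12.0 * (N - 1))

    pairs = [(i, j) for i in range(len(gs)) for j in range(i + 1, len(gs))]
    m = len(pairs)
    out = []
    for i, j in pairs:
        diff = mean_ranks[i] - mean_ranks[j]
        se = np.sqrt(S * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = diff / se if se > 0 else 0.0
        p = float(2.0 * norm.sf(abs(z)))
        if correction == "bonferroni":
            p_adj = min(1.0, m * p)
        else:
            p_adj = 1.0 - (1.0 - p) ** m
        out.append({"pair": (gs[i].label, gs[j].label),
                    "mean_rank_diff": float(diff), "z": float(z),
                    "p": p, "p_adjusted": float(p_adj)})
    return out


def significance_stars(p: float) -> str:
    """Convention: ** for p <= 0.01, *** for p <= 0.001, * for p <= 0.05."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def group_report(groups, correction: str = "bonferroni") -> str:
    """Human-readable Kruskal-Wallis + Dunn report."""
    gs = _coerce_groups(groups)
    res = kruskal_wallis(gs)
    pw = dunn_posthoc(gs, correction=correction)
    lines = [f"Kruskal-Wallis: H = {res.H:.3f}, df = {res.df}, "
             f"p = {res.p_value:.3g} (N = {res.n_total})"]
    for g in gs:
        lines.append(f"  {g.label}: n = {len(g.values)}, "
                     f"median = {np.median(g.values):.3g}, "
                     f"mean rank = {res.mean_ranks[g.label]:.2f}")
    lines.append(f"Dunn's pairwise comparisons ({correction}):")
    for rec in pw:
        a, b = rec["pair"]
        lines.append(f"  {a} vs {b}: z = {rec['z']:.3f}, "
                     f"adj. p = {rec['p_adjusted']:.3g} "
                     f"{significance_stars(rec['p_adjusted'])}")
    return "\n".join(lines)
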