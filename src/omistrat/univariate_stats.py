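"""Rank-based two-group and paired screening with FDR control.

Two-group comparisons (survivors vs non-survivors at D1, at D7, and on the
D7/D1 ratio) use the Wilcoxon rank-sum (Mann-Whitney) test; within-group time
trends (D1 vs D7 inside S and inside NS) use the Wilcoxon signed-rank test.
P-values are exact by enumeration for small samples without ties and use the
tie-corrected normal approximation otherwise. Multiplicity is controlled by
the Benjamini-Hochberg step-up procedure, and a feature is called
significant only under the joint rule p < alpha AND q < fdr (defaults 0.05
and 0.15).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import CohortMetadata, OmicsTable
from .preprocessing import RatioTable

__all__ = [
    "COMPARISONS",
    "rank_sum_test",
    "signed_rank_test",
    "bh_fdr",
    "screen",
]

COMPARISONS = (
    "S_vs_NS_at_D1",
    "S_vs_NS_at_D7",
    "S_vs_NS_ratio",
    "D1_vs_D7_within_S",
    "D1_vs_D7_within_NS",
)

#: largest combined sample size for which exact enumeration is used
EXACT_LIMIT = 25


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[~np.isnan(x)]


def rank_sum_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U statistic, p).

    Exact p by enumeration when the combined sample size is <= 25 and there
    are no ties; otherwise the normal approximation with midranks and tie
    correction. Symmetric in its arguments.
    """
    a, b = _clean(values_a), _clean(values_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test: a group is empty after removing missing")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    if no_ties and combined.size <= EXACT_LIMIT:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    if np.unique(combined).size == 1:
        # every observation identical: no evidence either way
        return float(a.size * b.size / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def signed_rank_test(values_d1, values_d7) -> tuple[float, float, str]:
    """Two-sided Wilcoxon signed-rank test on paired D1/D7 values.

    Returns (W statistic, p, trend) where trend is ``'down'`` if the median
    paired difference D7 - D1 is negative, ``'up'`` if positive and
    ``'flat'`` if zero. Pairs with a missing value are removed; zero
    differences are dropped before ranking (the classic Wilcoxon
    convention). Exact p by enumeration of sign patterns for <= 25 nonzero
    untied pairs, normal approximation otherwise.
    """
    d1 = np.asarray(values_d1, dtype=float)
    d7 = np.asarray(values_d7, dtype=float)
    if d1.shape != d7.shape:
        raise ValueError("signed-rank test: unequal numbers of paired values")
    ok = ~(np.isnan(d1) | np.isnan(d7))
    diff = d7[ok] - d1[ok]
    if diff.size == 0:
        raise ValueError("signed-rank test: no complete pairs")
    med = float(np.median(diff))
    trend = "down" if med < 0 else ("up" if med > 0 else "flat")

    nz = diff[diff != 0]
    if nz.size == 0:
        warnings.warn("signed-rank test: all differences are zero", UserWarning)
        return 0.0, 1.0, trend
    no_ties = np.unique(np.abs(nz)).size == nz.size
    method = "exact" if (no_ties and nz.size <= EXACT_LIMIT) else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0)), trend


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j), clipped at
    1; monotone nondecreasing in p and invariant to input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def screen(
    tables: Mapping[tuple[str, str], OmicsTable],
    metadata: CohortMetadata,
    ratios: Mapping[str, RatioTable] | None = None,
    alpha: float = 0.05,
    fdr: float = 0.15,
    fdr_scope: str = "per_family",
) -> pd.DataFrame:
    """Run the five comparison families over every layer present.

    For each layer with D1 and D7 tables: rank-sum S vs NS at each time
    point and signed-rank D1 vs D7 within each group; for each layer with a
    ratio table: rank-sum S vs NS on the D7/D1 ratio. FDR is controlled per
    comparison family per layer by default (``fdr_scope='global'`` pools all
    p-values instead). Output is one row per (layer, feature, comparison),
    sorted by q then p, with ``significant = (p < alpha) & (q < fdr)``.
    """
    if fdr_scope not in ("per_family", "global"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    metadata.require_both_groups()
    s_ids = metadata.group_samples("S")
    ns_ids = metadata.group_samples("NS")

    rows = []
    layers = sorted({layer for layer, _ in tables})
    for layer in layers:
        d1 = tables.get((layer, "D1"))
        d7 = tables.get((layer, "D7"))
        if d1 is None or d7 is None:
            continue
        for feat in d1.feature_ids:
            for tp, tab in (("S_vs_NS_at_D1", d1), ("S_vs_NS_at_D7", d7)):
                u, p = rank_sum_test(
                    tab.values.loc[[s for s in s_ids if s in tab.values.index], feat],
                    tab.values.loc[[s for s in ns_ids if s in tab.values.index], feat],
                )
                rows.append((layer, feat, tp, u, p, ""))
            for comp, ids in (
                ("D1_vs_D7_within_S", s_ids),
                ("D1_vs_D7_within_NS", ns_ids),
            ):
                ids_present = [s for s in ids if s in d1.values.index]
                w, p, trend = signed_rank_test(
                    d1.values.loc[ids_present, feat],
                    d7.values.loc[ids_present, feat],
                )
                rows.append((layer, feat, comp, w, p, trend))
    if ratios:
        for layer, ratio in ratios.items():
            grp = ratio.groups
            for feat in ratio.feature_ids:
                u, p = rank_sum_test(
                    ratio.values.loc[grp == "S", feat],
                    ratio.values.loc[grp == "NS", feat],
                )
                rows.append((layer, feat, "S_vs_NS_ratio", u, p, ""))

    out = pd.DataFrame(
        rows,
        columns=["layer", "feature_id", "comparison", "statistic",
                 "p_two_sided", "trend"],
    )
    out["q_value"] = np.nan
    if len(out):
        if fdr_scope == "global":
            out["q_value"] = bh_fdr(out["p_two_sided"].to_numpy())
        else:
            for (_, _), idx in out.groupby(["layer", "comparison"]).groups.items():
                out.loc[idx, "q_value"] = bh_fdr(
                    out.loc[idx, "p_two_sided"].to_numpy()
                )
    out["significant"] = (out["p_two_sided"] < alpha) & (out["q_value"] < fdr)
    return out.sort_values(
        ["q_value", "p_two_sided"], kind="mergesort"
    ).reset_index(drop=True)
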