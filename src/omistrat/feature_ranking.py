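"""Minimum-redundancy maximum-relevance (mRMR) feature ranking.

mRMR greedily orders features by mutual information (MI) with the binary
outcome (maximum relevance) while penalizing MI with the features already
selected (minimum redundancy). Continuous features are first discretized —
by default into three levels at mean +/- 0.5 standard deviations, the
convention of the original mRMR microarray work — so the plug-in MI
estimate is well defined on the 17-patient scale this pipeline targets.
(At such sample sizes a wider +/- 1 sigma band codes almost every value 0
and the class signal drowns in estimation noise; the alpha multiplier is a
parameter of :class:`DiscretizationRule`.)

The cascade used for multi-omics integration runs mRMR per layer and then
re-ranks pooled shortlists: the top-50 metabolites with the top-50 proteins
(tier 2), then the top-20 of that pool together with all clinical variables
(tier 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import RatioTable

__all__ = [
    "DiscretizationRule",
    "RankedFeatureList",
    "discretize",
    "mutual_information",
    "mrmr_rank",
    "cascade_rank",
]


@dataclass(frozen=True)
class DiscretizationRule:
    """How continuous columns are coded before MI estimation.

    ``ternary_mean_sigma`` codes a value v as -1 if v < mean - alpha*sigma,
    +1 if v > mean + alpha*sigma and 0 otherwise (sigma with denominator
    n-1); ``quantile_bins`` cuts at ``n_bins`` equal-probability quantiles.
    """

    scheme: str = "ternary_mean_sigma"
    alpha: float = 0.5
    n_bins: int = 3

    def __post_init__(self) -> None:
        if self.scheme not in ("ternary_mean_sigma", "quantile_bins"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


DEFAULT_RULE = DiscretizationRule()


def discretize(column, rule: DiscretizationRule = DEFAULT_RULE) -> np.ndarray:
    """Integer-code one continuous column according to ``rule``.

    A constant column yields all-zero codes with a warning (it carries no
    information either way).
    """
    x = np.asarray(column, dtype=float)
    if rule.scheme == "ternary_mean_sigma":
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        if sd == 0.0 or np.isnan(sd):
            warnings.warn("discretize: constant column coded all-zero",
                          UserWarning)
            return np.zeros(x.size, dtype=int)
        m = float(np.mean(x))
        codes = np.zeros(x.size, dtype=int)
        codes[x < m - rule.alpha * sd] = -1
        codes[x > m + rule.alpha * sd] = 1
        return codes
    # quantile bins
    qs = np.quantile(x, np.linspace(0, 1, rule.n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="left").astype(int)


def mutual_information(x_codes, y_codes) -> float:
    """Plug-in mutual information in bits between two integer-coded columns.

    I(X;Y) = sum over observed cells of p(x,y) log2 p(x,y)/(p(x)p(y));
    non-negative, zero for independent codes, symmetric.
    """
    x = np.asarray(x_codes)
    y = np.asarray(y_codes)
    if x.size != y.size:
        raise ValueError("mutual_information: length mismatch")
    if x.size == 0:
        return 0.0
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.zeros((nx, ny))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float((joint[nz] * np.log2(joint[nz] / (px @ py)[nz])).sum())
    return max(mi, 0.0)


@dataclass
class RankedFeatureList:
    """Ordered features with the relevance/redundancy bookkeeping of the
    greedy selection. ``table`` columns: feature, relevance (I(f; class)),
    redundancy (mean MI with the features selected before it) and score
    (the greedy objective at selection time)."""

    table: pd.DataFrame
    criterion: str = "MID"

    @property
    def features(self) -> list[str]:
        return list(self.table["feature"])

    def top(self, k: int) -> list[str]:
        if k > len(self.table):
            warnings.warn(
                f"requested top-{k} of a {len(self.table)}-feature ranking; "
                "using all features",
                UserWarning,
            )
        return self.features[:k]


def mrmr_rank(
    X: pd.DataFrame,
    y,
    k: int | None = None,
    rule: DiscretizationRule = DEFAULT_RULE,
    criterion: str = "MID",
) -> RankedFeatureList:
    """Greedy mRMR ranking of the columns of ``X`` against binary labels.

    Step 1 picks the feature with maximal relevance I(f; class); step t
    picks argmax of relevance minus mean MI with the already-selected set
    (MID) or relevance divided by that mean (MIQ). Ties — detected after
    rounding the objective to 12 decimals, so float summation order cannot
    split a mathematically exact tie — break toward higher relevance, then
    toward earlier column order, making runs reproducible.
    """
    if criterion not in ("MID", "MIQ"):
        raise ValueError(f"unknown criterion {criterion!r}")
    features = list(X.columns)
    if k is None:
        k = len(features)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(features):
        warnings.warn(
            f"k={k} exceeds the {len(features)} available features; ranking all",
            UserWarning,
        )
        k = len(features)
    y = np.asarray(y)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # constant columns
        codes = {f: discretize(X[f].to_numpy(), rule) for f in features}
    relevance = {f: mutual_information(codes[f], y) for f in features}

    selected: list[str] = []
    rows = []
    remaining = list(features)
    pair_mi: dict[tuple[str, str], float] = {}
    red_sum = {f: 0.0 for f in features}

    for step in range(k):
        best, best_key, best_red = None, None, 0.0
        for f in remaining:
            red = red_sum[f] / len(selected) if selected else 0.0
            if criterion == "MID":
                score = relevance[f] - red
            else:
                score = relevance[f] / max(red, 1e-12)
            key = (round(score, 12), round(relevance[f], 12))
            if best is None or key > best_key:
                best, best_key, best_red = f, key, red
        rows.append(
            {
                "feature": best,
                "relevance": relevance[best],
                "redundancy": best_red,
                "score": best_key[0],
            }
        )
        selected.append(best)
        remaining.remove(best)
        for f in remaining:
            mi = mutual_information(codes[f], codes[best])
            pair_mi[(f, best)] = mi
            red_sum[f] += mi

    return RankedFeatureList(table=pd.DataFrame(rows), criterion=criterion)


def cascade_rank(
    ratios: RatioTable,
    y=None,
    sizes: tuple[int, int, int, int] = (50, 50, 20, 17),
    rule: DiscretizationRule = DEFAULT_RULE,
    criterion: str = "MID",
) -> dict[str, RankedFeatureList]:
    """Three-tier cascaded mRMR over a merged multi-layer ratio table.

    * tier 1 — mRMR over the metabolite ratios;
    * tier 2 — mRMR over the pool of the first ``sizes[0]`` ranked
      metabolites and the first ``sizes[1]`` ranked proteins (the protein
      ranking is an independent mRMR run on the protein layer);
    * tier 3 — mRMR over the first ``sizes[2]`` features of tier 2 together
      with up to ``sizes[3]`` clinical variables.

    Shortlist cuts larger than the available feature count fall back to all
    features with a warning. Returns rankings keyed ``tier1``, ``proteins``,
    ``tier2``, ``tier3``.
    """
    if y is None:
        y = ratios.y()
    values = ratios.values
    met = ratios.layer_features("metabolite")
    prot = ratios.layer_features("protein")
    clin = ratios.layer_features("clinical")

    out: dict[str, RankedFeatureList] = {}
    out["tier1"] = mrmr_rank(values[met], y, rule=rule, criterion=criterion)
    out["proteins"] = mrmr_rank(values[prot], y, rule=rule, criterion=criterion)
    pool2 = out["tier1"].top(sizes[0]) + out["proteins"].top(sizes[1])
    out["tier2"] = mrmr_rank(values[pool2], y, rule=rule, criterion=criterion)
    pool3 = out["tier2"].top(sizes[2]) + clin[: sizes[3]]
    out["tier3"] = mrmr_rank(values[pool3], y, rule=rule, criterion=criterion)
    return out
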