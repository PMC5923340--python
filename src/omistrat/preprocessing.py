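"""Feature-retention filters, proteomics normalization, D7/D1 ratios, Z-scores.

The modeling substrate of the whole pipeline is the per-patient D7/D1 ratio
of each feature, which captures a week of evolution after shock diagnosis.
Before ratios are formed, each layer passes layer-specific quality filters:

* metabolites — kept only when missing (non-detectable) in fewer than 20 % of
  values within every outcome group, and when at least 50 % of all measured
  concentrations lie above the assay limit of detection (LOD);
* proteins — kept only when detected in every iTRAQ run, not a contaminant,
  and quantified with at least two unique peptides; raw peak intensities are
  log2-transformed and LOESS-normalized against the per-protein mean global
  intensity across all runs.

Below-LOD metabolite concentrations (including non-detectable peaks) are
imputed at LOD/2 before ratio formation so ratios stay finite; this is a
standard targeted-metabolomics convention and is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohort_io import (
    CohortMetadata,
    CohortValidationError,
    OmicsTable,
    ProteinEvidence,
)

__all__ = [
    "QCReport",
    "RatioTable",
    "filter_metabolites",
    "normalize_proteins",
    "compute_ratios",
    "merge_ratio_tables",
    "zscore",
]

#: machine-readable exclusion reason codes
REASONS = (
    "missingness_rule",
    "lod_rule",
    "evidence_rule",
    "contaminant_rule",
    "zero_denominator",
    "zero_variance",
)


@dataclass
class QCReport:
    """Per-feature retention bookkeeping.

    ``records`` has one row per examined feature with columns ``feature``,
    ``layer``, ``retained`` and ``reasons`` (semicolon-joined codes, empty
    for retained features). Counts always reconcile:
    retained + excluded == total per layer.
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["feature", "layer", "retained", "reasons"]
        )
    )

    def add(self, feature: str, layer: str, retained: bool,
            reasons: Sequence[str] = ()) -> None:
        if not retained and not reasons:
            raise ValueError(f"excluded feature {feature!r} needs >= 1 reason")
        self.records.loc[len(self.records)] = [
            feature, layer, bool(retained), ";".join(reasons)
        ]

    def retained_features(self, layer: str | None = None) -> list[str]:
        r = self.records
        if layer is not None:
            r = r[r["layer"] == layer]
        return list(r.loc[r["retained"], "feature"])

    def excluded(self) -> pd.DataFrame:
        return self.records[~self.records["retained"]].reset_index(drop=True)

    def counts(self) -> pd.DataFrame:
        g = self.records.groupby("layer")["retained"]
        out = pd.DataFrame(
            {"retained": g.sum().astype(int), "excluded": (~self.records[
                "retained"].astype(bool)).groupby(self.records["layer"]).sum(
            ).astype(int)}
        )
        out["total"] = out["retained"] + out["excluded"]
        return out

    @staticmethod
    def merge(*reports: "QCReport") -> "QCReport":
        frames = [r.records for r in reports]
        return QCReport(pd.concat(frames, ignore_index=True))


@dataclass
class RatioTable:
    """Per-patient D7/D1 ratios across one or more layers.

    One row per patient; ``layers`` maps each feature to its omics layer and
    ``groups`` carries the aligned outcome labels.
    """

    values: pd.DataFrame
    layers: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.values.index)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()][0]
            raise CohortValidationError(
                f"ratio table: patient {missing!r} lacks a group label"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def layer_features(self, layer: str) -> list[str]:
        return list(self.layers.index[self.layers == layer])

    def y(self) -> np.ndarray:
        """Binary outcome vector, S = 0, NS = 1."""
        return (self.groups == "NS").to_numpy(dtype=int)


# ----------------------------------------------------------------------
# Metabolite retention filters
# ----------------------------------------------------------------------

def filter_metabolites(
    table_d1: OmicsTable,
    table_d7: OmicsTable,
    metadata: CohortMetadata,
    max_missing_frac: float = 0.20,
    min_above_lod_frac: float | None = 0.50,
) -> tuple[list[str], QCReport]:
    """Apply the two metabolite retention rules.

    A metabolite is retained iff (1) its fraction of missing values is below
    ``max_missing_frac`` within every outcome group (both time points
    pooled), and (2) at least ``min_above_lod_frac`` of all its measured
    concentrations lie above the LOD. Pass ``min_above_lod_frac=None`` to
    disable rule 2 when no LOD mask is available.
    """
    if min_above_lod_frac is not None and (
        table_d1.below_lod_mask is None or table_d7.below_lod_mask is None
    ):
        raise CohortValidationError(
            "LOD rule requires a below-LOD mask on both time points; supply "
            "one or disable the rule with min_above_lod_frac=None"
        )
    features = table_d1.feature_ids
    if features != table_d7.feature_ids:
        raise CohortValidationError("D1 and D7 tables carry different features")

    report = QCReport()
    retained: list[str] = []
    group_samples = {g: metadata.group_samples(g) for g in ("S", "NS")}
    for feat in features:
        reasons = []
        for g, samp in group_samples.items():
            cells = pd.concat(
                [table_d1.values.loc[samp, feat], table_d7.values.loc[samp, feat]]
            )
            if cells.isna().mean() >= max_missing_frac:
                reasons.append("missingness_rule")
                break
        if min_above_lod_frac is not None:
            vals = pd.concat(
                [table_d1.values[feat], table_d7.values[feat]]
            )
            below = pd.concat(
                [table_d1.below_lod_mask[feat], table_d7.below_lod_mask[feat]]
            )
            above = (~below) & vals.notna()
            if above.mean() < min_above_lod_frac:
                reasons.append("lod_rule")
        ok = not reasons
        report.add(feat, "metabolite", ok, reasons)
        if ok:
            retained.append(feat)
    return retained, report


# ----------------------------------------------------------------------
# Proteomics normalization
# ----------------------------------------------------------------------

def normalize_proteins(
    raw_tables: Mapping[str, pd.DataFrame],
    evidence: ProteinEvidence,
    span: float = 0.75,
    reference: str = "per_protein_mean",
) -> tuple[dict[tuple[str, str], OmicsTable], QCReport]:
    """Select, log2-transform and LOESS-normalize raw protein intensities.

    ``raw_tables`` maps time point ('D1'/'D7') to a samples x proteins frame
    of strictly positive raw peak intensities. Proteins are retained iff
    detected in every iTRAQ run, not flagged as contaminant, and quantified
    with at least two unique peptides. Intensities are log2-transformed and,
    per sample, a degree-1 LOESS curve of the sample's deviation from the
    reference intensity (per-protein mean of the log2 intensities across all
    samples of all runs; ``reference='global_scalar'`` uses one grand mean
    instead) is fitted against the reference and subtracted, flattening the
    intensity-dependent trend.
    """
    if evidence.n_batches < 2:
        raise CohortValidationError("LOESS normalization expects >= 2 batches")
    if reference not in ("per_protein_mean", "global_scalar"):
        raise ValueError(f"unknown reference {reference!r}")

    report = QCReport()
    passes = evidence.passes()
    for prot_id, ok in passes.items():
        reasons = []
        if not ok:
            if not evidence.detected.loc[prot_id].all() or (
                evidence.unique_peptides.loc[prot_id] < 2
            ):
                reasons.append("evidence_rule")
            if bool(evidence.is_contaminant.loc[prot_id]):
                reasons.append("contaminant_rule")
        report.add(prot_id, "protein", bool(ok), reasons)
    keep = [p for p in passes.index if passes[p]]

    logs: dict[str, pd.DataFrame] = {}
    for tp, raw in raw_tables.items():
        sub = raw[ [c for c in raw.columns if c in set(keep)] ]
        arr = sub.to_numpy(dtype=float)
        bad = (arr <= 0) & ~np.isnan(arr)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise CohortValidationError(
                f"non-positive raw intensity at time point {tp}, sample "
                f"{sub.index[r]!r}, protein {sub.columns[c]!r}"
            )
        logs[tp] = pd.DataFrame(np.log2(arr), index=sub.index, columns=sub.columns)

    pooled = pd.concat(logs.values(), axis=0)
    ref = pooled.mean(axis=0)  # per-protein mean over all samples of all runs
    if reference == "global_scalar":
        ref = pd.Series(float(pooled.to_numpy().mean()), index=ref.index)

    out: dict[tuple[str, str], OmicsTable] = {}
    ref_arr = ref.to_numpy(dtype=float)
    order = np.argsort(ref_arr)
    for tp, log_tab in logs.items():
        corrected = log_tab.to_numpy(dtype=float).copy()
        for i in range(corrected.shape[0]):
            dev = corrected[i] - ref_arr
            obs = ~np.isnan(dev)
            if obs.sum() >= 10:
                trend = lowess(
                    dev[obs], ref_arr[obs], frac=span, it=2,
                    return_sorted=False,
                )
                corrected[i, obs] = corrected[i, obs] - trend
        out[("protein", tp)] = OmicsTable(
            layer="protein",
            timepoint=tp,
            values=pd.DataFrame(
                corrected, index=log_tab.index, columns=log_tab.columns
            ),
        )
    return out, report


# ----------------------------------------------------------------------
# D7/D1 ratios
# ----------------------------------------------------------------------

def compute_ratios(
    table_d1: OmicsTable,
    table_d7: OmicsTable,
    metadata: CohortMetadata,
    lod_impute: str = "half_lod",
) -> tuple[RatioTable, QCReport]:
    """Per-patient D7/D1 ratio of every feature of one layer.

    For concentration (metabolite) layers, below-LOD cells are imputed at
    LOD/2 before division (``lod_impute='half_lod'``, the default) so the
    ratio stays finite; with ``lod_impute='drop'`` censored cells stay as
    they are and features carrying them survive only if their values are
    usable. Features with a zero or missing denominator after imputation
    are dropped with reason ``zero_denominator`` (missing numerators drop
    the feature with reason ``missingness_rule``); protein log2 intensities
    are linearized (2**x) before division so the result is a true abundance
    ratio.
    """
    if lod_impute not in ("half_lod", "drop"):
        raise ValueError(f"unknown lod_impute {lod_impute!r}")
    s1, s7 = set(table_d1.sample_ids), set(table_d7.sample_ids)
    if s1 != s7:
        odd = sorted(s1.symmetric_difference(s7))[0]
        raise CohortValidationError(
            f"patient {odd!r} is present at only one time point"
        )
    if table_d1.feature_ids != table_d7.feature_ids:
        raise CohortValidationError("D1 and D7 tables carry different features")

    patients = table_d1.sample_ids
    d1 = table_d1.values.copy()
    d7 = table_d7.values.loc[patients].copy()

    if table_d1.value_semantics == "concentration_uM" and lod_impute == "half_lod":
        if table_d1.lod is None:
            raise CohortValidationError(
                "half-LOD imputation requires per-feature LOD values"
            )
        half = table_d1.lod / 2.0
        for tab, src in ((d1, table_d1), (d7, table_d7)):
            if src.below_lod_mask is None:
                continue
            censored = src.below_lod_mask.loc[tab.index]
            for feat in tab.columns:
                col = tab[feat]
                tab[feat] = col.where(~censored[feat], half[feat])

    if table_d1.value_semantics == "log2_intensity":
        d1, d7 = np.exp2(d1), np.exp2(d7)

    report = QCReport()
    kept = []
    for feat in d1.columns:
        denom, numer = d1[feat], d7[feat]
        reasons = []
        if denom.isna().any() or (denom == 0).any():
            reasons.append("zero_denominator")
        if numer.isna().any():
            reasons.append("missingness_rule")
        report.add(feat, table_d1.layer, not reasons, reasons)
        if not reasons:
            kept.append(feat)

    values = d7[kept] / d1[kept]
    ratio = RatioTable(
        values=values,
        layers=pd.Series(table_d1.layer, index=kept),
        groups=metadata.groups.reindex(values.index),
    )
    return ratio, report


def merge_ratio_tables(*tables: RatioTable) -> RatioTable:
    """Column-concatenate ratio tables from several layers over the same
    patients; feature ids must be globally unique."""
    first = tables[0]
    for t in tables[1:]:
        if not t.values.index.equals(first.values.index):
            raise CohortValidationError(
                "ratio tables cover different patient sets"
            )
    values = pd.concat([t.values for t in tables], axis=1)
    if values.columns.duplicated().any():
        dup = values.columns[values.columns.duplicated()][0]
        raise CohortValidationError(f"duplicate feature id {dup!r} across layers")
    layers = pd.concat([t.layers for t in tables])
    return RatioTable(values=values, layers=layers, groups=first.groups)


# ----------------------------------------------------------------------
# Z-score normalization
# ----------------------------------------------------------------------

@dataclass
class ZScoreResult:
    transformed: list[pd.DataFrame]
    mean: pd.Series
    sd: pd.Series
    dropped: list[str]


def zscore(
    train: pd.DataFrame, *apply_to: pd.DataFrame, ddof: int = 1
) -> ZScoreResult:
    """Standardize features using statistics fitted on ``train`` only.

    The same per-feature (mean, sd) — sd with denominator ``n - ddof`` — is
    applied to every additional frame, so no test-set information leaks into
    the scaling. Zero-variance features are dropped with a warning. The
    first element of ``transformed`` is the standardized training frame.
    """
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=ddof)
    dropped = list(sd.index[(sd == 0) | sd.isna()])
    if dropped:
        warnings.warn(
            f"zscore: dropping zero-variance feature(s) {dropped}", UserWarning
        )
    keep = [c for c in train.columns if c not in set(dropped)]
    mean, sd = mean[keep], sd[keep]
    frames = [(train[keep] - mean) / sd]
    for df in apply_to:
        frames.append((df[keep] - mean) / sd)
    return ZScoreResult(transformed=frames, mean=mean, sd=sd, dropped=dropped)
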