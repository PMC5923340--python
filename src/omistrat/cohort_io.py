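"""Data model, validation and TSV readers/writers for longitudinal omics cohorts.

A cohort is a set of wide feature tables (samples x features), one per omics
layer (metabolite, protein, clinical) and per sampling time point (D1, one day
after shock diagnosis; D7, one week after), plus a per-sample metadata table
carrying the 28-day mortality outcome: ``S`` (survivor) or ``NS``
(non-survivor).

Value semantics differ by layer: metabolite tables hold absolute
concentrations (µM, strictly positive where observed), protein tables hold
log2-scale normalized peak intensities, and clinical tables hold variables on
their natural clinical scales.  Missing cells are genuine missing values
(``NaN``), never zero.  Metabolite tables may carry a below-LOD mask flagging
concentrations censored at the assay's limit of detection, together with the
per-feature LOD value.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LAYERS = ("metabolite", "protein", "clinical")
TIMEPOINTS = ("D1", "D7")
GROUPS = ("S", "NS")
VALUE_SEMANTICS = ("concentration_uM", "log2_intensity", "clinical_native")

#: semantics conventionally attached to each layer
LAYER_SEMANTICS = {
    "metabolite": "concentration_uM",
    "protein": "log2_intensity",
    "clinical": "clinical_native",
}


class CohortValidationError(ValueError):
    """A table or metadata object violates a structural invariant."""


class CohortLoadError(CohortValidationError):
    """A file could not be loaded into a valid cohort object."""


def percent(count: int, total: int) -> int:
    """Frequency as an integer percentage, rounded half up.

    ``percent(8, 17) == 47`` — the convention used for all frequency columns
    in cohort summary tables.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))


@dataclass
class OmicsTable:
    """One omics layer at one time point.

    Parameters
    ----------
    layer : {'metabolite', 'protein', 'clinical'}
    timepoint : {'D1', 'D7'}
    values : pandas.DataFrame
        Samples as rows, features as columns. ``NaN`` marks missing.
    value_semantics : {'concentration_uM', 'log2_intensity', 'clinical_native'}
    below_lod_mask : pandas.DataFrame, optional
        Boolean, same shape as ``values``; ``True`` flags a concentration
        below the limit of detection (metabolite layers only).
    lod : pandas.Series, optional
        Per-feature limit of detection on the concentration scale.
    """

    layer: str
    timepoint: str
    values: pd.DataFrame
    value_semantics: str | None = None
    below_lod_mask: pd.DataFrame | None = None
    lod: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise CohortValidationError(f"unknown layer {self.layer!r}")
        if self.timepoint not in TIMEPOINTS:
            raise CohortValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.value_semantics is None:
            self.value_semantics = LAYER_SEMANTICS[self.layer]
        if self.value_semantics not in VALUE_SEMANTICS:
            raise CohortValidationError(
                f"unknown value_semantics {self.value_semantics!r}"
            )
        self.validate()

    # ------------------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise CohortValidationError(
                f"{self.layer}/{self.timepoint}: duplicate sample id {dup!r}"
            )
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise CohortValidationError(
                f"{self.layer}/{self.timepoint}: duplicate feature id {dup!r}"
            )
        if self.below_lod_mask is not None:
            if self.below_lod_mask.shape != self.values.shape:
                raise CohortValidationError(
                    f"{self.layer}/{self.timepoint}: below_lod_mask shape "
                    f"{self.below_lod_mask.shape} != values shape {self.values.shape}"
                )
            self.below_lod_mask = self.below_lod_mask.astype(bool)
            self.below_lod_mask.index = idx
            self.below_lod_mask.columns = cols
        if self.value_semantics == "concentration_uM":
            vals = self.values.to_numpy(dtype=float)
            bad = (vals <= 0) & ~np.isnan(vals)
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise CohortValidationError(
                    f"{self.layer}/{self.timepoint}: non-positive concentration "
                    f"at sample {idx[r]!r}, feature {cols[c]!r}"
                )


@dataclass
class CohortMetadata:
    """Per-sample outcome labels and covariates.

    ``table`` is indexed by sample id and carries at least a ``group`` column
    with values in ``{'S', 'NS'}``; ``batch`` (proteomics iTRAQ run id) and
    per-sample covariates such as age or BMI are optional columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if "group" not in t.columns:
            raise CohortValidationError("metadata lacks a 'group' column")
        if t.index.duplicated().any():
            dup = t.index[t.index.duplicated()][0]
            raise CohortValidationError(f"metadata: duplicate sample id {dup!r}")
        bad = set(t["group"].unique()) - set(GROUPS)
        if bad:
            raise CohortValidationError(
                f"metadata: group label(s) {sorted(bad)!r} outside {{'S','NS'}}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def group_samples(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def require_both_groups(self) -> None:
        for g in GROUPS:
            if not (self.table["group"] == g).any():
                raise CohortValidationError(f"group {g!r} is empty")

    def check_samples(self, table: OmicsTable) -> None:
        missing = set(table.sample_ids) - set(self.table.index)
        if missing:
            raise CohortValidationError(
                f"{table.layer}/{table.timepoint}: sample {sorted(missing)[0]!r} "
                "absent from metadata"
            )


@dataclass
class ProteinEvidence:
    """Identification evidence backing each quantified protein.

    ``detected`` is a boolean proteins x batches frame (one column per iTRAQ
    run), ``unique_peptides`` the count of unique peptides supporting
    quantification and ``is_contaminant`` flags abundant proteins that should
    have been removed by immunodepletion.
    """

    detected: pd.DataFrame
    unique_peptides: pd.Series
    is_contaminant: pd.Series

    def __post_init__(self) -> None:
        if (self.unique_peptides < 0).any():
            raise CohortValidationError("unique_peptides must be >= 0")
        for s in (self.unique_peptides, self.is_contaminant):
            if not s.index.equals(self.detected.index):
                raise CohortValidationError(
                    "evidence fields must share one protein index"
                )

    @property
    def n_batches(self) -> int:
        return self.detected.shape[1]

    def passes(self) -> pd.Series:
        """Proteins meeting all three selection criteria: detected in every
        iTRAQ run, not a contaminant, quantified with >= 2 unique peptides."""
        return (
            self.detected.all(axis=1)
            & ~self.is_contaminant.astype(bool)
            & (self.unique_peptides >= 2)
        )


# ----------------------------------------------------------------------
# TSV round trip
# ----------------------------------------------------------------------

def _provenance_lines(provenance: Mapping[str, object] | None) -> list[str]:
    lines = []
    if provenance:
        for k, v in provenance.items():
            lines.append(f"# {k}={v}")
    return lines


def _write_tsv(path: Path, df: pd.DataFrame, provenance=None, na_rep="") -> None:
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", na_rep=na_rep)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(
    directory: str | Path,
    tables: Iterable[OmicsTable],
    metadata: CohortMetadata,
    evidence: ProteinEvidence | None = None,
    provenance: Mapping[str, object] | None = None,
) -> Path:
    """Write a cohort as one wide TSV per layer per time point plus metadata.

    Missing cells are written as empty fields; below-LOD masks and LOD values
    are written alongside each metabolite table. Every file carries a
    ``#``-prefixed provenance header.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in tables:
        stem = f"{t.layer}_{t.timepoint}"
        _write_tsv(directory / f"{stem}.tsv", t.values, provenance)
        if t.below_lod_mask is not None:
            _write_tsv(
                directory / f"{stem}.below_lod.tsv",
                t.below_lod_mask.astype(int),
                provenance,
            )
        if t.lod is not None:
            _write_tsv(
                directory / f"{t.layer}.lod.tsv", t.lod.to_frame("lod"), provenance
            )
    _write_tsv(directory / "metadata.tsv", metadata.table, provenance)
    if evidence is not None:
        ev = evidence.detected.astype(int).copy()
        ev.columns = [f"detected_{c}" for c in evidence.detected.columns]
        ev["unique_peptides"] = evidence.unique_peptides
        ev["is_contaminant"] = evidence.is_contaminant.astype(int)
        _write_tsv(directory / "protein_evidence.tsv", ev, provenance)
    return directory


def read_cohort(
    directory: str | Path,
) -> tuple[dict[tuple[str, str], OmicsTable], CohortMetadata, ProteinEvidence | None]:
    """Read a cohort written by :func:`write_cohort`.

    Returns the tables keyed ``(layer, timepoint)``, the metadata and, if
    present on disk, the protein evidence. Tables are validated against the
    metadata; errors name the offending file and entity.
    """
    directory = Path(directory)
    meta_path = directory / "metadata.tsv"
    if not meta_path.exists():
        raise CohortLoadError(f"{meta_path}: file not found")
    try:
        metadata = CohortMetadata(_read_tsv(meta_path))
    except CohortValidationError as exc:
        raise CohortLoadError(f"{meta_path}: {exc}") from exc

    tables: dict[tuple[str, str], OmicsTable] = {}
    for layer in LAYERS:
        lod = None
        lod_path = directory / f"{layer}.lod.tsv"
        if lod_path.exists():
            lod = _read_tsv(lod_path)["lod"]
        for tp in TIMEPOINTS:
            path = directory / f"{layer}_{tp}.tsv"
            if not path.exists():
                continue
            values = _read_tsv(path)
            mask = None
            mask_path = directory / f"{layer}_{tp}.below_lod.tsv"
            if mask_path.exists():
                mask = _read_tsv(mask_path).astype(bool)
            try:
                table = OmicsTable(
                    layer=layer,
                    timepoint=tp,
                    values=values,
                    below_lod_mask=mask,
                    lod=lod,
                )
                metadata.check_samples(table)
            except CohortValidationError as exc:
                raise CohortLoadError(f"{path}: {exc}") from exc
            tables[(layer, tp)] = table

    evidence = None
    ev_path = directory / "protein_evidence.tsv"
    if ev_path.exists():
        ev = _read_tsv(ev_path)
        det_cols = [c for c in ev.columns if c.startswith("detected_")]
        detected = ev[det_cols].astype(bool)
        detected.columns = [c[len("detected_"):] for c in det_cols]
        evidence = ProteinEvidence(
            detected=detected,
            unique_peptides=ev["unique_peptides"].astype(int),
            is_contaminant=ev["is_contaminant"].astype(bool),
        )
    return tables, metadata, evidence


# ----------------------------------------------------------------------
# Cohort summary
# ----------------------------------------------------------------------

def outcome_rate_percent(metadata: CohortMetadata) -> int:
    """28-day mortality as an integer percentage of the cohort."""
    n_ns = len(metadata.group_samples("NS"))
    return percent(n_ns, len(metadata.table))


def cohort_summary(
    tables: Sequence[OmicsTable] | Mapping[tuple[str, str], OmicsTable],
    metadata: CohortMetadata,
    stat: str = "mean_sd",
) -> pd.DataFrame:
    """Per-group summary of every variable at every time point.

    ``stat='mean_sd'`` reports ``mean ± SD``; ``stat='median_iqr'`` reports
    ``median (25th, 75th percentile)`` with quartiles by linear interpolation
    (the inclusive convention). The result carries the group sizes and the
    outcome rate in ``DataFrame.attrs``.
    """
    if stat not in ("mean_sd", "median_iqr"):
        raise ValueError(f"unknown stat {stat!r}")
    metadata.require_both_groups()
    if isinstance(tables, Mapping):
        tables = list(tables.values())

    rows = []
    for t in tables:
        for g in GROUPS:
            samp = [s for s in metadata.group_samples(g) if s in t.values.index]
            sub = t.values.loc[samp]
            for feat in t.feature_ids:
                col = sub[feat].dropna().to_numpy(dtype=float)
                if stat == "mean_sd":
                    center = float(np.mean(col)) if col.size else np.nan
                    lo = hi = float(np.std(col, ddof=1)) if col.size > 1 else 0.0
                else:
                    center = float(np.median(col)) if col.size else np.nan
                    lo = float(np.percentile(col, 25)) if col.size else np.nan
                    hi = float(np.percentile(col, 75)) if col.size else np.nan
                rows.append(
                    {
                        "layer": t.layer,
                        "variable": feat,
                        "timepoint": t.timepoint,
                        "group": g,
                        "center": center,
                        "spread_low": lo,
                        "spread_high": hi,
                        "n": int(col.size),
                    }
                )
    summary = pd.DataFrame(rows)
    summary = summary.pivot_table(
        index=["layer", "variable", "timepoint"],
        columns="group",
        values=["center", "spread_low", "spread_high", "n"],
        sort=False,
        aggfunc="first",
    )
    summary.attrs["n_S"] = len(metadata.group_samples("S"))
    summary.attrs["n_NS"] = len(metadata.group_samples("NS"))
    summary.attrs["outcome_rate_percent"] = outcome_rate_percent(metadata)
    summary.attrs["stat"] = stat
    return summary
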