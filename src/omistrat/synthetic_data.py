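"""Synthetic septic-shock cohorts with planted group-discriminative effects.

The generator emulates the statistical structure the downstream analysis
assumes: a small two-group cohort (survivors S / non-survivors NS by 28-day
mortality) sampled at two time points (D1, D7), with

* metabolite absolute concentrations — lognormal, strictly positive, with
  below-LOD censoring and per-group missing-at-random non-detections,
* protein normalized peak intensities — approximately Gaussian on the log2
  scale, acquired in a small number of multiplexed iTRAQ runs ("batches")
  that add a per-run offset,
* clinical variables on their natural scales (e.g. MAP in mmHg),
* block-correlated features via shared latent Gaussian factors (lipid panels
  are strongly correlated in real plasma data), and
* planted effects: for selected features the expected log2(D7/D1) ratio of
  the NS group is shifted relative to the S group, which is exactly the kind
  of signal the D7/D1-ratio pipeline is built to recover.

The default :class:`CohortSpec` reproduces the shape of the reference cohort:
17 patients (9 S, 8 NS), 137 metabolites, 132 proteins, 17 continuous
clinical variables, 6 proteomics batches.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import (
    CohortMetadata,
    OmicsTable,
    ProteinEvidence,
)

__all__ = [
    "METABOLITE_PANEL_COMPOSITION",
    "CLINICAL_VARIABLES",
    "PlantedEffect",
    "CohortSpec",
    "SpecValidationError",
    "metabolite_panel_names",
    "default_retained_panel",
    "generate_cohort",
    "reference_planted_effects",
    "reference_cohort",
    "qc_challenge_cohort",
]


class SpecValidationError(ValueError):
    """A :class:`CohortSpec` field violates its constraint."""


# ----------------------------------------------------------------------
# The targeted panel and the clinical variable set being emulated
# ----------------------------------------------------------------------

#: class composition of the targeted metabolomics assay panel (186 analytes)
METABOLITE_PANEL_COMPOSITION = {
    "amino_acids_and_biogenic_amines": 40,
    "acylcarnitines": 40,
    "glycerophospholipids": 90,
    "sphingomyelins": 15,
    "monosaccharides": 1,
}

_AMINO_ACIDS = [
    "Ala", "Arg", "Asn", "Asp", "Cit", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr",
    "Val",
]
_BIOGENIC_AMINES = [
    "Ac-Orn", "ADMA", "alpha-AAA", "Carnosine", "Creatinine_met", "DOPA",
    "Dopamine", "Histamine", "Kynurenine", "Met-SO", "Nitro-Tyr", "OH-Pro",
    "PEA", "Putrescine", "Sarcosine", "Serotonin", "Spermidine", "Spermine",
    "total DMA",
]

_PC_AA_SPECIES = {
    24: (0, 1, 2, 3), 26: (0, 1, 2, 3), 28: (0, 1, 2, 4), 30: (0, 1, 2, 3),
    32: (0, 1, 2, 3), 34: (1, 2, 3, 4), 36: (1, 2, 3, 6), 38: (3, 4, 5, 6),
    40: (2, 4, 5, 6), 42: (1, 2, 5, 6),
}
_PC_AE_SPECIES = {
    30: (0, 1, 2, 3, 4), 32: (0, 1, 2, 4), 34: (0, 2, 3, 4, 5),
    36: (0, 1, 2, 3), 38: (0, 3, 4, 5, 6), 40: (1, 4, 5, 6),
    42: (1, 2, 3, 5, 7), 44: (3, 4, 5, 6),
}
_LYSO_PC = [
    (14, 0), (16, 0), (16, 1), (17, 0), (18, 0), (18, 1), (18, 2),
    (20, 3), (20, 4), (24, 0), (26, 0), (26, 1), (28, 0), (28, 1),
]
_SPHINGOMYELINS = [
    "SM C16:0", "SM C16:1", "SM C18:0", "SM C18:1", "SM C20:2", "SM C22:3",
    "SM C24:0", "SM C24:1", "SM C26:0", "SM C26:1", "SM OH C14:1",
    "SM OH C16:1", "SM OH C22:1", "SM OH C22:2", "SM OH C24:1",
]


def metabolite_panel_names() -> list[str]:
    """The 186 analyte names of the emulated targeted panel, in panel order."""
    names: list[str] = list(_AMINO_ACIDS) + list(_BIOGENIC_AMINES)
    names += [f"C{n}" for n in range(0, 19)]
    names += [f"C{n}:1" for n in range(2, 19)]
    names += [f"C{n}-OH" for n in (3, 4, 5, 14)]
    names += [f"lysoPC a C{c}:{d}" for c, d in _LYSO_PC]
    names += [f"PC aa C{c}:{d}" for c, ds in _PC_AA_SPECIES.items() for d in ds]
    names += [f"PC ae C{c}:{d}" for c, ds in _PC_AE_SPECIES.items() for d in ds]
    names += list(_SPHINGOMYELINS)
    names += ["H1"]
    assert len(names) == sum(METABOLITE_PANEL_COMPOSITION.values())
    return names


#: the 17 continuous clinical variables entering the integrated models,
#: with a typical septic-shock scale (location, lognormal CV, unit)
CLINICAL_VARIABLES = {
    "Heart Rate": (95.0, 0.15, "bpm"),
    "MAP": (78.0, 0.12, "mmHg"),
    "CVP": (10.0, 0.30, "mmHg"),
    "Urine Output": (2200.0, 0.50, "mL/day"),
    "PEEP": (8.0, 0.30, "cmH2O"),
    "FiO2": (52.0, 0.20, "%"),
    "ScvO2": (76.0, 0.07, "%"),
    "PvCO2": (47.0, 0.08, "mmHg"),
    "PaCO2": (43.0, 0.10, "mmHg"),
    "PaO2": (115.0, 0.30, "mmHg"),
    "PvO2": (44.0, 0.08, "mmHg"),
    "pHa": (7.40, 0.005, "pH"),
    "pHv": (7.37, 0.005, "pH"),
    "Creatinine": (2.2, 0.40, "mg/dL"),
    "Bilirubin": (2.5, 0.60, "mg/dL"),
    "Lactate": (3.2, 0.50, "mmol/L"),
    "Platelets": (80.0, 0.50, "x10^3/mm^3"),
}


# ----------------------------------------------------------------------
# Specification of a synthetic cohort
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEffect:
    """A group-discriminative shift on one feature's D7/D1 log-ratio.

    ``log2_ratio_shift`` is the expected difference, NS minus S, of the
    feature's log2(D7/D1); its sign is the planted direction (negative means
    the feature falls over time in non-survivors relative to survivors).
    """

    feature_id: str
    layer: str
    log2_ratio_shift: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.log2_ratio_shift))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group, two-time-point cohort.

    Defaults reproduce the reference cohort shape: 9 survivors, 8
    non-survivors, 137 metabolites, 132 proteins, 17 clinical variables and
    6 proteomics batches. Noise scales are on the log2-ratio scale.
    """

    n_survivors: int = 9
    n_nonsurvivors: int = 8
    n_metabolites: int = 137
    n_proteins: int = 132
    n_clinical: int = 17
    n_batches: int = 6
    planted_features: tuple[PlantedEffect, ...] = ()
    block_correlation: float = 0.5
    block_size: int = 5
    lod_quantile: float = 0.05
    missing_rate_per_group: float = 0.02
    ratio_noise_sd: float = 0.25
    drift_sd: float = 0.15
    metabolite_log_sd: float = 0.6
    protein_log2_sd: float = 0.5
    batch_offset_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_survivors", "n_nonsurvivors", "n_metabolites",
                     "n_proteins", "n_clinical", "n_batches", "block_size"):
            if int(getattr(self, name)) < 1:
                raise SpecValidationError(f"{name} must be >= 1")
        for name in ("lod_quantile", "missing_rate_per_group"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise SpecValidationError(f"{name} must be in [0, 1)")
        if not (0.0 <= self.block_correlation < 1.0):
            raise SpecValidationError("block_correlation must be in [0, 1)")
        for name in ("ratio_noise_sd", "drift_sd", "metabolite_log_sd",
                     "protein_log2_sd", "batch_offset_sd"):
            if getattr(self, name) < 0:
                raise SpecValidationError(f"{name} must be >= 0")

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)


def _feature_names(spec: CohortSpec) -> dict[str, list[str]]:
    panel = metabolite_panel_names()
    if spec.n_metabolites <= len(panel):
        if spec.n_metabolites == 137:
            met = default_retained_panel()[0]
        else:
            met = panel[: spec.n_metabolites]
    else:
        met = panel + [f"met_{i:04d}" for i in range(len(panel), spec.n_metabolites)]
    prot = [f"prot_{i:04d}" for i in range(spec.n_proteins)]
    clin_names = list(CLINICAL_VARIABLES)
    if spec.n_clinical <= len(clin_names):
        clin = clin_names[: spec.n_clinical]
    else:
        clin = clin_names + [
            f"clin_{i:02d}" for i in range(len(clin_names), spec.n_clinical)
        ]
    return {"metabolite": met, "protein": prot, "clinical": clin}


def _block_noise(rng, n_samples: int, n_features: int, rho: float,
                 block_size: int) -> np.ndarray:
    """Standard-normal features x samples noise with correlation rho within
    consecutive blocks of ``block_size`` features (shared latent factor)."""
    eps = rng.standard_normal((n_features, n_samples))
    if rho <= 0.0:
        return eps
    n_blocks = -(-n_features // block_size)
    g = rng.standard_normal((n_blocks, n_samples))
    shared = np.repeat(g, block_size, axis=0)[:n_features]
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps


def _planted_shift_matrix(spec: CohortSpec, layer: str, features: list[str],
                          is_ns: np.ndarray) -> np.ndarray:
    """Features x samples matrix of log2-ratio shifts applied to NS samples."""
    shift = np.zeros((len(features), is_ns.size))
    index = {f: i for i, f in enumerate(features)}
    for eff in spec.planted_features:
        if eff.layer != layer:
            continue
        if eff.feature_id not in index:
            raise SpecValidationError(
                f"planted_features: feature {eff.feature_id!r} does not exist "
                f"in the generated {layer} layer"
            )
        shift[index[eff.feature_id], is_ns] += eff.log2_ratio_shift
    return shift


def generate_cohort(
    spec: CohortSpec,
) -> tuple[dict[tuple[str, str], OmicsTable], CohortMetadata, ProteinEvidence]:
    """Generate a cohort according to ``spec``; identical seed, identical output.

    Returns the tables keyed ``(layer, timepoint)``, the sample metadata
    (group labels, proteomics batch ids) and protein identification evidence
    (by construction every generated protein passes the evidence criteria;
    tests exercising the evidence filter construct failing evidence
    directly).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = _feature_names(spec)

    n_s, n_ns = spec.n_survivors, spec.n_nonsurvivors
    n = n_s + n_ns
    sample_ids = [f"P{i + 1:02d}" for i in range(n)]
    groups = np.array(["S"] * n_s + ["NS"] * n_ns)
    is_ns = groups == "NS"
    batches = np.array([f"batch{(i % spec.n_batches) + 1}" for i in range(n)])

    meta = CohortMetadata(
        pd.DataFrame(
            {"group": groups, "batch": batches},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    tables: dict[tuple[str, str], OmicsTable] = {}

    # --- metabolites: lognormal concentrations ------------------------
    met = names["metabolite"]
    p_met = len(met)
    log_mu = rng.uniform(np.log(0.05), np.log(200.0), size=p_met)
    z1 = _block_noise(rng, n, p_met, spec.block_correlation, spec.block_size)
    d1_met = np.exp(log_mu[:, None] + spec.metabolite_log_sd * z1)
    drift = rng.normal(0.0, spec.drift_sd, size=p_met)
    znoise = _block_noise(rng, n, p_met, spec.block_correlation, spec.block_size)
    log2_ratio = (
        drift[:, None]
        + spec.ratio_noise_sd * znoise
        + _planted_shift_matrix(spec, "metabolite", met, is_ns)
    )
    d7_met = d1_met * np.exp2(log2_ratio)

    pooled = np.concatenate([d1_met, d7_met], axis=1)
    lod = np.quantile(pooled, spec.lod_quantile, axis=1)
    mask_d1 = d1_met < lod[:, None]
    mask_d7 = d7_met < lod[:, None]

    # per-group completely-at-random non-detections, metabolite layer only
    miss_d1 = np.zeros_like(mask_d1)
    miss_d7 = np.zeros_like(mask_d7)
    for grp_mask in (~is_ns, is_ns):
        for miss in (miss_d1, miss_d7):
            u = rng.random((p_met, int(grp_mask.sum())))
            miss[:, grp_mask] = u < spec.missing_rate_per_group
    d1_met = np.where(miss_d1, np.nan, d1_met)
    d7_met = np.where(miss_d7, np.nan, d7_met)
    mask_d1 &= ~miss_d1
    mask_d7 &= ~miss_d7

    lod_ser = pd.Series(lod, index=met, name="lod")
    for tp, vals, m in (("D1", d1_met, mask_d1), ("D7", d7_met, mask_d7)):
        tables[("metabolite", tp)] = OmicsTable(
            layer="metabolite",
            timepoint=tp,
            values=pd.DataFrame(vals.T, index=sample_ids, columns=met),
            below_lod_mask=pd.DataFrame(m.T, index=sample_ids, columns=met),
            lod=lod_ser,
        )

    # --- proteins: Gaussian log2 intensities with batch offsets -------
    prot = names["protein"]
    p_prot = len(prot)
    base = rng.uniform(12.0, 18.0, size=p_prot)
    z1 = _block_noise(rng, n, p_prot, spec.block_correlation, spec.block_size)
    offsets = rng.normal(0.0, spec.batch_offset_sd, size=spec.n_batches)
    batch_idx = np.array([int(b[5:]) - 1 for b in batches])
    d1_prot = base[:, None] + spec.protein_log2_sd * z1 + offsets[batch_idx][None, :]
    drift = rng.normal(0.0, spec.drift_sd, size=p_prot)
    znoise = _block_noise(rng, n, p_prot, spec.block_correlation, spec.block_size)
    d7_prot = d1_prot + (
        drift[:, None]
        + spec.ratio_noise_sd * znoise
        + _planted_shift_matrix(spec, "protein", prot, is_ns)
    )
    for tp, vals in (("D1", d1_prot), ("D7", d7_prot)):
        tables[("protein", tp)] = OmicsTable(
            layer="protein",
            timepoint=tp,
            values=pd.DataFrame(vals.T, index=sample_ids, columns=prot),
        )

    evidence = ProteinEvidence(
        detected=pd.DataFrame(
            True,
            index=pd.Index(prot, name="protein_id"),
            columns=[f"batch{i + 1}" for i in range(spec.n_batches)],
        ),
        unique_peptides=pd.Series(
            2 + rng.poisson(4.0, size=p_prot), index=prot, name="unique_peptides"
        ),
        is_contaminant=pd.Series(False, index=prot, name="is_contaminant"),
    )

    # --- clinical variables on their natural scales -------------------
    clin = names["clinical"]
    scales = [
        CLINICAL_VARIABLES.get(c, (10.0, 0.30, "a.u."))[:2] for c in clin
    ]
    loc = np.array([s[0] for s in scales])
    cv = np.array([s[1] for s in scales])
    z1 = rng.standard_normal((len(clin), n))
    d1_clin = loc[:, None] * np.exp(cv[:, None] * z1)
    drift = rng.normal(0.0, spec.drift_sd, size=len(clin))
    znoise = rng.standard_normal((len(clin), n))
    log2_ratio = (
        drift[:, None]
        + spec.ratio_noise_sd * znoise
        + _planted_shift_matrix(spec, "clinical", clin, is_ns)
    )
    d7_clin = d1_clin * np.exp2(log2_ratio)
    for tp, vals in (("D1", d1_clin), ("D7", d7_clin)):
        tables[("clinical", tp)] = OmicsTable(
            layer="clinical",
            timepoint=tp,
            values=pd.DataFrame(vals.T, index=sample_ids, columns=clin),
        )

    return tables, meta, evidence


# ----------------------------------------------------------------------
# Presets
# ----------------------------------------------------------------------

def default_retained_panel() -> tuple[list[str], list[str]]:
    """Deterministic split of the 186-analyte panel into the 137 analytes
    the quality filters retain and the 49 they exclude (in the emulation).

    The excluded set never touches the features carrying planted effects in
    the reference preset, so planted signal always survives QC.
    """
    panel = metabolite_panel_names()
    protected = {e.feature_id for e in reference_planted_effects()
                 if e.layer == "metabolite"}
    rng = np.random.default_rng(186)
    candidates = [f for f in panel if f not in protected]
    excluded = set(rng.choice(candidates, size=49, replace=False))
    retained = [f for f in panel if f not in excluded]
    return retained, [f for f in panel if f in excluded]


def reference_planted_effects(shift: float = 0.75) -> tuple[PlantedEffect, ...]:
    """The reference preset's ten planted effects, split across layers.

    The magnitude defaults to three times the generator's log2-ratio noise
    standard deviation (0.25), i.e. a 3-sigma effect; signs follow the kind
    of biology the pipeline targets (falling phosphatidylcholine species and
    complement-like proteins in non-survivors, rising pressures).
    """
    return (
        PlantedEffect("PC aa C42:6", "metabolite", -shift),
        PlantedEffect("PC aa C36:3", "metabolite", -shift),
        PlantedEffect("PC aa C34:3", "metabolite", -shift),
        PlantedEffect("lysoPC a C24:0", "metabolite", -shift),
        PlantedEffect("SM OH C16:1", "metabolite", -shift),
        PlantedEffect("Tyr", "metabolite", +shift),
        PlantedEffect("prot_0007", "protein", -shift),
        PlantedEffect("prot_0021", "protein", -shift),
        PlantedEffect("prot_0042", "protein", +shift),
        PlantedEffect("MAP", "clinical", -shift),
    )


def reference_cohort(
    seed: int,
) -> tuple[dict[tuple[str, str], OmicsTable], CohortMetadata, ProteinEvidence]:
    """Convenience preset mirroring the reference cohort: 9 S + 8 NS
    patients, 137 metabolites, 132 proteins, 17 clinical variables, 6
    proteomics batches, ten 3-sigma planted effects split across layers.

    The preset emulates the post-QC modeling table, where every retained
    metabolite was measured for all patients at both time points:
    non-detection is represented by below-LOD censoring (handled by LOD/2
    imputation at the ratio stage) rather than by missing cells, so the
    per-group missing rate is 0 here. Cohorts exercising the missingness
    filter are produced by :func:`qc_challenge_cohort` or by a custom
    :class:`CohortSpec`.
    """
    spec = CohortSpec(
        planted_features=reference_planted_effects(),
        missing_rate_per_group=0.0,
        seed=seed,
    )
    return generate_cohort(spec)


def qc_challenge_cohort(
    seed: int,
) -> tuple[
    dict[tuple[str, str], OmicsTable],
    CohortMetadata,
    ProteinEvidence,
    dict[str, list[str]],
]:
    """A 186-analyte cohort constructed so that exactly 137 metabolites pass
    the retention filters, with known ground truth.

    Of the 49 analytes built to fail, 25 are given >= 20 % missing values
    within the survivor group (missingness rule) and 24 have more than half
    of all their concentrations pushed below the LOD (LOD rule). Returns the
    tables, metadata, evidence and a truth dict with keys ``retained``,
    ``fail_missing`` and ``fail_lod``.
    """
    retained, excluded = default_retained_panel()
    spec = CohortSpec(
        n_metabolites=186,
        planted_features=reference_planted_effects(),
        lod_quantile=0.0,
        missing_rate_per_group=0.0,
        seed=seed,
    )
    tables, meta, evidence = generate_cohort(spec)

    fail_missing, fail_lod = excluded[:25], excluded[25:]
    s_samples = meta.group_samples("S")[:3]  # 3/9 patients, both time points
    all_samples = meta.sample_ids
    for tp in ("D1", "D7"):
        t = tables[("metabolite", tp)]
        t.values.loc[s_samples, fail_missing] = np.nan
        t.below_lod_mask.loc[s_samples, fail_missing] = False
        # 9/17 patients below LOD at both time points -> 53% of all values
        t.below_lod_mask.loc[all_samples[:9], fail_lod] = True
    truth = {
        "retained": retained,
        "fail_missing": fail_missing,
        "fail_lod": fail_lod,
    }
    return tables, meta, evidence, truth
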